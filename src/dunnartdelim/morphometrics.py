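"""Craniodental / external morphometric analysis pipeline.

The procedure, in the order the driver enforces:

1. drop variables with > 20% missing cells, then individuals with > 15%
   missing over the surviving variables;
2. prune multicollinearity: of any variable pair with |Pearson r| above a
   threshold (default 0.90, pairwise-complete), keep the anchor (fewer
   missing cells; ties by column order) and drop the other, iterating;
3. UPGMA clustering on Euclidean distances of the observed (pre-imputation)
   data;
4. impute the remaining missing cells by chained-equations predictive mean
   matching (PMM);
5. on the completed table: correlation PCA, geometric-mean size and
   log-shape ratios (Mosimann), ANOVA on size, and leave-one-out k-nearest
   neighbor classification per grouping and data flavor.

Univariate per-variable tests follow a Bartlett gate: equal group variances
-> one-way ANOVA with Tukey HSD pairwise comparisons; unequal -> the
Kruskal-Wallis rank test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .distances import DistanceMatrix

__all__ = [
    "MorphoTable",
    "SizeShape",
    "PCAResult",
    "ClassificationResult",
    "UnivariateTestResult",
    "filter_missing",
    "prune_correlated",
    "pmm_impute",
    "univariate_tests",
    "size_and_shape",
    "pca_correlation",
    "euclidean_matrix",
    "upgma_cluster",
    "knn_classify_loo",
    "descriptive_stats",
    "morpho_pipeline",
]


@dataclass
class MorphoTable:
    """Specimens x measurements (mm) with group labels and optional sex.

    ``data`` is a float DataFrame indexed by specimen id; missing cells are
    NaN; present values must be positive (linear measurements).
    """

    data: pd.DataFrame
    groups: pd.Series
    sex: pd.Series | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate variable names")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate specimen ids")
        if (self.data.to_numpy() <= 0).any():
            bad = self.data.columns[(self.data <= 0).any()].tolist()
            raise ValueError(f"non-positive measurements in {bad}")
        self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            raise ValueError("specimens without group label")
        if self.sex is not None:
            self.sex = self.sex.reindex(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def p(self) -> int:
        return self.data.shape[1]

    def missing_fraction(self, axis: int) -> pd.Series:
        return self.data.isna().mean(axis=axis)

    def is_complete(self) -> bool:
        return not self.data.isna().any().any()

    def replace(self, data: pd.DataFrame) -> "MorphoTable":
        return MorphoTable(
            data,
            self.groups.loc[data.index],
            None if self.sex is None else self.sex.loc[data.index],
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "MorphoTable":
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if "id" not in cols or "group" not in cols:
            raise ValueError(f"{path}: need 'id' and 'group' columns")
        df = df.set_index(cols["id"])
        groups = df.pop(cols["group"]).astype(str)
        sex = df.pop(cols["sex"]).astype(str) if "sex" in cols else None
        return cls(df.astype(float), groups, sex)

    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        if self.sex is not None:
            out.insert(1, "sex", self.sex)
        out.to_csv(path, index_label="id")


# ---------------------------------------------------------------------------
# Filtering and imputation


def filter_missing(
    table: MorphoTable, var_thresh: float = 0.20, ind_thresh: float = 0.15
) -> tuple[MorphoTable, list[dict]]:
    """Missing-data filters: variables first, then individuals.

    Variables whose missing fraction exceeds *var_thresh* are removed; then
    individuals whose missing fraction over the surviving variables exceeds
    *ind_thresh* are removed. Returns the filtered table and a removal log
    of ``{"kind", "name", "fraction"}`` entries.
    """
    if not (0 < var_thresh < 1 and 0 < ind_thresh < 1):
        raise ValueError("thresholds must be in (0, 1)")
    log: list[dict] = []
    vfrac = table.missing_fraction(axis=0)
    keep_vars = [v for v in table.data.columns if vfrac[v] <= var_thresh]
    for v in table.data.columns:
        if vfrac[v] > var_thresh:
            log.append({"kind": "variable", "name": v, "fraction": float(vfrac[v])})
    if not keep_vars:
        raise ValueError("all variables removed by missingness filter")
    sub = table.data[keep_vars]
    ifrac = sub.isna().mean(axis=1)
    keep_inds = [i for i in sub.index if ifrac[i] <= ind_thresh]
    for i in sub.index:
        if ifrac[i] > ind_thresh:
            log.append({"kind": "individual", "name": i, "fraction": float(ifrac[i])})
    if not keep_inds:
        raise ValueError("all individuals removed by missingness filter")
    return table.replace(sub.loc[keep_inds]), log


def prune_correlated(
    table: MorphoTable, r_thresh: float = 0.90
) -> tuple[MorphoTable, list[dict]]:
    """Iteratively drop one variable of each highly correlated pair.

    Pearson correlations use pairwise-complete observations. Of the pair
    with the largest |r| above *r_thresh*, the variable with more missing
    cells is dropped (ties by later column order). Repeats until no pair
    exceeds the threshold.
    """
    if table.p < 2:
        raise ValueError("need at least 2 variables")
    data = table.data.copy()
    log: list[dict] = []
    while True:
        corr = data.corr(method="pearson").abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.isna().all().all() or corr.max().max() <= r_thresh:
            break
        # largest |r| pair; lexicographic tie-break on names
        best = None
        cols = list(data.columns)
        for a, b in itertools.combinations(cols, 2):
            r = corr.loc[a, b]
            if pd.isna(r) or r <= r_thresh:
                continue
            key = (-r, a, b)
            if best is None or key < best[0]:
                best = (key, a, b)
        if best is None:
            break
        _, a, b = best
        na, nb = data[a].isna().sum(), data[b].isna().sum()
        if na < nb or (na == nb and cols.index(a) < cols.index(b)):
            anchor, drop = a, b
        else:
            anchor, drop = b, a
        log.append(
            {"kind": "variable", "name": drop, "anchor": anchor,
             "r": float(data[anchor].corr(data[drop]))}
        )
        data = data.drop(columns=[drop])
        if data.shape[1] == 1:
            break
    return table.replace(data), log


def pmm_impute(
    table: MorphoTable, donors: int = 5, iterations: int = 50, seed: int = 0
) -> MorphoTable:
    """Chained-equations predictive mean matching.

    Missing cells start at column means. Each iteration visits every
    incomplete variable in column order, regresses it (ordinary least
    squares with intercept) on all other variables over the rows where it
    is observed, predicts all rows, and replaces each missing cell with the
    observed value of one of the *donors* observed rows whose predictions
    are closest, sampled uniformly with the seeded generator. A single
    completed table is returned (single imputation; seed recorded upstream).
    """
    X = table.data.to_numpy(dtype=float).copy()
    mask = np.isnan(X)
    if not mask.any():
        return table
    n_complete = (~mask).sum(axis=0)
    too_few = [
        v for v, c in zip(table.data.columns, n_complete) if c < donors
    ]
    if too_few:
        raise ValueError(f"variables with < {donors} complete cases: {too_few}")
    rng = np.random.default_rng(seed)
    col_means = np.nanmean(X, axis=0)
    for j in range(X.shape[1]):
        X[mask[:, j], j] = col_means[j]
    incomplete = [j for j in range(X.shape[1]) if mask[:, j].any()]
    for _ in range(iterations):
        for j in incomplete:
            obs = ~mask[:, j]
            others = [k for k in range(X.shape[1]) if k != j]
            A = np.column_stack([np.ones(X.shape[0]), X[:, others]])
            coef, *_ = np.linalg.lstsq(A[obs], X[obs, j], rcond=None)
            pred = A @ coef
            obs_idx = np.flatnonzero(obs)
            for i in np.flatnonzero(mask[:, j]):
                gaps = np.abs(pred[obs_idx] - pred[i])
                pool = obs_idx[np.argsort(gaps, kind="stable")[:donors]]
                donor = pool[rng.integers(len(pool))]
                X[i, j] = X[donor, j]
    return table.replace(
        pd.DataFrame(X, index=table.data.index, columns=table.data.columns)
    )


# ---------------------------------------------------------------------------
# Univariate tests


@dataclass
class UnivariateTestResult:
    variable: str
    test: str  # "anova" | "kruskal_wallis" | "na"
    statistic: float
    pvalue: float
    bartlett_statistic: float
    bartlett_pvalue: float
    tukey_pvalues: dict[tuple[str, str], float] = field(default_factory=dict)
    note: str = ""


def univariate_tests(
    table: MorphoTable, alpha_bartlett: float = 0.05
) -> list[UnivariateTestResult]:
    """Per-variable group comparison with a Bartlett variance gate.

    Bartlett p >= alpha: one-way ANOVA + Tukey HSD pairwise p-values.
    Bartlett p < alpha: Kruskal-Wallis (no Tukey). Degenerate variables
    (a group with < 2 observed values) yield an ``"na"`` entry.
    """
    labels = [g for g in pd.unique(table.groups)]
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    out = []
    for v in table.data.columns:
        samples = [
            table.data.loc[table.groups == g, v].dropna().to_numpy() for g in labels
        ]
        if any(len(s) < 2 for s in samples):
            out.append(
                UnivariateTestResult(v, "na", math.nan, math.nan, math.nan,
                                     math.nan, note="group with < 2 observations")
            )
            continue
        bstat, bp = stats.bartlett(*samples)
        if bp >= alpha_bartlett:
            fstat, fp = stats.f_oneway(*samples)
            res = stats.tukey_hsd(*samples)
            tk = {
                (labels[i], labels[j]): float(res.pvalue[i, j])
                for i, j in itertools.combinations(range(len(labels)), 2)
            }
            out.append(
                UnivariateTestResult(v, "anova", float(fstat), float(fp),
                                     float(bstat), float(bp), tk)
            )
        else:
            kstat, kp = stats.kruskal(*samples)
            out.append(
                UnivariateTestResult(v, "kruskal_wallis", float(kstat), float(kp),
                                     float(bstat), float(bp),
                                     note="unequal variances")
            )
    return out


def univariate_frame(results: list[UnivariateTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "variable": r.variable, "test": r.test, "statistic": r.statistic,
            "pvalue": r.pvalue, "bartlett_statistic": r.bartlett_statistic,
            "bartlett_pvalue": r.bartlett_pvalue, "note": r.note,
        }
        for (a, b), p in r.tukey_pvalues.items():
            row[f"tukey_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Size and shape


@dataclass
class SizeShape:
    """Mosimann decomposition: geometric-mean size and log-shape ratios."""

    gm: pd.Series  # per-specimen geometric mean (size proxy)
    shape: pd.DataFrame  # log(x_ij / gm_i); rows sum to zero


def size_and_shape(table: MorphoTable) -> SizeShape:
    """Geometric-mean size proxy and log-shape ratios per specimen.

    Requires a complete, positive table. Each shape vector sums to zero,
    and multiplying a specimen's row by c > 0 leaves it unchanged.
    """
    if not table.is_complete():
        raise ValueError("size_and_shape requires a complete table")
    X = table.data.to_numpy(dtype=float)
    logX = np.log(X)
    loggm = logX.mean(axis=1)
    gm = pd.Series(np.exp(loggm), index=table.data.index, name="gm")
    shape = pd.DataFrame(
        logX - loggm[:, None], index=table.data.index, columns=table.data.columns
    )
    return SizeShape(gm, shape)


# ---------------------------------------------------------------------------
# Ordination and clustering


@dataclass
class PCAResult:
    scores: pd.DataFrame  # specimens x PCs
    loadings: pd.DataFrame  # variables x PCs
    variance_fractions: np.ndarray


def pca_correlation(data: pd.DataFrame) -> PCAResult:
    """PCA on the Pearson correlation matrix (standardized variables).

    Components are ordered by decreasing variance fraction; each loading
    vector's sign is fixed so its largest-magnitude entry is positive.
    """
    if data.isna().any().any():
        raise ValueError("PCA requires a complete table")
    sd = data.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant variables: {constant}")
    Z = (data - data.mean()) / sd
    C = np.corrcoef(data.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    for k in range(evecs.shape[1]):
        pivot = np.argmax(np.abs(evecs[:, k]))
        if evecs[pivot, k] < 0:
            evecs[:, k] *= -1
    pcs = [f"PC{i + 1}" for i in range(len(evals))]
    scores = pd.DataFrame(Z.to_numpy() @ evecs, index=data.index, columns=pcs)
    loadings = pd.DataFrame(evecs, index=data.columns, columns=pcs)
    return PCAResult(scores, loadings, evals / evals.sum())


def euclidean_matrix(data: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between specimens.

    Missing cells are handled pairwise-complete with rescaling by the
    fraction of usable variables: d = sqrt(p/m * sum over the m jointly
    observed variables), the convention of common statistical software.
    A pair with no jointly observed variable is an error.
    """
    X = data.to_numpy(dtype=float)
    n, p = X.shape
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = ~np.isnan(X[i]) & ~np.isnan(X[j])
        m = int(both.sum())
        if m == 0:
            raise ValueError(
                f"no shared observed variables for {data.index[i]!r} and "
                f"{data.index[j]!r}"
            )
        d = math.sqrt(p / m * float(((X[i, both] - X[j, both]) ** 2).sum()))
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(tuple(str(i) for i in data.index), vals, "euclidean")


def upgma_cluster(dist: DistanceMatrix) -> dendropy.Tree:
    """UPGMA (average-linkage) dendrogram as an ultrametric rooted tree.

    Node heights are half the merging average distance, so tip-to-tip
    patristic distance through the shallowest shared ancestor equals the
    average-linkage merge distance.
    """
    n = dist.n
    if np.isnan(dist.values).any():
        raise ValueError("complete distance matrix required")
    condensed = dist.values[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="average")
    tns = dendropy.TaxonNamespace(list(dist.labels))
    nodes: dict[int, tuple[dendropy.Node, float]] = {
        i: (dendropy.Node(taxon=tns.get_taxon(lab)), 0.0)
        for i, lab in enumerate(dist.labels)
    }
    for k, (a, b, d, _) in enumerate(Z):
        height = d / 2.0
        parent = dendropy.Node()
        for child_id in (int(a), int(b)):
            child, ch = nodes.pop(child_id)
            parent.add_child(child)
            child.edge.length = max(height - ch, 0.0)
        nodes[n + k] = (parent, height)
    (root, _), = nodes.values()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Classification


@dataclass
class ClassificationResult:
    k: int
    per_group: pd.DataFrame  # group, n, percent_correct
    overall_percent: float
    predicted: pd.Series

    def __post_init__(self) -> None:
        w = (self.per_group.n * self.per_group.percent_correct).sum()
        if not math.isclose(self.overall_percent, w / self.per_group.n.sum(),
                            abs_tol=1e-8):
            raise ValueError("overall accuracy is not the weighted group mean")


def _loo_predict(D: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    n = len(labels)
    pred = np.empty(n, dtype=object)
    for i in range(n):
        row = D[i].copy()
        row[i] = np.inf
        order = np.argsort(row, kind="stable")
        neigh = labels[order[:k]]
        uniq, counts = np.unique(neigh, return_counts=True)
        top = counts.max()
        winners = uniq[counts == top]
        pred[i] = winners[0] if len(winners) == 1 else labels[order[0]]
    return pred


def knn_classify_loo(
    data: pd.DataFrame,
    labels: pd.Series,
    k: int | str = "auto",
    standardize: bool = True,
) -> ClassificationResult:
    """Leave-one-out k-nearest-neighbor classification.

    Euclidean distances on optionally standardized variables; majority
    vote among the k nearest, with voting ties broken by the single
    nearest neighbor's label. ``k="auto"`` picks the odd k in 1..15
    (k < n) maximizing LOO overall accuracy, smallest k on ties; the
    chosen k is always reported.
    """
    if data.isna().any().any():
        raise ValueError("complete table required")
    labels = labels.reindex(data.index)
    if labels.nunique() < 2:
        raise ValueError("need >= 2 groups")
    X = data.to_numpy(dtype=float)
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    sq = (X**2).sum(axis=1)
    D = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0))
    lab = labels.to_numpy()
    n = len(lab)
    if isinstance(k, str):
        if k != "auto":
            raise ValueError("k must be an integer or 'auto'")
        candidates = [kk for kk in range(1, 16, 2) if kk < n]
        accs = [
            (float((_loo_predict(D, lab, kk) == lab).mean()), -kk) for kk in candidates
        ]
        k = -max(accs)[1]
    else:
        if k >= n:
            raise ValueError("k must be < number of specimens")
    pred = _loo_predict(D, lab, int(k))
    correct = pred == lab
    rows = []
    for g in pd.unique(lab):
        sel = lab == g
        rows.append(
            {"group": g, "n": int(sel.sum()),
             "percent_correct": 100.0 * float(correct[sel].mean())}
        )
    per_group = pd.DataFrame(rows)
    overall = 100.0 * float(correct.mean())
    return ClassificationResult(
        int(k), per_group, overall, pd.Series(pred, index=data.index, name="predicted")
    )


# ---------------------------------------------------------------------------
# Descriptive statistics


def descriptive_stats(table: MorphoTable, by_sex: bool = False) -> pd.DataFrame:
    """Per-group (optionally per-sex) n, mean, SD, min, max per variable.

    Missing cells are excluded per cell; SD is NaN-flagged for n = 1.
    """
    keys = [table.groups]
    names = ["group"]
    if by_sex:
        if table.sex is None:
            raise ValueError("no sex column available")
        keys.append(table.sex)
        names.append("sex")
    rows = []
    for key, sub in table.data.groupby(keys):
        if not isinstance(key, tuple):
            key = (key,)
        for v in table.data.columns:
            col = sub[v].dropna()
            rows.append(
                {
                    **dict(zip(names, key)),
                    "variable": v,
                    "n": int(len(col)),
                    "mean": float(col.mean()) if len(col) else math.nan,
                    "sd": float(col.std(ddof=1)) if len(col) > 1 else math.nan,
                    "min": float(col.min()) if len(col) else math.nan,
                    "max": float(col.max()) if len(col) else math.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Driver


@dataclass
class MorphoPipelineResult:
    filtered: MorphoTable
    removal_log: list[dict]
    pruned: MorphoTable
    prune_log: list[dict]
    dendrogram: dendropy.Tree
    imputed: MorphoTable
    univariate: list[UnivariateTestResult]
    pca_raw: PCAResult
    size_shape: SizeShape
    pca_shape: PCAResult
    size_tests: UnivariateTestResult
    classification_raw: ClassificationResult
    classification_shape: ClassificationResult
    classification_clade_raw: ClassificationResult | None
    classification_clade_shape: ClassificationResult | None
    descriptives: pd.DataFrame


def morpho_pipeline(
    table: MorphoTable,
    var_thresh: float = 0.20,
    ind_thresh: float = 0.15,
    r_thresh: float = 0.90,
    donors: int = 5,
    iterations: int = 50,
    seed: int = 0,
    k: int | str = "auto",
    clade_labels: pd.Series | None = None,
) -> MorphoPipelineResult:
    """Run the full morphometric procedure in its fixed order.

    ``clade_labels`` optionally maps specimens to genetic clades for the
    clade-level classification comparison; PCA and classification use the
    imputed table throughout.
    """
    filtered, removal_log = filter_missing(table, var_thresh, ind_thresh)
    pruned, prune_log = prune_correlated(filtered, r_thresh)
    dendrogram = upgma_cluster(euclidean_matrix(pruned.data))
    imputed = pmm_impute(pruned, donors=donors, iterations=iterations, seed=seed)
    uni = univariate_tests(imputed)
    pca_raw = pca_correlation(imputed.data)
    ss = size_and_shape(imputed)
    pca_shape = pca_correlation(ss.shape)
    size_table = MorphoTable(ss.gm.to_frame("gm"), imputed.groups, imputed.sex)
    size_tests = univariate_tests(size_table)[0]
    cls_raw = knn_classify_loo(imputed.data, imputed.groups, k=k)
    cls_shape = knn_classify_loo(ss.shape, imputed.groups, k=k)
    cls_clade_raw = cls_clade_shape = None
    if clade_labels is not None:
        clades = clade_labels.reindex(imputed.data.index)
        if clades.isna().any():
            raise ValueError("clade labels missing for some specimens")
        cls_clade_raw = knn_classify_loo(imputed.data, clades, k=k)
        cls_clade_shape = knn_classify_loo(ss.shape, clades, k=k)
    return MorphoPipelineResult(
        filtered, removal_log, pruned, prune_log, dendrogram, imputed, uni,
        pca_raw, ss, pca_shape, size_tests, cls_raw, cls_shape,
        cls_clade_raw, cls_clade_shape, descriptive_stats(table),
    )
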