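"""Synthetic sequence alignments and morphometric tables.

The generators reproduce the statistical structure the analysis assumes,
so that every pipeline stage can be exercised without real data:

* **Sequences** evolve site-independently under the Kimura two-parameter
  substitution process along an ultrametric species tree of group
  ancestors (branch lengths in My), with a star genealogy of equal-length
  tip branches within each group. The substitution rate is calibrated as
  *pairwise* percent divergence per My (default 2.1), so the expected K2P
  distance between two samples whose lineages split t My ago is
  rate x t percent — the same convention the dating module inverts.
* **Morphometrics** are multiplicative: measurement x_ij = base mean of
  variable j x group size factor x individual lognormal size deviate x
  per-cell lognormal noise, plus optional near-duplicate clone variables
  (for the collinearity filter) and missing-completely-at-random cells.

All outputs are deterministic for a fixed seed and config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .morphometrics import MorphoTable
from .seqio import (
    Alignment,
    GroupMap,
    read_newick,
    write_fasta_alignment,
    write_group_map,
)

__all__ = [
    "SeqSimConfig",
    "MorphoSimConfig",
    "simulate_alignment",
    "simulate_morphotable",
    "write_fixture_set",
]

_BASES = "AGCT"  # codes 0..3; purines first so code>>1 gives the class


@dataclass
class SeqSimConfig:
    """Configuration for the K2P sequence simulator.

    ``species_tree`` is an ultrametric Newick string over the group labels
    with branch lengths in My; each leaf branch ends at the group ancestor,
    which sits ``within_group_time`` My before the present. ``kappa`` is
    the transition/transversion *rate* ratio (alpha/beta).
    """

    groups: list[tuple[str, int]]
    species_tree: str
    pairwise_rate: float = 2.1  # percent divergence per My, per pair
    within_group_time: float = 0.3  # My
    length: int = 1000
    kappa: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1 or self.kappa <= 0 or self.pairwise_rate <= 0:
            raise ValueError("invalid simulation config")
        if self.within_group_time < 0:
            raise ValueError("times must be >= 0")


def _k2p_step(states: np.ndarray, t: float, alpha: float, beta: float,
              rng: np.random.Generator) -> np.ndarray:
    """Evolve state codes for duration t under K2P (closed-form kernel)."""
    if t == 0:
        return states.copy()
    e4b = math.exp(-4.0 * beta * t)
    e2ab = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    q_tv = 0.5 - 0.5 * e4b  # total over both transversion targets
    u = rng.random(states.shape)
    out = states.copy()
    ts = u < p_ts
    tv = (u >= p_ts) & (u < p_ts + q_tv)
    out[ts] ^= 1  # transition partner (A<->G, C<->T)
    which = rng.integers(2, 3 + 1, size=int(tv.sum()))  # xor with 2 or 3
    out[tv] ^= which.astype(states.dtype)
    return out


def simulate_alignment(
    cfg: SeqSimConfig,
) -> tuple[Alignment, GroupMap, dict]:
    """Simulate one locus; returns alignment, group map, and true params."""
    tree = read_newick(cfg.species_tree, is_string=True)
    tree_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    want = {g for g, _ in cfg.groups}
    if tree_labels != want:
        raise ValueError(
            f"species tree labels {sorted(tree_labels)} do not match groups "
            f"{sorted(want)}"
        )
    n_by_group = dict(cfg.groups)
    rng = np.random.default_rng(cfg.seed)
    # per-lineage rate so that pairwise divergence accrues at pairwise_rate
    mu = (cfg.pairwise_rate / 100.0) / 2.0
    beta = mu / (cfg.kappa + 2.0)
    alpha = mu * cfg.kappa / (cfg.kappa + 2.0)
    root_states = rng.integers(0, 4, size=cfg.length).astype(np.uint8)
    states: dict = {tree.seed_node: root_states}
    records: list[tuple[str, str]] = []
    assignments: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        if nd is not tree.seed_node:
            t = nd.edge.length or 0.0
            states[nd] = _k2p_step(states[nd.parent_node], t, alpha, beta, rng)
        if nd.is_leaf():
            label = nd.taxon.label
            for i in range(n_by_group[label]):
                tip = _k2p_step(states[nd], cfg.within_group_time, alpha, beta, rng)
                rid = f"{label}_{i + 1:02d}"
                records.append((rid, "".join(_BASES[c] for c in tip)))
                assignments[rid] = label
    aln = Alignment("sim", tuple(records))
    truth = {
        "pairwise_rate": cfg.pairwise_rate,
        "within_group_time": cfg.within_group_time,
        "kappa": cfg.kappa,
        "length": cfg.length,
        "seed": cfg.seed,
        "species_tree": cfg.species_tree,
    }
    return aln, GroupMap(assignments), truth


@dataclass
class MorphoSimConfig:
    """Configuration for the multiplicative morphometric simulator.

    ``groups`` holds (label, n, size_factor). ``cv_size`` is the spread of
    the per-individual size deviate, ``cv_noise`` the per-cell measurement
    noise, both as coefficients of variation of a lognormal.
    """

    groups: list[tuple[str, int, float]]
    variable_base_means: list[float]
    variable_names: list[str] | None = None
    cv_noise: float = 0.03
    cv_size: float = 0.03
    missing_rate: float = 0.0
    n_correlated_clones: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sf <= 0 for _, _, sf in self.groups):
            raise ValueError("size factors must be > 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.variable_names is None:
            self.variable_names = [
                f"V{j + 1:02d}" for j in range(len(self.variable_base_means))
            ]
        if len(self.variable_names) != len(self.variable_base_means):
            raise ValueError("variable names/means length mismatch")


def _lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_morphotable(cfg: MorphoSimConfig) -> tuple[MorphoTable, dict]:
    """Simulate a measurement table; returns the table and true params."""
    rng = np.random.default_rng(cfg.seed)
    base = np.asarray(cfg.variable_base_means, dtype=float)
    p = len(base)
    rows, ids, labels = [], [], []
    for label, n, sf in cfg.groups:
        size_dev = _lognormal(rng, cfg.cv_size, n)
        noise = _lognormal(rng, cfg.cv_noise, (n, p))
        block = base[None, :] * sf * size_dev[:, None] * noise
        rows.append(block)
        ids.extend(f"{label}_{i + 1:02d}" for i in range(n))
        labels.extend([label] * n)
    X = np.vstack(rows)
    names = list(cfg.variable_names)
    # near-duplicate clones of the first variables (0.5% multiplicative jitter)
    for c in range(cfg.n_correlated_clones):
        src = c % p
        clone = X[:, src] * _lognormal(rng, 0.005, X.shape[0])
        X = np.column_stack([X, clone])
        names.append(f"{cfg.variable_names[src]}_clone{c + 1}")
    df = pd.DataFrame(X, index=ids, columns=names)
    if cfg.missing_rate > 0:
        mask = rng.random(df.shape) < cfg.missing_rate
        df = df.mask(mask)
    table = MorphoTable(df, pd.Series(labels, index=ids, name="group"))
    truth = {
        "groups": [list(g) for g in cfg.groups],
        "cv_noise": cfg.cv_noise,
        "cv_size": cfg.cv_size,
        "missing_rate": cfg.missing_rate,
        "seed": cfg.seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Canonical fixture study

#: Ultrametric species tree (My) for the canonical fixture: a deep 3.9-My
#: split between a western clade (WA+NT, split 0.6 My) and an eastern clade
#: (Qld+PNG, split 0.6 My), plus a distant outgroup at 14 My. Group
#: ancestors sit 0.3 My before the present (the within-group star depth).
FIXTURE_TREE = (
    "(((WA:0.3,NT:0.3):3.3,(Qld:0.3,PNG:0.3):3.3):10.1,OUT:13.7);"
)
FIXTURE_GROUPS = [("WA", 7), ("NT", 7), ("Qld", 7), ("PNG", 7), ("OUT", 2)]

#: Base means roughly matching adult dunnart cranial measurements in mm.
FIXTURE_MEANS = [24.7, 8.8, 9.8, 5.8, 1.7, 2.5, 6.8, 5.5, 15.5, 2.5]
FIXTURE_VARS = ["BL", "FL", "NL", "PML", "NWA", "NWP", "RWP", "IOW", "ZW", "UIL"]


def fixture_seq_config(seed: int = 0, fast: bool = True) -> SeqSimConfig:
    """Canonical fixture loci: a fast cytb-like locus and a slow locus.

    The slow locus has within_group_time = 0, so conspecific sequences are
    identical and shared haplotypes are guaranteed by construction.
    """
    if fast:
        return SeqSimConfig(
            groups=FIXTURE_GROUPS, species_tree=FIXTURE_TREE,
            pairwise_rate=2.1, within_group_time=0.3, length=600,
            kappa=4.0, seed=seed,
        )
    return SeqSimConfig(
        groups=FIXTURE_GROUPS, species_tree=FIXTURE_TREE,
        pairwise_rate=0.35, within_group_time=0.0, length=567,
        kappa=4.0, seed=seed + 1,
    )


def fixture_morpho_config(seed: int = 0) -> MorphoSimConfig:
    """One small-bodied group and two equal-sized groups (3 subspecies).

    Noise levels emulate adult dasyurid skulls, whose per-variable
    coefficients of variation within a subspecies run roughly 5-15%:
    8% per-cell noise on top of a 4% individual size deviate, so only
    near-duplicate variables exceed the 0.90 collinearity threshold.
    """
    return MorphoSimConfig(
        groups=[("small", 15, 0.90), ("east1", 8, 1.0), ("east2", 7, 1.0)],
        variable_base_means=FIXTURE_MEANS,
        variable_names=FIXTURE_VARS,
        cv_noise=0.08,
        cv_size=0.04,
        missing_rate=0.04,
        n_correlated_clones=2,
        seed=seed + 2,
    )


def write_fixture_set(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Emit the canonical small study to *out_dir*.

    Files: ``cytb_like.fasta`` (fast locus), ``slow_locus.fasta``,
    ``groups.tsv``, ``morpho.csv`` and ``truth.yaml`` with the generating
    parameters. Returns the path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    truth: dict = {"seed": seed}
    aln_fast, groups, t_fast = simulate_alignment(fixture_seq_config(seed, fast=True))
    aln_slow, _, t_slow = simulate_alignment(fixture_seq_config(seed, fast=False))
    paths["cytb_like"] = out / "cytb_like.fasta"
    write_fasta_alignment(
        Alignment("cytb_like", aln_fast.records), paths["cytb_like"]
    )
    paths["slow_locus"] = out / "slow_locus.fasta"
    write_fasta_alignment(
        Alignment("slow_locus", aln_slow.records), paths["slow_locus"]
    )
    # clade annotation: deep western clade (WA+NT) vs eastern (Qld+PNG)
    clade = {"WA": "west", "NT": "west", "Qld": "east", "PNG": "east",
             "OUT": "outgroup"}
    gm = GroupMap(
        groups.assignments,
        population={i: g for i, g in groups.assignments.items()},
        metadata=pd.DataFrame(
            {"clade": [clade[g] for g in groups.assignments.values()]},
            index=list(groups.assignments),
        ),
    )
    paths["groups"] = out / "groups.tsv"
    df = pd.DataFrame(
        {
            "id": list(gm.assignments),
            "group": list(gm.assignments.values()),
            "population": [gm.population[i] for i in gm.assignments],
            "clade": [clade[g] for g in gm.assignments.values()],
        }
    )
    df.to_csv(paths["groups"], sep="\t", index=False)
    table, t_morpho = simulate_morphotable(fixture_morpho_config(seed))
    paths["morpho"] = out / "morpho.csv"
    table.write_csv(paths["morpho"])
    truth.update(
        {"cytb_like": t_fast, "slow_locus": t_slow, "morpho": t_morpho,
         "clades": clade, "deep_split_my": 3.9, "shallow_split_my": 0.6}
    )
    paths["truth"] = out / "truth.yaml"
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return paths
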