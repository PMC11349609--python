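"""Full-analysis orchestration from a single YAML config.

Runs, per locus: pairwise K2P distances, group summaries, dating and the
haplotype network; on a supplied or internally built (NJ) tree: the
delimitation report; on the morphometric CSV: the full measurement
pipeline. Writes a run manifest recording parameters and seeds so every
output is reproducible.

Config layout (YAML, flat sections)::

    loci:
      - {name: cytb, fasta: cytb.fasta, mode: k2p_all, date_rule: rate}
    groups: groups.tsv
    tree: optional.nwk          # else NJ on the first locus
    outgroup: [OUT]             # group labels used to root
    pairs:                      # delimitation clade pairs, by group label
      - [[WA, NT], [Qld, PNG]]
    rate: 2.1
    network: {epsilon: 0, max_steps: null}
    morpho: {csv: morpho.csv, clade_column: clade}
    seed: 0
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dating import DatingParams, date_group_summary
from .delimitation import CladePair, delimit_report
from .distances import group_summary, pairwise_matrix
from .morphometrics import MorphoTable, morpho_pipeline, univariate_frame
from .network import (
    build_parsimony_network,
    collapse_haplotypes,
    mask_uninformative_columns,
)
from .seqio import read_fasta_alignment, read_group_map, read_newick, write_newick
from .treebuild import neighbor_joining, patristic_distances, root_by_outgroup

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = Path(path).parent
    for locus in cfg.get("loci", []):
        locus["fasta"] = str((base / locus["fasta"]).resolve())
    if "groups" in cfg:
        cfg["groups"] = str((base / cfg["groups"]).resolve())
    if cfg.get("tree"):
        cfg["tree"] = str((base / cfg["tree"]).resolve())
    if cfg.get("morpho", {}).get("csv"):
        cfg["morpho"]["csv"] = str((base / cfg["morpho"]["csv"]).resolve())
    return cfg


@_stage("distances")
def _run_distances(locus: dict, groups, out: Path) -> tuple:
    aln = read_fasta_alignment(locus["fasta"], locus["name"])
    mode = locus.get("mode", "k2p_all")
    matrix = pairwise_matrix(aln, mode)
    gsub = groups.subset([i for i in matrix.labels])
    summary = group_summary(matrix, gsub, as_percent=True)
    matrix.write_square_tsv(out / f"{locus['name']}_distances.tsv")
    matrix.write_long_csv(out / f"{locus['name']}_distances_long.csv")
    summary.write_csv(out / f"{locus['name']}_group_summary.csv")
    summary.format_matrix().to_csv(out / f"{locus['name']}_group_matrix.csv")
    return aln, matrix, summary


@_stage("dating")
def _run_dating(locus: dict, summary, rate: float, out: Path) -> pd.DataFrame:
    rule = locus.get("date_rule", "rate")
    dated = date_group_summary(summary, rule, DatingParams(cytb_rate=rate))
    dated.to_csv(out / f"{locus['name']}_dating.csv", index=False)
    return dated


@_stage("network")
def _run_network(locus: dict, aln, groups, netcfg: dict, out: Path):
    masked, retained = mask_uninformative_columns(aln)
    haps = collapse_haplotypes(masked, groups.subset(list(masked.ids)))
    net = build_parsimony_network(
        haps,
        epsilon=int(netcfg.get("epsilon", 0)),
        max_steps=netcfg.get("max_steps"),
        retained_columns=retained,
    )
    net.write_csv(
        out / f"{locus['name']}_network_edges.csv",
        out / f"{locus['name']}_network_nodes.csv",
    )
    return net


@_stage("tree")
def _get_tree(cfg: dict, matrix, groups, out: Path):
    if cfg.get("tree"):
        tree = read_newick(cfg["tree"])
    else:
        tree = neighbor_joining(matrix)
    outgroup_labels = cfg.get("outgroup") or []
    if outgroup_labels:
        tips = {
            i for g in outgroup_labels for i in groups.members(g)
            if i in {l.taxon.label for l in tree.leaf_node_iter()}
        }
        tree = root_by_outgroup(tree, tips)
    write_newick(tree, out / "delimitation_tree.nwk")
    return tree


@_stage("delimitation")
def _run_delimitation(cfg: dict, tree, groups, out: Path) -> pd.DataFrame:
    tip_set = {l.taxon.label for l in tree.leaf_node_iter()}
    pairs = [
        CladePair.from_groups(groups, a_labels, b_labels, restrict_to=tip_set)
        for a_labels, b_labels in cfg.get("pairs", [])
    ]
    dist = patristic_distances(tree)
    report = delimit_report(tree, dist, pairs)
    report.to_csv(out / "delimitation_report.csv", index=False)
    return report


@_stage("morpho")
def _run_morpho(mcfg: dict, seed: int, out: Path):
    table = MorphoTable.read_csv(mcfg["csv"])
    clades = None
    if mcfg.get("clade_map"):
        clades = pd.Series(mcfg["clade_map"]).reindex(table.data.index)
    res = morpho_pipeline(
        table,
        var_thresh=float(mcfg.get("var_thresh", 0.20)),
        ind_thresh=float(mcfg.get("ind_thresh", 0.15)),
        r_thresh=float(mcfg.get("r_thresh", 0.90)),
        donors=int(mcfg.get("donors", 5)),
        iterations=int(mcfg.get("iterations", 50)),
        seed=seed,
        k=mcfg.get("k", "auto"),
        clade_labels=clades,
    )
    res.descriptives.to_csv(out / "morpho_descriptives.csv", index=False)
    univariate_frame(res.univariate).to_csv(out / "morpho_univariate.csv", index=False)
    pd.DataFrame(res.removal_log + res.prune_log).to_csv(
        out / "morpho_removals.csv", index=False
    )
    res.imputed.write_csv(out / "morpho_imputed.csv")
    res.pca_raw.scores.to_csv(out / "morpho_pca_scores.csv")
    res.pca_raw.loadings.to_csv(out / "morpho_pca_loadings.csv")
    res.pca_shape.scores.to_csv(out / "morpho_pca_shape_scores.csv")
    write_newick(res.dendrogram, out / "morpho_dendrogram.nwk")
    cls_rows = [
        {"dataset": name, "k": c.k, "overall_percent": c.overall_percent}
        for name, c in [
            ("raw", res.classification_raw),
            ("shape", res.classification_shape),
            ("clade_raw", res.classification_clade_raw),
            ("clade_shape", res.classification_clade_shape),
        ]
        if c is not None
    ]
    pd.DataFrame(cls_rows).to_csv(out / "morpho_classification.csv", index=False)
    return res


def run_full_analysis(config: dict | str | Path, out_dir: str | Path,
                      seed: int = 0) -> dict:
    """Run every configured stage; returns the in-memory results bundle.

    Any stage failure aborts with a stage-named :class:`StageError`;
    partial outputs are retained next to a ``FAILED`` marker file.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", seed))
    results: dict = {"loci": {}}
    try:
        groups = read_group_map(config["groups"])
        first_matrix = None
        for locus in config.get("loci", []):
            aln, matrix, summary = _run_distances(locus, groups, out)
            if first_matrix is None:
                first_matrix = matrix
            dated = _run_dating(locus, summary, float(config.get("rate", 2.1)), out)
            net = _run_network(locus, aln, groups, config.get("network", {}), out)
            results["loci"][locus["name"]] = {
                "alignment": aln, "matrix": matrix, "summary": summary,
                "dating": dated, "network": net,
            }
        if first_matrix is not None and config.get("pairs"):
            tree = _get_tree(config, first_matrix, groups, out)
            results["tree"] = tree
            results["delimitation"] = _run_delimitation(config, tree, groups, out)
        if config.get("morpho", {}).get("csv"):
            results["morpho"] = _run_morpho(config["morpho"], seed, out)
        else:
            log.info("no morpho block in config; morphometrics skipped")
    except StageError:
        (out / "FAILED").write_text("pipeline aborted; see log\n")
        raise
    manifest = {
        "package": "dunnartdelim",
        "version": __version__,
        "seed": seed,
        "config": {
            k: v for k, v in config.items() if k != "morpho"
        } | {"morpho": config.get("morpho", {})},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    results["manifest"] = manifest
    return results
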