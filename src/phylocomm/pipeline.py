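"""End-to-end orchestration: presence calling → diversity → clustering →
screens → phylogenetic structure → optional qPCR concordance.

A :class:`PipelineConfig` (YAML-loadable) names the inputs and parameters;
:func:`run_pipeline` executes the stages, writes every output TSV/Newick plus
a JSON manifest of effective parameters, seed and per-stage row counts, and
logs stage boundaries. Reruns with the same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .community import bray_curtis, upgma
from .diversity import per_sample_metrics
from .io import (
    HIGH,
    LOW,
    SampleGroups,
    format_float,
    read_newick,
    read_probe_call_table,
    read_sample_groups,
    write_abundance_matrix,
    write_screen_table,
)
from .phylo import NullModelConfig, per_sample_phylo_metrics
from .presence import build_abundance_matrix, call_presence, positive_fraction
from .qpcr import concordance, read_qpcr_table
from .screens import ScreenThresholds, correlation_screen, differential_screen
from .table1 import TABLE1_COLUMNS, table1_fixture
from .screens import welch_t

__all__ = ["PipelineConfig", "run_pipeline", "table1_check"]

log = logging.getLogger("phylocomm")


@dataclass
class PipelineConfig:
    """Paths and parameters for one full analysis run."""

    probe_table: str
    tree: str
    out_dir: str
    metadata: str | None = None
    qpcr: str | None = None
    pf_threshold: float = 0.90
    log_base: str = "e"
    focal_taxon_id: str = "3821"
    group_k: int = 5
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    n_permutations: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = ScreenThresholds(**thr)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "phylocomm",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "pf_threshold": config.pf_threshold,
            "log_base": config.log_base,
            "focal_taxon_id": config.focal_taxon_id,
            "group_k": config.group_k,
            "thresholds": asdict(config.thresholds),
            "n_permutations": config.n_permutations,
        },
        "stages": {},
        "outputs": [],
    }

    def stage_done(name: str, **counts) -> None:
        log.info("stage %s done: %s", name, counts)
        manifest["stages"][name] = counts

    def record(path: Path) -> str:
        manifest["outputs"].append(str(path))
        return str(path)

    try:
        # --- presence calling ---------------------------------------------
        table = read_probe_call_table(config.probe_table)
        pf = positive_fraction(table)
        presence = call_presence(pf, config.pf_threshold)
        matrix = build_abundance_matrix(table, presence, config.log_base)
        write_abundance_matrix(matrix, out / "abundance.tsv", out / "presence.tsv")
        record(out / "abundance.tsv")
        record(out / "presence.tsv")
        stage_done("call", taxa_in=table.shape[0], taxa_retained=len(matrix.taxon_ids),
                   samples=len(matrix.sample_ids))

        # --- diversity -----------------------------------------------------
        metrics = per_sample_metrics(matrix)
        stage_done("diversity", samples=len(metrics))

        # --- clustering ----------------------------------------------------
        dissim = bray_curtis(matrix)
        dissim.to_frame().map(format_float).to_csv(
            out / "dissimilarity.tsv", sep="\t", lineterminator="\n")
        record(out / "dissimilarity.tsv")
        dendro = upgma(dissim)
        (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        record(out / "dendrogram.nwk")
        stage_done("cluster", merges=len(dendro.merges))

        # --- screens ---------------------------------------------------
        groups = None
        if config.metadata:
            meta = read_sample_groups(config.metadata)
            if len(meta.high) >= 2 and len(meta.low) >= 2:
                groups = meta
        diff = differential_screen(
            matrix, groups=groups, focal_taxon_id=config.focal_taxon_id,
            k=config.group_k, thresholds=config.thresholds)
        write_screen_table(diff, out / "screen_differential.tsv")
        record(out / "screen_differential.tsv")
        corr = correlation_screen(matrix, config.focal_taxon_id, config.thresholds)
        write_screen_table(corr, out / "screen_correlation.tsv")
        record(out / "screen_correlation.tsv")
        stage_done("screens",
                   differential_significant=sum(r.significant for r in diff),
                   correlation_significant=sum(r.significant for r in corr))

        # --- phylogenetic structure -----------------------------------
        tree = read_newick(config.tree)
        null_cfg = NullModelConfig(n_permutations=config.n_permutations,
                                   rng_seed=config.seed)
        phylo = per_sample_phylo_metrics(matrix, tree, null_cfg)
        combined = metrics.join(phylo[["nri", "nti"]])
        combined.map(format_float).to_csv(
            out / "community_metrics.tsv", sep="\t", lineterminator="\n")
        record(out / "community_metrics.tsv")
        stage_done("phylo", samples=len(phylo))

        # --- qPCR concordance -----------------------------------------
        if config.qpcr:
            qtab = read_qpcr_table(config.qpcr)
            f = matrix.taxon_index(config.focal_taxon_id)
            import pandas as pd

            inten = pd.Series(np.exp(matrix.abundance[f]), index=matrix.sample_ids)
            conc = concordance(qtab, inten)
            with open(out / "qpcr_concordance.tsv", "w") as fh:
                fh.write("r\tp\tslope\tintercept\tn\n")
                fh.write(f"{format_float(conc.r)}\t{format_float(conc.p)}\t"
                         f"{format_float(conc.slope)}\t{format_float(conc.intercept)}\t"
                         f"{conc.n}\n")
            record(out / "qpcr_concordance.tsv")
            stage_done("qpcr", shared_samples=conc.n)
    except Exception as exc:
        done = list(manifest["stages"])
        raise RuntimeError(
            f"pipeline aborted after stages {done}: {exc}"
        ) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def table1_check() -> dict[str, dict[str, float]]:
    """Group comparisons on the published per-sample metric table.

    Welch two-tailed t (high vs low focal-abundance samples) for each metric
    column; returns {metric: {t, df, p}}.
    """
    df, groups = table1_fixture()
    out: dict[str, dict[str, float]] = {}
    for col in TABLE1_COLUMNS:
        hi = df.loc[groups.high, col].to_numpy(float)
        lo = df.loc[groups.low, col].to_numpy(float)
        t, dfree, p = welch_t(hi, lo)
        out[col] = {"t": t, "df": dfree, "p": p}
    return out
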