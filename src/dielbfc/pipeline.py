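"""End-to-end pipeline: screening -> clustering -> rhythm report.

The driver reads an expression TSV and sample sheet, runs the screening
cascade (missingness, detection, ANOVA, PCA), clusters the selected genes
under the Bayesian Fourier model, scores every cluster's rhythmicity, and
writes all tabular outputs, the polar plot and a run log. All randomness
flows from the single top-level seed in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cluster import pooled_clustering, run_agglomeration
from .errors import PipelineError
from .fourier import DEFAULT_HARMONICS, build_basis
from .matrix import ExpressionMatrix, read_expression, read_sample_sheet
from .model import NIGPrior
from .rhythm import plot_polar, polar_summary, rhythm_table, summarize_partition
from .screen import (
    amplitude_bins,
    amplitudes,
    anova_screen,
    detect_expressed,
    filter_missingness,
    pca_select,
    screen_table,
)

log = logging.getLogger("dielbfc")


@dataclass
class PipelineConfig:
    """Declarative configuration; defaults are the standard cuts for this analysis.

    max_missing_frac 0.7, detection_factor 2.6 and anova_alpha 1e-3 are the
    screening cascade's cuts; n_select is the PCA dispersion budget;
    harmonics {1,3,6,9} + constant give the 9-column basis; rhythmic/robust
    THR cuts are 0.4 and 0.6.
    """

    expression: str = "expression.tsv"
    sample_sheet: str = "samples.tsv"
    out_dir: str = "dielbfc_out"
    max_missing_frac: float = 0.7
    detection_factor: float = 2.6
    anova_alpha: float = 1e-3
    n_select: int = 2038
    harmonics: tuple[int, ...] = DEFAULT_HARMONICS
    period: float | None = None  # None -> 24 h x number of kinetics
    m0: float = 0.0
    v0: float = 100.0
    a0: float = 0.001
    b0: float = 0.001
    partition_prior: str = "uniform"
    alpha: float = 1.0
    pool_size: int | None = None
    seed: int = 0
    rhythmic_cut: float = 0.4
    robust_cut: float = 0.6
    plot_format: str = "svg"

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_missing_frac < 1.0):
            raise ValueError("max_missing_frac must be in [0, 1)")
        if self.detection_factor <= 0:
            raise ValueError("detection_factor must be > 0")
        if not (0.0 < self.anova_alpha < 1.0):
            raise ValueError("anova_alpha must be in (0, 1)")
        if not (0.0 <= self.rhythmic_cut < self.robust_cut <= 1.0):
            raise ValueError("need 0 <= rhythmic_cut < robust_cut <= 1")
        self.harmonics = tuple(int(h) for h in self.harmonics)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["harmonics"] = list(d["harmonics"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)

    def prior(self) -> NIGPrior:
        return NIGPrior(m0=self.m0, v0=self.v0, a0=self.a0, b0=self.b0)

    def digest(self) -> str:
        d = asdict(self)
        d["harmonics"] = list(d["harmonics"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunArtifacts:
    """Paths and summary counts of one pipeline run."""

    out_dir: Path
    summary: dict = field(default_factory=dict)


def validate_inputs(expression: str | Path, sample_sheet: str | Path) -> list[dict]:
    """Structural diagnostics for the two input TSVs.

    Returns a list of ``{"level": "fatal"|"warning", "message": ...}`` dicts;
    an empty list means the inputs are clean.
    """
    diags: list[dict] = []

    def fatal(msg: str) -> None:
        diags.append({"level": "fatal", "message": msg})

    try:
        samples = read_sample_sheet(sample_sheet)
    except (OSError, ValueError) as e:
        fatal(f"sample sheet unreadable: {e}")
        return diags
    sids = [s.sample_id for s in samples]
    if len(set(sids)) != len(sids):
        fatal("duplicate sample ids in sample sheet")
    for s in samples:
        if s.background <= 0:
            fatal(f"sample {s.sample_id}: background must be > 0, got {s.background}")

    try:
        df = pd.read_csv(expression, sep="\t", index_col="gene_id", na_values=["NA"])
    except (OSError, ValueError) as e:
        fatal(f"expression table unreadable: {e}")
        return diags
    missing_cols = [sid for sid in sids if sid not in df.columns]
    for sid in missing_cols:
        fatal(f"expression table lacks a column for sample {sid}")
    extra = [c for c in df.columns if c not in set(sids)]
    for c in extra:
        fatal(f"expression column {c} has no sample-sheet entry")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        fatal(f"duplicate gene ids: {dups}")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ].tolist()
    for c in non_numeric:
        fatal(f"column {c} has non-numeric entries (missing values must be 'NA')")
    return diags


def run_pipeline(cfg: PipelineConfig) -> RunArtifacts:
    """Execute screen -> cluster -> rhythm and write every artifact.

    Raises :class:`PipelineError` naming the failing stage; aborts cleanly
    with "no genes selected" when the screening cascade empties the gene set.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    diags = validate_inputs(cfg.expression, cfg.sample_sheet)
    fatals = [d for d in diags if d["level"] == "fatal"]
    if fatals:
        raise PipelineError(f"stage validate: {fatals[0]['message']}")

    samples = read_sample_sheet(cfg.sample_sheet)
    m = read_expression(cfg.expression, samples)
    summary: dict = {"genes_in": m.n_genes, "n_samples": m.n_samples}

    # --- screening cascade -------------------------------------------------
    try:
        m1 = filter_missingness(m, cfg.max_missing_frac)
        summary["dropped_missingness"] = m.n_genes - m1.n_genes
        expressed = detect_expressed(m1, cfg.detection_factor)
        m2 = m1.subset(expressed.index[expressed])
        summary["expressed"] = m2.n_genes
        if m2.n_genes == 0:
            raise PipelineError("stage screen: no genes selected")
        anova = anova_screen(m2, cfg.anova_alpha)
        m3 = m2.subset(anova.index[anova["selected"]])
        summary["anova_selected"] = m3.n_genes
        if m3.n_genes == 0:
            raise PipelineError("stage screen: no genes selected")
        n_select = min(cfg.n_select, m3.n_genes)
        selected_pca, pca_score = pca_select(m3, n_select)
        m4 = m3.subset(selected_pca)
        summary["pca_selected"] = m4.n_genes
        amp = amplitudes(m1)
        _, hist_anova = amplitude_bins(m3)
        _, hist_pca = amplitude_bins(m4)
        hist = pd.DataFrame(
            {
                "bin": hist_anova["bin"],
                "anova_count": hist_anova["count"],
                "pca_count": hist_pca["count"],
            }
        )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage screen: {e}") from e

    table = screen_table(m1, expressed, anova, pca_score, selected_pca, amp)
    table.to_csv(out / "screen.tsv", sep="\t", index=False, na_rep="NA", float_format="%.6g")
    hist.to_csv(out / "amplitude_histogram.tsv", sep="\t", index=False)

    # --- clustering --------------------------------------------------------
    try:
        basis = build_basis(samples, cfg.harmonics, cfg.period)
        prior = cfg.prior()
        if cfg.pool_size:
            partitions = pooled_clustering(
                m4, cfg.pool_size, cfg.seed, basis, prior,
                cfg.partition_prior, cfg.alpha,
            )
        else:
            partitions = [
                run_agglomeration(m4, basis, prior, cfg.partition_prior, cfg.alpha)
            ]
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage cluster: {e}") from e

    assign_rows = []
    traj_rows = []
    all_summaries = []
    cluster_offset = 0
    for pool_idx, p in enumerate(partitions, start=1):
        a = p.assignments()
        for gid, cid in a.items():
            assign_rows.append((gid, f"P{pool_idx}_C{cid}"))
        for step, pair, score in p.merge_history:
            traj_rows.append(
                (pool_idx, step, pair[0] if pair else "NA", pair[1] if pair else "NA", score)
            )
        summaries = summarize_partition(p.clusters, cfg.rhythmic_cut, cfg.robust_cut)
        for s in summaries:
            s.cluster_id = f"P{pool_idx}_{s.cluster_id}"
        all_summaries.extend(summaries)
        cluster_offset += p.n_clusters

    assign = pd.DataFrame(assign_rows, columns=["gene_id", "cluster_id"])
    assign = assign.set_index("gene_id").loc[m4.gene_ids].reset_index()
    assign.to_csv(out / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        traj_rows, columns=["pool", "step", "merged_i", "merged_j", "score"]
    ).to_csv(out / "trajectory.tsv", sep="\t", index=False, float_format="%.6f")

    summary["clusters"] = sum(p.n_clusters for p in partitions)
    summary["rhythmic_clusters"] = sum(
        s.rhythm_class in ("rhythmic", "robust") for s in all_summaries
    )
    summary["robust_clusters"] = sum(s.rhythm_class == "robust" for s in all_summaries)

    # --- rhythm report -----------------------------------------------------
    try:
        rhythm_table(all_summaries).to_csv(
            out / "rhythm.tsv", sep="\t", index=False, na_rep="NA", float_format="%.6f"
        )
        pol = polar_summary(all_summaries)
        pol.to_csv(out / "polar.tsv", sep="\t", index=False, float_format="%.6f")
        plot_polar(all_summaries, out / f"polar.{cfg.plot_format}")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage rhythm: {e}") from e

    cfg.to_yaml(out / "config.yaml")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    from . import __version__ as _pkg_version

    (out / "run_log.txt").write_text(
        "\n".join(
            [
                f"dielbfc {_pkg_version}",
                f"python {sys.version.split()[0]}",
                f"numpy {np.__version__}  pandas {pd.__version__}",
                f"config_hash {cfg.digest()}",
                f"seed {cfg.seed}",
            ]
        )
        + "\n"
    )
    return RunArtifacts(out_dir=out, summary=summary)
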