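"""Synthetic diel expression data with ground-truth labels.

Emulates the statistical structure of a two-colour microarray diel time
course after normalisation: log2 expression over 3 replicate days (kinetics),
24-h cosine waveforms for rhythmic genes with peak-to-trough amplitudes on the
delta-log2 scale, arrhythmic genes as noise around a constant, non-expressed
genes drawn below the detection limit (2.6x the per-sample background on the
linear scale), and missing values at a configurable rate.

Array physics (dye bias, print-tip structure) is out of scope; the generator
starts from the normalised log-ratio matrix the downstream analysis assumes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .design import SampleDesign
from .errors import InvalidSpecError
from .matrix import ExpressionMatrix, TruthLabels

#: Default log2 baseline for expressed genes; with a unit linear background
#: this sits ~64x above background, comfortably past the 2.6x detection cut.
DEFAULT_BASELINE = 6.0


def simulate_expression(
    design: Sequence[SampleDesign],
    n_clusters: int,
    genes_per_cluster: int,
    phases: Sequence[float],
    amplitudes: Sequence[float],
    n_arrhythmic: int = 0,
    n_unexpressed: int = 0,
    noise_sd: float = 0.3,
    missing_frac: float = 0.0,
    seed: int = 0,
    baseline: float = DEFAULT_BASELINE,
    detection_factor: float = 2.6,
) -> tuple[ExpressionMatrix, TruthLabels]:
    """Simulate a gene x sample log2 matrix plus truth labels.

    Rhythmic gene g in cluster c has mean profile
    ``baseline + (amplitude_c / 2) * cos(2*pi*(tod - phase_c) / 24)`` with
    i.i.d. Gaussian noise of sd ``noise_sd``. Arrhythmic genes are noise around
    the baseline. Unexpressed genes are drawn uniformly below
    ``detection_factor * background`` on the linear scale so they fail the
    detection filter at every sample. Missing entries are masked at rate
    ``missing_frac``. Fully reproducible from ``seed``.
    """
    if len(phases) != n_clusters or len(amplitudes) != n_clusters:
        raise InvalidSpecError(
            f"phases ({len(phases)}) and amplitudes ({len(amplitudes)}) "
            f"must both have length n_clusters ({n_clusters})"
        )
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")
    if not (0.0 <= missing_frac < 1.0):
        raise InvalidSpecError("missing_frac must be in [0, 1)")
    if min(n_arrhythmic, n_unexpressed, n_clusters, genes_per_cluster) < 0:
        raise InvalidSpecError("gene counts must be nonnegative")

    rng = np.random.default_rng(seed)
    tod = np.array([s.tod for s in design], dtype=float)
    bg = np.array([s.background for s in design], dtype=float)
    n_samples = len(design)

    rows: list[np.ndarray] = []
    records: list[dict] = []

    for c in range(n_clusters):
        mean = baseline + (amplitudes[c] / 2.0) * np.cos(2 * np.pi * (tod - phases[c]) / 24.0)
        for g in range(genes_per_cluster):
            rows.append(mean + rng.normal(0.0, noise_sd, n_samples))
            records.append(
                dict(
                    gene_id=f"R{c + 1:02d}_{g + 1:03d}",
                    gene_class="rhythmic",
                    true_cluster=c + 1,
                    phase_h=float(phases[c]) % 24.0,
                    amplitude=float(amplitudes[c]),
                )
            )

    for g in range(n_arrhythmic):
        rows.append(baseline + rng.normal(0.0, noise_sd, n_samples))
        records.append(
            dict(
                gene_id=f"A_{g + 1:03d}",
                gene_class="arrhythmic",
                true_cluster=None,
                phase_h=None,
                amplitude=0.0,
            )
        )

    for g in range(n_unexpressed):
        # strictly below factor*background at every sample, on the linear scale
        linear = rng.uniform(0.0, detection_factor * bg)
        linear = np.maximum(linear, 1e-6)
        rows.append(np.log2(linear))
        records.append(
            dict(
                gene_id=f"U_{g + 1:03d}",
                gene_class="unexpressed",
                true_cluster=None,
                phase_h=None,
                amplitude=0.0,
            )
        )

    if not rows:
        raise InvalidSpecError("simulation would produce zero genes")

    values = np.vstack(rows)
    if missing_frac > 0:
        mask = rng.random(values.shape) < missing_frac
        values = np.where(mask, np.nan, values)

    gene_ids = [r["gene_id"] for r in records]
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=[s.sample_id for s in design])
    truth = TruthLabels(pd.DataFrame.from_records(records))
    return ExpressionMatrix(df, list(design)), truth
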