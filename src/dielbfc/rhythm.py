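"""Rhythmicity scoring and phase-resolved cluster summaries.

The third harmonic ratio (THR) is the fraction of a cluster's fitted harmonic
power carried by the diel harmonic (harmonic 3 of the 72-h fundamental, i.e.
the 24-h component): ``THR = (a3^2 + b3^2) / sum_h (a_h^2 + b_h^2)`` over the
included harmonic set, constant term excluded. Clusters with THR above 0.4
are called rhythmic; above 0.6, robustly rhythmic. The phase is the time of
day at which the diel component peaks, which places each cluster around the
24-h clock in the polar summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import SampleDesign, is_light
from .errors import ConfigurationError, UndefinedPhaseError
from .model import ClusterPosterior

RHYTHMIC_CUT = 0.4
ROBUST_CUT = 0.6
DIEL_HARMONIC = 3


@dataclass
class RhythmSummary:
    """Per-cluster rhythm report: THR, phase, class and polar encoding."""

    cluster_id: str
    size: int
    thr: float
    phase_h: float | None
    rhythm_class: str  # arrhythmic | rhythmic | robust
    polar: tuple[float | None, float, float]  # (angle rad, radius, dot size)
    flat: bool = False


def thr(
    post: ClusterPosterior,
    numerator_harmonic: int = DIEL_HARMONIC,
    denominator_harmonics: Sequence[int] | None = None,
) -> float:
    """Third harmonic ratio of a cluster posterior, in [0, 1].

    Returns 0.0 for a flat cluster (all harmonic power zero). The numerator
    harmonic and denominator set are overridable for non-default designs.
    """
    if numerator_harmonic not in post.harmonic_coeffs:
        raise ConfigurationError(
            f"harmonic {numerator_harmonic} absent from the fitted basis "
            f"{sorted(post.harmonic_coeffs)}"
        )
    denom_set = tuple(denominator_harmonics) if denominator_harmonics else post.harmonics
    missing = [h for h in denom_set if h not in post.harmonic_coeffs]
    if missing:
        raise ConfigurationError(f"denominator harmonics {missing} absent from basis")
    a3, b3 = post.harmonic_coeffs[numerator_harmonic]
    num = a3 * a3 + b3 * b3
    den = sum(a * a + b * b for h in denom_set for a, b in [post.harmonic_coeffs[h]])
    if den == 0.0:
        return 0.0
    return float(num / den)


def classify_rhythm(
    thr_value: float,
    rhythmic_cut: float = RHYTHMIC_CUT,
    robust_cut: float = ROBUST_CUT,
) -> str:
    """Strict-threshold classification: > robust_cut, > rhythmic_cut, else arrhythmic."""
    if not (0.0 <= rhythmic_cut < robust_cut <= 1.0):
        raise ValueError(
            f"need 0 <= rhythmic_cut < robust_cut <= 1, got {rhythmic_cut}, {robust_cut}"
        )
    if thr_value > robust_cut:
        return "robust"
    if thr_value > rhythmic_cut:
        return "rhythmic"
    return "arrhythmic"


def phase_estimate(post: ClusterPosterior, diel_period: float = 24.0,
                   numerator_harmonic: int = DIEL_HARMONIC) -> float:
    """Time of day (hours) at which the diel component peaks.

    The fitted component ``a cos(w t) + b sin(w t)`` peaks at
    ``t = atan2(b, a) / w``; with the diel harmonic's period equal to
    ``diel_period`` this maps directly to the design's time-of-day axis.
    """
    if numerator_harmonic not in post.harmonic_coeffs:
        raise ConfigurationError(f"harmonic {numerator_harmonic} absent from basis")
    a, b = post.harmonic_coeffs[numerator_harmonic]
    if a == 0.0 and b == 0.0:
        raise UndefinedPhaseError("cluster has no diurnal component")
    return (diel_period / (2.0 * math.pi)) * math.atan2(b, a) % diel_period


def summarize_partition(
    clusters: Sequence[ClusterPosterior],
    rhythmic_cut: float = RHYTHMIC_CUT,
    robust_cut: float = ROBUST_CUT,
    dot_scale: float = 1.0,
) -> list[RhythmSummary]:
    """One RhythmSummary per cluster; dot size grows linearly with cluster size."""
    out = []
    for c, post in enumerate(clusters):
        t = thr(post)
        flat = all(
            a == 0.0 and b == 0.0 for a, b in post.harmonic_coeffs.values()
        )
        try:
            phase = phase_estimate(post)
            angle = 2.0 * math.pi * phase / 24.0
        except (UndefinedPhaseError, ConfigurationError):
            phase, angle = None, None
        out.append(
            RhythmSummary(
                cluster_id=f"C{c + 1}",
                size=post.size,
                thr=t,
                phase_h=phase,
                rhythm_class=classify_rhythm(t, rhythmic_cut, robust_cut),
                polar=(angle, t, dot_scale * post.size),
                flat=flat,
            )
        )
    return out


def polar_summary(
    summaries: Sequence[RhythmSummary],
    light_on: float = 9.0,
    light_off: float = 21.0,
) -> pd.DataFrame:
    """Polar-plot table: one row per cluster with a defined phase.

    Columns: cluster_id, size, thr, phase_h, angle_rad (2*pi*phase/24), radius
    (= THR), dot_size (proportional to size), light (schedule at the peak).
    Clusters with undefined phase are omitted; the count of omissions is in
    ``df.attrs["n_undefined_phase"]``.
    """
    rows = []
    n_undef = 0
    for s in summaries:
        if s.phase_h is None:
            n_undef += 1
            continue
        rows.append(
            dict(
                cluster_id=s.cluster_id,
                size=s.size,
                thr=s.thr,
                phase_h=s.phase_h,
                angle_rad=s.polar[0],
                radius=s.polar[1],
                dot_size=s.polar[2],
                light=int(is_light(s.phase_h, light_on, light_off)),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size", "thr", "phase_h",
            "angle_rad", "radius", "dot_size", "light",
        ],
    )
    df.attrs["n_undefined_phase"] = n_undef
    return df


def rhythm_table(summaries: Sequence[RhythmSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [s.cluster_id for s in summaries],
            "size": [s.size for s in summaries],
            "thr": [s.thr for s in summaries],
            "phase_h": [s.phase_h for s in summaries],
            "rhythm_class": [s.rhythm_class for s in summaries],
        }
    )


def plot_polar(
    summaries: Sequence[RhythmSummary],
    path: str | Path,
    light_on: float = 9.0,
    light_off: float = 21.0,
    dot_scale: float = 6.0,
) -> None:
    """Clock-face plot: clusters at their peak time, radius = THR, dot ~ size.

    The dark portion of the entrainment schedule is shaded. Written as SVG or
    PNG depending on the path suffix; SVG output carries no timestamp so
    repeated runs are byte-identical.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "dielbfc"  # reproducible SVG ids
    fig = plt.figure(figsize=(5.5, 5.5))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)

    # shade the dark phase of the 24-h schedule
    dark = [h for h in np.linspace(0, 24, 241) if not is_light(h % 24, light_on, light_off)]
    for h in dark:
        ax.bar(2 * np.pi * h / 24.0, 1.0, width=2 * np.pi / 240.0,
               bottom=0.0, color="0.85", edgecolor="none", zorder=0)

    tab = polar_summary(summaries, light_on, light_off)
    if not tab.empty:
        ax.scatter(
            tab["angle_rad"], tab["radius"],
            s=dot_scale * tab["size"], marker="s",
            c="tab:blue", alpha=0.75, zorder=3,
        )
    ax.set_rlim(0, 1.0)
    ax.set_rticks([0.4, 0.6, 1.0])
    ax.set_xticks(np.arange(0, 2 * np.pi, np.pi / 4))
    ax.set_xticklabels([f"{int(h)}h" for h in np.arange(0, 24, 3)])
    ax.set_title("Cluster rhythmicity: angle = peak time, radius = THR")
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
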