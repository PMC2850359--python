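"""Gene screening cascade for diel time courses.

Stages, in pipeline order: missing-data filter, detection above background,
per-gene two-way ANOVA (time-of-day effect adjusted for kinetic), PCA
dispersion selection, and amplitude binning into unit-width delta-log2 strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegreesOfFreedomError
from .matrix import ExpressionMatrix

AMPLITUDE_BIN_LABELS = [f"{i}-{i + 1}" for i in range(9)]

_ZERO_TOL = 1e-10


@dataclass
class ScreenResult:
    """Per-gene screening outcome table plus the amplitude histogram."""

    table: pd.DataFrame  # gene_id, n_missing, expressed, F, p, pca_score,
    #                      amplitude, selected_anova, selected_pca
    histogram: pd.DataFrame  # bin, anova_count, pca_count


def filter_missingness(m: ExpressionMatrix, max_missing_frac: float = 0.7) -> ExpressionMatrix:
    """Drop genes whose missing fraction strictly exceeds ``max_missing_frac``.

    Survivor order is preserved. An empty matrix passes through unchanged.
    """
    if not (0.0 <= max_missing_frac < 1.0):
        raise ValueError("max_missing_frac must be in [0, 1)")
    if m.n_genes == 0:
        return m
    frac = m.mask.mean(axis=1)
    keep = frac.index[frac.values <= max_missing_frac]
    return m.subset(keep)


def detect_expressed(m: ExpressionMatrix, factor: float = 2.6) -> pd.Series:
    """Expressed iff the linear signal reaches ``factor x background`` at least once.

    Values are log2, backgrounds linear; missing entries are ignored. Ties at
    exactly ``factor x background`` count as expressed. Genes with every entry
    missing are flagged not-expressed with a warning.
    """
    bg = m.backgrounds()
    if np.any(bg <= 0):
        raise ValueError("per-sample background must be > 0 for detection")
    linear = np.power(2.0, m.values.to_numpy())
    with np.errstate(invalid="ignore"):
        hit = linear >= factor * bg[None, :]
    hit = np.where(np.isnan(linear), False, hit)
    expressed = pd.Series(hit.any(axis=1), index=m.values.index, name="expressed")
    all_missing = m.mask.all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} gene(s) have no observed values; "
            "marked not expressed",
            stacklevel=2,
        )
        expressed[all_missing] = False
    return expressed


def _check_anova_design(m: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    tods = m.tods()
    kin = m.kinetics()
    levels = np.unique(tods)
    if levels.size < 2:
        raise DegreesOfFreedomError("ANOVA needs at least 2 time-of-day levels")
    for lv in levels:
        n_kin = np.unique(kin[tods == lv]).size
        if n_kin < 2:
            raise DegreesOfFreedomError(
                f"time-of-day level {lv:g} observed in only {n_kin} kinetic(s)"
            )
    return tods, kin


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded dummies dropping the first level."""
    out = np.zeros((codes.size, n_levels - 1))
    for j in range(1, n_levels):
        out[codes == j, j - 1] = 1.0
    return out


def _anova_one(y: np.ndarray, x_full: np.ndarray, x_red: np.ndarray) -> tuple[float, float]:
    """F and p for the extra term of ``x_full`` over ``x_red`` on observed ``y``."""
    obs = ~np.isnan(y)
    yo = y[obs]
    xf, xr = x_full[obs], x_red[obs]
    rank_f = np.linalg.matrix_rank(xf)
    rank_r = np.linalg.matrix_rank(xr)
    df1 = rank_f - rank_r
    df2 = yo.size - rank_f
    if df1 <= 0 or df2 <= 0:
        return np.nan, np.nan
    rss_f = float(np.sum((yo - xf @ np.linalg.lstsq(xf, yo, rcond=None)[0]) ** 2))
    rss_r = float(np.sum((yo - xr @ np.linalg.lstsq(xr, yo, rcond=None)[0]) ** 2))
    return _f_and_p(rss_r - rss_f, rss_f, df1, df2, float(np.sum(yo**2)))


def _f_and_p(ss_time: float, rss_full: float, df1: int, df2: int, scale: float) -> tuple[float, float]:
    tol = _ZERO_TOL * max(1.0, scale)
    if rss_full <= tol:
        if ss_time > tol:
            return np.inf, 0.0
        return 0.0, 1.0
    f = (ss_time / df1) / (rss_full / df2)
    f = max(f, 0.0)
    return f, float(stats.f.sf(f, df1, df2))


def anova_screen(m: ExpressionMatrix, alpha: float = 1e-3) -> pd.DataFrame:
    """Per-gene two-way fixed-effects ANOVA (time-of-day + kinetic, no interaction).

    Returns a DataFrame with columns ``F``, ``p`` and ``selected`` where ``F``
    and ``p`` test the time-of-day effect adjusted for kinetic and
    ``selected = p < alpha``. Complete genes share projection matrices and are
    computed in one vectorised pass; genes with missing entries fall back to a
    per-gene least-squares fit.
    """
    tods, kin = _check_anova_design(m)
    tod_codes = np.searchsorted(np.unique(tods), tods)
    kin_codes = np.searchsorted(np.unique(kin), kin)
    n = len(m.samples)
    intercept = np.ones((n, 1))
    x_red = np.hstack([intercept, _dummies(kin_codes, np.unique(kin).size)])
    x_full = np.hstack([x_red, _dummies(tod_codes, np.unique(tods).size)])
    rank_f = np.linalg.matrix_rank(x_full)
    rank_r = np.linalg.matrix_rank(x_red)
    df1, df2 = rank_f - rank_r, n - rank_f

    y = m.values.to_numpy()
    complete = ~np.isnan(y).any(axis=1)
    F = np.full(m.n_genes, np.nan)
    p = np.full(m.n_genes, np.nan)

    if complete.any():
        # residual-maker matrices shared across complete genes
        r_full = np.eye(n) - x_full @ np.linalg.pinv(x_full)
        r_red = np.eye(n) - x_red @ np.linalg.pinv(x_red)
        yc = y[complete]
        rss_f = np.einsum("gi,ij,gj->g", yc, r_full, yc)
        rss_r = np.einsum("gi,ij,gj->g", yc, r_red, yc)
        scale = np.einsum("gi,gi->g", yc, yc)
        vals = [
            _f_and_p(rr - rf, rf, df1, df2, sc)
            for rr, rf, sc in zip(rss_r, rss_f, scale)
        ]
        F[complete] = [v[0] for v in vals]
        p[complete] = [v[1] for v in vals]

    for g in np.flatnonzero(~complete):
        F[g], p[g] = _anova_one(y[g], x_full, x_red)

    selected = (p < alpha) & ~np.isnan(p)
    return pd.DataFrame(
        {"F": F, "p": p, "selected": selected}, index=m.values.index
    )


def pca_select(m: ExpressionMatrix, n_select: int) -> tuple[list[str], pd.Series]:
    """Keep the ``n_select`` genes with largest dispersion on the PC1/PC2 plane.

    Genes are observations, samples dimensions; each gene is centred on its own
    mean and missing entries are mean-imputed before the decomposition. The
    score is the squared projection length onto the first two principal axes.
    Ties break deterministically by gene order. Returns the selected gene ids
    (input order preserved) and the per-gene score.
    """
    if n_select <= 0:
        raise ValueError("n_select must be positive")
    if n_select > m.n_genes:
        raise ValueError(f"n_select ({n_select}) exceeds gene count ({m.n_genes})")
    y = m.values.to_numpy().copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        gene_mean = np.nanmean(y, axis=1)
    gene_mean = np.where(np.isnan(gene_mean), 0.0, gene_mean)
    y = np.where(np.isnan(y), gene_mean[:, None], y)
    yc = y - y.mean(axis=1, keepdims=True)
    # right singular vectors span the sample-space principal axes
    _, s, vt = np.linalg.svd(yc, full_matrices=False)
    k = min(2, vt.shape[0])
    proj = yc @ vt[:k].T
    score = pd.Series(np.sum(proj**2, axis=1), index=m.values.index, name="pca_score")
    order = np.argsort(-score.to_numpy(), kind="stable")[:n_select]
    chosen = set(score.index[order])
    selected = [g for g in m.gene_ids if g in chosen]
    return selected, score


def amplitudes(m: ExpressionMatrix) -> pd.Series:
    """Peak-to-trough range of the per-time-of-day median profile, per gene."""
    tods = m.tods()
    med = []
    for lv in np.unique(tods):
        cols = m.values.iloc[:, np.flatnonzero(tods == lv)]
        med.append(cols.median(axis=1, skipna=True))
    profile = pd.concat(med, axis=1)
    amp = profile.max(axis=1, skipna=True) - profile.min(axis=1, skipna=True)
    return amp.fillna(0.0).rename("amplitude")


def amplitude_bins(m: ExpressionMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Amplitudes plus their histogram over unit bins [0-1) ... [8-9].

    Bins are right-open except the last; amplitudes above 9 are clipped into
    the top stratum.
    """
    amp = amplitudes(m)
    counts, _ = np.histogram(np.clip(amp.to_numpy(), 0.0, 9.0), bins=np.arange(10.0))
    hist = pd.DataFrame({"bin": AMPLITUDE_BIN_LABELS, "count": counts})
    return amp, hist


def screen_table(
    m: ExpressionMatrix,
    expressed: pd.Series,
    anova: pd.DataFrame,
    pca_score: pd.Series,
    selected_pca: list[str],
    amp: pd.Series,
) -> pd.DataFrame:
    """Assemble the one-row-per-gene screening report."""
    idx = m.values.index
    sel_pca = idx.isin(selected_pca)
    return pd.DataFrame(
        {
            "gene_id": idx,
            "n_missing": m.mask.sum(axis=1).to_numpy(),
            "expressed": expressed.reindex(idx).to_numpy(),
            "F": anova["F"].reindex(idx).to_numpy(),
            "p": anova["p"].reindex(idx).to_numpy(),
            "pca_score": pca_score.reindex(idx).to_numpy(),
            "amplitude": amp.reindex(idx).to_numpy(),
            "selected_anova": anova["selected"]
            .reindex(idx, fill_value=False)
            .astype(bool)
            .to_numpy(),
            "selected_pca": sel_pca,
        }
    ).reset_index(drop=True)
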