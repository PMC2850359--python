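"""Fourier design matrices over the concatenated multi-day time axis.

With K replicate days laid end to end the fundamental period is ``24*K`` hours
(72 h for the default 3-kinetic design), so harmonic ``K`` is the 24-h diel
component — harmonic 3 in the default configuration. The default harmonic set
{1, 3, 6, 9} plus the constant gives a 9-column design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import SampleDesign

DEFAULT_HARMONICS: tuple[int, ...] = (1, 3, 6, 9)


@dataclass(frozen=True)
class FourierBasis:
    """Design matrix B over a harmonic set and fundamental period.

    Column 0 is the constant; columns ``2i-1, 2i`` are
    ``cos(2*pi*h_i*t/period)`` and ``sin(2*pi*h_i*t/period)`` for the i-th
    harmonic in ascending order.
    """

    times: tuple[float, ...]
    harmonics: tuple[int, ...]
    period: float
    matrix: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def columns_for(self, harmonic: int) -> tuple[int, int]:
        """(cosine, sine) column indices for a harmonic."""
        i = self.harmonics.index(harmonic)
        return 2 * i + 1, 2 * i + 2


def build_basis(
    design: Sequence[SampleDesign],
    harmonics: Sequence[int] = DEFAULT_HARMONICS,
    period: float | None = None,
) -> FourierBasis:
    """Build the Fourier design matrix for a sample design.

    ``period`` defaults to the full concatenated span, ``24 * max(kinetic)``.
    """
    if len(design) == 0:
        raise ValueError("design must be nonempty")
    hs = [int(h) for h in harmonics]
    if not hs:
        raise ValueError("harmonics must be nonempty")
    if any(h < 1 for h in hs):
        raise ValueError("harmonics must be >= 1")
    if len(set(hs)) != len(hs):
        raise ValueError(f"duplicate harmonic values in {hs}")
    hs = sorted(hs)
    if period is None:
        period = 24.0 * max(s.kinetic for s in design)
    if period <= 0:
        raise ValueError("period must be > 0")

    t = np.array([s.t for s in design], dtype=float)
    cols = [np.ones_like(t)]
    for h in hs:
        w = 2.0 * np.pi * h * t / period
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return FourierBasis(
        times=tuple(t.tolist()),
        harmonics=tuple(hs),
        period=float(period),
        matrix=np.column_stack(cols),
    )
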