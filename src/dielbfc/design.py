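"""Sample designs for light/dark-entrained time courses.

A *kinetic* is one biological-replicate time course (one sampled day).
Kinetics are laid end to end on a concatenated multi-day axis
``t = 24*(kinetic - 1) + tod`` so that a Fourier fit over the full span sees
biological replicates as consecutive days; with three kinetics the fundamental
period is 72 h and harmonic 3 is the 24-h diel component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import InvalidDesignError

#: Default time-of-day grid (hours): every 3 h over one day with a duplicated
#: dawn point at Time 9.
DEFAULT_TODS: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 9.0, 12.0, 15.0, 18.0, 21.0)

DEFAULT_LIGHT_ON = 9.0
DEFAULT_LIGHT_OFF = 21.0


@dataclass(frozen=True)
class SampleDesign:
    """Metadata for one array sample.

    Parameters
    ----------
    sample_id : str
        Unique sample token, e.g. ``"K2_T15"``.
    kinetic : int
        Biological-replicate series index, 1-based.
    tod : float
        Nominal time of day in hours, in ``[0, 24)``.
    t : float
        Position on the concatenated multi-day axis, ``24*(kinetic-1) + tod``.
    light : bool
        True if the sample falls in the light phase of the entrainment schedule.
    background : float
        Per-sample background signal on the linear scale; must be positive for
        the detection filter to be meaningful.
    """

    sample_id: str
    kinetic: int
    tod: float
    t: float
    light: bool
    background: float


def is_light(tod: float, light_on: float, light_off: float) -> bool:
    """Light flag for a time of day under a half-open [on, off) schedule.

    Handles schedules that wrap midnight (``light_on > light_off``).
    """
    tod = tod % 24.0
    if light_on < light_off:
        return light_on <= tod < light_off
    return tod >= light_on or tod < light_off


def make_design(
    n_kinetics: int = 3,
    tods: Sequence[float] = DEFAULT_TODS,
    light_on: float = DEFAULT_LIGHT_ON,
    light_off: float = DEFAULT_LIGHT_OFF,
    backgrounds: Sequence[float] | float = 1.0,
) -> list[SampleDesign]:
    """Build the sample sheet for ``n_kinetics`` replicate days.

    ``backgrounds`` may be a scalar (shared by all samples) or one value per
    sample in kinetic-major order. Duplicated ``tods`` values are allowed (the
    overlapping dawn time points).
    """
    if len(tods) == 0:
        raise InvalidDesignError("tods must be nonempty")
    if n_kinetics < 1:
        raise InvalidDesignError("n_kinetics must be >= 1")
    if light_on == light_off:
        raise InvalidDesignError("light_on and light_off must differ")
    for tod in tods:
        if not (0.0 <= tod < 24.0):
            raise InvalidDesignError(f"time of day {tod!r} outside [0, 24)")

    n_samples = n_kinetics * len(tods)
    try:
        bg = [float(backgrounds)] * n_samples  # type: ignore[arg-type]
    except TypeError:
        bg = [float(b) for b in backgrounds]  # type: ignore[union-attr]
        if len(bg) != n_samples:
            raise InvalidDesignError(
                f"backgrounds has {len(bg)} entries, design needs {n_samples}"
            )
    if any(b < 0 for b in bg):
        raise InvalidDesignError("backgrounds must be nonnegative")

    samples: list[SampleDesign] = []
    i = 0
    for k in range(1, n_kinetics + 1):
        n_dup: dict[float, int] = {}
        for tod in tods:
            rep = n_dup.get(tod, 0)
            n_dup[tod] = rep + 1
            suffix = chr(ord("a") + rep) if rep else ""
            samples.append(
                SampleDesign(
                    sample_id=f"K{k}_T{tod:g}{suffix}",
                    kinetic=k,
                    tod=float(tod),
                    t=24.0 * (k - 1) + float(tod),
                    light=is_light(tod, light_on, light_off),
                    background=bg[i],
                )
            )
            i += 1
    return samples
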