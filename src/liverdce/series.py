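"""Time-series containers for ROI-mean MR signal and gadolinium concentration.

All series live on a uniform time grid with ``t = 0`` at the contrast bolus
injection; negative times are pre-contrast baseline frames.  Samples can be
flagged invalid (e.g. where the SPGR inversion has no real solution under
noise) and every downstream operation excludes invalid samples rather than
clamping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: relative tolerance on grid uniformity, as a fraction of the frame interval
GRID_RTOL = 0.01

COMPARTMENTS = frozenset({"tissue", "ees", "intracellular", "arterial", "venous", "plasma"})


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def check_uniform(times: np.ndarray, frame_interval: float | None = None) -> float:
    """Validate that *times* is strictly increasing and uniformly spaced.

    Returns the frame interval.  Raises ``ValueError`` if spacing deviates by
    more than ``GRID_RTOL`` of the frame interval.
    """
    times = _as_float_array(times)
    if times.size < 2:
        raise ValueError("time grid needs at least two samples")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    ref = float(frame_interval) if frame_interval is not None else float(np.median(dt))
    if np.any(np.abs(dt - ref) > GRID_RTOL * ref):
        raise ValueError(
            f"non-uniform sampling: frame interval {ref:g} s, observed spacing "
            f"in [{dt.min():g}, {dt.max():g}] s exceeds {GRID_RTOL:.0%} tolerance"
        )
    return ref


@dataclass(frozen=True)
class AcquisitionParams:
    """SPGR acquisition and timing parameters.

    Parameters
    ----------
    tr : repetition time (s).
    flip_angle_deg : flip angle in degrees, converted to radians internally.
    frame_interval : time between dynamic volumes (s).
    bolus_time : injection time on the series clock (s), >= 0.
    n_baseline : number of pre-contrast frames averaged into S(0).
    """

    tr: float
    flip_angle_deg: float
    frame_interval: float
    bolus_time: float = 0.0
    n_baseline: int = 1

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if not 0 < self.flip_angle_deg < 90:
            raise ValueError("flip_angle_deg must be in (0, 90)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.bolus_time < 0:
            raise ValueError("bolus_time must be >= 0")
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")

    @property
    def flip_angle_rad(self) -> float:
        return float(np.deg2rad(self.flip_angle_deg))

    @property
    def cos_flip(self) -> float:
        return float(np.cos(self.flip_angle_rad))


@dataclass(frozen=True)
class SignalSeries:
    """ROI-mean signal intensity vs. bolus-relative time (arbitrary units)."""

    times: np.ndarray
    values: np.ndarray
    s0: float
    valid_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        times = _as_float_array(self.times)
        values = _as_float_array(self.values)
        mask = (
            np.ones(times.shape, dtype=bool)
            if self.valid_mask is None
            else np.asarray(self.valid_mask, dtype=bool)
        )
        if not (times.shape == values.shape == mask.shape):
            raise ValueError("times, values and valid_mask must have equal length")
        check_uniform(times)
        if not self.s0 > 0:
            raise ValueError("baseline signal s0 must be > 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid_mask", mask)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def with_values(self, values, valid_mask=None) -> "SignalSeries":
        return replace(
            self,
            values=values,
            valid_mask=self.valid_mask if valid_mask is None else valid_mask,
        )


@dataclass(frozen=True)
class ConcentrationSeries:
    """Gadolinium concentration (mM) vs. bolus-relative time for one compartment.

    ``compartment`` is one of ``tissue`` (Ct), ``ees`` (Ce), ``intracellular``
    (Ci), ``arterial`` (Ca), ``venous`` (Cv) or ``plasma`` (Cp).
    """

    times: np.ndarray
    values: np.ndarray
    compartment: str
    valid_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; expected one of {sorted(COMPARTMENTS)}"
            )
        times = _as_float_array(self.times)
        values = _as_float_array(self.values)
        mask = (
            np.ones(times.shape, dtype=bool)
            if self.valid_mask is None
            else np.asarray(self.valid_mask, dtype=bool)
        )
        if not (times.shape == values.shape == mask.shape):
            raise ValueError("times, values and valid_mask must have equal length")
        check_uniform(times)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid_mask", mask)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def with_values(self, values, valid_mask=None) -> "ConcentrationSeries":
        return replace(
            self,
            values=values,
            valid_mask=self.valid_mask if valid_mask is None else valid_mask,
        )


def same_grid(a, b, atol: float = 1e-9) -> bool:
    """True if two series share one time grid (to *atol* seconds)."""
    return a.times.shape == b.times.shape and bool(np.allclose(a.times, b.times, atol=atol))


def require_same_grid(a, b, what: str = "series") -> None:
    if not same_grid(a, b):
        raise ValueError(f"{what} must share the same time grid")
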