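"""Forward liver kinetic models as discrete causal convolutions.

Two models are implemented on a shared uniform time grid:

* the single-input reference-region (TRISTAN) model — hepatocyte influx k1
  and efflux k2 acting on the EES concentration Ce (spleen surrogate),
  Ci[n] = dt * sum_m exp(-k2 (t_n - t_m) / vh) * (k1/vh) * Ce[m],
  the closed-form solution of vh dCi/dt = k1 Ce - k2 Ci; and

* the dual-input biexponential (Berks) model — liver impulse response
  h(tau) = a+ exp(-b+ tau) + a- exp(-b- tau) convolved with the plasma input
  Cp = (fa Ca + (1-fa) Cv) / (1 - Hct).

The rectangle-rule convolution carries the dt scaling so discrete results
agree with continuous-time solutions as dt -> 0.  Rates are fitted in s^-1
and reported in min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import ConcentrationSeries, check_uniform, require_same_grid

#: lower parameter bound shared by both models (machine epsilon)
EPS = 2.0**-52
#: upper parameter bound (s^-1 for rates, pure fraction for fa)
UPPER = 1.0


def _check_bounds(name: str, value: float) -> None:
    if not EPS <= value <= UPPER:
        raise ValueError(f"{name} = {value!r} outside [{EPS:g}, {UPPER:g}]")


@dataclass(frozen=True)
class TristanParams:
    """Hepatocyte influx/efflux rates (s^-1) and hepatocyte volume fraction
    vh = 1 - ve_liver."""

    k1: float
    k2: float
    vh: float = 0.77

    def __post_init__(self):
        _check_bounds("k1", self.k1)
        _check_bounds("k2", self.k2)
        if not 0 < self.vh < 1:
            raise ValueError("vh must be in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2])


@dataclass(frozen=True)
class BerksParams:
    """Biexponential impulse-response amplitudes/rates (s^-1) and arterial
    flow fraction fa (dimensionless)."""

    alpha_plus: float
    beta_plus: float
    alpha_minus: float
    beta_minus: float
    fa: float

    def __post_init__(self):
        for name in ("alpha_plus", "beta_plus", "alpha_minus", "beta_minus", "fa"):
            _check_bounds(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_plus, self.beta_plus, self.alpha_minus, self.beta_minus, self.fa])

    def normalized(self) -> "BerksParams":
        """Report the exponential pair with the larger decay rate as (+)."""
        if self.beta_plus >= self.beta_minus:
            return self
        return BerksParams(
            alpha_plus=self.alpha_minus,
            beta_plus=self.beta_minus,
            alpha_minus=self.alpha_plus,
            beta_minus=self.beta_plus,
            fa=self.fa,
        )

    def kernel(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        return self.alpha_plus * np.exp(-self.beta_plus * tau) + self.alpha_minus * np.exp(
            -self.beta_minus * tau
        )


@dataclass(frozen=True)
class Hematocrit:
    hct: float

    def __post_init__(self):
        if not 0 < self.hct < 1:
            raise ValueError("hematocrit must be in (0, 1)")


def _filled(series: ConcentrationSeries) -> np.ndarray:
    """Input values with invalid samples linearly interpolated (convolution
    inputs must be gap-free; residuals still exclude invalid samples)."""
    v = np.asarray(series.values, dtype=float)
    valid = series.valid_mask & np.isfinite(v)
    if valid.all():
        return v
    if not valid.any():
        raise ValueError("input series has no valid samples")
    idx = np.arange(v.size)
    return np.interp(idx, idx[valid], v[valid])


def _causal_convolve(kernel: np.ndarray, values: np.ndarray, dt: float) -> np.ndarray:
    return dt * np.convolve(kernel, values)[: values.size]


def tristan_forward(params: TristanParams, ce: ConcentrationSeries, dt: float | None = None) -> ConcentrationSeries:
    """Intracellular concentration Ci predicted from the EES curve Ce."""
    step = check_uniform(ce.times, dt)
    n = ce.values.size
    tau = np.arange(n) * step
    kernel = (params.k1 / params.vh) * np.exp(-params.k2 * tau / params.vh)
    ci = _causal_convolve(kernel, _filled(ce), step)
    return ConcentrationSeries(times=ce.times, values=ci, compartment="intracellular")


def plasma_input(
    ca: ConcentrationSeries, cv: ConcentrationSeries, fa: float, hct: Hematocrit
) -> ConcentrationSeries:
    """Dual-input plasma concentration Cp = (fa Ca + (1-fa) Cv) / (1 - Hct)."""
    if not 0 <= fa <= 1:
        raise ValueError("fa must be in [0, 1]")
    require_same_grid(ca, cv, "Ca and Cv")
    values = (fa * _filled(ca) + (1.0 - fa) * _filled(cv)) / (1.0 - hct.hct)
    valid = ca.valid_mask & cv.valid_mask
    return ConcentrationSeries(times=ca.times, values=values, compartment="plasma", valid_mask=valid)


def berks_forward(
    params: BerksParams,
    ca: ConcentrationSeries,
    cv: ConcentrationSeries,
    hct: Hematocrit,
    dt: float | None = None,
) -> ConcentrationSeries:
    """Liver tissue concentration Ct predicted from arterial and venous inputs."""
    step = check_uniform(ca.times, dt)
    require_same_grid(ca, cv, "Ca and Cv")
    cp = plasma_input(ca, cv, params.fa, hct)
    tau = np.arange(ca.values.size) * step
    ct = _causal_convolve(params.kernel(tau), _filled(cp), step)
    return ConcentrationSeries(times=ca.times, values=ct, compartment="tissue")


def to_reporting_units(rate_per_s: float) -> float:
    """Convert a rate constant from s^-1 (fitting units) to min^-1."""
    if rate_per_s < 0:
        raise ValueError("rate must be >= 0")
    return rate_per_s * 60.0


def from_reporting_units(rate_per_min: float) -> float:
    """Convert a rate constant from min^-1 (reporting units) to s^-1."""
    if rate_per_min < 0:
        raise ValueError("rate must be >= 0")
    return rate_per_min / 60.0
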