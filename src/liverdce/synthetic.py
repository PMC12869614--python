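"""Synthetic DCE-MRI liver studies with known ground-truth kinetics.

A study is assembled causally: a gamma-variate arterial bolus with a
biexponential washout tail (Ca), a dispersed portal-venous copy (Cv), the
plasma mixture Cp, a fast-equilibrating spleen EES surrogate (Ce), and a
liver curve generated by the TRISTAN or Berks forward model.  Each
compartment is then rendered to SPGR signal intensity with the registry
relaxometry constants and additive Gaussian noise, at the dog (7.65 s) or
pig (13.4-13.5 s) frame interval over a 60-minute session.  The generating
parameters ride along, so every pipeline stage can be tested for parameter
recovery without any imaging download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import conversion
from .constants import default_registry, is_hepatospecific
from .models import (
    BerksParams,
    Hematocrit,
    TristanParams,
    berks_forward,
    from_reporting_units,
    plasma_input,
    tristan_forward,
)
from .preprocessing import DynamicVolume, RoiMask
from .series import AcquisitionParams, ConcentrationSeries, SignalSeries
from .study import StudyData

#: default per-ROI baseline signal levels (arbitrary units)
DEFAULT_S0 = {"liver": 500.0, "spleen": 400.0, "aorta": 300.0, "portal_vein": 300.0}

#: ceiling (min^-1) on hepatocyte uptake allowed for non-hepatospecific agents
NONSPECIFIC_K1_MAX_PER_MIN = 0.01


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate bolus plus biexponential washout tail.

    Ca(t) = amplitude * [ (t/tp)^r exp(r (1 - t/tp))
                          + ramp(t) * (f1 exp(-t/tau1) + f2 exp(-t/tau2)) ]
    with ramp(t) = 1 - exp(-t/tp); zero for t < 0.  The peak sits near
    *peak_time* and the curve is linear in *amplitude*.
    """

    amplitude: float = 2.5  # mM, whole-blood peak
    peak_time: float = 45.0  # s
    shape: float = 3.0  # gamma-variate sharpness r
    tail_fractions: tuple[float, float] = (0.16, 0.06)
    tail_taus: tuple[float, float] = (240.0, 1800.0)

    def __post_init__(self):
        if self.amplitude <= 0 or self.peak_time <= 0 or self.shape <= 0:
            raise ValueError("amplitude, peak_time and shape must be > 0")
        if any(f < 0 for f in self.tail_fractions) or any(t <= 0 for t in self.tail_taus):
            raise ValueError("tail fractions must be >= 0 and taus > 0")


@dataclass(frozen=True)
class Scenario:
    """Complete recipe for one synthetic study."""

    name: str
    species: str
    agent: str
    frame_interval: float
    duration: float = 3600.0
    n_baseline: int = 10
    tristan: TristanParams | None = None
    berks: BerksParams | None = None
    aif: AifParams = field(default_factory=AifParams)
    portal_dispersion_tau: float = 12.0
    spleen_tau: float = 30.0
    fa: float = 0.25
    hct: float = 0.40
    noise_sigma: float = 0.005
    seed: int = 1
    spleen_in_fov: bool = True
    tr: float = 0.005
    flip_angle_deg: float = 15.0

    def __post_init__(self):
        if self.duration < 1800:
            raise ValueError("duration must be >= 1800 s (30 min)")
        if not 1 <= self.frame_interval <= 30:
            raise ValueError("frame_interval must be in [1, 30] s")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.tristan is None and self.berks is None:
            raise ValueError("scenario needs TRISTAN and/or Berks ground truth")
        if (
            self.tristan is not None
            and not is_hepatospecific(self.agent)
            and self.tristan.k1 * 60.0 > NONSPECIFIC_K1_MAX_PER_MIN
        ):
            raise ValueError(
                f"scenario {self.name!r}: hepatospecific uptake "
                f"(k1 = {self.tristan.k1 * 60:g} min^-1) requested for "
                f"non-hepatospecific agent {self.agent!r}"
            )

    @property
    def acq(self) -> AcquisitionParams:
        return AcquisitionParams(
            tr=self.tr,
            flip_angle_deg=self.flip_angle_deg,
            frame_interval=self.frame_interval,
            bolus_time=self.n_baseline * self.frame_interval,
            n_baseline=self.n_baseline,
        )

    def times(self) -> np.ndarray:
        n_post = int(np.ceil(self.duration / self.frame_interval)) + 1
        return (np.arange(-self.n_baseline, n_post)) * self.frame_interval


def _tristan_from_dict(d: dict) -> TristanParams:
    return TristanParams(
        k1=from_reporting_units(d["k1_per_min"]),
        k2=from_reporting_units(d["k2_per_min"]),
        vh=1.0 - d.get("ve_liver", 0.23),
    )


def scenario_from_dict(name: str, d: dict) -> Scenario:
    kwargs = dict(d)
    tristan = kwargs.pop("tristan", None)
    berks = kwargs.pop("berks", None)
    aif = kwargs.pop("aif", None)
    return Scenario(
        name=name,
        tristan=_tristan_from_dict(tristan) if tristan else None,
        berks=BerksParams(**berks) if berks else None,
        aif=AifParams(**aif) if aif else AifParams(),
        **kwargs,
    )


def builtin_scenarios() -> dict[str, Scenario]:
    """The packaged scenario library, keyed by name."""
    with resources.files("liverdce.data").joinpath("scenarios.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {name: scenario_from_dict(name, d) for name, d in raw.items()}


def get_scenario(name: str, **overrides) -> Scenario:
    scenarios = builtin_scenarios()
    if name not in scenarios:
        raise KeyError(f"unknown scenario {name!r}; built-ins: {sorted(scenarios)}")
    base = scenarios[name]
    if overrides:
        from dataclasses import replace

        base = replace(base, **overrides)
    return base


def make_aif(aif: AifParams, times: np.ndarray) -> ConcentrationSeries:
    """Arterial whole-blood concentration curve on the bolus clock."""
    t = np.asarray(times, dtype=float)
    tp, r = aif.peak_time, aif.shape
    u = np.clip(t, 0.0, None) / tp
    with np.errstate(invalid="ignore"):
        bolus = np.where(t > 0, u**r * np.exp(r * (1.0 - u)), 0.0)
    ramp = np.where(t > 0, 1.0 - np.exp(-np.clip(t, 0.0, None) / tp), 0.0)
    tail = np.zeros_like(t)
    for f, tau in zip(aif.tail_fractions, aif.tail_taus):
        tail += f * np.exp(-np.clip(t, 0.0, None) / tau)
    values = aif.amplitude * (bolus + ramp * tail)
    values[t <= 0] = 0.0
    if np.any(values < 0):
        raise ValueError("AIF parameters produced negative concentrations")
    return ConcentrationSeries(times=t, values=values, compartment="arterial")


def _exponential_disperse(series: ConcentrationSeries, tau: float, compartment: str) -> ConcentrationSeries:
    """Convolve with the normalised kernel (1/tau) exp(-t/tau) (rectangle rule,
    kernel renormalised on the discrete grid so mass is preserved)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    dt = series.dt
    n = series.values.size
    kernel = np.exp(-np.arange(n) * dt / tau)
    kernel /= kernel.sum() * dt  # discrete mass preservation
    values = dt * np.convolve(kernel, series.values)[:n]
    return ConcentrationSeries(times=series.times, values=values, compartment=compartment)


def make_portal(ca: ConcentrationSeries, tau: float, dt: float | None = None) -> ConcentrationSeries:
    """Portal-venous curve: the arterial bolus dispersed through the gut with
    a single-exponential transit-time kernel (zero bulk delay)."""
    return _exponential_disperse(ca, tau, "venous")


def make_spleen_ees(cp_like: ConcentrationSeries, tau: float, dt: float | None = None) -> ConcentrationSeries:
    """EES concentration: fast exponential equilibration toward the plasma
    curve (default tau = 30 s)."""
    return _exponential_disperse(cp_like, tau, "ees")


@dataclass
class SyntheticStudy:
    """Ground-truth concentration curves plus rendered noisy signals."""

    scenario: Scenario
    times: np.ndarray
    concentrations: dict[str, ConcentrationSeries]
    signals: dict[str, SignalSeries]

    @property
    def ground_truth(self) -> dict[str, TristanParams | BerksParams]:
        gt = {}
        if self.scenario.tristan is not None:
            gt["tristan"] = self.scenario.tristan
        if self.scenario.berks is not None:
            gt["berks"] = self.scenario.berks
        return gt

    def to_study_data(self) -> StudyData:
        return StudyData(
            signals=dict(self.signals),
            species=self.scenario.species,
            agent=self.scenario.agent,
            acq=self.scenario.acq,
            hct=Hematocrit(self.scenario.hct),
        )


def make_study(scenario: Scenario) -> SyntheticStudy:
    """Build the full synthetic study for *scenario*."""
    reg = default_registry()
    times = scenario.times()
    acq = scenario.acq
    hct = Hematocrit(scenario.hct)

    ca = make_aif(scenario.aif, times)
    cv = make_portal(ca, scenario.portal_dispersion_tau)
    cp = plasma_input(ca, cv, scenario.fa, hct)
    ce = make_spleen_ees(cp, scenario.spleen_tau)

    liver = reg.lookup(scenario.species, scenario.agent, "liver")
    ve = liver.ve
    if scenario.tristan is not None:
        ci = tristan_forward(scenario.tristan, ce)
        ct_values = ve * ce.values + (1.0 - ve) * ci.values
        ct = ConcentrationSeries(times=times, values=ct_values, compartment="tissue")
    else:
        ct = berks_forward(scenario.berks, ca, cv, hct)
        ci_values = (ct.values - ve * ce.values) / (1.0 - ve)
        ci = ConcentrationSeries(times=times, values=ci_values, compartment="intracellular")

    concentrations = {"ca": ca, "cv": cv, "cp": cp, "ce": ce, "ci": ci, "ct": ct}

    spleen = reg.lookup(scenario.species, scenario.agent, "spleen")
    blood = reg.lookup(scenario.species, scenario.agent, "blood")
    render = {
        "liver": (ct, liver.t1_0, liver.r1),
        "spleen": (ce, spleen.t1_0, spleen.r1 * spleen.ve),
        "aorta": (ca, blood.t1_0, blood.r1),
        "portal_vein": (cv, blood.t1_0, blood.r1),
    }
    if not scenario.spleen_in_fov:
        del render["spleen"]

    rng = np.random.default_rng(scenario.seed)
    signals: dict[str, SignalSeries] = {}
    for roi in ("liver", "spleen", "aorta", "portal_vein"):  # fixed draw order
        if roi not in render:
            continue
        curve, t1_0, relaxivity = render[roi]
        s0 = DEFAULT_S0[roi]
        clean = conversion.concentration_to_signal(curve, acq, t1_0, relaxivity, s0)
        noise = rng.normal(0.0, scenario.noise_sigma * s0, size=clean.values.size)
        noisy = clean.values + noise
        # baseline recomputed from the noisy pre-contrast frames, as in a
        # real analysis
        s0_est = conversion.baseline_signal(times, noisy, scenario.n_baseline)
        signals[roi] = SignalSeries(times=times, values=noisy, s0=s0_est)
    return SyntheticStudy(scenario=scenario, times=times, concentrations=concentrations, signals=signals)


# --- 4D phantom ------------------------------------------------------------

_REGIONS = {  # fractional (x, y) boxes painted with each ROI's signal
    "liver": ((0.05, 0.45), (0.05, 0.9)),
    "spleen": ((0.55, 0.9), (0.05, 0.4)),
    "aorta": ((0.55, 0.7), (0.55, 0.7)),
    "portal_vein": ((0.75, 0.9), (0.55, 0.7)),
}


def make_phantom_4d(
    scenario: Scenario, shape: tuple[int, int, int] = (24, 24, 4)
) -> tuple[DynamicVolume, dict[str, RoiMask]]:
    """Rectangular-region 4D phantom whose voxel time courses are the
    scenario's rendered ROI signals plus independent noise."""
    if len(shape) != 3 or shape[0] < 16 or shape[1] < 16 or shape[2] < 4:
        raise ValueError("phantom shape must be 3D and at least (16, 16, 4)")
    study = make_study(scenario)
    nx, ny, nz = shape
    nt = study.times.size
    background = 100.0
    data = np.full((nx, ny, nz, nt), background)
    masks: dict[str, RoiMask] = {}
    occupancy = np.zeros(shape, dtype=bool)
    rng = np.random.default_rng(scenario.seed + 1)
    for roi, ((x0, x1), (y0, y1)) in _REGIONS.items():
        if roi not in study.signals:
            continue
        sl = (
            slice(int(x0 * nx), int(x1 * nx)),
            slice(int(y0 * ny), int(y1 * ny)),
            slice(1, nz - 1) if nz > 2 else slice(0, nz),
        )
        region = np.zeros(shape, dtype=bool)
        region[sl] = True
        if (occupancy & region).any():
            raise ValueError(f"phantom region {roi!r} overlaps a previous region")
        occupancy |= region
        course = study.signals[roi].values
        nvox = int(region.sum())
        noise = rng.normal(0.0, scenario.noise_sigma * DEFAULT_S0[roi], size=(nvox, nt))
        data[region] = course[None, :] + noise
        masks[roi] = RoiMask(mask=region, label=roi)
    data = np.clip(data, 0.0, None)
    vol = DynamicVolume(data=data, frame_interval=scenario.frame_interval, bolus_frame=scenario.n_baseline)
    return vol, masks
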