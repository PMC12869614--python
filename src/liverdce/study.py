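"""Study-level container: ROI signal curves plus acquisition/physiology
context, and the conversion chain that turns them into model-ready
concentration curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import conversion
from .constants import ConstantsRegistry, default_registry
from .models import Hematocrit
from .preprocessing import FilterSpec, blended_median_filter
from .series import AcquisitionParams, ConcentrationSeries, SignalSeries

#: ROI names understood by the pipeline; CSV columns use these names
ROI_NAMES = ("liver", "spleen", "aorta", "portal_vein")


@dataclass
class StudyData:
    """ROI-mean signal curves for one DCE-MRI scan with its context.

    ``signals`` maps ROI name -> :class:`SignalSeries`; missing ROIs (e.g. a
    spleen outside the field of view) are simply absent from the dict.
    """

    signals: dict[str, SignalSeries]
    species: str
    agent: str
    acq: AcquisitionParams
    hct: Hematocrit = field(default_factory=lambda: Hematocrit(0.40))

    def __post_init__(self):
        unknown = set(self.signals) - set(ROI_NAMES)
        if unknown:
            raise ValueError(f"unknown ROI names {sorted(unknown)}; expected {ROI_NAMES}")
        if "liver" not in self.signals:
            raise ValueError("study requires a liver curve")

    def filtered(self, spec: FilterSpec = FilterSpec()) -> "StudyData":
        """Noise-filtered copy (blended median filter in the signal domain)."""
        return StudyData(
            signals={k: blended_median_filter(s, spec) for k, s in self.signals.items()},
            species=self.species,
            agent=self.agent,
            acq=self.acq,
            hct=self.hct,
        )


def convert_study(
    study: StudyData, registry: ConstantsRegistry | None = None
) -> dict[str, ConcentrationSeries]:
    """Convert every available ROI signal to concentration.

    Returns a dict with keys among ``ct`` (liver tissue), ``ce`` (spleen EES
    surrogate), ``ci`` (liver intracellular, when both liver and spleen are
    present), ``ca`` (arterial) and ``cv`` (portal venous).
    """
    reg = registry if registry is not None else default_registry()
    acq = study.acq
    out: dict[str, ConcentrationSeries] = {}

    liver = reg.lookup(study.species, study.agent, "liver")
    r1_liv, valid_liv = conversion.signal_to_relaxation(study.signals["liver"], acq, liver.t1_0)
    out["ct"] = conversion.relaxation_to_tissue_concentration(
        r1_liv, study.signals["liver"].times, liver.r1_0, liver.r1, "tissue", valid_liv
    )

    if "spleen" in study.signals:
        spleen = reg.lookup(study.species, study.agent, "spleen")
        r1_spl, valid_spl = conversion.signal_to_relaxation(
            study.signals["spleen"], acq, spleen.t1_0
        )
        out["ce"] = conversion.spleen_to_ees_concentration(
            r1_spl, study.signals["spleen"].times, spleen.r1_0, spleen.r1, spleen.ve, valid_spl
        )
        out["ci"] = conversion.liver_intracellular_concentration(out["ct"], out["ce"], liver.ve)

    blood = None
    for roi, key, comp in (("aorta", "ca", "arterial"), ("portal_vein", "cv", "venous")):
        if roi in study.signals:
            if blood is None:
                blood = reg.lookup(study.species, study.agent, "blood")
            r1_b, valid_b = conversion.signal_to_relaxation(study.signals[roi], acq, blood.t1_0)
            out[key] = conversion.relaxation_to_tissue_concentration(
                r1_b, study.signals[roi].times, blood.r1_0, blood.r1, comp, valid_b
            )
    return out


def percent_enhancement(series: SignalSeries) -> np.ndarray:
    """Percent signal enhancement over baseline, 100 * (S(t) - S0) / S0."""
    if not series.s0 > 0:
        raise ValueError("s0 must be > 0")
    return 100.0 * (series.values - series.s0) / series.s0
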