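"""SPGR signal-intensity to gadolinium-concentration conversion.

The chain is: normalised signal -> longitudinal relaxation rate R1(t)
(inverting the spoiled-gradient-echo steady-state equation with fixed
pre-contrast R1(0)), then concentration via the in-situ relaxivity,
C(t) = (R1(t) - R1(0)) / r1.  The spleen acts as a surrogate for the liver
EES: Ce = (R1 - R1(0)) / (r1_spleen * ve_spleen), and the hepatocyte
(intracellular) concentration follows from the two-compartment partition
Ci = (Ct - ve * Ce) / (1 - ve).

Noise can push a sample outside the invertible range of the SPGR equation
(normalised enhancement a >= 1, or a non-positive log argument); such samples
are marked invalid rather than clamped, so the peak is never silently biased.
Negative concentrations from noise are retained un-floored so that fitting
objectives see unbiased residuals.
"""

from __future__ import annotations

import numpy as np

from .series import AcquisitionParams, ConcentrationSeries, SignalSeries, require_same_grid


def spgr_signal(r1: np.ndarray, acq: AcquisitionParams, s0: float, r1_0: float) -> np.ndarray:
    """Forward SPGR steady-state signal for relaxation rate *r1* (s^-1).

    Normalised so that ``r1 == r1_0`` yields exactly ``s0``.
    """
    r1 = np.asarray(r1, dtype=float)
    if np.any(r1 <= 0):
        raise ValueError("SPGR signal undefined for non-positive R1")
    cos_t = acq.cos_flip
    e = np.exp(-r1 * acq.tr)
    e0 = np.exp(-r1_0 * acq.tr)
    a = (1.0 - e) / (1.0 - cos_t * e)
    a0 = (1.0 - e0) / (1.0 - cos_t * e0)
    return s0 * a / a0


def signal_to_relaxation(
    series: SignalSeries, acq: AcquisitionParams, t1_0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the SPGR equation: signal series -> R1(t) in s^-1.

    Parameters
    ----------
    t1_0 : fixed pre-contrast T1 in ms.

    Returns
    -------
    (r1, valid) : relaxation-rate array (s^-1) and validity mask.  Samples
    where the inversion has no real positive solution are flagged invalid
    (r1 set to NaN there).
    """
    if t1_0 <= 0:
        raise ValueError("t1_0 must be > 0")
    if not series.s0 > 0:
        raise ValueError("baseline signal s0 must be > 0")
    r1_0 = 1000.0 / t1_0
    cos_t = acq.cos_flip
    e0 = np.exp(-r1_0 * acq.tr)
    a = (series.values / series.s0) * (1.0 - e0) / (1.0 - cos_t * e0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_arg = (1.0 - a) / (1.0 - cos_t * a)
        r1 = -np.log(log_arg) / acq.tr
    valid = series.valid_mask & (a < 1.0) & (log_arg > 0) & np.isfinite(r1) & (r1 > 0)
    r1 = np.where(valid, r1, np.nan)
    if not valid.any():
        raise ValueError("all samples invalid after SPGR inversion of signal series")
    return r1, valid


def relaxation_to_tissue_concentration(
    r1: np.ndarray,
    times: np.ndarray,
    r1_0: float,
    relaxivity: float,
    compartment: str = "tissue",
    valid: np.ndarray | None = None,
) -> ConcentrationSeries:
    """C(t) = (R1(t) - R1(0)) / r1_tissue for liver Ct, aorta Ca or portal Cv."""
    if relaxivity <= 0:
        raise ValueError("relaxivity must be > 0")
    r1 = np.asarray(r1, dtype=float)
    if valid is None:
        valid = np.isfinite(r1)
    values = np.where(valid, (r1 - r1_0) / relaxivity, np.nan)
    return ConcentrationSeries(times=times, values=values, compartment=compartment, valid_mask=valid)


def spleen_to_ees_concentration(
    r1: np.ndarray,
    times: np.ndarray,
    r1_0: float,
    relaxivity_spleen: float,
    ve_spleen: float,
    valid: np.ndarray | None = None,
) -> ConcentrationSeries:
    """Spleen-surrogate EES concentration Ce = (R1 - R1(0)) / (r1_spleen * ve_spleen)."""
    if not 0 < ve_spleen < 1:
        raise ValueError("ve_spleen must be in (0, 1)")
    base = relaxation_to_tissue_concentration(
        r1, times, r1_0, relaxivity_spleen * ve_spleen, compartment="ees", valid=valid
    )
    return base


def liver_intracellular_concentration(
    ct: ConcentrationSeries, ce: ConcentrationSeries, ve_liver: float
) -> ConcentrationSeries:
    """Hepatocyte concentration Ci = (Ct - ve * Ce) / (1 - ve).

    Negative values under noise are retained.  Invalidity propagates: a
    sample is valid only where both Ct and Ce are.
    """
    if not 0 < ve_liver < 1:
        raise ValueError("ve_liver must be in (0, 1)")
    require_same_grid(ct, ce, "Ct and Ce")
    valid = ct.valid_mask & ce.valid_mask
    values = np.where(valid, (ct.values - ve_liver * ce.values) / (1.0 - ve_liver), np.nan)
    return ConcentrationSeries(
        times=ct.times, values=values, compartment="intracellular", valid_mask=valid
    )


def concentration_to_signal(
    c: ConcentrationSeries,
    acq: AcquisitionParams,
    t1_0: float,
    relaxivity: float,
    s0: float,
) -> SignalSeries:
    """Render a concentration series to SPGR signal (exact inverse of the
    conversion chain; used by the synthetic-study generator)."""
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    if relaxivity <= 0:
        raise ValueError("relaxivity must be > 0")
    r1_0 = 1000.0 / t1_0
    r1 = r1_0 + relaxivity * np.asarray(c.values, dtype=float)
    if np.any(r1[c.valid_mask] <= 0):
        raise ValueError("concentration implies non-physical (non-positive) R1")
    values = np.where(c.valid_mask, spgr_signal(np.where(c.valid_mask, r1, r1_0), acq, s0, r1_0), np.nan)
    return SignalSeries(times=c.times, values=values, s0=s0, valid_mask=c.valid_mask)


def baseline_signal(times: np.ndarray, values: np.ndarray, n_baseline: int | None = None) -> float:
    """Mean pre-contrast signal S(0): average of the frames before t = 0.

    By default all strictly pre-bolus frames are used; *n_baseline* restricts
    to the last n of them.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    pre = values[times < 0]
    if pre.size == 0:
        raise ValueError("no pre-contrast frames (times < 0) to form baseline")
    if n_baseline is not None:
        if n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")
        pre = pre[-n_baseline:]
    s0 = float(pre.mean())
    if s0 <= 0:
        raise ValueError("baseline signal s0 must be > 0")
    return s0
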