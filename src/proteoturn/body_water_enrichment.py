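"""Body-water deuterium enrichment from GC-MS acetone-exchange assays.

Plasma water is equilibrated with acetone, and the acetone ion ratio
I59/I58 (selected-ion monitoring of m/z 58 and 59) rises linearly with
percent D2O over the 0-5% calibration range. A straight-line fit of the
external standards is inverted to read plasma samples, and per-period means
give the precursor enrichment used in the turnover model.

The molar percent enrichment (MPE, %) converts to a deuterium-to-protium
mole ratio as MPE/(100 - MPE); the experimental D:H ratio is the natural
background plus that excess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

#: VSMOW deuterium abundance expressed as a D:H mole ratio.
DH_NATURAL = 1.5576e-4


@dataclass
class CalibrationStandardSet:
    """External D2O standards: known percent enrichment with replicate
    m/z 58 / 59 ion intensities."""

    enrichment_pct: np.ndarray  # one entry per replicate measurement
    i58: np.ndarray
    i59: np.ndarray

    def __post_init__(self):
        self.enrichment_pct = np.asarray(self.enrichment_pct, float)
        self.i58 = np.asarray(self.i58, float)
        self.i59 = np.asarray(self.i59, float)
        if np.unique(self.enrichment_pct).size < 2:
            raise ValueError("need >= 2 distinct enrichment levels")
        if np.any(self.i58 <= 0) or np.any(self.i59 <= 0):
            raise ValueError("ion intensities must be positive")

    def mean_ratios(self) -> tuple[np.ndarray, np.ndarray]:
        """(levels, mean replicate I59/I58 per level), levels sorted."""
        ratios = self.i59 / self.i58
        levels = np.unique(self.enrichment_pct)
        means = np.array(
            [ratios[self.enrichment_pct == lv].mean() for lv in levels]
        )
        return levels, means


@dataclass
class CalibrationCurve:
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("calibration curve is not invertible (slope 0)")


@dataclass
class PrecursorEnrichment:
    """Precursor-pool enrichment for one subject in one study period."""

    subject: str
    period: str
    mpe_pct: float
    dh_exp: float
    dh_nat: float = DH_NATURAL

    @property
    def excess(self) -> float:
        return self.dh_exp - self.dh_nat


def fit_calibration(standards: CalibrationStandardSet) -> CalibrationCurve:
    """OLS of mean replicate ion ratio against known percent enrichment."""
    levels, means = standards.mean_ratios()
    res = scipy.stats.linregress(levels, means)
    fitted = res.intercept + res.slope * levels
    resid = means - fitted
    dof = max(len(levels) - 2, 1)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
    )


def enrichment_from_sample(
    curve: CalibrationCurve, ratios: np.ndarray
) -> tuple[float, list[str]]:
    """Invert the calibration for a sample's replicate I59/I58 ratios.

    Returns (MPE %, qc_flags); a negative inversion is clamped to zero and
    flagged rather than propagated.
    """
    ratios = np.asarray(ratios, float)
    if ratios.size == 0:
        raise ValueError("no replicate ratios supplied")
    mpe = (ratios.mean() - curve.intercept) / curve.slope
    flags = []
    if mpe < 0:
        flags.append("negative_enrichment_clamped")
        mpe = 0.0
    return float(mpe), flags


def to_dh_ratio(
    mpe_pct: float,
    subject: str = "",
    period: str = "",
    dh_nat: float = DH_NATURAL,
) -> PrecursorEnrichment:
    """Convert molar percent enrichment to the experimental D:H ratio."""
    if not 0 <= mpe_pct < 100:
        raise ValueError("MPE must lie in [0, 100)")
    dh_exp = dh_nat + mpe_pct / (100.0 - mpe_pct)
    return PrecursorEnrichment(
        subject=subject, period=period, mpe_pct=float(mpe_pct),
        dh_exp=float(dh_exp), dh_nat=float(dh_nat),
    )


@dataclass
class SteadyState:
    mean: float
    sd: float
    stable: bool
    values: np.ndarray = field(repr=False, default=None)


def period_steady_state(
    values: np.ndarray, tolerance: float = 0.5
) -> SteadyState:
    """Mean/SD of a per-day MPE series; stable when max-min <= tolerance."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need >= 2 enrichment values")
    return SteadyState(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        stable=bool(values.max() - values.min() <= tolerance),
        values=values,
    )
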