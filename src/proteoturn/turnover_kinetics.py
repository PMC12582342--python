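"""Rise-to-plateau deuterium labelling kinetics: RIA, k_deg, FSR, ASR.

During D2O labelling the relative isotopomer abundance of a peptide,

    RIA = m1 / (m0 + m1),

rises from its natural baseline toward a plateau set by the peptide's count
N of deuterium-accessible C-H positions and the precursor-pool excess D:H
ratio:

    RIA_plateau = 1 - [ 1/(1 - RIA_t0) + N * (DH_exp - DH_nat) ]^-1

With samples at the start (t0) and end (t1) of a labelling period the
first-order rate constant follows from inverting the mono-exponential
rise, and is adjusted by the end/start abundance ratio to give the
degradation rate constant k_deg. FSR is the unadjusted rate as %/day; the
absolute synthesis rate multiplies k_deg by the protein's absolute
abundance at the end of labelling (ng per ug total protein).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPARTMENTS = ("mitochondrial", "myofibrillar", "sarcoplasmic")


@dataclass
class IsotopomerSeries:
    """m0/m1 intensities of one peptide at the two period boundaries."""

    peptide_id: str
    accession: str
    t0: float
    t1: float
    i_m0_t0: float
    i_m1_t0: float
    i_m0_t1: float
    i_m1_t1: float

    def __post_init__(self):
        if self.t1 <= self.t0:
            raise ValueError("t1 must exceed t0")
        for v in (self.i_m0_t0, self.i_m1_t0, self.i_m0_t1, self.i_m1_t1):
            if v < 0:
                raise ValueError("isotopomer intensities must be >= 0")
        if self.i_m0_t0 + self.i_m1_t0 <= 0 or self.i_m0_t1 + self.i_m1_t1 <= 0:
            raise ValueError("m0 + m1 must be positive at both boundaries")


@dataclass
class TurnoverResult:
    peptide_id: str
    accession: str
    ria_t0: float
    ria_t1: float
    ria_plateau: float
    k: float | None  # /day, unadjusted rise-to-plateau rate
    k_deg: float | None  # /day, abundance-adjusted
    fsr: float | None  # %/day
    p_t0: float | None  # ng/ug total protein
    p_t1: float | None
    asr: float | None  # ng/ug/day
    qc_flags: set = field(default_factory=set)
    rise_frac: float | None = None  # (RIA_t1-RIA_t0)/(plateau-RIA_t0)
    dt: float | None = None  # labelling window (days)
    n_peptides: int = 1
    k_iqr: float = 0.0

    @property
    def usable(self) -> bool:
        return self.k is not None and not self.qc_flags

    @property
    def frac_usable(self) -> bool:
        """Whether the rise fraction may enter protein aggregation.

        Flags that invalidate the fraction itself (no kinetic headroom,
        baseline QC failure) exclude a peptide; a negative or >= 1
        fraction is retained — it is informative noise around the truth
        and dropping it would bias slow proteins upward.
        """
        blocking = {"plateau_too_close", "baseline_deviation"}
        return self.rise_frac is not None and not (self.qc_flags & blocking)


@dataclass
class ProteinRecord:
    accession: str
    mw_kda: float
    compartment: str

    def __post_init__(self):
        if self.mw_kda <= 0:
            raise ValueError("molecular weight must be positive")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")


def compute_ria(i_m0: float, i_m1: float) -> float:
    """RIA = m1 / (m0 + m1)."""
    if i_m0 < 0 or i_m1 < 0:
        raise ValueError("intensities must be non-negative")
    total = i_m0 + i_m1
    if total <= 0:
        raise ValueError("m0 + m1 must be positive")
    return i_m1 / total


def ria_plateau(
    ria_t0: float, n_exch: float, dh_exp: float, dh_nat: float
) -> float:
    """Plateau RIA at full labelling.

    Reduces exactly to ria_t0 when the excess enrichment is zero, and
    increases monotonically in both N and DH_exp toward 1.
    """
    if not 0 <= ria_t0 < 1:
        raise ValueError("RIA_t0 must lie in [0, 1)")
    if n_exch < 0:
        raise ValueError("N must be non-negative")
    if dh_exp < dh_nat:
        raise ValueError("DH_exp must be >= DH_nat")
    excess = dh_exp - dh_nat
    if n_exch * excess == 0.0:
        return ria_t0  # unlabelled limit, exact by construction
    return 1.0 - 1.0 / (1.0 / (1.0 - ria_t0) + n_exch * excess)


def rate_constant(
    ria_t0: float,
    ria_t1: float,
    plateau: float,
    t0: float,
    t1: float,
) -> tuple[float | None, set]:
    """Invert the mono-exponential rise for the rate constant (per day).

    Returns (k, qc_flags). A decline (RIA_t1 < RIA_t0) or a value at or
    beyond the plateau leaves k undefined with a named flag; these are QC
    outcomes, not errors.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if plateau <= ria_t0:
        raise ValueError("plateau must exceed RIA_t0")
    flags: set = set()
    if ria_t1 < ria_t0:
        flags.add("negative_rise")
        return None, flags
    if ria_t1 >= plateau:
        flags.add("at_plateau")
        return None, flags
    frac = (ria_t1 - ria_t0) / (plateau - ria_t0)
    k = -math.log(1.0 - frac) / (t1 - t0)
    return k, flags


def absolute_abundance(fmol_per_ug: float, mw_kda: float) -> float:
    """LFQ relative abundance (fmol/ug) x MW (kDa) -> ng/ug total protein.

    fmol x kDa = pg, hence the 1e-3 factor to report ng/ug.
    """
    if fmol_per_ug < 0 or mw_kda < 0:
        raise ValueError("inputs must be non-negative")
    return fmol_per_ug * mw_kda * 1e-3


def k_deg_adjusted(k: float, p_t0: float, p_t1: float) -> float:
    """Abundance-adjusted degradation rate: k * P(t1)/P(t0)."""
    if p_t0 <= 0:
        raise ValueError("P(t0) must be positive")
    return k * p_t1 / p_t0


def asr(p_t1: float, k_deg: float) -> float:
    """Absolute synthesis rate: P(t1) * k_deg (ng/ug/day)."""
    if not (np.isfinite(p_t1) and np.isfinite(k_deg)):
        raise ValueError("inputs must be finite")
    if p_t1 < 0 or k_deg < 0:
        raise ValueError("inputs must be non-negative")
    return p_t1 * k_deg


def fsr(k: float) -> float:
    """Fractional synthesis rate: the rate constant as %/day."""
    return 100.0 * k


def peptide_turnover(
    series: IsotopomerSeries,
    n_exch: float,
    dh_exp: float,
    dh_nat: float,
    p_t0: float | None = None,
    p_t1: float | None = None,
    min_rise: float = 0.01,
    ria_baseline_check: float | None = None,
    baseline_tol: float = 0.03,
) -> TurnoverResult:
    """Full per-peptide chain: RIA at both boundaries -> plateau -> k ->
    (optionally) abundance-adjusted k_deg, FSR and ASR.

    ``ria_baseline_check`` is the theoretical natural RIA used only as a QC
    cross-check against the measured start value.
    """
    ria0 = compute_ria(series.i_m0_t0, series.i_m1_t0)
    ria1 = compute_ria(series.i_m0_t1, series.i_m1_t1)
    plateau = ria_plateau(ria0, n_exch, dh_exp, dh_nat)
    flags: set = set()
    if ria_baseline_check is not None and abs(ria0 - ria_baseline_check) > baseline_tol:
        flags.add("baseline_deviation")
    k = kd = f = asr_val = frac = None
    if plateau - ria0 < min_rise:
        flags.add("plateau_too_close")
    else:
        frac = (ria1 - ria0) / (plateau - ria0)
        k, kin_flags = rate_constant(ria0, ria1, plateau, series.t0, series.t1)
        flags |= kin_flags
        if k is not None:
            f = fsr(k)
            if p_t0 is not None and p_t1 is not None and p_t0 > 0:
                kd = k_deg_adjusted(k, p_t0, p_t1)
                asr_val = asr(p_t1, kd)
    return TurnoverResult(
        peptide_id=series.peptide_id,
        accession=series.accession,
        ria_t0=ria0,
        ria_t1=ria1,
        ria_plateau=plateau,
        k=k,
        k_deg=kd,
        fsr=f,
        p_t0=p_t0,
        p_t1=p_t1,
        asr=asr_val,
        qc_flags=flags,
        rise_frac=frac,
        dt=series.t1 - series.t0,
    )


def aggregate_protein(peptides: list[TurnoverResult]) -> TurnoverResult | None:
    """Protein-level rate from the median per-peptide rise fraction.

    Per-peptide rise fractions are pooled with the median — including
    negative and >= 1 values, which are symmetric noise around the true
    fraction for slow and fast proteins respectively; excluding them
    before aggregation truncates the noise distribution and biases slow
    proteins upward. The exponential is inverted once, at the protein
    level. A negative aggregate fraction yields a negative rate carried
    with the ``negative_rise`` flag (never clipped); an aggregate >= 1 is
    flagged ``at_plateau`` with no finite rate. Returns None (protein
    dropped) when no peptide fraction survives QC.
    """
    usable = [p for p in peptides if p.frac_usable]
    if not usable:
        return None
    frac_med = float(np.median([p.rise_frac for p in usable]))
    dt = float(np.median([p.dt for p in usable]))
    p_t1 = usable[0].p_t1
    p_t0 = usable[0].p_t0
    flags: set = set()
    k_med = kd_med = f = asr_val = None
    if frac_med >= 1.0:
        flags.add("at_plateau")
    else:
        k_med = -math.log(1.0 - frac_med) / dt
        if k_med < 0:
            flags.add("negative_rise")
        f = fsr(k_med)
        if p_t0 is not None and p_t1 is not None and p_t0 > 0:
            kd_med = k_deg_adjusted(k_med, p_t0, p_t1)
            asr_val = p_t1 * kd_med  # may be negative, carried flagged
    ks = [p.k for p in usable if p.k is not None]
    iqr = float(np.subtract(*np.percentile(ks, [75, 25]))) if len(ks) > 1 else 0.0
    return TurnoverResult(
        peptide_id="*",
        accession=usable[0].accession,
        ria_t0=float(np.median([p.ria_t0 for p in usable])),
        ria_t1=float(np.median([p.ria_t1 for p in usable])),
        ria_plateau=float(np.median([p.ria_plateau for p in usable])),
        k=k_med,
        k_deg=kd_med,
        fsr=f,
        p_t0=p_t0,
        p_t1=p_t1,
        asr=asr_val,
        qc_flags=flags,
        rise_frac=frac_med,
        dt=dt,
        n_peptides=len(usable),
        k_iqr=iqr,
    )


def compartment_sum_asr(
    protein_results: pd.DataFrame,
    annotation: dict[str, ProteinRecord],
) -> pd.DataFrame:
    """Sum protein ASR within each cellular compartment.

    ``protein_results`` needs columns subject, period, accession, asr.
    Proteins missing from the annotation are treated as sarcoplasmic (the
    catch-all soluble pool) and counted in the ``n_unannotated`` column.
    """
    df = protein_results.copy()

    def _comp(acc):
        rec = annotation.get(acc)
        return rec.compartment if rec is not None else "sarcoplasmic"

    df["compartment"] = df["accession"].map(_comp)
    df["unannotated"] = ~df["accession"].isin(annotation)
    out = (
        df.groupby(["subject", "period", "compartment"])
        .agg(asr_sum=("asr", "sum"), n_proteins=("asr", "size"),
             n_unannotated=("unannotated", "sum"))
        .reset_index()
    )
    return out
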