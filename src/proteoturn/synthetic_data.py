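"""In-silico D2O labelling cohort with known ground truth.

Emulates the full data bundle of a three-period (free-living / energy
balance / energy deficit) heavy-water labelling study: peptide mass
isotopomer intensities at every period boundary, label-free peptide
intensity tables with a spiked ADH1 standard, GC-MS body-water
calibration and plasma tables, targeted PRM light/heavy fragment tables,
a physiology table, a compartment annotation table and a protein FASTA —
everything derivable from an explicit GroundTruth plus configured noise.

The labelling forward model is the exact inverse of the analysis: within
each 5-day period the relative isotopomer abundance rises from its
boundary start value toward the plateau fixed by the peptide's
exchangeable-hydrogen count and the subject's precursor enrichment,

    RIA(t) = RIA_t0 + (RIA_plateau - RIA_t0) * (1 - exp(-k t)),

and boundary values chain across consecutive periods. With all noise
levels at zero the pipeline therefore recovers every true rate constant
to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .peptide_isotopes import (
    PeptideSpec,
    composition_from_sequence,
    exchangeable_h_count,
    load_exchangeable_h_table,
    load_isotope_abundances,
    natural_isotope_pattern,
)
from .body_water_enrichment import DH_NATURAL
from .turnover_kinetics import ria_plateau
from .energetics import EEE_TARGET_KCAL_PER_KG_FFM

# typical vertebrate amino-acid frequencies (percent), K/R handled
# separately so sequences digest into tryptic segments
_AA = "ACDEFGHILMNPQSTVWY"
_AA_FREQ = np.array(
    [8.3, 1.4, 5.5, 6.7, 3.5, 7.1, 2.2, 4.3, 9.7, 2.4, 4.0, 6.1, 4.0,
     7.4, 5.3, 6.0, 1.2, 2.7]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

PERIODS = (("FL", -5.0, 0.0), ("EB", 0.0, 5.0), ("ED", 5.0, 10.0))
TIMEPOINTS = (-5, 0, 5, 10)


def forward_ria(ria_t0: float, plateau: float, k: float, t: float) -> float:
    """Mono-exponential rise-to-plateau: RIA after t days of labelling."""
    if plateau < ria_t0:
        raise ValueError("plateau must be >= RIA_t0")
    if k < 0 or t < 0:
        raise ValueError("k and t must be non-negative")
    return ria_t0 + (plateau - ria_t0) * (1.0 - math.exp(-k * t))


@dataclass(frozen=True)
class CohortDesign:
    """Study conditions for the simulated cohort.

    Defaults reproduce the target study layout: 10 subjects, three
    consecutive 5-day periods sampled at days -5/0/5/10, body-water
    enrichment steady near 0.84% with 0.11% between-subject spread, and
    an energy-deficit effect multiplying mitochondrial degradation rates
    (hence summed synthesis) by 1.47.
    """

    n_subjects: int = 10
    n_proteins: int = 300
    peptides_per_protein: int = 5
    target_mpe_pct: float = 0.84
    mpe_between_subject_sd: float = 0.11
    compartment_fractions: tuple = (
        ("sarcoplasmic", 0.53), ("myofibrillar", 0.20), ("mitochondrial", 0.27)
    )
    # lognormal medians of the degradation rate constant (/day)
    k_deg_median: tuple = (
        ("myofibrillar", 0.01), ("sarcoplasmic", 0.05), ("mitochondrial", 0.02)
    )
    k_deg_sigma: float = 0.4
    ed_mito_k_multiplier: float = 1.47
    intensity_cv: float = 0.02  # isotopomer channel noise
    lfq_cv: float = 0.15  # protein-level abundance noise per sample
    peptide_response_sd: float = 0.1  # fixed per-peptide response (log-sd)
    sample_scale_sd: float = 0.2  # per-sample instrument factor (log-sd)
    abundance_fmol_median: float = 5.0
    abundance_fmol_sigma: float = 1.0
    adh1_load_fmol: float = 50.0
    total_protein_ug: float = 1.0
    gcms_slope: float = 0.01  # ion-ratio units per % D2O
    gcms_intercept: float = 0.036  # natural acetone m+1 background
    gcms_noise_sd: float = 1e-4
    gcms_days_per_period: int = 3
    ffm_mean_kg: float = 65.0
    ffm_sd_kg: float = 6.0
    ea_by_period: tuple = (("FL", 40.0), ("EB", 45.0), ("ED", 10.0))

    def __post_init__(self):
        if self.n_subjects < 2 or self.n_proteins < 1:
            raise ValueError("need >= 2 subjects and >= 1 protein")
        if any(f <= 0 for _, f in self.compartment_fractions):
            raise ValueError("compartment fractions must be positive")
        if self.ed_mito_k_multiplier <= 0:
            raise ValueError("condition multipliers must be positive")

    def noiseless(self) -> "CohortDesign":
        return replace(
            self, intensity_cv=0.0, lfq_cv=0.0, gcms_noise_sd=0.0,
            mpe_between_subject_sd=0.0,
        )


SMALL = CohortDesign(n_subjects=4, n_proteins=40, peptides_per_protein=2)
PAPER = CohortDesign()

PRESETS = {"paper": PAPER, "small": SMALL}


@dataclass
class GroundTruth:
    proteins: pd.DataFrame  # accession, compartment, mw_kda, sequence, fmol_per_ug
    peptides: pd.DataFrame  # peptide_id, accession, sequence, n_exch, ria_natural
    kinetics: pd.DataFrame  # accession, period, k_true
    enrichment: pd.DataFrame  # subject, period, mpe_pct, dh_exp


@dataclass
class SimulatedCohort:
    design: CohortDesign
    truth: GroundTruth
    isotopomers: pd.DataFrame
    lfq_peptides: pd.DataFrame
    gcms_standards: pd.DataFrame
    gcms_samples: pd.DataFrame
    prm: pd.DataFrame
    physiology: pd.DataFrame
    annotation: pd.DataFrame
    fasta: dict[str, str]


def _lognoise(rng, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _make_protein(rng) -> tuple[str, list[str]]:
    """Random protein as a concatenation of tryptic segments; returns the
    sequence and its tryptic peptides of usable length (7-25)."""
    n_seg = int(rng.integers(20, 40))
    segments = []
    for _ in range(n_seg):
        length = int(rng.integers(4, 24))
        interior = rng.choice(list(_AA), size=length, p=_AA_FREQ)
        terminus = rng.choice(["K", "R"])
        segments.append("".join(interior) + terminus)
    seq = "".join(segments)
    peptides = [s for s in segments if 7 <= len(s) <= 25]
    return seq, peptides


def simulate_cohort(
    design: CohortDesign = PAPER, seed: int = 0
) -> SimulatedCohort:
    """Generate the full data bundle plus ground truth (deterministic
    under a fixed seed)."""
    rng = np.random.default_rng(seed)
    h_table = load_exchangeable_h_table()
    iso_ab = load_isotope_abundances()

    # ---- proteins, peptides, compartments -------------------------------
    comps, fracs = zip(*design.compartment_fractions)
    n_by_comp = np.floor(np.array(fracs) / sum(fracs) * design.n_proteins).astype(int)
    n_by_comp[0] += design.n_proteins - n_by_comp.sum()
    compartments = np.repeat(comps, n_by_comp)

    prot_rows, pep_rows, fasta = [], [], {}
    k_median = dict(design.k_deg_median)
    fmol_truth = design.abundance_fmol_median * rng.lognormal(
        0.0, design.abundance_fmol_sigma, design.n_proteins
    )
    for i in range(design.n_proteins):
        acc = f"SYN{i:04d}"
        seq, cands = _make_protein(rng)
        while len(cands) < design.peptides_per_protein:
            seq2, cands2 = _make_protein(rng)
            seq, cands = seq + seq2, cands + cands2
        chosen = [cands[int(j)] for j in
                  rng.choice(len(cands), design.peptides_per_protein, replace=False)]
        mw_kda = _pmass.calculate_mass(sequence=seq, average=True) / 1000.0
        fasta[acc] = seq
        prot_rows.append(
            {"accession": acc, "compartment": compartments[i],
             "mw_kda": mw_kda, "sequence": seq,
             "fmol_per_ug": fmol_truth[i]}
        )
        for j, pseq in enumerate(chosen):
            comp = composition_from_sequence(PeptideSpec(sequence=pseq))
            pattern = natural_isotope_pattern(comp, order=2, abundances=iso_ab)
            pep_rows.append(
                {"peptide_id": f"{acc}_p{j}", "accession": acc,
                 "sequence": pseq,
                 "n_exch": exchangeable_h_count(pseq, h_table),
                 "ria_natural": pattern.natural_ria()}
            )
    proteins = pd.DataFrame(prot_rows)
    peptides = pd.DataFrame(pep_rows)

    # ---- true degradation rates per period ------------------------------
    kin_rows = []
    base_k = {}
    for i, acc in enumerate(proteins["accession"]):
        comp = compartments[i]
        base = k_median[comp] * rng.lognormal(0.0, design.k_deg_sigma)
        base_k[acc] = base
        for period, _, _ in PERIODS:
            k_true = base
            if period == "ED" and comp == "mitochondrial":
                k_true = base * design.ed_mito_k_multiplier
            kin_rows.append({"accession": acc, "period": period, "k_true": k_true})
    kinetics = pd.DataFrame(kin_rows)
    k_lookup = kinetics.set_index(["accession", "period"])["k_true"]

    # ---- precursor enrichment per subject/period ------------------------
    subjects = [f"S{i + 1:02d}" for i in range(design.n_subjects)]
    enr_rows = []
    for subj in subjects:
        offset = rng.normal(0.0, design.mpe_between_subject_sd)
        mpe = max(design.target_mpe_pct + offset, 0.05)
        for period, _, _ in PERIODS:
            dh_exp = DH_NATURAL + mpe / (100.0 - mpe)
            enr_rows.append(
                {"subject": subj, "period": period, "mpe_pct": mpe,
                 "dh_exp": dh_exp}
            )
    enrichment = pd.DataFrame(enr_rows)
    dh_lookup = enrichment.set_index(["subject", "period"])["dh_exp"]

    # ---- isotopomer boundary tables -------------------------------------
    iso_rows = []
    pep_idx = peptides.set_index("peptide_id")
    for subj in subjects:
        for pid, prow in pep_idx.iterrows():
            acc = prow["accession"]
            ria = prow["ria_natural"]  # start of FL labelling
            total_i = 1e6
            for period, t0, t1 in PERIODS:
                dh_exp = dh_lookup[(subj, period)]
                plateau = ria_plateau(ria, prow["n_exch"], dh_exp, DH_NATURAL)
                k_true = k_lookup[(acc, period)]
                ria_end = forward_ria(ria, plateau, k_true, t1 - t0)
                for boundary, r in (("start", ria), ("end", ria_end)):
                    noise = _lognoise(rng, design.intensity_cv, 2)
                    iso_rows.append(
                        {"peptide_id": pid, "accession": acc,
                         "subject": subj, "period": period,
                         "boundary": boundary,
                         "i_m0": total_i * (1.0 - r) * noise[0],
                         "i_m1": total_i * r * noise[1]}
                    )
                ria = ria_end
    isotopomers = pd.DataFrame(iso_rows)

    # ---- LFQ peptide intensity table ------------------------------------
    samples = [f"{s}_D{d}" for s in subjects for d in TIMEPOINTS]
    response = rng.lognormal(0.0, design.peptide_response_sd, len(peptides))
    scale = rng.lognormal(0.0, design.sample_scale_sd, len(samples))
    prot_fmol = proteins.set_index("accession")["fmol_per_ug"]
    # protein x sample biological/technical noise, shared by the
    # protein's peptides so protein-level CV matches the configured value
    prot_noise = _lognoise(
        rng, design.lfq_cv, (design.n_proteins, len(samples))
    )
    prot_pos = {a: i for i, a in enumerate(proteins["accession"])}
    lfq_rows = []
    base_response = 1e5 / design.adh1_load_fmol * design.total_protein_ug
    for p_i, prow in peptides.iterrows():
        acc = prow["accession"]
        vals = (
            prot_fmol[acc] * base_response * response[p_i]
            * scale * prot_noise[prot_pos[acc]]
        )
        row = {"accession": acc, "peptide_id": prow["peptide_id"],
               "conflict": False}
        row.update(dict(zip(samples, vals)))
        lfq_rows.append(row)
    # spiked ADH1 standard: constant amount in every sample, >= 3 peptides
    adh1_resp = rng.lognormal(0.0, design.peptide_response_sd, 4)
    for j in range(4):
        vals = design.adh1_load_fmol * base_response * adh1_resp[j] * scale
        row = {"accession": "ADH1_STD", "peptide_id": f"ADH1_p{j}",
               "conflict": False}
        row.update(dict(zip(samples, vals)))
        lfq_rows.append(row)
    lfq_peptides = pd.DataFrame(lfq_rows)

    # ---- GC-MS tables ----------------------------------------------------
    std_rows = []
    for pct in np.arange(0.0, 5.01, 0.5):
        for rep in range(3):
            ratio = (design.gcms_intercept + design.gcms_slope * pct
                     + rng.normal(0.0, design.gcms_noise_sd))
            i58 = 1e5
            std_rows.append(
                {"enrichment_pct": pct, "rep": rep + 1,
                 "i58": i58, "i59": ratio * i58}
            )
    gcms_standards = pd.DataFrame(std_rows)

    smp_rows = []
    mpe_lookup = enrichment.set_index(["subject", "period"])["mpe_pct"]
    for subj in subjects:
        for period, t0, t1 in PERIODS:
            days = np.linspace(t0 + 1, t1, design.gcms_days_per_period)
            for day in days:
                for rep in range(3):
                    ratio = (design.gcms_intercept
                             + design.gcms_slope * mpe_lookup[(subj, period)]
                             + rng.normal(0.0, design.gcms_noise_sd))
                    i58 = 1e5
                    smp_rows.append(
                        {"subject": subj, "period": period,
                         "day": float(day), "rep": rep + 1,
                         "i58": i58, "i59": ratio * i58}
                    )
    gcms_samples = pd.DataFrame(smp_rows)

    # ---- PRM light/heavy fragment table ---------------------------------
    prm_rows = []
    prm_truth = {"PLIN2": (1.0, 0.8), "PLIN5": (0.5, 0.3)}  # (spike, base fmol)
    frag_pattern = np.array([1.0, 0.7, 0.45, 0.25])
    for target, (spike, base) in prm_truth.items():
        for pep in (f"{target}_pep1", f"{target}_pep2"):
            for subj in subjects:
                for day in (0, 5, 10):
                    true_fmol = base * (1.5 if day == 10 else 1.0)
                    lh = true_fmol / spike
                    heavy = frag_pattern * 2e5
                    light = lh * heavy * _lognoise(rng, design.intensity_cv, 4)
                    for f_i in range(4):
                        prm_rows.append(
                            {"target": target, "peptide": pep,
                             "sample": f"{subj}_D{day}",
                             "fragment": f"y{f_i + 3}",
                             "light_i": light[f_i], "heavy_i": heavy[f_i]}
                        )
    prm = pd.DataFrame(prm_rows)

    # ---- physiology ------------------------------------------------------
    phys_rows = []
    ea_by_period = dict(design.ea_by_period)
    rer = {"FL": (0.85, 0.92), "EB": (0.85, 0.92), "ED": (0.78, 0.85)}
    for subj in subjects:
        ffm = rng.normal(design.ffm_mean_kg, design.ffm_sd_kg)
        eee = EEE_TARGET_KCAL_PER_KG_FFM * ffm
        for period, t0, t1 in PERIODS:
            ei = ea_by_period[period] * ffm + eee
            rer_rest, rer_ex = rer[period]
            vo2_rest, vo2_ex = 0.30, 2.5
            phys_rows.append(
                {"subject": subj, "period": period,
                 "energy_intake_kcal": ei, "eee_kcal": eee, "ffm_kg": ffm,
                 "vo2_rest": vo2_rest, "vco2_rest": vo2_rest * rer_rest,
                 "vo2_ex": vo2_ex, "vco2_ex": vo2_ex * rer_ex}
            )
    physiology = pd.DataFrame(phys_rows)

    annotation = proteins[["accession", "compartment", "mw_kda"]].copy()
    truth = GroundTruth(
        proteins=proteins, peptides=peptides, kinetics=kinetics,
        enrichment=enrichment,
    )
    return SimulatedCohort(
        design=design, truth=truth, isotopomers=isotopomers,
        lfq_peptides=lfq_peptides, gcms_standards=gcms_standards,
        gcms_samples=gcms_samples, prm=prm, physiology=physiology,
        annotation=annotation, fasta=fasta,
    )
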