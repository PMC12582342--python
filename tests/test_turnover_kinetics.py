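"""Rise-to-plateau kinetics: RIA, plateau, rate constants, ASR, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

import proteoturn.turnover_kinetics as tk
from proteoturn.body_water_enrichment import DH_NATURAL


class TestRia:
    @pytest.mark.parametrize(
        "m0,m1,expected", [(1.0, 0.0, 0.0), (0.5, 0.5, 0.5), (0.9, 0.3, 0.25)]
    )
    def test_ratio(self, m0, m1, expected):
        assert tk.compute_ria(m0, m1) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            tk.compute_ria(0.0, 0.0)

    def test_scale_free(self, rng):
        m0, m1 = rng.uniform(0.1, 1.0, 2)
        assert tk.compute_ria(m0, m1) == pytest.approx(
            tk.compute_ria(7.3 * m0, 7.3 * m1)
        )


class TestPlateau:
    def test_zero_excess_identity_exact_randomized(self, rng):
        for _ in range(200):
            ria0 = rng.uniform(0.0, 0.95)
            n = rng.uniform(0.0, 40.0)
            assert tk.ria_plateau(ria0, n, DH_NATURAL, DH_NATURAL) == ria0

    def test_worked_example(self):
        got = tk.ria_plateau(0.27, 20.0, DH_NATURAL + 0.0084, DH_NATURAL)
        assert got == pytest.approx(1 - 1 / (1 / 0.73 + 0.168), abs=1e-12)
        assert got == pytest.approx(0.34975, abs=5e-6)

    def test_monotone_in_n_and_enrichment_with_unit_limit(self):
        base = tk.ria_plateau(0.3, 10, DH_NATURAL + 0.008, DH_NATURAL)
        assert tk.ria_plateau(0.3, 20, DH_NATURAL + 0.008, DH_NATURAL) > base
        assert tk.ria_plateau(0.3, 10, DH_NATURAL + 0.016, DH_NATURAL) > base
        assert tk.ria_plateau(0.3, 1e9, DH_NATURAL + 0.5, DH_NATURAL) == pytest.approx(1.0)

    def test_saturated_baseline_rejected(self):
        with pytest.raises(ValueError):
            tk.ria_plateau(1.0, 10, DH_NATURAL + 0.008, DH_NATURAL)


class TestRateConstant:
    def test_no_incorporation_gives_zero(self):
        k, flags = tk.rate_constant(0.3, 0.3, 0.4, 0, 5)
        assert k == 0.0 and not flags

    def test_forward_inverse_round_trip(self):
        ria0, plateau, true_k = 0.27, 0.34975, 0.05
        ria1 = ria0 + (plateau - ria0) * (1 - math.exp(-true_k * 5))
        k, flags = tk.rate_constant(ria0, ria1, plateau, 0, 5)
        assert k == pytest.approx(true_k, abs=1e-12)
        assert not flags

    def test_at_plateau_flagged_without_finite_k(self):
        k, flags = tk.rate_constant(0.3, 0.4, 0.4, 0, 5)
        assert k is None and "at_plateau" in flags

    def test_decline_flagged_not_clipped(self):
        k, flags = tk.rate_constant(0.3, 0.29, 0.4, 0, 5)
        assert k is None and "negative_rise" in flags

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            tk.rate_constant(0.3, 0.35, 0.4, 5, 5)


class TestAbundanceChain:
    def test_unit_conversion(self):
        # 100 fmol/ug x 10 kDa = 1000 pg/ug = 1 ng/ug
        assert tk.absolute_abundance(100, 10) == pytest.approx(1.0)
        assert tk.absolute_abundance(0, 10) == 0.0
        assert tk.absolute_abundance(100, 20) == pytest.approx(
            2 * tk.absolute_abundance(100, 10)
        )

    def test_k_deg_abundance_scaling(self):
        assert tk.k_deg_adjusted(0.05, 1.0, 1.0) == pytest.approx(0.05)
        assert tk.k_deg_adjusted(0.05, 1.0, 2.0) == pytest.approx(0.10)
        assert tk.k_deg_adjusted(0.04, 1.5, 1.2) == pytest.approx(0.032)
        with pytest.raises(ValueError):
            tk.k_deg_adjusted(0.05, 0.0, 1.0)

    def test_asr_identity(self, rng):
        assert tk.asr(2.0, 0.05) == pytest.approx(0.1)
        assert tk.asr(2.0, 0.0) == 0.0
        for _ in range(20):
            p, kd = rng.uniform(0.01, 10), rng.uniform(0.0, 0.5)
            assert tk.asr(p, kd) / p == pytest.approx(kd)

    def test_fsr_is_percent_per_day(self):
        assert tk.fsr(0.05) == pytest.approx(5.0)
        assert tk.fsr(0.0) == 0.0

    def test_asr_invariant_to_intensity_rescaling(self):
        """RIA is scale-free, so rescaling all of a peptide's intensities
        leaves the whole Eq-chain output unchanged."""
        def chain(scale):
            s = tk.IsotopomerSeries(
                "p", "P1", 0, 5,
                i_m0_t0=0.7 * scale, i_m1_t0=0.3 * scale,
                i_m0_t1=0.65 * scale, i_m1_t1=0.35 * scale,
            )
            res = tk.peptide_turnover(
                s, n_exch=20, dh_exp=DH_NATURAL + 0.0084, dh_nat=DH_NATURAL,
                p_t0=1.5, p_t1=1.4,
            )
            return res.asr

        assert chain(1.0) == pytest.approx(chain(123.4), rel=1e-12)


def _pep(frac, dt=5.0, p_t0=1.0, p_t1=1.0, flags=frozenset()):
    k = -math.log(1 - frac) / dt if 0 <= frac < 1 else None
    return tk.TurnoverResult(
        peptide_id="p", accession="P1", ria_t0=0.3, ria_t1=0.32,
        ria_plateau=0.4, k=k, k_deg=k, fsr=None, p_t0=p_t0, p_t1=p_t1,
        asr=None, qc_flags=set(flags), rise_frac=frac, dt=dt,
    )


class TestAggregation:
    def test_single_peptide_protein_equals_it(self):
        res = tk.aggregate_protein([_pep(0.2)])
        assert res.k == pytest.approx(-math.log(0.8) / 5)
        assert res.n_peptides == 1

    def test_median_rise_fraction_then_single_inversion(self):
        fracs = [0.1, 0.25, 0.4]
        res = tk.aggregate_protein([_pep(f) for f in fracs])
        assert res.rise_frac == pytest.approx(0.25)
        assert res.k == pytest.approx(-math.log(1 - 0.25) / 5)

    def test_negative_fraction_retained_in_median(self):
        """A noisy negative rise is informative and must not be dropped
        before pooling — exclusion would bias slow proteins upward."""
        res = tk.aggregate_protein([_pep(-0.05), _pep(0.02), _pep(0.03)])
        assert res.rise_frac == pytest.approx(0.02)
        assert res.k > 0

    def test_negative_aggregate_reported_flagged(self):
        res = tk.aggregate_protein([_pep(-0.1), _pep(-0.2), _pep(0.01)])
        assert res.k < 0
        assert "negative_rise" in res.qc_flags

    def test_gap_flagged_peptides_excluded(self):
        bad = _pep(0.9, flags={"plateau_too_close"})
        res = tk.aggregate_protein([bad, _pep(0.2), _pep(0.3)])
        assert res.n_peptides == 2
        assert res.rise_frac == pytest.approx(0.25)

    def test_no_usable_peptides_drops_protein(self):
        bad = _pep(0.5, flags={"plateau_too_close"})
        assert tk.aggregate_protein([bad]) is None

    def test_aggregate_at_plateau_flagged(self):
        res = tk.aggregate_protein([_pep(1.2), _pep(1.1), _pep(1.3)])
        assert res.k is None and "at_plateau" in res.qc_flags


class TestCompartmentSums:
    def _annotation(self):
        return {
            "M1": tk.ProteinRecord("M1", 30.0, "mitochondrial"),
            "M2": tk.ProteinRecord("M2", 40.0, "mitochondrial"),
            "Y1": tk.ProteinRecord("Y1", 200.0, "myofibrillar"),
        }

    def test_sums_and_partition_conservation(self):
        df = pd.DataFrame(
            {
                "subject": ["s1"] * 4,
                "period": ["EB"] * 4,
                "accession": ["M1", "M2", "Y1", "X9"],
                "asr": [0.1, 0.2, 0.5, 0.05],
            }
        )
        sums = tk.compartment_sum_asr(df, self._annotation())
        by_comp = sums.set_index("compartment")["asr_sum"]
        assert by_comp["mitochondrial"] == pytest.approx(0.3)
        assert by_comp["myofibrillar"] == pytest.approx(0.5)
        # unannotated X9 falls into the sarcoplasmic catch-all
        assert by_comp["sarcoplasmic"] == pytest.approx(0.05)
        assert by_comp.sum() == pytest.approx(df["asr"].sum())
        assert int(sums["n_unannotated"].sum()) == 1

    def test_empty_compartment_absent_sums_conserve(self):
        df = pd.DataFrame(
            {"subject": ["s1"], "period": ["EB"], "accession": ["M1"],
             "asr": [0.1]}
        )
        sums = tk.compartment_sum_asr(df, self._annotation())
        assert sums["asr_sum"].sum() == pytest.approx(0.1)

    def test_invalid_compartment_rejected(self):
        with pytest.raises(ValueError):
            tk.ProteinRecord("P", 10.0, "nuclear")
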