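"""Phenotype decoding, the 50% normalization, replicate stats and fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from splitdrive.crosses import CrossSpec, partner_male, run_cross
from splitdrive.estimators import (
    DecodingError,
    InfeasibleObservationError,
    estimate_frequencies,
    fit_preset_from_observed,
    summarize_replicates,
    ttest_equal_var,
)
from splitdrive.genetics import (
    DepositionContext,
    Genotype,
    PresetRegistry,
    Promoter,
    PromoterPreset,
    Sex,
    WT_CAS9,
    WhiteAllele,
    XChromosomeState,
    YellowAllele,
    ZERO_SOMA,
)
from splitdrive.germline import ZERO_EVENTS


def table_from_counts(counts):
    """Build a phenotype table from (sex, eye, body, gfp, rfp, n) tuples."""
    rows = []
    for sex, eye, body, gfp, rfp, n in counts:
        rows.extend(
            {"generation": "F2", "replicate": 1, "sex": sex, "eye": eye,
             "body": body, "gfp": gfp, "rfp": rfp}
            for _ in range(n)
        )
    return pd.DataFrame(rows)


class TestDecoding:
    def test_fifty_percent_normalization_arithmetic(self):
        """w– father, 75% GFP+ and 25% red GFP−: homing 50%, cleavage 50%."""
        t = table_from_counts([
            ("female", "white", "brown", True, False, 75),
            ("female", "red", "brown", False, False, 25),
        ])
        est = estimate_frequencies(t, "w-")
        assert est["homing"].mean == pytest.approx(50.0)
        assert est["cleavage_w"].mean == pytest.approx(50.0)
        assert est["r2_w"].mean == pytest.approx(0.0)

    def test_all_gfp_means_complete_homing(self):
        t = table_from_counts([("male", "white", "brown", True, False, 40)])
        assert estimate_frequencies(t, "w-")["homing"].mean == pytest.approx(100.0)

    def test_mosaic_eye_decodes_as_intact_allele(self):
        """Somatic patches sit on a functional germline allele."""
        t = table_from_counts([
            ("male", "mosaic", "brown", False, True, 30),
            ("male", "white", "brown", True, True, 30),
        ])
        est = estimate_frequencies(t, "w-")
        assert est["intact_w"].mean == pytest.approx(100.0)
        assert est["r2_w"].mean == pytest.approx(0.0)

    def test_w_plus_father_design_reads_males_only(self):
        t = table_from_counts([
            ("female", "red", "brown", False, False, 50),  # masked daughters
            ("male", "white", "brown", True, False, 30),
            ("male", "red", "brown", False, False, 10),
        ])
        est = estimate_frequencies(t, "w+")
        assert est["homing"].mean == pytest.approx((0.75 - 0.5) * 200)

    def test_w_plus_father_without_males_is_an_error(self):
        t = table_from_counts([("female", "red", "brown", False, False, 10)])
        with pytest.raises(DecodingError):
            estimate_frequencies(t, "w+")

    def test_yellow_scored_in_gfp_negative_males_only(self):
        t = table_from_counts([
            ("male", "white", "yellow", True, False, 50),   # founder y- chromosome
            ("male", "red", "yellow", False, False, 30),    # induced LOF
            ("male", "red", "brown", False, False, 70),     # intact
            ("female", "red", "yellow", False, False, 20),  # excluded: not male
        ])
        est = estimate_frequencies(t, "w-")
        assert est["cleavage_y"].mean == pytest.approx(30.0)

    def test_normalization_identity_for_w_minus_designs(self, registry):
        from splitdrive.crosses import female_class_genotype

        t = run_cross(
            CrossSpec(mother=female_class_genotype("f1_female_1", "BicC"),
                      father=partner_male("w-"), n_progeny=400, seed=6),
            registry,
        )
        est = estimate_frequencies(t, "w-")
        for rep in range(3):
            total = (est["homing"].per_replicate[rep]
                     + est["r2_w"].per_replicate[rep]
                     + est["intact_w"].per_replicate[rep])
            assert total == pytest.approx(100.0, abs=1e-9)


class TestGeneratorRoundTrip:
    def test_known_gamete_distribution_recovered(self):
        """Simulating with fitted (60, 30, 10) parameters and re-estimating
        recovers homing/R2/intact within 3 sigma at n=1e5."""
        params = fit_preset_from_observed(60.0, 30.0, 10.0, "maternal_protein")
        preset = PromoterPreset(Promoter.BICC, "maternal_protein", params,
                                ZERO_SOMA)
        inert = PromoterPreset(Promoter.BICC, "inert", ZERO_EVENTS, ZERO_SOMA)
        reg = PresetRegistry({(Promoter.BICC, "maternal_protein"): preset,
                              (Promoter.BICC, "inert"): inert})
        mother = Genotype(
            Sex.FEMALE,
            XChromosomeState(WhiteAllele.W_GDE, YellowAllele.Y_MINUS),
            XChromosomeState(WhiteAllele.W_PLUS, YellowAllele.Y_PLUS),
            (WT_CAS9, WT_CAS9),
            DepositionContext(maternal_cas9_protein=True, zygotic_grna=True,
                              promoter_of_maternal_source=Promoter.BICC),
        )
        t = run_cross(
            CrossSpec(mother=mother, father=partner_male("w-"),
                      n_replicates=1, n_progeny=100_000, seed=23),
            reg,
        )
        est = estimate_frequencies(t, "w-")
        n_alleles = len(t)  # every row reads one maternal allele; pool is half
        for quantity, truth in (("homing", 60.0), ("r2_w", 30.0), ("intact_w", 10.0)):
            p = truth / 200.0  # gamete-scale probability
            sigma_pct = 200.0 * math.sqrt(p * (1 - p) / n_alleles)
            assert abs(est[quantity].mean - truth) < 3 * sigma_pct, quantity


class TestReplicateStats:
    def test_constant_replicates(self):
        assert summarize_replicates([10, 10, 10]) == (10.0, 0.0)

    def test_cross_promoter_mean_of_printed_values(self):
        mean, _ = summarize_replicates([11.2, 13.2, 18.6, 36.7])
        assert mean == pytest.approx(19.925)

    def test_two_value_sd_closed_form(self):
        a, b = 3.0, 8.0
        _, sd = summarize_replicates([a, b])
        assert sd == pytest.approx(abs(a - b) / math.sqrt(2))

    def test_single_replicate_sd_undefined(self):
        mean, sd = summarize_replicates([42.0])
        assert mean == 42.0 and sd is None


class TestTTest:
    def test_identical_groups(self):
        res = ttest_equal_var([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_closed_form_pooled_variance(self):
        res = ttest_equal_var([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.224745, abs=1e-5)
        assert res.df == 4

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        res = ttest_equal_var(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_matches_permutation_oracle(self):
        """Two-sided p agrees with a label-permutation null within MC error."""
        rng = np.random.default_rng(2)
        a = [1.1, 2.3, 0.7, 1.9, 1.5]
        b = [2.8, 3.1, 2.2, 3.6]
        res = ttest_equal_var(a, b)
        pooled = np.array(a + b)
        na = len(a)
        obs = abs(np.mean(a) - np.mean(b))
        n_perm = 100_000
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[:na].mean() - pooled[na:].mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        mc_err = 3 * math.sqrt(p_perm * (1 - p_perm) / n_perm)
        # permutation p and t p differ by distributional assumptions; allow
        # the MC band plus a small model tolerance on these tiny samples
        assert abs(res.p - p_perm) < mc_err + 0.02

    def test_zero_variance_unequal_means_degenerate(self):
        res = ttest_equal_var([1, 1], [2, 2])
        assert res.p == 0.0 and res.degenerate

    def test_groups_need_two_values(self):
        with pytest.raises(ValueError):
            ttest_equal_var([1], [1, 2])


class TestFitting:
    def test_pure_germline_inversion(self):
        p = fit_preset_from_observed(60, 30, 10)
        assert (p.c_germ_w, p.h) == (pytest.approx(0.9), pytest.approx(2 / 3, abs=1e-3))

    def test_shadow_drive_observation(self):
        p = fit_preset_from_observed(59.3, 38.7, 2.0)
        assert p.c_germ_w == pytest.approx(0.980)
        assert p.h == pytest.approx(0.605, abs=1e-3)

    def test_embryonic_only_context_cannot_home(self):
        with pytest.raises(InfeasibleObservationError):
            fit_preset_from_observed(10, 80, 10, embryonic_only=True)

    def test_embryonic_only_cutting_goes_to_c_emb(self):
        p = fit_preset_from_observed(0, 90, 10, embryonic_only=True)
        assert p.c_emb_w == pytest.approx(0.9) and p.c_germ_w == 0.0

    def test_inert_context_rejects_nonzero_events(self):
        with pytest.raises(InfeasibleObservationError):
            fit_preset_from_observed(10, 10, 80, "inert")
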