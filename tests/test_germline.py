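"""Gamete-distribution model: exact expectations, invariants, stochastic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splitdrive.genetics import (
    DepositionContext,
    Genotype,
    Promoter,
    Sex,
    WT_CAS9,
    WhiteAllele,
    XChromosomeState,
    YellowAllele,
    cas9_transgene,
)
from splitdrive.germline import (
    GermlineEventParams,
    ZERO_EVENTS,
    apply_embryonic_cleavage,
    expected_generation,
    invert_outcome_fractions,
    make_gamete_distribution,
    male_gametes,
)

X_GDE = XChromosomeState(WhiteAllele.W_GDE, YellowAllele.Y_MINUS)
X_WT = XChromosomeState(WhiteAllele.W_PLUS, YellowAllele.Y_PLUS)
X_R2 = XChromosomeState(WhiteAllele.W_R2, YellowAllele.Y_R2)

SHADOW_CTX = DepositionContext(
    maternal_cas9_protein=True, zygotic_grna=True,
    promoter_of_maternal_source=Promoter.BICC,
)
RNP_CTX = DepositionContext(
    maternal_cas9_protein=True, maternal_grna=True, zygotic_grna=True,
    promoter_of_maternal_source=Promoter.BICC,
)


def het_female(ctx=SHADOW_CTX, x2=X_WT, cas9=(WT_CAS9, WT_CAS9)):
    return Genotype(Sex.FEMALE, X_GDE, x2, cas9, ctx)


def white_marginal(dist):
    out = {}
    for x, p in dist.items():
        out[x.white] = out.get(x.white, 0.0) + p
    return out


params_strategy = st.builds(
    GermlineEventParams,
    c_emb_w=st.floats(0, 1), c_germ_w=st.floats(0, 1), h=st.floats(0, 1),
    r1_w=st.floats(0, 1), c_y=st.floats(0, 1), r1_y=st.floats(0, 1),
    c_emb_y=st.floats(0, 1),
)


class TestGameteDistribution:
    def test_mendelian_segregation_without_events(self):
        dist = make_gamete_distribution(het_female(), ZERO_EVENTS)
        assert dist == {X_GDE: 0.5, X_WT: 0.5}

    def test_shadow_drive_white_partition_matches_fitted_outcomes(self):
        """Fitting homing 59.3 / R2 38.7 / intact 2.0 gives GDe gametes at
        0.5 + 0.5*0.593 = 0.7965, R2 at 0.1935 and intact w+ at 0.010."""
        params = invert_outcome_fractions(59.3, 38.7, 2.0)
        w = white_marginal(make_gamete_distribution(het_female(), params))
        assert w[WhiteAllele.W_GDE] == pytest.approx(0.7965)
        assert w[WhiteAllele.W_R2] == pytest.approx(0.19350)
        assert w[WhiteAllele.W_PLUS] == pytest.approx(0.010)

    @given(params=params_strategy)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_resistance_alleles_are_terminal(self, params):
        """R1/R2 chromosomes transmit unchanged under any event parameters."""
        dist = make_gamete_distribution(het_female(x2=X_R2, ctx=RNP_CTX), params)
        assert dist == {X_GDE: 0.5, X_R2: 0.5}

    @given(params=params_strategy, maternal=st.booleans(), zygotic=st.booleans())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_distribution_normalizes_and_stays_in_state_space(
        self, params, maternal, zygotic
    ):
        ctx = DepositionContext(
            maternal_cas9_protein=maternal, zygotic_grna=True,
            zygotic_cas9=zygotic,
            promoter_of_maternal_source=Promoter.NOS if maternal else None,
        )
        cas9 = (cas9_transgene("nos"), WT_CAS9) if zygotic else (WT_CAS9, WT_CAS9)
        dist = make_gamete_distribution(het_female(ctx=ctx, cas9=cas9), params)
        assert math.isclose(sum(dist.values()), 1.0, abs_tol=1e-12)
        for x in dist:
            assert isinstance(x.white, WhiteAllele)
            assert isinstance(x.yellow, YellowAllele)

    def test_embryonic_cutting_cannibalizes_homing_substrate(self):
        """Raising c_emb_w can only reduce the expected drive-allele frequency."""
        prev = 1.0
        for c_emb in np.linspace(0, 1, 11):
            params = GermlineEventParams(c_emb_w=c_emb, c_germ_w=0.95, h=0.7)
            w = white_marginal(make_gamete_distribution(het_female(ctx=RNP_CTX), params))
            gde = w[WhiteAllele.W_GDE]
            assert gde <= prev + 1e-12
            prev = gde

    def test_shadow_drive_homes_without_zygotic_cas9(self):
        params = GermlineEventParams(c_germ_w=0.9, h=0.5)
        mother = het_female(ctx=SHADOW_CTX)  # no Cas9 gene
        assert not mother.carries_cas9_gene
        w = white_marginal(make_gamete_distribution(mother, params))
        assert w[WhiteAllele.W_GDE] > 0.5

    def test_grna_without_any_cas9_source_is_inert(self):
        ctx = DepositionContext(zygotic_grna=True)
        params = GermlineEventParams(c_germ_w=1.0, h=1.0, c_y=1.0)
        dist = make_gamete_distribution(het_female(ctx=ctx), params)
        assert dist == {X_GDE: 0.5, X_WT: 0.5}

    def test_homing_requires_a_donor_chromosome(self):
        """Without a GDe homolog, germline cuts resolve by NHEJ only."""
        mother = Genotype(Sex.FEMALE, X_WT, X_WT, (WT_CAS9, WT_CAS9), RNP_CTX)
        params = GermlineEventParams(c_germ_w=1.0, h=1.0)
        w = white_marginal(make_gamete_distribution(mother, params))
        assert WhiteAllele.W_GDE not in w
        assert w[WhiteAllele.W_R2] == pytest.approx(1.0)

    @given(params=params_strategy)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_cleavable_allele_partition_conserves_mass(self, params):
        w = white_marginal(make_gamete_distribution(het_female(ctx=RNP_CTX), params))
        receiver_half = sum(p for a, p in w.items() if a is not WhiteAllele.W_GDE)
        homed = w.get(WhiteAllele.W_GDE, 0.0) - 0.5
        assert math.isclose(receiver_half + homed, 0.5, abs_tol=1e-12)

    def test_male_input_rejected(self):
        male = Genotype(Sex.MALE, X_GDE, None)
        with pytest.raises(ValueError):
            make_gamete_distribution(male, ZERO_EVENTS)


class TestMaleGametes:
    def test_transmits_single_x_unchanged(self):
        male = Genotype(Sex.MALE, X_WT, None)
        assert male_gametes(male) == {X_WT: 0.5, None: 0.5}

    def test_cas9_father_identical_at_target_loci(self):
        plain = Genotype(Sex.MALE, X_WT, None)
        carrier = Genotype(Sex.MALE, X_WT, None, (cas9_transgene("Ubi"), WT_CAS9))
        assert male_gametes(plain) == male_gametes(carrier)

    def test_female_input_rejected(self):
        with pytest.raises(ValueError):
            male_gametes(het_female())

    def test_sex_ratio_binomial(self):
        rng = np.random.default_rng(42)
        n = 100_000
        y_count = rng.binomial(n, male_gametes(Genotype(Sex.MALE, X_WT, None))[None])
        sigma = math.sqrt(n * 0.25)
        assert abs(y_count - n / 2) < 3 * sigma


class TestEmbryonicCleavage:
    def test_no_maternal_protein_means_no_conversion(self):
        rng = np.random.default_rng(0)
        z = het_female(ctx=DepositionContext(zygotic_grna=True))
        params = GermlineEventParams(c_emb_w=1.0)
        assert apply_embryonic_cleavage(z, params, rng) == z

    def test_complete_rnp_conversion_yields_r2_never_gde(self):
        rng = np.random.default_rng(0)
        z = het_female(ctx=RNP_CTX)
        params = GermlineEventParams(c_emb_w=1.0, r1_w=0.0)
        out = apply_embryonic_cleavage(z, params, rng)
        assert out.x2.white is WhiteAllele.W_R2
        assert out.x1.white is WhiteAllele.W_GDE  # drive allele untouched

    def test_survival_fraction_matches_binomial(self):
        rng = np.random.default_rng(7)
        params = GermlineEventParams(c_emb_w=0.9)
        n = 100_000
        survivors = 0
        z = het_female(ctx=RNP_CTX)
        for _ in range(n):
            if apply_embryonic_cleavage(z, params, rng).x2.white is WhiteAllele.W_PLUS:
                survivors += 1
        sigma = math.sqrt(n * 0.9 * 0.1)
        assert abs(survivors - 0.1 * n) < 3 * sigma


class TestExpectedGeneration:
    def test_mendelian_cross_daughters_half_gfp(self):
        mother = het_female(ctx=DepositionContext(zygotic_grna=True))
        father = Genotype(Sex.MALE, X_WT, None)
        dist = expected_generation([(mother, 1.0)], [(father, 1.0)], ZERO_EVENTS)
        daughters = {g: p for g, p in dist.items() if g.sex is Sex.FEMALE}
        assert sum(daughters.values()) == pytest.approx(0.5)
        gfp = sum(p for g, p in daughters.items() if g.carries_gde)
        assert gfp == pytest.approx(0.25)  # half of the daughters

    def test_distribution_sums_to_one_with_events(self):
        mother = het_female(ctx=RNP_CTX)
        father = Genotype(Sex.MALE, X_WT, None)
        params = GermlineEventParams(c_emb_w=0.5, c_germ_w=0.9, h=0.6, c_y=0.8)
        dist = expected_generation([(mother, 1.0)], [(father, 1.0)], params)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_pool_frequencies_must_normalize(self):
        mother = het_female()
        father = Genotype(Sex.MALE, X_WT, None)
        with pytest.raises(ValueError):
            expected_generation([(mother, 0.7)], [(father, 1.0)], ZERO_EVENTS)


class TestInversion:
    def test_algebraic_inversion(self):
        p = invert_outcome_fractions(60.0, 30.0, 10.0)
        assert p.c_germ_w == pytest.approx(0.9)
        assert p.h == pytest.approx(2 / 3, abs=1e-3)

    def test_no_events_observation(self):
        p = invert_outcome_fractions(0.0, 0.0, 100.0)
        assert p.c_germ_w == 0.0

    def test_inconsistent_r2_rejected(self):
        with pytest.raises(ValueError):
            invert_outcome_fractions(60.0, 10.0, 10.0)

    def test_yellow_inversion_deflates_by_in_frame_fraction(self):
        p = invert_outcome_fractions(0, 0, 100, yellow_lof_pct=89.4, r1_y=0.1)
        assert p.c_y == pytest.approx(0.894 / 0.9)
        # forward check: expected LOF among cut alleles reproduces the input
        assert p.c_y * (1 - p.r1_y) == pytest.approx(0.894)
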