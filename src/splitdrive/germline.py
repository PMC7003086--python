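"""Gamete distributions under cleavage, homing and resistance-allele formation.

A heterozygous female transmits her GDe chromosome unchanged at frequency
0.5.  Her cleavable wild-type *white* allele is partitioned — in expectation —
into {uncut w+, homed wGDe, in-frame wR1, frameshift wR2} by four event
probabilities:

* ``c_emb_w``  — probability of a cut in the early embryo, before the
  developmental stages where HDR is efficient.  Embryonic cuts never home;
  they resolve by NHEJ and convert the whole animal (soma and germline
  precursors alike).  Nonzero only when the egg was loaded with both
  maternal Cas9 protein and gRNA.
* ``c_germ_w`` — probability a still-intact allele is cut at the
  HDR-competent germline stage.
* ``h``        — probability a germline-stage cut is repaired by HDR off the
  GDe donor (homing) rather than by NHEJ.
* ``r1_w``     — in-frame fraction among NHEJ repairs.

The *yellow* effector locus has no homology donor, so its cuts (``c_y``)
resolve by NHEJ only, splitting ``r1_y`` in-frame vs LOF.  Resistance
classes (R1/R2 at either locus, and the founder y– null) are terminal and
pass through every operation unchanged.

:func:`expected_generation` is the exact deterministic oracle the stochastic
cross engine is validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .genetics import (
    Cas9Allele,
    DepositionContext,
    Genotype,
    Sex,
    WhiteAllele,
    XChromosomeState,
    YellowAllele,
    effective_context,
)

__all__ = [
    "GermlineEventParams",
    "ZERO_EVENTS",
    "GameteDistribution",
    "make_gamete_distribution",
    "male_gametes",
    "apply_embryonic_cleavage",
    "expected_generation",
    "offspring_context",
    "invert_outcome_fractions",
]

_TOL = 1e-12


@dataclass(frozen=True)
class GermlineEventParams:
    c_emb_w: float = 0.0
    c_germ_w: float = 0.0
    h: float = 0.0
    r1_w: float = 0.0
    c_y: float = 0.0
    r1_y: float = 0.0
    c_emb_y: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_emb_w", "c_germ_w", "h", "r1_w", "c_y", "r1_y", "c_emb_y"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


ZERO_EVENTS = GermlineEventParams()

#: A gamete distribution maps X-chromosome states (or ``None`` for a
#: Y-bearing sperm) to probabilities summing to 1.
GameteDistribution = dict[Optional[XChromosomeState], float]


def check_distribution(dist: GameteDistribution) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"gamete distribution sums to {total}, not 1")
    if any(p < -_TOL for p in dist.values()):
        raise ValueError("negative gamete probability")


def _accumulate(dist: dict, key, p: float) -> None:
    if p > 0.0:
        dist[key] = dist.get(key, 0.0) + p


def _white_partition(
    white: WhiteAllele,
    donor_present: bool,
    params: GermlineEventParams,
    emb_active: bool,
    germ_active: bool,
) -> dict[WhiteAllele, float]:
    """Expected fate of one white allele through the embryonic then germline stage."""
    if white is not WhiteAllele.W_PLUS:
        return {white: 1.0}  # GDe transmits unchanged; R1/R2 are terminal
    out: dict[WhiteAllele, float] = {}
    p_emb = params.c_emb_w if emb_active else 0.0
    _accumulate(out, WhiteAllele.W_R1, p_emb * params.r1_w)
    _accumulate(out, WhiteAllele.W_R2, p_emb * (1.0 - params.r1_w))
    survive = 1.0 - p_emb
    p_cut = params.c_germ_w if germ_active else 0.0
    p_home = params.h if donor_present else 0.0
    _accumulate(out, WhiteAllele.W_GDE, survive * p_cut * p_home)
    nhej = survive * p_cut * (1.0 - p_home)
    _accumulate(out, WhiteAllele.W_R1, nhej * params.r1_w)
    _accumulate(out, WhiteAllele.W_R2, nhej * (1.0 - params.r1_w))
    _accumulate(out, WhiteAllele.W_PLUS, survive * (1.0 - p_cut))
    return out


def _yellow_partition(
    yellow: YellowAllele,
    params: GermlineEventParams,
    emb_active: bool,
    germ_active: bool,
) -> dict[YellowAllele, float]:
    if yellow is not YellowAllele.Y_PLUS:
        return {yellow: 1.0}
    out: dict[YellowAllele, float] = {}
    p_emb = params.c_emb_y if emb_active else 0.0
    _accumulate(out, YellowAllele.Y_R1, p_emb * params.r1_y)
    _accumulate(out, YellowAllele.Y_R2, p_emb * (1.0 - params.r1_y))
    survive = 1.0 - p_emb
    p_cut = params.c_y if germ_active else 0.0
    _accumulate(out, YellowAllele.Y_R1, survive * p_cut * params.r1_y)
    _accumulate(out, YellowAllele.Y_R2, survive * p_cut * (1.0 - params.r1_y))
    _accumulate(out, YellowAllele.Y_PLUS, survive * (1.0 - p_cut))
    return out


def make_gamete_distribution(
    mother: Genotype,
    params: GermlineEventParams,
    *,
    embryonic_applied: bool = False,
) -> GameteDistribution:
    """Exact expected X-gamete frequencies of a female.

    Cutting requires both a Cas9 source (her inherited transgene or maternal
    carryover protein) and a gRNA source (her own GDe allele or maternal
    carryover gRNA); otherwise segregation is Mendelian.  Homing additionally
    requires a GDe donor on the homologous chromosome.  With
    ``embryonic_applied=True`` the pre-HDR embryonic stage is skipped: the
    genotype is taken as already post-:func:`apply_embryonic_cleavage`
    (the stochastic engine uses this split; marginal frequencies agree).
    """
    if mother.sex is not Sex.FEMALE:
        raise ValueError("gamete distribution with cleavage/homing is defined for females")
    ctx = effective_context(mother)
    germ_active = ctx.has_cas9_source and ctx.has_grna_source
    emb_active = (
        not embryonic_applied
        and ctx.maternal_cas9_protein
        and ctx.has_grna_source
    )
    dist: GameteDistribution = {}
    for own, other in ((mother.x1, mother.x2), (mother.x2, mother.x1)):
        donor = other.white is WhiteAllele.W_GDE
        w_part = _white_partition(own.white, donor, params, emb_active, germ_active)
        y_part = _yellow_partition(own.yellow, params, emb_active, germ_active)
        for w, pw in w_part.items():
            for y, py in y_part.items():
                _accumulate(dist, XChromosomeState(w, y), 0.5 * pw * py)
    check_distribution(dist)
    return dist


def male_gametes(father: Genotype) -> GameteDistribution:
    """X- and Y-bearing sperm at 1:1; no cutting or homing in the male germline."""
    if father.sex is not Sex.MALE:
        raise ValueError("male_gametes requires a male genotype")
    return {father.x1: 0.5, None: 0.5}


def apply_embryonic_cleavage(
    zygote: Genotype,
    params: GermlineEventParams,
    rng,
) -> Genotype:
    """Whole-animal NHEJ conversion of cleavable alleles at the zygote stage.

    Active only when the egg carried maternal Cas9 protein together with a
    gRNA source; cuts resolve to R1/R2 (never the drive allele, since HDR is
    inefficient this early) and apply to soma and germline precursors alike.
    """
    ctx = effective_context(zygote)
    if not (ctx.maternal_cas9_protein and ctx.has_grna_source):
        return zygote

    def convert(x: XChromosomeState) -> XChromosomeState:
        white, yellow = x.white, x.yellow
        if white is WhiteAllele.W_PLUS and rng.random() < params.c_emb_w:
            white = WhiteAllele.W_R1 if rng.random() < params.r1_w else WhiteAllele.W_R2
        if yellow is YellowAllele.Y_PLUS and rng.random() < params.c_emb_y:
            yellow = YellowAllele.Y_R1 if rng.random() < params.r1_y else YellowAllele.Y_R2
        return XChromosomeState(white, yellow)

    return replace(
        zygote,
        x1=convert(zygote.x1),
        x2=None if zygote.x2 is None else convert(zygote.x2),
    )


def offspring_context(mother: Genotype, offspring_x: tuple, offspring_cas9: tuple) -> DepositionContext:
    """Deposition context of an offspring, derived from what its mother carried."""
    deposits = mother.carries_cas9_gene
    return DepositionContext(
        maternal_cas9_protein=deposits,
        maternal_grna=mother.carries_gde,
        zygotic_cas9=any(a.is_transgene for a in offspring_cas9),
        zygotic_grna=any(x.carries_gde for x in offspring_x if x is not None),
        promoter_of_maternal_source=mother.cas9_promoter if deposits else None,
    )


def _cas9_gametes(ind: Genotype) -> dict[Cas9Allele, float]:
    a, b = ind.cas9
    if a == b:
        return {a: 1.0}
    return {a: 0.5, b: 0.5}


def expected_generation(
    mother_pool: list[tuple[Genotype, float]],
    father_pool: list[tuple[Genotype, float]],
    params: GermlineEventParams,
) -> dict[Genotype, float]:
    """Exact offspring genotype distribution: the oracle for the stochastic engine.

    Convolves maternal gamete distributions (embryonic stage included in
    expectation) with paternal X/Y segregation and independent autosomal
    Cas9 segregation; offspring contexts follow from the mother's carriage.
    """
    for name, pool in (("mother", mother_pool), ("father", father_pool)):
        total = sum(f for _, f in pool)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{name} pool frequencies sum to {total}, not 1")
    out: dict[Genotype, float] = {}
    for mother, fm in mother_pool:
        egg_dist = make_gamete_distribution(mother, params)
        cas9_m = _cas9_gametes(mother)
        for father, ff in father_pool:
            sperm_dist = male_gametes(father)
            cas9_f = _cas9_gametes(father)
            for egg, pe in egg_dist.items():
                for sperm, ps in sperm_dist.items():
                    for cm, pcm in cas9_m.items():
                        for cf, pcf in cas9_f.items():
                            cas9 = (cm, cf)
                            if sperm is None:
                                sex, x1, x2 = Sex.MALE, egg, None
                            else:
                                sex, x1, x2 = Sex.FEMALE, egg, sperm
                            ctx = offspring_context(mother, (x1, x2), cas9)
                            child = Genotype(sex, x1, x2, cas9, ctx)
                            _accumulate(out, child, fm * ff * pe * ps * pcm * pcf)
    total = sum(out.values())
    assert math.isclose(total, 1.0, abs_tol=1e-9)
    return out


def invert_outcome_fractions(
    homing_pct: float,
    r2_pct: float,
    intact_pct: float,
    *,
    yellow_lof_pct: float = 0.0,
    r1_w: float = 0.0,
    r1_y: float = 0.1,
    c_emb_w: float = 0.0,
    tol: float = 1.5,
) -> GermlineEventParams:
    """Invert observed germline outcome percentages into event probabilities.

    For a pure germline context: ``c_germ = (100 − intact)/100`` and
    ``h = homing/(100 − intact)``.  The observed LOF (R2) share is checked for
    consistency against the implied NHEJ split within ``tol`` percentage
    points.  Observed yellow LOF is deflated by the in-frame fraction:
    ``c_y = yellow_lof/(100·(1 − r1_y))``.  ``c_emb_w`` is attached verbatim
    (the germline-stage observations are conditional on surviving the embryo).
    """
    for name, v in (("homing", homing_pct), ("r2", r2_pct), ("intact", intact_pct)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} percentage {v} outside [0, 100]")
    if homing_pct + r2_pct + intact_pct > 100.0 + tol:
        raise ValueError("homing + r2 + intact exceeds 100%")
    cleaved = 100.0 - intact_pct
    c_germ = cleaved / 100.0
    h = 0.0 if cleaved <= 0 else homing_pct / cleaved
    if h > 1.0 + 1e-9:
        raise ValueError("homing exceeds total cleavage")
    implied_r2 = cleaved * (1.0 - h) * (1.0 - r1_w)
    if abs(implied_r2 - r2_pct) > tol:
        raise ValueError(
            f"observed R2 {r2_pct}% inconsistent with implied {implied_r2:.2f}% "
            f"under r1_w={r1_w}"
        )
    if not 0.0 <= yellow_lof_pct <= 100.0:
        raise ValueError("yellow LOF percentage outside [0, 100]")
    c_y = yellow_lof_pct / (100.0 * (1.0 - r1_y)) if yellow_lof_pct else 0.0
    if c_y > 1.0:
        raise ValueError("yellow LOF observation implies cut probability > 1")
    return GermlineEventParams(
        c_emb_w=c_emb_w,
        c_germ_w=c_germ,
        h=min(h, 1.0),
        r1_w=r1_w,
        c_y=c_y,
        r1_y=r1_y,
    )
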