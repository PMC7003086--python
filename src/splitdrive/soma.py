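"""Phenotype rendering: eye/body color, mosaicism, and fluorescent markers.

Constitutive genetics are deterministic: GFP reports carriage of the drive
element, RFP the Cas9 transgene; eye color follows the white-locus classes
(GDe insertion, R2 and the founder situation are nulls; w+ and the in-frame
wR1 are functional) and body color the yellow-locus classes.  On top of that,
an individual with an active nuclease (zygotic Cas9 gene or maternal
carryover protein, plus a gRNA source) and a cleavable allele is scored
visibly mosaic at that locus with the promoter- and context-specific
penetrance.  Mosaicism is a per-fly, per-locus presence/absence call, not a
patch-area model, and is distinct from constitutive loss of function so the
estimators can exclude somatic noise when decoding germline-transmitted
alleles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .genetics import (
    FUNCTIONAL_WHITE,
    FUNCTIONAL_YELLOW,
    Genotype,
    Sex,
    SomaticPenetrance,
    WhiteAllele,
    YellowAllele,
    effective_context,
)

__all__ = ["Eye", "Body", "PhenotypeRecord", "render_phenotype"]


class Eye(enum.Enum):
    RED = "red"
    WHITE = "white"
    MOSAIC = "mosaic"


class Body(enum.Enum):
    BROWN = "brown"
    YELLOW = "yellow"
    MOSAIC = "mosaic"


@dataclass(frozen=True)
class PhenotypeRecord:
    """What a scorer sees on one fly: the estimators' only input."""

    sex: Sex
    eye: Eye
    body: Body
    gfp: bool
    rfp: bool


def render_phenotype(ind: Genotype, preset: SomaticPenetrance, rng) -> PhenotypeRecord:
    """Score one fly: constitutive genetics first, then mosaicism draws."""
    xs = ind.x_chromosomes
    gfp = any(x.white is WhiteAllele.W_GDE for x in xs)
    rfp = ind.carries_cas9_gene

    functional_w = [x.white in FUNCTIONAL_WHITE for x in xs]
    functional_y = [x.yellow in FUNCTIONAL_YELLOW for x in xs]
    eye = Eye.RED if any(functional_w) else Eye.WHITE
    body = Body.BROWN if any(functional_y) else Body.YELLOW

    ctx = effective_context(ind)
    active = ctx.has_cas9_source and ctx.has_grna_source
    if active:
        # Somatic cutting shows only where every functional copy on display is
        # cleavable (an uncleavable in-frame R1 copy masks mosaic patches).
        w_func = [x.white for x in xs if x.white in FUNCTIONAL_WHITE]
        exposed_w = bool(w_func) and all(w is WhiteAllele.W_PLUS for w in w_func)
        if eye is Eye.RED and exposed_w and rng.random() < preset.p_som_white:
            eye = Eye.MOSAIC
        y_func = [x.yellow for x in xs if x.yellow in FUNCTIONAL_YELLOW]
        exposed_y = bool(y_func) and all(y is YellowAllele.Y_PLUS for y in y_func)
        if body is Body.BROWN and exposed_y and rng.random() < preset.p_som_yellow:
            body = Body.MOSAIC
    return PhenotypeRecord(ind.sex, eye, body, gfp, rfp)
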