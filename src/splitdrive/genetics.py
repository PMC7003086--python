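"""Allele, genotype and deposition-context state space of the split homing drive.

The drive element (GDe) sits in the X-linked *white* locus and carries two
gRNAs — a driver gRNA against *white* and a cargo effector gRNA against
*yellow* — plus a GFP eye marker.  Cas9 is supplied from a separate autosomal
transgene (RFP-marked) under one of four promoters, or as maternally
deposited protein.  All alleles are symbolic classes: the simulator never
represents cassette sequence.

The promoter preset registry maps (promoter, deposition context) to the
germline event parameters and somatic penetrances fitted from observed cross
outcomes; presets live in a bundled YAML file so they can be regenerated from
the observation table with :func:`splitdrive.estimators.fit_preset_from_observed`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import yaml

__all__ = [
    "WhiteAllele",
    "YellowAllele",
    "XChromosomeState",
    "Cas9Class",
    "Promoter",
    "Cas9Allele",
    "DepositionContext",
    "Sex",
    "Genotype",
    "SomaticPenetrance",
    "PromoterPreset",
    "PresetRegistry",
    "ConfigurationError",
    "context_key",
    "load_default_registry",
]


class ConfigurationError(ValueError):
    """Unknown promoter, unregistered context, or malformed preset data."""


class WhiteAllele(enum.Enum):
    """Allele classes at the *white* locus (drive target)."""

    W_PLUS = "w+"      # wild type, cleavable, red eye
    W_GDE = "wGDe"     # drive element insertion: gRNAs + GFP, white eye (null)
    W_R1 = "wR1"       # in-frame NHEJ product: functional (red eye), uncleavable
    W_R2 = "wR2"       # frameshift NHEJ product: loss of function, uncleavable


class YellowAllele(enum.Enum):
    """Allele classes at the *yellow* locus (effector target, no homing donor)."""

    Y_PLUS = "y+"      # wild type, cleavable, brown body
    Y_MINUS = "y-"     # founder-line null carried on the GDe chromosome
    Y_R1 = "yR1"       # in-frame NHEJ product, functional
    Y_R2 = "yR2"       # Cas9-induced loss of function


#: Resistance classes are terminal: no operation may rewrite them.
TERMINAL_WHITE = frozenset({WhiteAllele.W_R1, WhiteAllele.W_R2})
TERMINAL_YELLOW = frozenset({YellowAllele.Y_R1, YellowAllele.Y_R2, YellowAllele.Y_MINUS})

#: Phenotypically functional (red-eye / brown-body) classes.
FUNCTIONAL_WHITE = frozenset({WhiteAllele.W_PLUS, WhiteAllele.W_R1})
FUNCTIONAL_YELLOW = frozenset({YellowAllele.Y_PLUS, YellowAllele.Y_R1})


@dataclass(frozen=True)
class XChromosomeState:
    """One X chromosome: its white-locus and yellow-locus allele classes.

    A chromosome with ``white == W_GDE`` carries both gRNAs and the GFP
    marker.  The canonical drive founder chromosome is ``(W_GDE, Y_MINUS)``.
    """

    white: WhiteAllele
    yellow: YellowAllele

    @property
    def carries_gde(self) -> bool:
        return self.white is WhiteAllele.W_GDE


class Cas9Class(enum.Enum):
    PLUS = "+"
    CAS9 = "Cas9"


class Promoter(enum.Enum):
    """Promoters driving the autosomal SpCas9 transgene."""

    NOS = "nos"    # nanos: early germline-limited
    VAS = "vas"    # vasa: early germline-limited
    BICC = "BicC"  # Bicaudal C: late germline-limited, strong deposition
    UBI = "Ubi"    # Ubiquitin 63E: germline + soma

    @classmethod
    def parse(cls, name: str) -> "Promoter":
        for p in cls:
            if p.value.lower() == str(name).lower():
                return p
        raise ConfigurationError(
            f"unknown promoter {name!r}; expected one of "
            + ", ".join(p.value for p in cls)
        )


@dataclass(frozen=True)
class Cas9Allele:
    """One autosomal Cas9-locus allele; the transgene carries the RFP marker."""

    cls: Cas9Class = Cas9Class.PLUS
    promoter: Optional[Promoter] = None

    def __post_init__(self) -> None:
        if self.cls is Cas9Class.CAS9 and self.promoter is None:
            raise ValueError("a Cas9 transgene allele needs a promoter")
        if self.cls is Cas9Class.PLUS and self.promoter is not None:
            raise ValueError("a wild-type Cas9-locus allele has no promoter")

    @property
    def is_transgene(self) -> bool:
        return self.cls is Cas9Class.CAS9


WT_CAS9 = Cas9Allele()


def cas9_transgene(promoter: Promoter | str) -> Cas9Allele:
    if isinstance(promoter, str):
        promoter = Promoter.parse(promoter)
    return Cas9Allele(Cas9Class.CAS9, promoter)


@dataclass(frozen=True)
class DepositionContext:
    """What nuclease/gRNA sources an individual received at fertilization.

    ``maternal_cas9_protein`` / ``maternal_grna`` record carryover loaded into
    the egg by the mother (protein only if she carried a Cas9 transgene, gRNA
    only if she carried a GDe allele).  Paternal Cas9 never sets a protein
    flag — sperm carries too little protein to act — only ``zygotic_cas9``
    through the inherited gene.
    """

    maternal_cas9_protein: bool = False
    maternal_grna: bool = False
    zygotic_cas9: bool = False
    zygotic_grna: bool = False
    promoter_of_maternal_source: Optional[Promoter] = None

    def __post_init__(self) -> None:
        if self.maternal_cas9_protein and self.promoter_of_maternal_source is None:
            raise ValueError("maternal Cas9 protein requires its source promoter")

    @property
    def has_cas9_source(self) -> bool:
        return self.maternal_cas9_protein or self.zygotic_cas9

    @property
    def has_grna_source(self) -> bool:
        return self.maternal_grna or self.zygotic_grna


INERT_CONTEXT = DepositionContext()


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"


@dataclass(frozen=True)
class Genotype:
    """Sex, one or two X chromosomes, the autosomal Cas9 pair, and context.

    Males carry exactly one X (``x2 is None``); homing is impossible in males
    because there is no homologous receiver chromosome.
    """

    sex: Sex
    x1: XChromosomeState
    x2: Optional[XChromosomeState]
    cas9: tuple[Cas9Allele, Cas9Allele] = (WT_CAS9, WT_CAS9)
    context: DepositionContext = INERT_CONTEXT

    def __post_init__(self) -> None:
        if self.sex is Sex.MALE and self.x2 is not None:
            raise ValueError("males are hemizygous: exactly one X chromosome")
        if self.sex is Sex.FEMALE and self.x2 is None:
            raise ValueError("females carry two X chromosomes")

    @property
    def x_chromosomes(self) -> tuple[XChromosomeState, ...]:
        return (self.x1,) if self.x2 is None else (self.x1, self.x2)

    @property
    def carries_gde(self) -> bool:
        return any(x.carries_gde for x in self.x_chromosomes)

    @property
    def carries_cas9_gene(self) -> bool:
        return any(a.is_transgene for a in self.cas9)

    @property
    def cas9_promoter(self) -> Optional[Promoter]:
        for a in self.cas9:
            if a.is_transgene:
                return a.promoter
        return None

    def with_context(self, context: DepositionContext) -> "Genotype":
        return replace(self, context=context)


# ---------------------------------------------------------------------------
# Deposition-context keys and the promoter preset registry
# ---------------------------------------------------------------------------

#: Registry context keys.  "inert" = no cutting possible (missing Cas9 or
#: gRNA source, e.g. paternal-protein-only females); "maternal_protein" =
#: carryover protein with the individual's own GDe providing gRNA (F1 females
#: from Cas9 mothers); "maternal_rnp" = protein AND gRNA carryover (F2 females
#: whose mother carried both GDe and Cas9) — cutting starts pre-HDR in the
#: early embryo; "zygotic" = inherited Cas9 gene only (paternal Cas9).
CONTEXT_KEYS = ("inert", "maternal_protein", "maternal_rnp", "zygotic")


def context_key(context: DepositionContext) -> str:
    """Collapse a DepositionContext into the registry's preset key."""
    if not (context.has_cas9_source and context.has_grna_source):
        return "inert"
    if context.maternal_cas9_protein and context.maternal_grna:
        return "maternal_rnp"
    if context.maternal_cas9_protein:
        return "maternal_protein"
    return "zygotic"


@dataclass(frozen=True)
class SomaticPenetrance:
    """Probability that a cleavable locus is scored visibly mosaic in the soma."""

    p_som_white: float = 0.0
    p_som_yellow: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_som_white, self.p_som_yellow):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"penetrance {p} outside [0, 1]")


ZERO_SOMA = SomaticPenetrance()


@dataclass(frozen=True)
class PromoterPreset:
    """Fitted per-promoter, per-context event parameters.

    ``germline`` is a :class:`splitdrive.germline.GermlineEventParams`;
    ``soma`` the mosaicism penetrances; ``strong_maternal_deposition`` flags
    promoters whose carryover protein also mutates the effector locus in germ
    cells (BicC, Ubi).
    """

    promoter: Promoter
    context: str
    germline: "object"  # GermlineEventParams; typed loosely to avoid a cycle
    soma: SomaticPenetrance
    strong_maternal_deposition: bool = False


class PresetRegistry:
    """Lookup of promoter × context parameter slices."""

    def __init__(self, presets: dict[tuple[Promoter, str], PromoterPreset]):
        self._presets = presets

    def get(self, promoter: Promoter | str, context: DepositionContext | str) -> PromoterPreset:
        if isinstance(promoter, str):
            promoter = Promoter.parse(promoter)
        key = context if isinstance(context, str) else context_key(context)
        if key not in CONTEXT_KEYS:
            raise ConfigurationError(f"unregistered context key {key!r}")
        try:
            return self._presets[(promoter, key)]
        except KeyError:
            raise ConfigurationError(
                f"no preset registered for promoter {promoter.value!r}, context {key!r}"
            ) from None

    def with_override(
        self,
        promoter: Promoter | str,
        context: str,
        germline: Optional[object] = None,
        soma: Optional[SomaticPenetrance] = None,
    ) -> "PresetRegistry":
        """A copy of the registry with one preset slice replaced (e.g. freshly
        fitted parameters for a round-trip experiment)."""
        if isinstance(promoter, str):
            promoter = Promoter.parse(promoter)
        current = self.get(promoter, context)
        new = replace(
            current,
            germline=germline if germline is not None else current.germline,
            soma=soma if soma is not None else current.soma,
        )
        presets = dict(self._presets)
        presets[(promoter, context)] = new
        return PresetRegistry(presets)

    def params_for_mother(self, mother: Genotype) -> "object":
        """Germline event parameters applying in a given female's germ cells.

        The promoter is her own transgene's if she carries one, else the
        maternal carryover source's.
        """
        key = context_key(effective_context(mother))
        if key == "inert":
            from .germline import ZERO_EVENTS

            return ZERO_EVENTS
        promoter = mother.cas9_promoter or mother.context.promoter_of_maternal_source
        return self.get(promoter, key).germline

    def soma_for(self, ind: Genotype) -> SomaticPenetrance:
        key = context_key(effective_context(ind))
        if key == "inert":
            return ZERO_SOMA
        promoter = ind.cas9_promoter or ind.context.promoter_of_maternal_source
        return self.get(promoter, key).soma


def effective_context(ind: Genotype) -> DepositionContext:
    """Context with the zygotic flags reconciled against the carried alleles."""
    return replace(
        ind.context,
        zygotic_cas9=ind.carries_cas9_gene,
        zygotic_grna=ind.carries_gde,
    )


def load_default_registry() -> tuple[PresetRegistry, dict]:
    """Load the bundled preset file.

    Returns the registry plus the raw ``observed`` block (the printed cross
    outcome frequencies the presets were fitted from), which downstream code
    uses as worked-example inputs.
    """
    from .germline import GermlineEventParams, invert_outcome_fractions

    text = resources.files("splitdrive.data").joinpath("presets.yaml").read_text()
    raw = yaml.safe_load(text)
    presets: dict[tuple[Promoter, str], PromoterPreset] = {}
    for pname, contexts in raw["promoters"].items():
        promoter = Promoter.parse(pname)
        strong = bool(contexts.get("strong_maternal_deposition", False))
        for ckey in CONTEXT_KEYS:
            if ckey == "inert":
                from .germline import ZERO_EVENTS

                presets[(promoter, ckey)] = PromoterPreset(
                    promoter, ckey, ZERO_EVENTS, ZERO_SOMA, strong
                )
                continue
            block = contexts[ckey]
            obs = block["observed"]
            germ = invert_outcome_fractions(
                homing_pct=obs["homing"],
                r2_pct=obs["r2"],
                intact_pct=obs["intact"],
                yellow_lof_pct=obs.get("yellow_lof", 0.0),
                r1_w=block.get("r1_w", 0.0),
                r1_y=block.get("r1_y", 0.1),
                c_emb_w=block.get("c_emb_w", 0.0),
            )
            soma = SomaticPenetrance(
                p_som_white=block["soma"]["white"],
                p_som_yellow=block["soma"]["yellow"],
            )
            presets[(promoter, ckey)] = PromoterPreset(promoter, ckey, germ, soma, strong)
    return PresetRegistry(presets), raw.get("observed", {})
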