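"""Exact Punnett-square calculators for rescue-based drive designs.

Two proposed architectures counter resistance-allele accumulation by
targeting a haplo-sufficient essential gene (EG) and carrying a recoded,
cleavage-resistant rescue, plus a cargo gRNA-mediated effector (GME) that
knocks out an unlinked host gene (HG):

* **HGD+R+GME** — a homing drive inserted in the EG: germline cuts on the
  receiver chromosome are either converted by HDR (rate ``h``) or become
  non-rescued lesions; maternally deposited Cas9/gRNA cleaves every
  remaining wild-type EG allele in the zygote, so offspring without the
  rescue die of lethal biallelic mosaicism.
* **CGD+R+GME** — cleavage-only: no HDR (``h`` forced to 0); biased
  inheritance comes purely from the death of non-carriers.

The EG locus is collapsed to three allele classes — ``D`` (drive + rescue
haplotype), ``WT`` (intact, cleavable) and ``CLV`` (cleaved, non-rescued) —
plus an optional in-frame functional ``R1`` class that is immune to cutting
and viable.  The HG effector locus is modeled as unlinked, cut with the same
deposition completeness; "refractoriness" is the fraction of viable
offspring with both HG alleles knocked out.

:func:`simulate_spread` iterates the calculator as a deterministic
infinite-population, random-mating recursion with viability renormalization
each generation.  Setting ``lethal_mosaicism=False`` recovers a neutral
split-drive recursion (the *white*-target configuration) in which cleaved
alleles simply accumulate as resistance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "EGAllele",
    "ArchitectureSpec",
    "OffspringOutcome",
    "punnett_offspring",
    "drive_transmission",
    "viable_fraction",
    "refractoriness",
    "simulate_spread",
    "r1_leakage",
    "split_white_preset",
]

# Essential-gene locus allele classes.
D = "D"      # drive construct with recoded rescue
WT = "WT"    # wild type: cleavable, functional
CLV = "CLV"  # cleaved, non-rescued (lethal when biallelic under mosaicism)
R1 = "R1"    # in-frame functional repair: immune and viable

EGAllele = str
Pair = tuple[EGAllele, EGAllele]

KINDS = ("HGD_R_GME", "CGD_R_GME")


@dataclass(frozen=True)
class ArchitectureSpec:
    kind: str = "HGD_R_GME"
    cut: float = 1.0          # cut probability per cleavable EG allele
    h: float = 0.0            # HDR (homing) probability, HGD kind only
    deposition: float = 1.0   # maternal deposition completeness in [0, 1]
    rescue: bool = True
    r1: float = 0.0           # in-frame fraction among non-HDR repairs
    lethal_mosaicism: bool = True

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        for name in ("cut", "h", "deposition", "r1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.kind == "CGD_R_GME" and self.h != 0.0:
            # Cleavage-only drives have no homology donor at the cut site.
            object.__setattr__(self, "h", 0.0)


@dataclass(frozen=True)
class OffspringOutcome:
    genotype: Pair
    zygote_fraction: float
    viable: bool
    carries_drive: bool
    p_hg_knockout: float  # P(both host-gene alleles cut) for this class


def _functional(allele: EGAllele, spec: ArchitectureSpec) -> bool:
    if allele == WT or allele == R1:
        return True
    return allele == D and spec.rescue


def _is_viable(pair: Iterable[EGAllele], spec: ArchitectureSpec) -> bool:
    if not spec.lethal_mosaicism:
        return True
    return any(_functional(a, spec) for a in pair)


def _gametes(pair: Pair, spec: ArchitectureSpec) -> dict[EGAllele, float]:
    """Germline gamete distribution; cutting requires carrying the drive."""
    carrier = D in pair
    out: dict[EGAllele, float] = {}

    def add(a: EGAllele, p: float) -> None:
        if p > 0:
            out[a] = out.get(a, 0.0) + p

    for allele in pair:
        if allele == WT and carrier:
            add(WT, 0.5 * (1.0 - spec.cut))
            add(D, 0.5 * spec.cut * spec.h)
            nhej = 0.5 * spec.cut * (1.0 - spec.h)
            add(R1, nhej * spec.r1)
            add(CLV, nhej * (1.0 - spec.r1))
        else:
            add(allele, 0.5)
    return out


def _deposition_fates(allele: EGAllele, p_dep: float, spec: ArchitectureSpec) -> dict[EGAllele, float]:
    if allele != WT or p_dep <= 0:
        return {allele: 1.0}
    out = {WT: 1.0 - p_dep}
    if spec.r1 > 0:
        out[R1] = p_dep * spec.r1
    out[CLV] = p_dep * (1.0 - spec.r1)
    return {a: p for a, p in out.items() if p > 0}


def punnett_offspring(
    spec: ArchitectureSpec, mother: Pair, father: Pair
) -> list[OffspringOutcome]:
    """Enumerate exact offspring fractions of one cross.

    Maternal deposition (completeness × cut) converts offspring wild-type EG
    alleles in the zygote when the mother carries the drive; the father
    contributes only genes (no sperm protein effect), so paternal carriers
    drive through their offspring's zygotic cutting alone.
    """
    for name, pair in (("mother", mother), ("father", father)):
        if set(pair) - {D, WT, CLV, R1}:
            raise ValueError(f"unknown EG allele in {name} genotype {pair}")
        if not _is_viable(pair, spec):
            raise ValueError(f"{name} genotype {pair} is inviable: contract violation")

    p_dep = spec.deposition * spec.cut if D in mother else 0.0
    agg: dict[tuple[Pair, bool], float] = {}
    for egg, pe in _gametes(mother, spec).items():
        for sperm, ps in _gametes(father, spec).items():
            for egg2, pde in _deposition_fates(egg, p_dep, spec).items():
                for sperm2, pds in _deposition_fates(sperm, p_dep, spec).items():
                    geno: Pair = tuple(sorted((egg2, sperm2)))  # type: ignore[assignment]
                    key = (geno, D in geno)
                    agg[key] = agg.get(key, 0.0) + pe * ps * pde * pds

    outcomes = []
    for (geno, carries), frac in sorted(agg.items()):
        # Host-gene cutting: maternal deposition plus zygotic expression in
        # drive-carrying offspring, per HG allele, both alleles independent.
        p_zyg = spec.cut if carries else 0.0
        p_hg = 1.0 - (1.0 - p_dep) * (1.0 - p_zyg)
        outcomes.append(
            OffspringOutcome(
                genotype=geno,
                zygote_fraction=frac,
                viable=_is_viable(geno, spec),
                carries_drive=carries,
                p_hg_knockout=p_hg * p_hg,
            )
        )
    total = sum(o.zygote_fraction for o in outcomes)
    assert abs(total - 1.0) < 1e-12, "zygote fractions must conserve"
    return outcomes


def viable_fraction(outcomes: list[OffspringOutcome]) -> float:
    return sum(o.zygote_fraction for o in outcomes if o.viable)


def drive_transmission(outcomes: list[OffspringOutcome]) -> float:
    """Drive-carrying percentage among viable offspring."""
    viable = viable_fraction(outcomes)
    if viable == 0:
        raise ZeroDivisionError("no viable offspring")
    carriers = sum(o.zygote_fraction for o in outcomes if o.viable and o.carries_drive)
    return carriers / viable * 100.0


def refractoriness(outcomes: list[OffspringOutcome]) -> float:
    """Percentage of viable offspring with both host-gene alleles knocked out."""
    viable = viable_fraction(outcomes)
    if viable == 0:
        raise ZeroDivisionError("no viable offspring")
    knocked = sum(o.zygote_fraction * o.p_hg_knockout for o in outcomes if o.viable)
    return knocked / viable * 100.0


def _hardy_weinberg(freqs: dict[EGAllele, float]) -> dict[Pair, float]:
    out: dict[Pair, float] = {}
    alleles = sorted(freqs)
    for a, b in itertools.product(alleles, repeat=2):
        pair: Pair = tuple(sorted((a, b)))  # type: ignore[assignment]
        out[pair] = out.get(pair, 0.0) + freqs[a] * freqs[b]
    return out


def simulate_spread(
    spec: ArchitectureSpec,
    initial_drive_frequency: float,
    generations: int,
) -> pd.DataFrame:
    """Deterministic random-mating recursion of genotype frequencies.

    Starts from Hardy–Weinberg proportions at the given drive allele
    frequency; each generation convolves the Punnett calculator over all
    parental genotype pairs and renormalizes over viable offspring.
    """
    if not 0.0 < initial_drive_frequency < 1.0:
        raise ValueError("initial drive frequency must be in (0, 1)")
    if generations < 1:
        raise ValueError("need at least one generation")
    genotypes = _hardy_weinberg(
        {D: initial_drive_frequency, WT: 1.0 - initial_drive_frequency}
    )
    records = [_trajectory_row(0, genotypes)]
    cache: dict[tuple[Pair, Pair], list[OffspringOutcome]] = {}
    for g in range(1, generations + 1):
        nxt: dict[Pair, float] = {}
        for (gm, fm), (gf, ff) in itertools.product(genotypes.items(), repeat=2):
            if fm <= 0 or ff <= 0:
                continue
            key = (gm, gf)
            if key not in cache:
                cache[key] = punnett_offspring(spec, gm, gf)
            for o in cache[key]:
                if o.viable:
                    nxt[o.genotype] = nxt.get(o.genotype, 0.0) + fm * ff * o.zygote_fraction
        total = sum(nxt.values())
        if total == 0:
            raise RuntimeError("population extinct: no viable offspring")
        genotypes = {geno: f / total for geno, f in nxt.items()}
        records.append(_trajectory_row(g, genotypes))
    return pd.DataFrame(records)


def _trajectory_row(generation: int, genotypes: dict[Pair, float]) -> dict:
    allele_freq = {a: 0.0 for a in (D, WT, CLV, R1)}
    carrier = 0.0
    for pair, f in genotypes.items():
        for a in pair:
            allele_freq[a] += 0.5 * f
        if D in pair:
            carrier += f
    return {
        "generation": generation,
        "freq_drive": allele_freq[D],
        "freq_wt": allele_freq[WT],
        "freq_cleaved": allele_freq[CLV],
        "freq_r1": allele_freq[R1],
        "carrier_freq": carrier,
    }


def r1_leakage(spec: ArchitectureSpec, generations: int,
               initial_drive_frequency: float = 0.1) -> pd.DataFrame:
    """Trajectory including the functional-resistant class (requires r1 < 1 check upstream)."""
    if not 0.0 <= spec.r1 <= 1.0:
        raise ValueError("r1 outside [0, 1]")
    return simulate_spread(spec, initial_drive_frequency, generations)


def split_white_preset(cut: float = 0.95, h: float = 0.6, r1: float = 0.0) -> ArchitectureSpec:
    """Neutral split-drive recursion: a recessive-viable target (the *white*
    configuration), so cleaved alleles persist as resistance instead of dying."""
    return ArchitectureSpec(
        kind="HGD_R_GME", cut=cut, h=h, deposition=0.0, rescue=True,
        r1=r1, lethal_mosaicism=False,
    )
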