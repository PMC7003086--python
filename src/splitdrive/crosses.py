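"""Seeded, replicated crosses and the multi-generation scoring schemes.

The characterization experiment crosses a GDe line to heterozygous Cas9
lines in both directions, yielding four F1 female classes:

* ♀#1 — heterozygous ``wGDe/w+`` with maternally deposited Cas9 protein only
  (mother carried Cas9, daughter did not inherit the gene): shadow drive.
* ♀#2 — trans-heterozygous with maternal protein plus the inherited gene.
* ♀#3 — heterozygous from a Cas9 father, no gene, no protein: inert control.
* ♀#4 — trans-heterozygous with paternally inherited Cas9: zygotic only.

Heterozygous females are test-crossed to ``w–,y+`` males and trans-
heterozygous to ``w+,y+`` males.  F2 virgin females collected among ♀#2's
progeny (♀#5 heterozygous, ♀#6 trans-heterozygous, both selected by marker
phenotype) carry protein *and* gRNA carryover — the RNP context whose
embryonic pre-HDR cutting drives resistance-allele accumulation into F3.

Progeny tables keep the true genotype alongside the scored phenotype so
estimator accuracy is testable; estimators may only read phenotype columns.
The maternal X is always ``x1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genetics import (
    DepositionContext,
    Genotype,
    PresetRegistry,
    Promoter,
    Sex,
    WT_CAS9,
    WhiteAllele,
    XChromosomeState,
    YellowAllele,
    cas9_transgene,
)
from .germline import (
    apply_embryonic_cleavage,
    make_gamete_distribution,
    male_gametes,
    offspring_context,
)
from .soma import Eye, render_phenotype

__all__ = [
    "CrossSpec",
    "SchemePreset",
    "FEMALE_CLASSES",
    "SCHEME_NAMES",
    "EmptyTableError",
    "ExtinctSelectionError",
    "founder_female",
    "female_class_genotype",
    "partner_male",
    "run_cross",
    "run_female_class_cross",
    "run_scheme",
    "phenotype_view",
    "write_progeny_tsv",
]

PHENOTYPE_COLUMNS = ["generation", "replicate", "sex", "eye", "body", "gfp", "rfp"]

X_GDE = XChromosomeState(WhiteAllele.W_GDE, YellowAllele.Y_MINUS)
X_WT = XChromosomeState(WhiteAllele.W_PLUS, YellowAllele.Y_PLUS)
X_W_NULL = XChromosomeState(WhiteAllele.W_R2, YellowAllele.Y_PLUS)  # w–,y+ tester


class EmptyTableError(ValueError):
    pass


class ExtinctSelectionError(RuntimeError):
    """No females of the required marker combination were available."""


@dataclass(frozen=True)
class CrossSpec:
    """One replicated cross: defaults mirror triplicate 10♀ × 10♂ vials."""

    mother: Union[Genotype, Sequence[Genotype]]
    father: Genotype
    n_replicates: int = 3
    n_mothers: int = 10
    n_fathers: int = 10
    n_progeny: int = 200
    seed: int = 0
    generation: str = "F1"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.n_progeny < 1:
            raise EmptyTableError("zero progeny requested")


def _sample_mothers(pool: Sequence[Genotype], n: int, rng) -> list[Genotype]:
    if len(pool) == 0:
        raise ExtinctSelectionError("empty mother pool")
    if len(pool) >= n:
        idx = rng.choice(len(pool), size=n, replace=False)
    else:
        idx = rng.choice(len(pool), size=n, replace=True)
    return [pool[i] for i in idx]


def _run_replicate(
    mothers: list[Genotype],
    father: Genotype,
    n_progeny: int,
    rng,
    registry: PresetRegistry,
    generation: str,
    replicate: int,
) -> list[dict]:
    # Embryonic conversion happens once per mother at her own zygote stage;
    # her gamete distribution then carries germline-stage events only.
    converted = []
    for m in mothers:
        params = registry.params_for_mother(m)
        m2 = apply_embryonic_cleavage(m, params, rng)
        dist = make_gamete_distribution(m2, params, embryonic_applied=True)
        states = list(dist.keys())
        probs = np.array([dist[s] for s in states])
        converted.append((m2, states, probs / probs.sum()))

    sperm = male_gametes(father)
    sperm_states = list(sperm.keys())
    sperm_probs = np.array([sperm[s] for s in sperm_states])

    rows = []
    m_idx = rng.integers(0, len(converted), size=n_progeny)
    for i in range(n_progeny):
        mother, egg_states, egg_probs = converted[m_idx[i]]
        egg = egg_states[rng.choice(len(egg_states), p=egg_probs)]
        s = sperm_states[rng.choice(len(sperm_states), p=sperm_probs)]
        cas9 = (mother.cas9[rng.integers(0, 2)], father.cas9[rng.integers(0, 2)])
        if s is None:
            sex, x1, x2 = Sex.MALE, egg, None
        else:
            sex, x1, x2 = Sex.FEMALE, egg, s
        ctx = offspring_context(mother, (x1, x2), cas9)
        child = Genotype(sex, x1, x2, cas9, ctx)
        phen = render_phenotype(child, registry.soma_for(child), rng)
        rows.append(
            {
                "generation": generation,
                "replicate": replicate,
                "sex": phen.sex.value,
                "eye": phen.eye.value,
                "body": phen.body.value,
                "gfp": phen.gfp,
                "rfp": phen.rfp,
                "genotype": child,
            }
        )
    return rows


def run_cross(spec: CrossSpec, registry: PresetRegistry) -> pd.DataFrame:
    """Run all replicates of one cross; bit-reproducible for a fixed seed."""
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    rows: list[dict] = []
    for rep, ss in enumerate(seeds, start=1):
        rng = np.random.default_rng(ss)
        if isinstance(spec.mother, Genotype):
            mothers = [spec.mother] * spec.n_mothers
        else:
            mothers = _sample_mothers(list(spec.mother), spec.n_mothers, rng)
        rows.extend(
            _run_replicate(
                mothers, spec.father, spec.n_progeny, rng, registry,
                spec.generation, rep,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Named female classes and schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SchemePreset:
    """A female class plus its designated test-cross male."""

    name: str
    het: bool              # heterozygous (no Cas9 gene) vs trans-heterozygous
    maternal_protein: bool
    maternal_grna: bool
    father_w: str          # "w-" or "w+": decoding key for the estimators
    rnp: bool = False      # F2 collection from a GDe+Cas9 mother


FEMALE_CLASSES: dict[str, SchemePreset] = {
    "f1_female_1": SchemePreset("f1_female_1", het=True, maternal_protein=True,
                                maternal_grna=False, father_w="w-"),
    "f1_female_2": SchemePreset("f1_female_2", het=False, maternal_protein=True,
                                maternal_grna=False, father_w="w+"),
    "f1_female_3": SchemePreset("f1_female_3", het=True, maternal_protein=False,
                                maternal_grna=True, father_w="w-"),
    "f1_female_4": SchemePreset("f1_female_4", het=False, maternal_protein=False,
                                maternal_grna=True, father_w="w+"),
    "f2_female_5": SchemePreset("f2_female_5", het=True, maternal_protein=True,
                                maternal_grna=True, father_w="w-", rnp=True),
    "f2_female_6": SchemePreset("f2_female_6", het=False, maternal_protein=True,
                                maternal_grna=True, father_w="w+", rnp=True),
}

SCHEME_NAMES = ("F1_cross", "score_F1_females_1_to_4", "F2_collection", "F3_scoring")


def female_class_genotype(cls: str, promoter: Promoter | str) -> Genotype:
    """Canonical genotype + deposition context of a named female class."""
    preset = FEMALE_CLASSES[cls]
    if isinstance(promoter, str):
        promoter = Promoter.parse(promoter)
    cas9 = (WT_CAS9, WT_CAS9) if preset.het else (cas9_transgene(promoter), WT_CAS9)
    ctx = DepositionContext(
        maternal_cas9_protein=preset.maternal_protein,
        maternal_grna=preset.maternal_grna,
        zygotic_cas9=not preset.het,
        zygotic_grna=True,
        promoter_of_maternal_source=promoter if preset.maternal_protein else None,
    )
    return Genotype(Sex.FEMALE, X_GDE, X_WT, cas9, ctx)


def partner_male(father_w: str) -> Genotype:
    x = X_W_NULL if father_w == "w-" else X_WT
    return Genotype(Sex.MALE, x, None)


def founder_female(kind: str, promoter: Promoter | str) -> Genotype:
    """F0 mothers: the Cas9-line female (w+ background) or the GDe homozygote."""
    if kind == "cas9_line":
        return Genotype(Sex.FEMALE, X_WT, X_WT, (cas9_transgene(promoter), WT_CAS9))
    if kind == "gde_line":
        return Genotype(Sex.FEMALE, X_GDE, X_GDE)
    raise ValueError(f"unknown founder kind {kind!r}")


def founder_male(kind: str, promoter: Promoter | str) -> Genotype:
    if kind == "cas9_line":
        return Genotype(Sex.MALE, X_WT, None, (cas9_transgene(promoter), WT_CAS9))
    if kind == "gde_line":
        return Genotype(Sex.MALE, X_GDE, None)
    raise ValueError(f"unknown founder kind {kind!r}")


def run_female_class_cross(
    cls: str,
    promoter: Promoter | str,
    registry: PresetRegistry,
    *,
    n_replicates: int = 3,
    n_progeny: int = 200,
    seed: int = 0,
    generation: Optional[str] = None,
) -> pd.DataFrame:
    """Test-cross one named female class to its designated male."""
    preset = FEMALE_CLASSES[cls]
    mother = female_class_genotype(cls, promoter)
    spec = CrossSpec(
        mother=mother,
        father=partner_male(preset.father_w),
        n_replicates=n_replicates,
        n_progeny=n_progeny,
        seed=seed,
        generation=generation or ("F3" if preset.rnp else "F2"),
    )
    return run_cross(spec, registry)


def _select_f2_mothers(table: pd.DataFrame, replicate: int, want_rfp: bool, cls: str):
    sub = table[
        (table["replicate"] == replicate)
        & (table["sex"] == Sex.FEMALE.value)
        & table["gfp"]
        & (table["rfp"] == want_rfp)
        & (table["eye"] != Eye.WHITE.value)  # white-eyed GFP+ lack the w+ receiver
    ]
    if sub.empty:
        raise ExtinctSelectionError(
            f"no eligible females for class {cls} in replicate {replicate}"
        )
    return list(sub["genotype"])


def run_scheme(
    name: str,
    promoter: Promoter | str,
    registry: PresetRegistry,
    *,
    n_replicates: int = 3,
    n_progeny: int = 200,
    n_collect: int = 10,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Run a named multi-generation scheme; returns generation → progeny table."""
    if name not in SCHEME_NAMES:
        raise ValueError(f"unknown scheme {name!r}; expected one of {SCHEME_NAMES}")
    if isinstance(promoter, str):
        promoter = Promoter.parse(promoter)
    child_seeds = [int(s.generate_state(1)[0] % 2**31)
                   for s in np.random.SeedSequence(seed).spawn(8)]

    if name == "F1_cross":
        spec = CrossSpec(
            mother=founder_female("cas9_line", promoter),
            father=founder_male("gde_line", promoter),
            n_replicates=n_replicates, n_progeny=n_progeny,
            seed=child_seeds[0], generation="F1",
        )
        return {"F1": run_cross(spec, registry)}

    if name == "score_F1_females_1_to_4":
        maternal = run_scheme("F1_cross", promoter, registry,
                              n_replicates=n_replicates, n_progeny=n_progeny,
                              seed=child_seeds[0])["F1"]
        paternal_spec = CrossSpec(
            mother=founder_female("gde_line", promoter),
            father=founder_male("cas9_line", promoter),
            n_replicates=n_replicates, n_progeny=n_progeny,
            seed=child_seeds[1], generation="F1",
        )
        maternal = maternal.assign(direction="maternal_cas9")
        paternal = run_cross(paternal_spec, registry).assign(direction="paternal_cas9")
        return {"F1": pd.concat([maternal, paternal], ignore_index=True)}

    if name == "F2_collection":
        tables = []
        for i, cls in enumerate(["f1_female_1", "f1_female_2", "f1_female_3", "f1_female_4"]):
            t = run_female_class_cross(
                cls, promoter, registry,
                n_replicates=n_replicates, n_progeny=n_progeny,
                seed=child_seeds[2 + i], generation="F2",
            )
            tables.append(t.assign(female_class=cls))
        return {"F2": pd.concat(tables, ignore_index=True)}

    # F3_scoring: chain ♀#2 → F2 → select ♀#5/♀#6 by marker → F3
    f2 = run_female_class_cross(
        "f1_female_2", promoter, registry,
        n_replicates=n_replicates, n_progeny=n_progeny,
        seed=child_seeds[6], generation="F2",
    ).assign(female_class="f1_female_2")
    out = {"F2": f2}
    for j, cls in enumerate(["f2_female_5", "f2_female_6"]):
        want_rfp = not FEMALE_CLASSES[cls].het
        father = partner_male(FEMALE_CLASSES[cls].father_w)
        seeds = np.random.SeedSequence(child_seeds[7] + j).spawn(n_replicates)
        rows: list[dict] = []
        for rep in range(1, n_replicates + 1):
            rng = np.random.default_rng(seeds[rep - 1])
            pool = _select_f2_mothers(f2, rep, want_rfp, cls)
            mothers = _sample_mothers(pool, n_collect, rng)
            rows.extend(
                _run_replicate(mothers, father, n_progeny, rng, registry, "F3", rep)
            )
        out[f"F3_{cls}"] = pd.DataFrame(rows).assign(female_class=cls)
    return out


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def phenotype_view(table: pd.DataFrame) -> pd.DataFrame:
    """The scorer-visible columns only (what estimators are allowed to read)."""
    return table[PHENOTYPE_COLUMNS].copy()


def _truth_frame(table: pd.DataFrame) -> pd.DataFrame:
    recs = []
    for g in table["genotype"]:
        recs.append(
            {
                "x1_white": g.x1.white.value,
                "x1_yellow": g.x1.yellow.value,
                "x2_white": "" if g.x2 is None else g.x2.white.value,
                "x2_yellow": "" if g.x2 is None else g.x2.yellow.value,
                "cas9_copies": sum(a.is_transgene for a in g.cas9),
                "maternal_cas9_protein": g.context.maternal_cas9_protein,
                "maternal_grna": g.context.maternal_grna,
            }
        )
    return pd.concat(
        [table[PHENOTYPE_COLUMNS].reset_index(drop=True), pd.DataFrame(recs)], axis=1
    )


def write_progeny_tsv(table: pd.DataFrame, path, truth_path=None) -> None:
    phenotype_view(table).to_csv(path, sep="\t", index=False)
    if truth_path is not None:
        _truth_frame(table).to_csv(truth_path, sep="\t", index=False)


def read_progeny_tsv(path) -> pd.DataFrame:
    """Read a phenotype table written by :func:`write_progeny_tsv`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gfp", "rfp"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    return df
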