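"""Round-trip quantification workflows: invert an observation, simulate, re-estimate.

Each function fits event parameters from a set of observed cross-outcome
percentages, runs the corresponding seeded cross at replicate scale, and
decodes the frequencies back from the scored phenotypes.  Consistency of the
output with the input (within replicate sampling error) validates the whole
chain: generative model, cross engine, phenotype scoring, and estimator.
"""

from __future__ import annotations

from typing import Optional

from .crosses import (
    CrossSpec,
    founder_female,
    founder_male,
    run_cross,
    run_female_class_cross,
)
from .estimators import (
    FrequencyEstimate,
    estimate_frequencies,
    estimate_somatic_penetrance,
    fit_preset_from_observed,
)
from .genetics import PresetRegistry, SomaticPenetrance, load_default_registry

__all__ = [
    "shadow_drive_roundtrip",
    "zygotic_cas9_roundtrip",
    "somatic_penetrance_roundtrip",
]


def _base_registry(registry: Optional[PresetRegistry]) -> PresetRegistry:
    return registry if registry is not None else load_default_registry()[0]


def shadow_drive_roundtrip(
    promoter: str = "BicC",
    homing_pct: float = 59.3,
    r2_pct: float = 38.7,
    yellow_lof_pct: float = 89.4,
    *,
    n_replicates: int = 3,
    n_progeny: int = 500,
    seed: int = 0,
    registry: Optional[PresetRegistry] = None,
) -> dict[str, FrequencyEstimate]:
    """♀#1 workflow: maternal Cas9 protein only, test-crossed to w–,y+ males.

    Germline yellow LOF is scored in GFP− male progeny; white classes are
    readable in all progeny against the w– background.
    """
    params = fit_preset_from_observed(
        homing_pct, r2_pct, 100.0 - homing_pct - r2_pct,
        "maternal_protein", yellow_lof_pct=yellow_lof_pct,
    )
    reg = _base_registry(registry).with_override(
        promoter, "maternal_protein", germline=params
    )
    table = run_female_class_cross(
        "f1_female_1", promoter, reg,
        n_replicates=n_replicates, n_progeny=n_progeny, seed=seed,
    )
    return estimate_frequencies(table, "f1_female_1")


def zygotic_cas9_roundtrip(
    promoter: str = "Ubi",
    homing_pct: float = 88.0,
    r2_pct: float = 9.9,
    *,
    n_replicates: int = 3,
    n_progeny: int = 500,
    seed: int = 0,
    registry: Optional[PresetRegistry] = None,
) -> dict[str, FrequencyEstimate]:
    """♀#4 workflow: paternally inherited Cas9 (no deposition), crossed to
    w+,y+ males; maternal white alleles decoded from male progeny only."""
    params = fit_preset_from_observed(
        homing_pct, r2_pct, 100.0 - homing_pct - r2_pct, "zygotic"
    )
    reg = _base_registry(registry).with_override(promoter, "zygotic", germline=params)
    table = run_female_class_cross(
        "f1_female_4", promoter, reg,
        n_replicates=n_replicates, n_progeny=n_progeny, seed=seed,
    )
    return estimate_frequencies(table, "f1_female_4")


def somatic_penetrance_roundtrip(
    promoter: str = "BicC",
    p_som_white_pct: float = 64.3,
    p_som_yellow_pct: float = 0.0,
    *,
    n_replicates: int = 3,
    n_progeny: int = 500,
    seed: int = 0,
    registry: Optional[PresetRegistry] = None,
) -> FrequencyEstimate:
    """Paternal-Cas9 F0 cross: GDe homozygous mothers × Cas9/+ males; the
    fraction of GFP+/RFP+ (trans-heterozygous) F1 daughters scored mosaic
    white reads back the fitted zygotic penetrance."""
    soma = SomaticPenetrance(p_som_white_pct / 100.0, p_som_yellow_pct / 100.0)
    reg = _base_registry(registry).with_override(promoter, "zygotic", soma=soma)
    spec = CrossSpec(
        mother=founder_female("gde_line", promoter),
        father=founder_male("cas9_line", promoter),
        n_replicates=n_replicates, n_progeny=n_progeny, seed=seed,
        generation="F1",
    )
    table = run_cross(spec, reg)
    return estimate_somatic_penetrance(table, "white")
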