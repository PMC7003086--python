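"""Allele-class frequency estimation from phenotype tables, and replicate stats.

The quantification convention: a heterozygous female's cleavable allele is
half her gamete pool under Mendelian segregation, so class frequencies are
"normalized to 50%" — homing% = (GDe fraction − 0.5)/0.5 × 100, LOF
resistance% = R2 fraction / 0.5 × 100, etc.  Decoding depends on the test
male:

* ``w–`` father: the maternal white allele is readable in every offspring
  (GFP+ → wGDe; GFP− constitutive white → wR2; GFP− red or mosaic → intact).
* ``w+`` father: the paternal w+ masks maternal R2 in daughters, so only male
  progeny (whose single X is maternal) are decoded.

Yellow LOF is scored only in GFP− male progeny (receiver chromosomes that
did not home; unbiased because white and yellow outcomes are independent).
Mosaic phenotypes decode as *intact* underlying alleles: somatic patches sit
on a functional germline allele.  The in-frame wR1 class is phenotypically
red and therefore pooled with w+ into "intact", so true cleavage is
underestimated by the R1 fraction — the same caveat that applies to the
scored crosses.

The statistical unit is the replicate cross, not the fly: means and sample
SDs are computed over replicates and compared with a pooled-variance
two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .crosses import FEMALE_CLASSES, SchemePreset
from .genetics import DepositionContext, context_key
from .germline import GermlineEventParams, invert_outcome_fractions

__all__ = [
    "FrequencyEstimate",
    "TTestResult",
    "DecodingError",
    "InfeasibleObservationError",
    "estimate_frequencies",
    "estimate_somatic_penetrance",
    "summarize_replicates",
    "ttest_equal_var",
    "fit_preset_from_observed",
    "estimates_frame",
]

QUANTITIES = ("homing", "r2_w", "intact_w", "cleavage_w", "cleavage_y")


class DecodingError(ValueError):
    """The design and the table disagree (e.g. w+ father but no male rows)."""


class InfeasibleObservationError(ValueError):
    """The observation cannot be produced under the stated context."""


@dataclass(frozen=True)
class FrequencyEstimate:
    quantity: str
    per_replicate: tuple[float, ...]
    mean: float
    sd: Optional[float]
    n_replicates: int


def summarize_replicates(values: Sequence[float]) -> tuple[float, Optional[float]]:
    """Arithmetic mean and sample SD (n−1); SD is undefined for one replicate."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("no replicate values")
    mean = sum(vals) / len(vals)
    if len(vals) < 2:
        return mean, None
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
    return mean, sd


def _make_estimate(quantity: str, values: Sequence[float]) -> FrequencyEstimate:
    mean, sd = summarize_replicates(values)
    return FrequencyEstimate(quantity, tuple(float(v) for v in values), mean, sd, len(values))


def _clamp_pct(v: float) -> float:
    return min(100.0, max(0.0, v))


def _decode_white(rows: pd.DataFrame) -> tuple[float, float, float]:
    n = len(rows)
    f_gde = float(rows["gfp"].sum()) / n
    gfp_neg = rows[~rows["gfp"]]
    f_r2 = float((gfp_neg["eye"] == "white").sum()) / n
    f_intact = float((gfp_neg["eye"] != "white").sum()) / n
    return f_gde, f_r2, f_intact


def estimate_frequencies(
    table: pd.DataFrame,
    design: Union[SchemePreset, str],
) -> dict[str, FrequencyEstimate]:
    """Per-replicate allele-class frequencies, normalized to the 50% pool.

    ``design`` is a female-class name / :class:`SchemePreset` (identifying the
    test male's white genotype) or directly ``"w-"`` / ``"w+"``.
    """
    if isinstance(design, SchemePreset):
        father_w = design.father_w
    elif design in FEMALE_CLASSES:
        father_w = FEMALE_CLASSES[design].father_w
    elif design in ("w-", "w+"):
        father_w = design
    else:
        raise DecodingError(f"unknown design {design!r}")

    per_rep: dict[str, list[float]] = {q: [] for q in QUANTITIES}
    for _, rep_rows in table.groupby("replicate"):
        if father_w == "w+":
            informative = rep_rows[rep_rows["sex"] == "male"]
            if informative.empty:
                raise DecodingError(
                    "w+ father design requires male progeny rows to decode "
                    "maternal white alleles"
                )
        else:
            informative = rep_rows
        f_gde, f_r2, f_intact = _decode_white(informative)
        homing = _clamp_pct((f_gde - 0.5) * 200.0)
        r2 = _clamp_pct(f_r2 * 200.0)
        intact = _clamp_pct(f_intact * 200.0)
        per_rep["homing"].append(homing)
        per_rep["r2_w"].append(r2)
        per_rep["intact_w"].append(intact)
        per_rep["cleavage_w"].append(_clamp_pct(100.0 - intact))

        males = rep_rows[(rep_rows["sex"] == "male") & ~rep_rows["gfp"]]
        if males.empty:
            per_rep["cleavage_y"].append(float("nan"))
        else:
            per_rep["cleavage_y"].append(
                float((males["body"] == "yellow").sum()) / len(males) * 100.0
            )
    return {q: _make_estimate(q, vals) for q, vals in per_rep.items()}


def estimate_somatic_penetrance(table: pd.DataFrame, locus: str = "white") -> FrequencyEstimate:
    """Fraction (%) of trans-heterozygous (GFP+/RFP+) females scored mosaic."""
    if locus not in ("white", "yellow"):
        raise ValueError("locus must be 'white' or 'yellow'")
    column = "eye" if locus == "white" else "body"
    values = []
    for _, rep_rows in table.groupby("replicate"):
        trans_het = rep_rows[
            (rep_rows["sex"] == "female") & rep_rows["gfp"] & rep_rows["rfp"]
        ]
        if trans_het.empty:
            raise DecodingError("no trans-heterozygous females to score")
        values.append(
            float((trans_het[column] == "mosaic").sum()) / len(trans_het) * 100.0
        )
    return _make_estimate(f"p_som_{locus}", values)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def ttest_equal_var(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sample Student's t-test with pooled (equal) variance, two-sided."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    df = na + nb - 2
    pooled = (ssa + ssb) / df
    if pooled == 0.0:
        if ma == mb:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, ma - mb), df, 0.0, degenerate=True)
    t = (ma - mb) / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t, df, p)


def fit_preset_from_observed(
    homing_pct: float,
    r2_pct: float,
    intact_pct: float,
    context: Union[DepositionContext, str] = "maternal_protein",
    *,
    yellow_lof_pct: float = 0.0,
    r1_w: float = 0.0,
    r1_y: float = 0.1,
    embryonic_only: bool = False,
) -> GermlineEventParams:
    """Invert observed outcome percentages into generative event parameters.

    For a germline-competent context the cutting goes into ``c_germ_w``; with
    ``embryonic_only=True`` (deposition acting strictly pre-HDR) it goes into
    ``c_emb_w`` and any requested homing is infeasible.  The round trip —
    simulate with the fitted parameters, re-estimate — recovers the inputs
    within sampling error.
    """
    key = context if isinstance(context, str) else context_key(context)
    if key == "inert" and (homing_pct or r2_pct or yellow_lof_pct):
        raise InfeasibleObservationError(
            "nonzero event frequencies in a context with no nuclease"
        )
    if embryonic_only:
        if homing_pct > 0:
            raise InfeasibleObservationError(
                "homing requires germline-stage cleavage; an embryonic-only "
                "context cannot produce it"
            )
        params = invert_outcome_fractions(
            0.0, r2_pct, intact_pct,
            yellow_lof_pct=yellow_lof_pct, r1_w=r1_w, r1_y=r1_y,
        )
        return GermlineEventParams(
            c_emb_w=params.c_germ_w, c_germ_w=0.0, h=0.0,
            r1_w=r1_w, c_y=params.c_y, r1_y=r1_y,
        )
    return invert_outcome_fractions(
        homing_pct, r2_pct, intact_pct,
        yellow_lof_pct=yellow_lof_pct, r1_w=r1_w, r1_y=r1_y,
    )


def estimates_frame(estimates: dict[str, FrequencyEstimate]) -> pd.DataFrame:
    """Flatten estimates for TSV output (percentages at full precision)."""
    rows = []
    for q, e in estimates.items():
        rows.append(
            {
                "quantity": q,
                "mean_pct": e.mean,
                "sd_pct": e.sd if e.sd is not None else np.nan,
                "n_replicates": e.n_replicates,
                "per_replicate": ";".join(f"{v:.6g}" for v in e.per_replicate),
            }
        )
    return pd.DataFrame(rows)
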