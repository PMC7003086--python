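"""gRNA target-site validation and cut-site indel classification.

Sanger-resolved amplicons are aligned to the reference target region and the
net length change within a window around the SpCas9 blunt cut (3 bp 5′ of
the NGG PAM) decides the allele class: no change and an intact site → wild
type; an in-frame change (net divisible by 3), or no length change but
substitutions disrupting the seed/PAM, → functional-resistant R1; any
frameshift → loss-of-function R2.  The seed/PAM substitution rule is an
operational proxy — which substitutions truly abolish recognition is not
knowable from phenotype alone.

Alignment scoring (match +1, mismatch −1, gap open −4, gap extend −1,
leftmost placement on ties) is configurable; classification is invariant to
flank length beyond the window and, for indels, depends only on the net
length change modulo 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio import Align

__all__ = [
    "WHITE_TARGET",
    "YELLOW_TARGET",
    "TargetSite",
    "IndelCall",
    "MutationParams",
    "TargetValidationError",
    "validate_target",
    "classify_indel",
    "generate_mutant_amplicons",
]

#: The two genomic target sites (protospacer + PAM) of the drive and the
#: effector gRNAs at *white* and *yellow*.
WHITE_TARGET = "GGCGATACTTGGATGCCCTGCGG"
YELLOW_TARGET = "GGTTTTGGACACTGGAACCGTGG"

DNA = set("ACGT")
WINDOW = 20          # bp each side of the cut inspected for events
SEED_START = 12      # 0-based protospacer index of the seed region (positions 13-20)


class TargetValidationError(ValueError):
    pass


@dataclass(frozen=True)
class TargetSite:
    """A 20-nt protospacer with its NGG PAM; blunt cut 3 bp 5′ of the PAM."""

    protospacer: str
    pam: str
    cut_offset: int = 17      # bases from target start to the cut
    reading_frame_offset: int = 0

    @property
    def sequence(self) -> str:
        return self.protospacer + self.pam


@dataclass(frozen=True)
class IndelCall:
    net_change: int                      # signed bp, within the cut window
    classification: str                  # "WT" | "R1" | "R2"
    span: Optional[tuple[int, int]]      # 0-based half-open ref coords of events
    outside_window: bool = False         # events existed but fell outside


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


def validate_target(seq: str, reading_frame_offset: int = 0) -> TargetSite:
    """Accept exactly a 20-nt protospacer followed by an NGG PAM."""
    seq = str(seq)
    if seq != seq.upper() or (set(seq) - DNA):
        raise TargetValidationError(f"target {seq!r} is not an uppercase DNA string")
    if len(seq) != 23:
        raise TargetValidationError(
            f"target length {len(seq)} != 23 (20-nt protospacer + 3-nt PAM)"
        )
    pam = seq[20:]
    if pam[1:] != "GG":
        raise TargetValidationError(f"PAM {pam!r} does not match NGG")
    return TargetSite(seq[:20], pam, reading_frame_offset=reading_frame_offset)


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _locate_site(reference: str, site: TargetSite) -> int:
    idx = reference.find(site.sequence)
    if idx < 0:
        raise ValueError("target site not found in the reference sequence")
    if reference.find(site.sequence, idx + 1) >= 0:
        raise ValueError("target site occurs more than once in the reference")
    if idx < WINDOW or len(reference) - (idx + 23) < WINDOW:
        raise ValueError(f"reference must extend >= {WINDOW} bp beyond the site")
    return idx


def classify_indel(
    reference: str,
    observed: str,
    site: TargetSite,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> IndelCall:
    """Globally align one resolved amplicon and classify the cut-site allele."""
    reference = str(reference).upper()
    observed = str(observed).upper()
    start = _locate_site(reference, site)
    cut = start + site.cut_offset
    lo, hi = cut - WINDOW, cut + WINDOW

    aln = _aligner(scoring).align(reference, observed)[0]
    ref_blocks, obs_blocks = aln.aligned

    events: list[tuple[int, int, int]] = []  # (ref_pos, net, ref_span_end)
    mismatches: list[int] = []
    prev_r = prev_q = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, obs_blocks):
        if rs > prev_r:           # deletion of ref[prev_r:rs]
            events.append((prev_r, -(rs - prev_r), rs))
        if qs > prev_q:           # insertion at ref position rs
            events.append((rs, qs - prev_q, rs))
        for i in range(re_ - rs):
            if reference[rs + i] != observed[qs + i]:
                mismatches.append(rs + i)
        prev_r, prev_q = re_, qe
    if len(reference) > prev_r:
        events.append((prev_r, -(len(reference) - prev_r), len(reference)))
    if len(observed) > prev_q:
        events.append((len(reference), len(observed) - prev_q, len(reference)))

    inside = [(p, n, e) for p, n, e in events if lo <= p <= hi]
    outside = [ev for ev in events if ev not in inside]
    net = sum(n for _, n, _ in inside)
    span = None
    if inside:
        span = (min(p for p, _, _ in inside), max(e for _, _, e in inside))

    if net == 0:
        seed_lo = start + SEED_START
        disrupting = [m for m in mismatches if seed_lo <= m < start + 23]
        if inside or disrupting:
            # In-frame rearrangement at the site, or site-disrupting
            # substitutions: functional-resistant.
            cls = "R1"
        else:
            cls = "WT"
    elif net % 3 == 0:
        cls = "R1"
    else:
        cls = "R2"
    return IndelCall(net, cls, span, outside_window=bool(outside) and not inside)


@dataclass(frozen=True)
class MutationParams:
    """Truth-labeled mutant generation for classifier validation."""

    wt_fraction: float = 0.1
    r1_fraction: float = 0.3          # among mutants
    del_sizes: tuple[int, ...] = tuple(range(1, 13))
    ins_sizes: tuple[int, ...] = tuple(range(1, 7))


def generate_mutant_amplicons(
    reference: str,
    site: TargetSite,
    params: MutationParams,
    n: int,
    seed: int,
) -> list[tuple[str, str, str]]:
    """Emit ``(name, sequence, truth_label)`` records around the cut site."""
    import numpy as np

    reference = str(reference).upper()
    start = _locate_site(reference, site)
    cut = start + site.cut_offset
    rng = np.random.default_rng(seed)
    in_frame_del = [s for s in params.del_sizes if s % 3 == 0]
    shift_del = [s for s in params.del_sizes if s % 3 != 0]
    in_frame_ins = [s for s in params.ins_sizes if s % 3 == 0]
    shift_ins = [s for s in params.ins_sizes if s % 3 != 0]

    records = []
    for i in range(n):
        if rng.random() < params.wt_fraction:
            records.append((f"amp{i:04d}", reference, "WT"))
            continue
        label = "R1" if rng.random() < params.r1_fraction else "R2"
        sizes_del = in_frame_del if label == "R1" else shift_del
        sizes_ins = in_frame_ins if label == "R1" else shift_ins
        use_del = bool(sizes_del) and (not sizes_ins or rng.random() < 0.7)
        if use_del:
            k = int(rng.choice(sizes_del))
            lo = cut - k // 2
            seq = reference[:lo] + reference[lo + k:]
        else:
            k = int(rng.choice(sizes_ins))
            ins = "".join(rng.choice(list("ACGT"), size=k))
            seq = reference[:cut] + ins + reference[cut:]
        records.append((f"amp{i:04d}", seq, label))
    return records
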