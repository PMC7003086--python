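# Methods

## The system being modeled

`splitdrive` simulates a split homing gene drive in *Drosophila
melanogaster*.  The drive element (GDe) is inserted in the X-linked *white*
locus and carries two gRNAs — a driver gRNA against *white* itself and a
cargo "gRNA-mediated effector" (GME) against the unlinked-but-X-linked
*yellow* locus — plus a 3xP3-GFP eye marker.  SpCas9 is supplied from a
separate autosomal transgene (Opie2-DsRed marked) under one of four
promoters (*nos*, *vas*, *BicC*, *Ubi*), or as protein loaded maternally
into the egg.  Drive activity therefore requires bringing the two halves
together, and the experimentally measurable quantities are phenotype
frequencies in test-cross progeny.

Both targets are recessive-viable with scorable phenotypes (white eyes,
yellow body), so every germline event class leaves a countable trace:

* **homing** — HDR copies the GDe into a cleaved `w+` receiver allele
  (heterozygous females only; males are hemizygous and have no receiver);
* **R2** — frameshift NHEJ repair: loss of function, immune to re-cutting;
* **R1** — in-frame NHEJ repair: functionally wild type, immune to
  re-cutting, and phenotypically indistinguishable from `w+`;
* **intact** — never cut.

*yellow* has no homology donor in the GDe, so its cuts resolve by NHEJ only.

## Generative decomposition

Observed outcome frequencies are generated from per-allele event
probabilities, applied in developmental order:

| parameter  | meaning                                               | default source |
|------------|-------------------------------------------------------|----------------|
| `c_emb_w`  | cut probability in the early embryo, pre-HDR          | 0 for F1 contexts; fitted per promoter for the F2 (RNP) context |
| `c_germ_w` | cut probability at the HDR-competent germline stage   | `(100 − intact%)/100` from the observed cross |
| `h`        | HDR (homing) fraction among germline-stage cuts       | `homing%/(100 − intact%)` |
| `r1_w`     | in-frame fraction among NHEJ repairs at *white*       | 0 (no in-frame white alleles were recovered from F1 germ cells) |
| `c_y`      | cut probability at *yellow* (NHEJ only)               | `yellowLOF%/(100·(1 − r1_y))` |
| `r1_y`     | in-frame fraction at *yellow*                         | 0.1 — unconstrained by any observation; a documented default |

Embryonic cuts never home (HDR is inefficient in the early cleavage-stage
embryo) and convert the whole animal, soma and germline precursors alike.
Germline events are drawn independently per gamete; white and yellow
outcomes on the same chromosome are independent Bernoulli events.  R1/R2
classes (and the founder `y–` null) are terminal.

## Deposition contexts

What an individual can cut is set by what it received at fertilization:

* **inert** — missing either a Cas9 source or a gRNA source.  Paternal
  protein never counts: sperm does not carry enough Cas9 to act.
* **maternal_protein** — egg loaded with Cas9 protein (mother carried the
  transgene) but not gRNA; the individual's own GDe supplies gRNA once
  expressed.  This is the shadow-drive configuration: homing occurs even in
  females that did not inherit the Cas9 gene.
* **zygotic** — Cas9 gene inherited (typically paternally), no carryover.
* **maternal_rnp** — protein *and* gRNA carryover (mother carried both GDe
  and Cas9): cutting starts in the early embryo, before HDR is possible.

The RNP context is the package's mechanistic reading of the F2→F3 collapse:
F2 females collected from GDe+Cas9 mothers receive a fresh paternal `w+`,
yet their F3 progeny show mostly R2 and little homing.  Since the receiver
allele is new each generation, carryover timing — not inherited resistance —
is the only mechanism consistent with both the single-generation and the
multi-generation observations; it is encoded as a high fitted `c_emb_w`
(`c_emb = 1 − homing_F3/(c_germ·h)`, 0.86–0.89 across promoters), kept as
preset data rather than hard-coded behavior.

## Promoter presets

Presets are data (`src/splitdrive/data/presets.yaml`): each promoter ×
context block stores the observed germline outcome percentages and the
somatic penetrances; event parameters are re-derived at load time by the
same inversion exposed as `fit_preset_from_observed`.  Quantified anchors:
BicC maternal (homing 59.3, R2 38.7, yellow LOF 89.4), Ubi maternal
(67.0, 27.3, 26.0), Ubi zygotic (88.0, 9.9), BicC zygotic somatic white
penetrance 0.643 with no somatic yellow.  For *nos* and *vas*, which were
only bracketed in the single-generation figures, the maternal blocks carry
the per-promoter F2-generation values (80.0/11.2 and 80.2/13.2); zygotic
blocks reuse maternal fits where the two directions were reported as not
significantly different (all promoters except Ubi).  Germline yellow
cutting was only measured in maternal contexts; zygotic blocks reuse those
values as an explicit assumption.

## Cross engine and estimators

Crosses default to the experimental design: 3 replicates of 10♀ × 10♂, 200
progeny per replicate (configurable; the true per-vial counts are not
published).  Mothers within a replicate are exchangeable; each progeny
samples a mother, one maternal X from her exact gamete distribution
(embryonic conversion applied stochastically once per mother at her own
zygote stage), a paternal X or Y, and one autosomal Cas9 allele per parent.
A deterministic convolution (`expected_generation`) serves as the oracle
the sampler is verified against at n = 10⁵ (3σ per allele class).

Estimators read phenotype columns only and normalize to the heterozygous
female's 50% cleavable pool: `homing% = (GDe fraction − 0.5)/0.5·100`, etc.
Against a `w–` test male every offspring is informative; against `w+`
males only sons are decoded (paternal `w+` masks maternal R2 in daughters,
which also means daughter-only tables overstate intact alleles — the same
complementation caveat as in the scored crosses).  Yellow LOF is scored in
GFP− sons only; this is unbiased under white⊥yellow independence, and it
underestimates true cleavage by the in-frame fraction, exactly as
phenotype-based scoring must.  Progeny of RNP-context mothers are recorded
at their fertilization genotype; deposition-driven somatic conversion shows
through the mosaicism penetrance, never by rewriting the recorded genotype,
so "mosaic ⇒ intact underlying allele" stays a valid decoding rule.

Mosaicism itself is a per-fly, per-locus presence/absence Bernoulli (the
experiments scored presence, not patch area), suppressed when an
uncleavable functional copy (R1) would mask patches.

Replicates, not flies, are the statistical unit: means and sample SDs
(n−1) over replicates, compared with a pooled-variance two-sample t-test
(p from the t distribution; validated against a closed form and a
permutation null).  No multiple-testing correction is applied, matching the
source analysis.

## Drive architectures

The proposed rescue-based designs are exact calculators, not simulations.
The essential-gene locus is collapsed to {drive+rescue `D`, wild-type `WT`,
cleaved `CLV`, optional in-frame `R1`}; the host-gene effector locus is
unlinked and cut with the same deposition completeness.  Maternal
deposition (completeness × cut) converts offspring `WT` alleles in the
zygote; lethal biallelic mosaicism kills any offspring with no functional
allele.  HGD kind adds germline HDR at rate `h`; CGD kind forces `h = 0`.
Paternal carriers contribute zygotic cutting only (no sperm deposition) —
an assumption, since the designs do not specify paternal behavior.
Deposition completeness below 1 interpolates linearly between Mendelian and
full-cutting squares.  `simulate_spread` iterates the calculator as an
infinite-population random-mating recursion with viability renormalization;
`lethal_mosaicism=False` recovers the neutral recessive-viable (*white*)
configuration in which cleaved alleles accumulate as resistance.  In that
configuration the per-generation homing gain is monotone-decreasing from a
carrier-rich start (initial drive frequency 0.5, the heterozygote-cross
situation); a rare-drive invasion instead shows a logistic rise-then-fall.

## Amplicon classification

Target sites are validated as 20-nt protospacer + NGG PAM (23 characters),
blunt cut 3 bp 5′ of the PAM.  Observed sequences are globally aligned to
the reference (match +1, mismatch −1, gap open −4, gap extend −1, leftmost
gaps on ties) and the net length change within ±20 bp of the cut decides
the class; net-zero alleles with substitutions in the seed (protospacer
positions 13–20) or PAM are called R1, an operational proxy — which
substitutions truly abolish recognition cannot be determined from sequence
alone.  Coordinates are 0-based half-open internally, 1-based in reports.
Indels wholly outside the window yield WT with a warning flag.

## What the generator does and does not emulate

It reproduces: binomial gamete sampling from exact event-probability
distributions, replicate structure, marker-linked selection of F2 mothers,
deposition contexts propagated across generations, and mosaicism
penetrance.  It does not include: fitness costs of `y/w` loss (speculated
but unmeasured), per-female germline clustering beyond the embryonic
whole-animal conversion (per-vial clustering is unobservable without the
raw count tables), linkage of white/yellow repair outcomes, DNA-repair
kinetics, overlapping generations, or mate competition.  Passing tests
therefore demonstrate internal consistency of the inference chain under
these assumptions, not that real crosses lack such structure.

## Numerical choices and problem sizes

All probabilities are exact floats; gamete distributions must sum to 1
within 1e-9 (asserted).  Percentages are carried at full precision and
rounded only for display.  One `numpy` `SeedSequence` per run spawns one
child generator per replicate, so replicate counts can change without
perturbing earlier replicates.  Stochastic-vs-oracle checks use n = 10⁵
with 3σ binomial bounds; round-trip reproductions use the experimental
scale of 3 replicates × 500 progeny, where replicate-mean sampling SDs are
about 1.7–2.5 percentage points — agreement is therefore judged against
±2 SE, taking the larger of the empirical and the binomial SE (with three
replicates the empirical SE alone is an unstable yardstick).

## Known limitations

* `r1_y = 0.1` is a placeholder; no observation constrains it.
* The F1 maternal contexts put all cutting at the germline stage
  (`c_emb = 0`): single-generation data cannot separate embryonic from
  germline cuts, so the timing effect lives entirely in the RNP context.
* F3 R2 readouts overshoot slightly (~92% predicted where ~82% was scored
  in the `w+`-father design), consistent with the complementation bias the
  estimator documents but cannot remove from sons-only tables with finite
  mothers per vial.
* The architecture calculators collapse drive, rescue and essential gene
  to one haplotype and ignore drift, fitness costs and spatial structure.
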