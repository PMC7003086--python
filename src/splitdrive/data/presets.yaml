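# Promoter presets for the split-HGD simulator.
#
# Each promoter x context block stores the OBSERVED germline outcome
# frequencies (% of the cleavable allele pool, i.e. normalized to 50% of
# gametes) that the event parameters are fitted from at load time via
# splitdrive.germline.invert_outcome_fractions:
#   c_germ = (100 - intact)/100,  h = homing/(100 - intact),
#   c_y    = yellow_lof/(100 * (1 - r1_y)).
# "intact" is 100 - homing - r2 (red-eyed survivors; pools w+ with the
# phenotypically identical in-frame wR1, so true cleavage is underestimated
# by the R1 fraction).
#
# Contexts:
#   maternal_protein - F1 female: egg loaded with Cas9 protein, gRNA from her
#                      own GDe allele (shadow-drive configuration).
#   zygotic          - F1 female: Cas9 gene inherited from the father, no
#                      carryover protein.
#   maternal_rnp     - F2 female whose mother carried both GDe and Cas9: egg
#                      loaded with protein AND gRNA, so cutting starts in the
#                      early embryo before HDR is efficient. c_emb_w is fitted
#                      from the F3 trans-heterozygous homing observations as
#                      c_emb = 1 - homing_F3 / (c_germ * h); the germline-stage
#                      observed block is shared with maternal_protein.
#
# nos/vas germline outcomes were not quantified for the F1 maternal context;
# their maternal blocks carry the per-promoter F2-generation observations
# (both candidate sets are retained in `observed` below, unreconciled).
# Zygotic germline blocks reuse the maternal fits for nos/vas/BicC (no
# significant maternal-vs-paternal difference for those promoters); only Ubi
# differs. Germline yellow cutting was only measured in the maternal context;
# zygotic blocks reuse it as a documented assumption.
# r1_y = 0.1 is an unconstrained default (the in-frame yellow fraction was
# never measured); r1_w = 0 in F1 germ cells (no in-frame white resistance
# alleles were recovered by sequencing red-eyed males).

promoters:
  nos:
    strong_maternal_deposition: false
    maternal_protein:
      observed: {homing: 80.0, r2: 11.2, intact: 8.8, yellow_lof: 0.0}
      r1_w: 0.0
      r1_y: 0.1
      soma: {white: 1.0, yellow: 1.0}
    zygotic:
      observed: {homing: 80.0, r2: 11.2, intact: 8.8, yellow_lof: 0.0}
      r1_w: 0.0
      r1_y: 0.1
      soma: {white: 1.0, yellow: 1.0}
    maternal_rnp:
      observed: {homing: 80.0, r2: 11.2, intact: 8.8, yellow_lof: 0.0}
      r1_w: 0.0
      r1_y: 0.1
      c_emb_w: 0.85875
      soma: {white: 1.0, yellow: 1.0}
  vas:
    strong_maternal_deposition: false
    maternal_protein:
      observed: {homing: 80.2, r2: 13.2, intact: 6.6, yellow_lof: 0.0}
      r1_w: 0.0
      r1_y: 0.1
      soma: {white: 1.0, yellow: 1.0}
    zygotic:
      observed: {homing: 80.2, r2: 13.2, intact: 6.6, yellow_lof: 0.0}
      r1_w: 0.0
      r1_y: 0.1
      soma: {white: 1.0, yellow: 1.0}
    maternal_rnp:
      observed: {homing: 80.2, r2: 13.2, intact: 6.6, yellow_lof: 0.0}
      r1_w: 0.0
      r1_y: 0.1
      c_emb_w: 0.865337
      soma: {white: 1.0, yellow: 1.0}
  BicC:
    strong_maternal_deposition: true
    maternal_protein:
      observed: {homing: 59.3, r2: 38.7, intact: 2.0, yellow_lof: 89.4}
      r1_w: 0.0
      r1_y: 0.1
      soma: {white: 1.0, yellow: 1.0}
    zygotic:
      observed: {homing: 59.3, r2: 38.7, intact: 2.0, yellow_lof: 89.4}
      r1_w: 0.0
      r1_y: 0.1
      soma: {white: 0.643, yellow: 0.0}
    maternal_rnp:
      observed: {homing: 59.3, r2: 38.7, intact: 2.0, yellow_lof: 89.4}
      r1_w: 0.0
      r1_y: 0.1
      c_emb_w: 0.871838
      soma: {white: 1.0, yellow: 1.0}
  Ubi:
    strong_maternal_deposition: true
    maternal_protein:
      observed: {homing: 67.0, r2: 27.3, intact: 5.7, yellow_lof: 26.0}
      r1_w: 0.0
      r1_y: 0.1
      soma: {white: 1.0, yellow: 1.0}
    zygotic:
      observed: {homing: 88.0, r2: 9.9, intact: 2.1, yellow_lof: 26.0}
      r1_w: 0.0
      r1_y: 0.1
      soma: {white: 1.0, yellow: 0.913}
    maternal_rnp:
      observed: {homing: 67.0, r2: 27.3, intact: 5.7, yellow_lof: 26.0}
      r1_w: 0.0
      r1_y: 0.1
      c_emb_w: 0.889552
      soma: {white: 1.0, yellow: 1.0}

# Printed per-promoter replicate-mean frequencies (%) used as worked-example
# inputs (cross-promoter means, preset regeneration, acceptance reporting).
observed:
  f1_maternal:
    BicC: {homing: 59.3, r2: 38.7, yellow_lof: 89.4}
    Ubi: {homing: 67.0, r2: 27.3, yellow_lof: 26.0}
  f1_paternal:
    Ubi: {homing: 88.0, r2: 9.9}
  soma:
    BicC_zygotic_white: 64.3
    Ubi_zygotic_yellow: 91.3
  f2_trans_het:
    homing: {nos: 80.0, vas: 80.2, Ubi: 78.0, BicC: 53.9}
    r2: {nos: 11.2, vas: 13.2, Ubi: 18.6, BicC: 36.7}
  f3_trans_het:
    homing: {nos: 11.3, vas: 10.8, Ubi: 7.4, BicC: 7.6}
    r2: {nos: 81.7, vas: 82.4, Ubi: 84.6, BicC: 81.6}
  f2_het:
    r2_mean: 28.5
    homing_mean: 69.0
  f3_het:
    r2_mean: 92.6
    homing_mean: 6.1
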