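# Default architecture presets.
#
# cleavage_offset: bp from the spacer-proximal edge of a scaffold's binding
# site to the expected cut center.  The pairwise sums give the predicted
# optimal spacers (TtT 15, TtH 20, HtH 25 bp).
#
# windows: inclusive active spacer-length ranges per architecture.
#   results   -- windows observed in the yeast activity assay.
#   chr1-scan -- alternative, slightly different window set used for
#                chromosome-scale targetability scanning.
scaffolds:
  TALE_FOKI:
    cleavage_offset: 7.5
  FOKI_TALE:
    cleavage_offset: 12.5
array:
  repeats: 15.5
windows:
  results:
    TtT: [[10, 27]]
    HtH: [[22, 27]]
    TtH: [[18, 22], [27, 33]]
  chr1-scan:
    TtT: [[10, 16], [20, 25]]
    HtH: [[22, 27]]
    TtH: [[17, 23], [26, 33]]
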