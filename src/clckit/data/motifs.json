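{
 "clc_motifs": {
  "selectivity_filter": "GxGxPE",
  "clc_motif_2": "GKxGPxxH",
  "clc_motif_3": "PxxGxLF"
 },
 "sorting_signals": {
  "tyrosine": "YxxΦ",
  "dileucine_DXXLL": "DxxLL",
  "dileucine_DE_XXXL_LI": "[DE]xxxL[LI]"
 },
 "hydrophobic_class": "LIMFV"
}
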