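# Default 7-zone excitation-emission integration table (nm).
#
# A regional-integration-style partition of Ex 200-450 x Em 280-600 nm:
# zones I-II cover protein-like (tyrosine/tryptophan) signal, III fulvic-like
# material at short excitation, IV microbial by-product-like signal, and V-VII
# increasingly humified / lipofuscin-like material at long wavelengths.
#
# These boundaries are a documented default, not a fixed convention: the zone
# table is ordinary run configuration and every computation is
# boundary-agnostic. Supply your own table to match your instrument protocol.
zones:
  - {label: I,   ex_min: 200, ex_max: 250, em_min: 280, em_max: 330}
  - {label: II,  ex_min: 200, ex_max: 250, em_min: 330, em_max: 380}
  - {label: III, ex_min: 200, ex_max: 250, em_min: 380, em_max: 600}
  - {label: IV,  ex_min: 250, ex_max: 340, em_min: 280, em_max: 380}
  - {label: V,   ex_min: 250, ex_max: 340, em_min: 380, em_max: 600}
  - {label: VI,  ex_min: 340, ex_max: 450, em_min: 380, em_max: 480}
  - {label: VII, ex_min: 340, ex_max: 450, em_min: 480, em_max: 600}
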