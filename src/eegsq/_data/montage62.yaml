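# 62-channel extended 10-20 scalp layout used by default.
#
# 52 lateral electrodes grouped into 26 left/right homologous pairs plus
# 10 midline electrodes (names ending in "z", never paired).  The pair
# table drives the differential/rational asymmetry (DASM/RASM) features:
# edit this file to change which homologues are contrasted.
channels:
  - Fp1
  - Fpz
  - Fp2
  - AF7
  - AF3
  - AFz
  - AF4
  - AF8
  - F7
  - F5
  - F3
  - F1
  - Fz
  - F2
  - F4
  - F6
  - F8
  - FT7
  - FC5
  - FC3
  - FC1
  - FCz
  - FC2
  - FC4
  - FC6
  - FT8
  - T7
  - C5
  - C3
  - C1
  - Cz
  - C2
  - C4
  - C6
  - T8
  - TP7
  - CP5
  - CP3
  - CP1
  - CPz
  - CP2
  - CP4
  - CP6
  - TP8
  - P7
  - P5
  - P3
  - P1
  - Pz
  - P2
  - P4
  - P6
  - P8
  - PO7
  - PO3
  - POz
  - PO4
  - PO8
  - O1
  - Oz
  - O2
  - Iz
pairs:
  - [Fp1, Fp2]
  - [AF7, AF8]
  - [AF3, AF4]
  - [F7, F8]
  - [F5, F6]
  - [F3, F4]
  - [F1, F2]
  - [FT7, FT8]
  - [FC5, FC6]
  - [FC3, FC4]
  - [FC1, FC2]
  - [T7, T8]
  - [C5, C6]
  - [C3, C4]
  - [C1, C2]
  - [TP7, TP8]
  - [CP5, CP6]
  - [CP3, CP4]
  - [CP1, CP2]
  - [P7, P8]
  - [P5, P6]
  - [P3, P4]
  - [P1, P2]
  - [PO7, PO8]
  - [PO3, PO4]
  - [O1, O2]
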