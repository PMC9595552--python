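# SubCellBarCode neighborhood vocabulary mapped to the simplified
# four-compartment vocabulary (1:1 apart from Unassign, which carries no
# localization evidence). Columns: neighborhood <TAB> category
Mitochondria	mitochondria
Cytosol	cytoplasm
Nuclear	nucleus
Secretory	secretory
Unassign	unknown
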