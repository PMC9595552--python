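# Human Protein Atlas subcellular-location vocabulary mapped to the simplified
# four-compartment vocabulary. The grouping follows HPA's organelle-proteome
# groups (nuclear / cytoplasmic / secretory), except that mitochondria are kept
# as their own compartment instead of being pooled with the cytoplasm.
# Columns: hpa_location <TAB> category
Nucleoplasm	nucleus
Nuclear bodies	nucleus
Nuclear speckles	nucleus
Nuclear membrane	nucleus
Nucleoli	nucleus
Nucleoli fibrillar center	nucleus
Nucleoli rim	nucleus
Kinetochore	nucleus
Mitotic chromosome	nucleus
Mitochondria	mitochondria
Cytosol	cytoplasm
Cytoplasmic bodies	cytoplasm
Aggresome	cytoplasm
Rods & Rings	cytoplasm
Microtubules	cytoplasm
Microtubule ends	cytoplasm
Cytokinetic bridge	cytoplasm
Midbody	cytoplasm
Midbody ring	cytoplasm
Mitotic spindle	cytoplasm
Centrosome	cytoplasm
Centriolar satellite	cytoplasm
Actin filaments	cytoplasm
Focal adhesion sites	cytoplasm
Intermediate filaments	cytoplasm
Cleavage furrow	cytoplasm
Endoplasmic reticulum	secretory
Golgi apparatus	secretory
Vesicles	secretory
Endosomes	secretory
Lysosomes	secretory
Peroxisomes	secretory
Lipid droplets	secretory
Plasma membrane	secretory
Cell Junctions	secretory
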