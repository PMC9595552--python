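# BUSCA predicted-class vocabulary mapped to the simplified four-compartment
# vocabulary. Extracellular and membrane classes are pooled with the secretory
# compartment; plant-specific classes have no human counterpart and map to
# unknown. Columns: busca_class <TAB> category
mitochondrion	mitochondria
cytoplasm	cytoplasm
nucleus	nucleus
extracellular space	secretory
plasma membrane	secretory
organelle membrane	secretory
endomembrane system	secretory
chloroplast	unknown
chloroplast thylakoid lumen	unknown
chloroplast thylakoid membrane	unknown
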