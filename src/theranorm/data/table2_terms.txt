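# Additional failure-term examples, annotated by kind in the companion
# descriptions file: general categories, nonspecific compound identifiers,
# experimental compound codes, multi-language or misspelled labels,
# therapeutic descriptions, and unknown identifiers.
HDAC inhibitors
MEK Inhibitors
beta blocking agents, nonselective
Tyrosine kinase inhibitors
Pyrrollidine derivative 3
Carbamate derivative 3
Tetra-hydro-isoquinoline derivative 4
Benzene sulfonamide derivative 3
EVT-103
ADR-851
APN-201
Cysplatyna
Flourouracil
Vandetinib
Radiation Therapy
CD19 CAR Gene Transduced T Lymphocytes
Anti-PD-L1 CSR T Cells
Long-acting erythropoietin conjugate
Interferon-alpha lozenge
coxsackievirus type a21
249565746
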