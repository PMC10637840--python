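# Most frequent terms from public drug vocabularies that fail to normalize
# (general categories, regimens, cell therapies, misspellings, ...).
chemotherapy
carboplatin-taxol regimen
r3mab
car-t cells targeting mesothelin
anti-vegf
parp inhibitors
hdac inhibitors
src inhibitors
egfr inhibitors
opium derivatives and expectorants
oxymetazoline and tetracaine
antithrombotic agents
paracetamol, combinations excl. psycholeptics
vitamin b-complex with vitamin c
parathyroid hormones and analogues
high dose chemotherapy
flourouracil
pc regimen
car-t cells targeting muc1
cat regimen
sb3
carbo-tax regimen
liposomal doxorubicin
sgk1-inh
radiation ionizing radiotherapy
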