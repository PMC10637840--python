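{
  "schema": "theranorm-source-registry",
  "sources": [
    {"name": "rxcui", "display": "RxNorm", "priority_rank": 1, "version_label": ""},
    {"name": "ncit", "display": "NCIt", "priority_rank": 2, "version_label": ""},
    {"name": "hemonc", "display": "HemOnc", "priority_rank": 3, "version_label": ""},
    {"name": "drugbank", "display": "DrugBank", "priority_rank": 4, "version_label": ""},
    {"name": "drugsatfda", "display": "Drugs@FDA", "priority_rank": 5, "version_label": ""},
    {"name": "guidetopharmacology", "display": "GuideToPharmacology", "priority_rank": 6, "version_label": ""},
    {"name": "chembl", "display": "ChEMBL", "priority_rank": 7, "version_label": ""},
    {"name": "chemidplus", "display": "ChemIDplus", "priority_rank": 8, "version_label": ""},
    {"name": "wikidata", "display": "Wikidata", "priority_rank": 9, "version_label": ""}
  ],
  "synonyms": {
    "rxnorm": "rxcui",
    "nci": "ncit",
    "ncithesaurus": "ncit",
    "drugs@fda": "drugsatfda",
    "iuphar": "guidetopharmacology",
    "iuphar.ligand": "guidetopharmacology",
    "gtopdb": "guidetopharmacology",
    "chembl.compound": "chembl"
  },
  "external_namespaces": ["atc", "unii", "cas", "inchikey", "usan"]
}
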