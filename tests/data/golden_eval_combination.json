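{
 "n_terms": 3,
 "n_terms_undefined": 1,
 "median_auroc": 1.0,
 "median_auprc": 1.0,
 "n_perfect": 2,
 "median_auroc_restricted": NaN,
 "median_auprc_restricted": NaN,
 "by_size_bin": {
  "[10, 20]": {
   "n_terms": 0,
   "median_auroc": NaN,
   "median_auprc": NaN
  },
  "(20, 27]": {
   "n_terms": 0,
   "median_auroc": NaN,
   "median_auprc": NaN
  },
  "(27, 40]": {
   "n_terms": 0,
   "median_auroc": NaN,
   "median_auprc": NaN
  },
  "(40, 64]": {
   "n_terms": 0,
   "median_auroc": NaN,
   "median_auprc": NaN
  },
  "(64, 114]": {
   "n_terms": 0,
   "median_auroc": NaN,
   "median_auprc": NaN
  },
  "(114, 300]": {
   "n_terms": 0,
   "median_auroc": NaN,
   "median_auprc": NaN
  }
 },
 "by_ontology": {
  "BP": {
   "n_terms": 1,
   "median_auroc": 1.0,
   "median_auprc": 1.0,
   "pct_perfect": 100.0
  },
  "MF": {
   "n_terms": 1,
   "median_auroc": 1.0,
   "median_auprc": 1.0,
   "pct_perfect": 100.0
  }
 }
}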