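[
  {
    "name": "swallowing_dysfunction_6m",
    "endpoint_label": "Physician-rated swallowing dysfunction grade >=2 at 6 months",
    "grade_class": "ge2",
    "form": "logistic_linear",
    "intercept": -6.09,
    "terms": [
      {"covariate_key": "pcm.dmean", "coefficient": 0.057},
      {"covariate_key": "supraglottic_larynx.dmean", "coefficient": 0.037}
    ],
    "evidence_level": "2",
    "source_citation": "ILLUSTRATIVE coefficients (two-term logistic on pharyngeal constrictor and supraglottic larynx mean dose); transcribe the published model before clinical use"
  },
  {
    "name": "dysgeusia_hnqol",
    "endpoint_label": "Dysgeusia (HNQOL) grade >=2",
    "grade_class": "ge2",
    "form": "logistic_linear",
    "intercept": -5.08,
    "terms": [
      {"covariate_key": "oral_cavity.dmean", "coefficient": 0.089}
    ],
    "evidence_level": "3",
    "source_citation": "ILLUSTRATIVE coefficients (logistic on oral cavity mean dose); transcribe the published model before clinical use"
  },
  {
    "name": "dysgeusia_uwqol",
    "endpoint_label": "Dysgeusia (UWQOL) grade >=2",
    "grade_class": "ge2",
    "form": "logistic_linear",
    "intercept": -4.90,
    "terms": [
      {"covariate_key": "oral_cavity.dmean", "coefficient": 0.085}
    ],
    "evidence_level": "3",
    "source_citation": "ILLUSTRATIVE coefficients (logistic on oral cavity mean dose); transcribe the published model before clinical use"
  },
  {
    "name": "hearing_loss",
    "endpoint_label": "Sensorineural hearing loss grade >=2",
    "grade_class": "ge2",
    "form": "lkb_probit",
    "lkb": {"td50": 46.0, "m": 0.35, "a": 1.0, "structure": "ipsilateral_cochlea"},
    "evidence_level": "1b",
    "source_citation": "ILLUSTRATIVE parameters (LKB on ipsilateral cochlea gEUD, proton-derived endpoint applied to both techniques); transcribe the published model before clinical use"
  },
  {
    "name": "tinnitus",
    "endpoint_label": "Tinnitus grade >=2",
    "grade_class": "ge2",
    "form": "lkb_probit",
    "lkb": {"td50": 39.0, "m": 0.62, "a": 1.0, "structure": "ipsilateral_cochlea"},
    "evidence_level": "4",
    "source_citation": "ILLUSTRATIVE parameters (LKB on ipsilateral cochlea gEUD); transcribe the published model before clinical use"
  },
  {
    "name": "acute_oral_mucositis_gt1.5",
    "endpoint_label": "Acute oral mucositis grade >1.5",
    "grade_class": "ge2",
    "form": "logistic_linear",
    "intercept": -4.30,
    "terms": [
      {"covariate_key": "oral_cavity.dmean", "coefficient": 0.075}
    ],
    "evidence_level": "2",
    "source_citation": "ILLUSTRATIVE coefficients (logistic on oral cavity mean dose); transcribe the published model before clinical use"
  },
  {
    "name": "trismus",
    "endpoint_label": "Trismus grade >=2",
    "grade_class": "ge2",
    "form": "logistic_linear",
    "intercept": -7.50,
    "terms": [
      {"covariate_key": "ipsilateral_masseter.dmean", "coefficient": 0.05}
    ],
    "evidence_level": "4",
    "source_citation": "ILLUSTRATIVE coefficients (logistic on ipsilateral masseter mean dose; near-zero NTCP expected for lateralized parotid plans under both techniques); transcribe the published model before clinical use"
  }
]
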