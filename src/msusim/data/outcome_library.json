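{
  "description": "Reference mRS distributions (probabilities over mRS 0-6) for treatment at onset (dist_t0) and at the time of no effect (dist_no_effect), per patient-treatment cohort, with untreated baselines. Transcribed from the published stroke outcome model derived from reperfusion clinical-trial meta-analyses; utility weights per mRS level from Wang et al.",
  "cohorts": {
    "nLVO_IVT": {
      "t_no_effect_min": 378,
      "dist_t0":        [0.429808, 0.200192, 0.108212, 0.110215, 0.080761, 0.027312, 0.043500],
      "dist_no_effect": [0.197271, 0.262729, 0.117583, 0.124669, 0.142992, 0.059210, 0.095546]
    },
    "LVO_IVT": {
      "t_no_effect_min": 378,
      "dist_t0":        [0.112916, 0.087084, 0.127377, 0.157380, 0.213455, 0.113231, 0.188557],
      "dist_no_effect": [0.047898, 0.075678, 0.130282, 0.157104, 0.236614, 0.129324, 0.223100]
    },
    "LVO_MT": {
      "t_no_effect_min": 480,
      "dist_t0":        [0.305000, 0.095000, 0.148000, 0.129000, 0.161000, 0.091000, 0.071000],
      "dist_no_effect": [0.047781, 0.075487, 0.129963, 0.156716, 0.236028, 0.129005, 0.225020]
    }
  },
  "untreated": {
    "nLVO": [0.197144, 0.262856, 0.120032, 0.127736, 0.147909, 0.062025, 0.082298],
    "LVO":  [0.050000, 0.079000, 0.136000, 0.164000, 0.247000, 0.135000, 0.189000]
  },
  "utility_weights": [0.97, 0.88, 0.74, 0.55, 0.20, -0.19, 0.00],
  "cohort_mix": {"p_nLVO": 0.70, "p_LVO": 0.30},
  "combination_rule": "best_of"
}
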