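{
 "country": "UK",
 "gender": "female",
 "ethnicity": "Asian",
 "anthropometry": {
  "height": {
   "alpha": 162.0,
   "a1": -0.126,
   "a2": 0.0,
   "sigma": 6.0
  },
  "log_body_mass": {
   "alpha": 3.94,
   "a1": 0.009,
   "a2": -7e-05,
   "sigma": 0.2
  },
  "rho": 0.29
 },
 "cardiac_output": {
  "form": "female_cubic",
  "alpha": 1.703,
  "h1": 0.0257,
  "a1": 0.0173,
  "a2": -0.000916,
  "a3": 6.42e-06,
  "sigma": 0.093
 },
 "rho_adipose_muscle": -0.87,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.725,
    "h1": 0.0044
   },
   "sigma": 0.318,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.368,
    "a1": -0.002
   },
   "sigma": 0.065,
   "flow_c1": 0.132,
   "flow_sigma": 0.033
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.091,
    "h1": 0.0015
   },
   "sigma": 0.083,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.167,
    "h1": 0.0015
   },
   "sigma": 0.1,
   "flow_c1": 0.204,
   "flow_sigma": 0.046
  },
  "liver": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.659,
    "h1": 0.008
   },
   "sigma": 0.48,
   "flow_c1": 0.071,
   "flow_sigma": 0.019
  },
  "pancreas": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.0373,
    "h1": 0.00083
   },
   "sigma": 0.048,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.263,
    "h1": 0.0044
   },
   "sigma": 0.37,
   "flow_c1": 0.031,
   "flow_sigma": 0.008
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.057,
    "h1": 0.00067
   },
   "sigma": 0.021,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.247,
    "h1": 0.003
   },
   "sigma": 0.093,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.139,
    "h1": 0.0017
   },
   "sigma": 0.054,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "sexual_organs": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.012
   },
   "sigma": 0.0008,
   "flow_c1": 0.0002,
   "flow_sigma": 6e-05
  },
  "skin": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.377,
    "m1": 0.052,
    "m2": -0.0003
   },
   "sigma": 0.165,
   "flow_c1": 0.051,
   "flow_sigma": 0.0139
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.451,
    "a1": 0.0464,
    "a2": -0.00051,
    "h1": 0.044
   },
   "sigma": 0.096,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "adipose": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -3.29,
    "a1": -0.008,
    "a2": 0.00011,
    "h1": 0.0247,
    "b1": 0.103
   },
   "sigma": 0.268,
   "flow_c1": 0.092,
   "flow_sigma": 0.024
  },
  "muscle": {
   "family": "lognormal",
   "coeffs": {
    "alpha": 1.644,
    "a1": 0.0062,
    "a2": -9.4e-05,
    "h1": 0.0067,
    "b1": 0.0071
   },
   "sigma": 0.251,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  }
 }
}
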