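{
 "country": "UK",
 "gender": "female",
 "ethnicity": "Black",
 "anthropometry": {
  "height": {
   "alpha": 161.9,
   "a1": 0.228,
   "a2": -0.0049,
   "sigma": 6.3
  },
  "log_body_mass": {
   "alpha": 3.93,
   "a1": 0.0147,
   "a2": -0.00013,
   "sigma": 0.19
  },
  "rho": 0.36
 },
 "cardiac_output": {
  "form": "female_cubic",
  "alpha": 1.893,
  "h1": 0.0248,
  "a1": 0.009,
  "a2": -0.000869,
  "a3": 6.89e-06,
  "sigma": 0.093
 },
 "rho_adipose_muscle": -0.87,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.852,
    "h1": 0.005
   },
   "sigma": 0.321,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.374,
    "a1": -0.0021
   },
   "sigma": 0.064,
   "flow_c1": 0.132,
   "flow_sigma": 0.033
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.071,
    "h1": 0.0016
   },
   "sigma": 0.082,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.128,
    "h1": 0.0017
   },
   "sigma": 0.099,
   "flow_c1": 0.204,
   "flow_sigma": 0.046
  },
  "liver": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.528,
    "h1": 0.0084
   },
   "sigma": 0.474,
   "flow_c1": 0.071,
   "flow_sigma": 0.019
  },
  "pancreas": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.0485,
    "h1": 0.00072
   },
   "sigma": 0.048,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.49,
    "h1": 0.0056
   },
   "sigma": 0.368,
   "flow_c1": 0.031,
   "flow_sigma": 0.008
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.041,
    "h1": 0.00073
   },
   "sigma": 0.021,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.186,
    "h1": 0.003
   },
   "sigma": 0.093,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.101,
    "h1": 0.0019
   },
   "sigma": 0.053,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "sexual_organs": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.012
   },
   "sigma": 0.0007,
   "flow_c1": 0.0002,
   "flow_sigma": 6e-05
  },
  "skin": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.615,
    "m1": 0.0452,
    "m2": -0.00024
   },
   "sigma": 0.186,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.964,
    "a1": 0.024,
    "a2": -0.0003,
    "h1": 0.043
   },
   "sigma": 0.097,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "adipose": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.836,
    "a1": -0.0016,
    "a2": 3.8e-05,
    "h1": 0.026,
    "b1": 0.096
   },
   "sigma": 0.237,
   "flow_c1": 0.092,
   "flow_sigma": 0.024
  },
  "muscle": {
   "family": "lognormal",
   "coeffs": {
    "alpha": 1.88,
    "a1": 0.0039,
    "a2": -7.1e-05,
    "h1": 0.0059,
    "b1": 0.0035
   },
   "sigma": 0.256,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  }
 }
}
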