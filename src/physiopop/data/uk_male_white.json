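{
 "country": "UK",
 "gender": "male",
 "ethnicity": "White",
 "anthropometry": {
  "height": {
   "alpha": 176.0,
   "a1": 0.15,
   "a2": -0.003,
   "sigma": 6.9
  },
  "log_body_mass": {
   "alpha": 4.06,
   "a1": 0.0168,
   "a2": -0.00017,
   "sigma": 0.17
  },
  "rho": 0.41
 },
 "cardiac_output": {
  "form": "male_logistic",
  "alpha": 2.755,
  "h1": 0.025,
  "a1": -0.03,
  "a2": -0.707,
  "a3": -0.626,
  "sigma": 0.109
 },
 "rho_adipose_muscle": -0.9,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.503,
    "h1": 0.0044
   },
   "sigma": 0.324,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.488,
    "a1": -0.0023
   },
   "sigma": 0.07,
   "flow_c1": 0.128,
   "flow_sigma": 0.036
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.094,
    "h1": 0.0019
   },
   "sigma": 0.108,
   "flow_c1": 0.043,
   "flow_sigma": 0.013
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.128,
    "h1": 0.0019
   },
   "sigma": 0.116,
   "flow_c1": 0.217,
   "flow_sigma": 0.055
  },
  "liver": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.689,
    "h1": 0.01
   },
   "sigma": 0.591,
   "flow_c1": 0.069,
   "flow_sigma": 0.021
  },
  "pancreas": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.064,
    "h1": 0.0008
   },
   "sigma": 0.054,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.272,
    "h1": 0.0047
   },
   "sigma": 0.368,
   "flow_c1": 0.032,
   "flow_sigma": 0.01
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.067,
    "h1": 0.0006
   },
   "sigma": 0.055,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.194,
    "h1": 0.003
   },
   "sigma": 0.092,
   "flow_c1": 0.11,
   "flow_sigma": 0.03
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.139,
    "h1": 0.002
   },
   "sigma": 0.086,
   "flow_c1": 0.043,
   "flow_sigma": 0.013
  },
  "sexual_organs": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.0462
   },
   "sigma": 0.0027,
   "flow_c1": 0.0005,
   "flow_sigma": 0.0002
  },
  "skin": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.053,
    "m1": 0.0464,
    "m2": -0.00021
   },
   "sigma": 0.163,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 3.187,
    "a1": 0.379,
    "h1": 0.044,
    "h2": 0.0098
   },
   "sigma": 0.128,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "adipose": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -3.51,
    "a1": -0.0115,
    "a2": 0.00016,
    "h1": 0.023,
    "b1": 0.105
   },
   "sigma": 0.328,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "muscle": {
   "family": "lognormal",
   "coeffs": {
    "alpha": 1.595,
    "a1": 0.0076,
    "a2": -0.00011,
    "h1": 0.0071,
    "b1": 0.0181
   },
   "sigma": 0.228,
   "flow_c1": 0.181,
   "flow_sigma": 0.048
  }
 }
}
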