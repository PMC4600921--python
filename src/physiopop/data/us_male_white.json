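{
 "country": "US",
 "gender": "male",
 "ethnicity": "White",
 "anthropometry": {
  "height": {
   "alpha": 175.6,
   "a1": 0.136,
   "a2": -0.002,
   "sigma": 6.6
  },
  "log_body_mass": {
   "alpha": 3.96,
   "a1": 0.0197,
   "a2": -0.0002,
   "sigma": 0.19
  },
  "rho": 0.43
 },
 "cardiac_output": {
  "form": "male_logistic",
  "alpha": 2.749,
  "h1": 0.025,
  "a1": -0.031,
  "a2": -0.449,
  "a3": -0.82,
  "sigma": 0.11
 },
 "rho_adipose_muscle": -0.9,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.582,
    "h1": 0.0047
   },
   "sigma": 0.324,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.486,
    "a1": -0.0022
   },
   "sigma": 0.069,
   "flow_c1": 0.128,
   "flow_sigma": 0.036
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.098,
    "h1": 0.0018
   },
   "sigma": 0.081,
   "flow_c1": 0.043,
   "flow_sigma": 0.013
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.086,
    "h1": 0.002
   },
   "sigma": 0.113,
   "flow_c1": 0.217,
   "flow_sigma": 0.055
  },
  "liver": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.189,
    "h1": 0.0124
   },
   "sigma": 0.571,
   "flow_c1": 0.069,
   "flow_sigma": 0.021
  },
  "pancreas": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.035,
    "h1": 0.0009
   },
   "sigma": 0.053,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.166,
    "h1": 0.004
   },
   "sigma": 0.364,
   "flow_c1": 0.032,
   "flow_sigma": 0.01
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.038,
    "h1": 0.00075
   },
   "sigma": 0.053,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.189,
    "h1": 0.0031
   },
   "sigma": 0.09,
   "flow_c1": 0.11,
   "flow_sigma": 0.03
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.126,
    "h1": 0.0016
   },
   "sigma": 0.083,
   "flow_c1": 0.043,
   "flow_sigma": 0.013
  },
  "sexual_organs": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.045
   },
   "sigma": 0.0026,
   "flow_c1": 0.0005,
   "flow_sigma": 0.0002
  },
  "skin": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.068,
    "m1": 0.0462,
    "m2": -0.00021
   },
   "sigma": 0.163,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 3.044,
    "a1": 0.445,
    "h1": 0.043,
    "h2": 0.0093
   },
   "sigma": 0.127,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "adipose": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -3.536,
    "a1": -0.0094,
    "a2": 0.00014,
    "h1": 0.0232,
    "b1": 0.0105
   },
   "sigma": 0.325,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "muscle": {
   "family": "lognormal",
   "coeffs": {
    "alpha": 1.719,
    "a1": 0.0072,
    "a2": -0.00011,
    "h1": 0.0067,
    "b1": 0.0155
   },
   "sigma": 0.234,
   "flow_c1": 0.181,
   "flow_sigma": 0.048
  }
 }
}
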