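{
 "country": "UK",
 "gender": "male",
 "ethnicity": "Asian",
 "anthropometry": {
  "height": {
   "alpha": 174.4,
   "a1": -0.086,
   "a2": 0.0,
   "sigma": 6.3
  },
  "log_body_mass": {
   "alpha": 3.96,
   "a1": 0.0186,
   "a2": -0.00021,
   "sigma": 0.18
  },
  "rho": 0.42
 },
 "cardiac_output": {
  "form": "male_logistic",
  "alpha": 2.748,
  "h1": 0.026,
  "a1": -0.031,
  "a2": -0.513,
  "a3": -0.716,
  "sigma": 0.108
 },
 "rho_adipose_muscle": -0.9,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.401,
    "h1": 0.0035
   },
   "sigma": 0.323,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.49,
    "a1": -0.0022
   },
   "sigma": 0.07,
   "flow_c1": 0.128,
   "flow_sigma": 0.036
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.131,
    "h1": 0.0016
   },
   "sigma": 0.078,
   "flow_c1": 0.043,
   "flow_sigma": 0.013
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.105,
    "h1": 0.0019
   },
   "sigma": 0.108,
   "flow_c1": 0.217,
   "flow_sigma": 0.055
  },
  "liver": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.679,
    "h1": 0.0093
   },
   "sigma": 0.548,
   "flow_c1": 0.069,
   "flow_sigma": 0.021
  },
  "pancreas": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.05,
    "h1": 0.0008
   },
   "sigma": 0.05,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.3,
    "h1": 0.0046
   },
   "sigma": 0.363,
   "flow_c1": 0.032,
   "flow_sigma": 0.01
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.055,
    "h1": 0.0006
   },
   "sigma": 0.051,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.204,
    "h1": 0.003
   },
   "sigma": 0.087,
   "flow_c1": 0.11,
   "flow_sigma": 0.03
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.12,
    "h1": 0.0016
   },
   "sigma": 0.08,
   "flow_c1": 0.043,
   "flow_sigma": 0.013
  },
  "sexual_organs": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.043
   },
   "sigma": 0.0024,
   "flow_c1": 0.0005,
   "flow_sigma": 0.0002
  },
  "skin": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.943,
    "m1": 0.05,
    "m2": -0.00024
   },
   "sigma": 0.158,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 2.88,
    "a1": 0.357,
    "h1": 0.0429,
    "h2": 0.0097
   },
   "sigma": 0.121,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "adipose": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -3.658,
    "a1": -0.0126,
    "a2": 0.00018,
    "h1": 0.0242,
    "b1": 0.106
   },
   "sigma": 0.327,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "muscle": {
   "family": "lognormal",
   "coeffs": {
    "alpha": 1.517,
    "a1": 0.0081,
    "a2": -0.00012,
    "h1": 0.0075,
    "b1": 0.017
   },
   "sigma": 0.227,
   "flow_c1": 0.181,
   "flow_sigma": 0.048
  }
 }
}
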