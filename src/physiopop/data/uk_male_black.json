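{
 "country": "UK",
 "gender": "male",
 "ethnicity": "Black",
 "anthropometry": {
  "height": {
   "alpha": 178.8,
   "a1": -0.113,
   "a2": 0.0,
   "sigma": 7.4
  },
  "log_body_mass": {
   "alpha": 4.1,
   "a1": 0.0167,
   "a2": -0.0002,
   "sigma": 0.19
  },
  "rho": 0.45
 },
 "cardiac_output": {
  "form": "male_logistic",
  "alpha": 2.645,
  "h1": 0.026,
  "a1": -0.029,
  "a2": -0.399,
  "a3": -0.934,
  "sigma": 0.11
 },
 "rho_adipose_muscle": -0.9,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.299,
    "h1": 0.0035
   },
   "sigma": 0.32,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.482,
    "a1": -0.0021
   },
   "sigma": 0.07,
   "flow_c1": 0.128,
   "flow_sigma": 0.036
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.169,
    "h1": 0.0017
   },
   "sigma": 0.089,
   "flow_c1": 0.043,
   "flow_sigma": 0.013
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.119,
    "h1": 0.002
   },
   "sigma": 0.121,
   "flow_c1": 0.217,
   "flow_sigma": 0.055
  },
  "liver": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.867,
    "h1": 0.0098
   },
   "sigma": 0.621,
   "flow_c1": 0.069,
   "flow_sigma": 0.021
  },
  "pancreas": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.071,
    "h1": 0.0008
   },
   "sigma": 0.057,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.155,
    "h1": 0.0044
   },
   "sigma": 0.368,
   "flow_c1": 0.032,
   "flow_sigma": 0.01
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.039,
    "h1": 0.0008
   },
   "sigma": 0.058,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.229,
    "h1": 0.0033
   },
   "sigma": 0.097,
   "flow_c1": 0.11,
   "flow_sigma": 0.03
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.148,
    "h1": 0.0017
   },
   "sigma": 0.089,
   "flow_c1": 0.043,
   "flow_sigma": 0.013
  },
  "sexual_organs": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.048
   },
   "sigma": 0.0028,
   "flow_c1": 0.0005,
   "flow_sigma": 0.0002
  },
  "skin": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.051,
    "m1": 0.046,
    "m2": -0.0002
   },
   "sigma": 0.153,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 3.564,
    "a1": 0.44,
    "h1": 0.051,
    "h2": 0.0072
   },
   "sigma": 0.146,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "adipose": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -3.835,
    "a1": -0.0069,
    "a2": 0.0001,
    "h1": 0.0241,
    "b1": 0.103
   },
   "sigma": 0.338,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "muscle": {
   "family": "lognormal",
   "coeffs": {
    "alpha": 1.465,
    "a1": 0.0052,
    "a2": -8e-05,
    "h1": 0.0076,
    "b1": 0.026
   },
   "sigma": 0.219,
   "flow_c1": 0.181,
   "flow_sigma": 0.048
  }
 }
}
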