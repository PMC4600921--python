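{
 "country": "US",
 "gender": "male",
 "ethnicity": "Black",
 "anthropometry": {
  "height": {
   "alpha": 172.4,
   "a1": 0.267,
   "a2": -0.0038,
   "sigma": 7.0
  },
  "log_body_mass": {
   "alpha": 3.92,
   "a1": 0.0233,
   "a2": -0.00026,
   "sigma": 0.22
  },
  "rho": 0.28
 },
 "cardiac_output": {
  "form": "male_logistic",
  "alpha": 2.342,
  "h1": 0.026,
  "a1": -0.031,
  "a2": 0.403,
  "a3": 0.917,
  "sigma": 0.111
 },
 "rho_adipose_muscle": -0.9,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.603,
    "h1": 0.0049
   },
   "sigma": 0.325,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.49,
    "a1": -0.0023
   },
   "sigma": 0.07,
   "flow_c1": 0.128,
   "flow_sigma": 0.036
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.119,
    "h1": 0.0018
   },
   "sigma": 0.082,
   "flow_c1": 0.043,
   "flow_sigma": 0.013
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.127,
    "h1": 0.0019
   },
   "sigma": 0.113,
   "flow_c1": 0.217,
   "flow_sigma": 0.055
  },
  "liver": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.841,
    "h1": 0.009
   },
   "sigma": 0.586,
   "flow_c1": 0.069,
   "flow_sigma": 0.021
  },
  "pancreas": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.041,
    "h1": 0.0009
   },
   "sigma": 0.053,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.191,
    "h1": 0.0042
   },
   "sigma": 0.369,
   "flow_c1": 0.032,
   "flow_sigma": 0.01
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.029,
    "h1": 0.0008
   },
   "sigma": 0.053,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.165,
    "h1": 0.0034
   },
   "sigma": 0.092,
   "flow_c1": 0.11,
   "flow_sigma": 0.03
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.111,
    "h1": 0.0018
   },
   "sigma": 0.086,
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
    "alpha": 1.112,
    "m1": 0.0447,
    "m2": -0.0002
   },
   "sigma": 0.156,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 3.22,
    "a1": 0.635,
    "h1": 0.0474,
    "h2": 0.0076
   },
   "sigma": 0.149,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "adipose": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -3.919,
    "a1": -0.0049,
    "a2": 9e-05,
    "h1": 0.0241,
    "b1": 0.108
   },
   "sigma": 0.326,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "muscle": {
   "family": "lognormal",
   "coeffs": {
    "alpha": 1.812,
    "a1": 0.0048,
    "a2": -8e-05,
    "h1": 0.0065,
    "b1": 0.0163
   },
   "sigma": 0.226,
   "flow_c1": 0.181,
   "flow_sigma": 0.048
  }
 }
}
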