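{
 "country": "US",
 "gender": "female",
 "ethnicity": "White",
 "anthropometry": {
  "height": {
   "alpha": 162.1,
   "a1": 0.142,
   "a2": -0.0025,
   "sigma": 6.3
  },
  "log_body_mass": {
   "alpha": 3.88,
   "a1": 0.014,
   "a2": -0.00012,
   "sigma": 0.22
  },
  "rho": 0.31
 },
 "cardiac_output": {
  "form": "female_cubic",
  "alpha": 1.854,
  "h1": 0.0248,
  "a1": 0.0127,
  "a2": -0.000956,
  "a3": 7.39e-06,
  "sigma": 0.092
 },
 "rho_adipose_muscle": -0.86,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.661,
    "h1": 0.0037
   },
   "sigma": 0.323,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.37,
    "a1": -0.0021
   },
   "sigma": 0.065,
   "flow_c1": 0.132,
   "flow_sigma": 0.033
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.078,
    "h1": 0.0015
   },
   "sigma": 0.081,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.102,
    "h1": 0.0018
   },
   "sigma": 0.1,
   "flow_c1": 0.204,
   "flow_sigma": 0.046
  },
  "liver": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.386,
    "h1": 0.0092
   },
   "sigma": 0.471,
   "flow_c1": 0.071,
   "flow_sigma": 0.019
  },
  "pancreas": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.052,
    "h1": 0.0007
   },
   "sigma": 0.048,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.361,
    "h1": 0.0047
   },
   "sigma": 0.368,
   "flow_c1": 0.031,
   "flow_sigma": 0.008
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.045,
    "h1": 0.0007
   },
   "sigma": 0.021,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.168,
    "h1": 0.0033
   },
   "sigma": 0.092,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.108,
    "h1": 0.0018
   },
   "sigma": 0.052,
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
    "alpha": 0.656,
    "m1": 0.044,
    "m2": -0.00024
   },
   "sigma": 0.176,
   "flow_c1": 0.051,
   "flow_sigma": 0.0139
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.708,
    "a1": 0.0293,
    "a2": -0.00036,
    "h1": 0.042
   },
   "sigma": 0.092,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "adipose": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.7,
    "a1": -0.0035,
    "a2": 6e-05,
    "h1": 0.022,
    "b1": 0.096
   },
   "sigma": 0.24,
   "flow_c1": 0.092,
   "flow_sigma": 0.024
  },
  "muscle": {
   "family": "lognormal",
   "coeffs": {
    "alpha": 1.71,
    "a1": 0.0058,
    "a2": -9.5e-05,
    "h1": 0.0066,
    "b1": 0.0036
   },
   "sigma": 0.262,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  }
 }
}
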