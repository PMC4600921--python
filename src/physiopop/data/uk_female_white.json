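{
 "country": "UK",
 "gender": "female",
 "ethnicity": "White",
 "anthropometry": {
  "height": {
   "alpha": 163.9,
   "a1": 0.052,
   "a2": -0.0017,
   "sigma": 6.3
  },
  "log_body_mass": {
   "alpha": 4.0,
   "a1": 0.0099,
   "a2": -9e-05,
   "sigma": 0.2
  },
  "rho": 0.29
 },
 "cardiac_output": {
  "form": "female_cubic",
  "alpha": 1.87,
  "h1": 0.0246,
  "a1": 0.0122,
  "a2": -0.000908,
  "a3": 6.89e-06,
  "sigma": 0.093
 },
 "rho_adipose_muscle": -0.9,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.565,
    "h1": 0.0037
   },
   "sigma": 0.325,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.374,
    "a1": -0.0021
   },
   "sigma": 0.065,
   "flow_c1": 0.132,
   "flow_sigma": 0.033
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.116,
    "h1": 0.0014
   },
   "sigma": 0.089,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.137,
    "h1": 0.0018
   },
   "sigma": 0.107,
   "flow_c1": 0.204,
   "flow_sigma": 0.046
  },
  "liver": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.629,
    "h1": 0.0087
   },
   "sigma": 0.516,
   "flow_c1": 0.071,
   "flow_sigma": 0.019
  },
  "pancreas": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.031,
    "h1": 0.0009
   },
   "sigma": 0.052,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.309,
    "h1": 0.0049
   },
   "sigma": 0.364,
   "flow_c1": 0.031,
   "flow_sigma": 0.008
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.055,
    "h1": 0.00073
   },
   "sigma": 0.022,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.205,
    "h1": 0.003
   },
   "sigma": 0.1,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.109,
    "h1": 0.002
   },
   "sigma": 0.058,
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
    "m1": 0.045,
    "m2": -0.00024
   },
   "sigma": 0.166,
   "flow_c1": 0.051,
   "flow_sigma": 0.0139
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.801,
    "a1": 0.0377,
    "a2": -0.00045,
    "h1": 0.046
   },
   "sigma": 0.103,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "adipose": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -3.298,
    "a1": -0.0033,
    "a2": 6e-05,
    "h1": 0.024,
    "b1": 0.1
   },
   "sigma": 0.27,
   "flow_c1": 0.092,
   "flow_sigma": 0.024
  },
  "muscle": {
   "family": "lognormal",
   "coeffs": {
    "alpha": 1.84,
    "a1": 0.003,
    "a2": -5.5e-05,
    "h1": 0.006,
    "b1": 0.0072
   },
   "sigma": 0.256,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  }
 }
}
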