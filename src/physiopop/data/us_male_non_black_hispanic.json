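{
 "country": "US",
 "gender": "male",
 "ethnicity": "Non-Black Hispanic",
 "anthropometry": {
  "height": {
   "alpha": 171.0,
   "a1": -0.03,
   "a2": 0.0,
   "sigma": 6.4
  },
  "log_body_mass": {
   "alpha": 3.86,
   "a1": 0.0226,
   "a2": -0.00024,
   "sigma": 0.18
  },
  "rho": 0.44
 },
 "cardiac_output": {
  "form": "male_logistic",
  "alpha": 2.781,
  "h1": 0.026,
  "a1": -0.031,
  "a2": -0.458,
  "a3": -0.828,
  "sigma": 0.109
 },
 "rho_adipose_muscle": -0.9,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.628,
    "h1": 0.0047
   },
   "sigma": 0.322,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.488,
    "a1": -0.0022
   },
   "sigma": 0.069,
   "flow_c1": 0.128,
   "flow_sigma": 0.036
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.094,
    "h1": 0.0018
   },
   "sigma": 0.076,
   "flow_c1": 0.043,
   "flow_sigma": 0.013
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.059,
    "h1": 0.0021
   },
   "sigma": 0.105,
   "flow_c1": 0.217,
   "flow_sigma": 0.055
  },
  "liver": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.726,
    "h1": 0.0089
   },
   "sigma": 0.546,
   "flow_c1": 0.069,
   "flow_sigma": 0.021
  },
  "pancreas": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.034,
    "h1": 0.0009
   },
   "sigma": 0.05,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.201,
    "h1": 0.004
   },
   "sigma": 0.37,
   "flow_c1": 0.032,
   "flow_sigma": 0.01
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.039,
    "h1": 0.0007
   },
   "sigma": 0.05,
   "flow_c1": 0.011,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.197,
    "h1": 0.003
   },
   "sigma": 0.09,
   "flow_c1": 0.11,
   "flow_sigma": 0.03
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.064,
    "h1": 0.0019
   },
   "sigma": 0.078,
   "flow_c1": 0.043,
   "flow_sigma": 0.013
  },
  "sexual_organs": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.046
   },
   "sigma": 0.0027,
   "flow_c1": 0.0005,
   "flow_sigma": 0.0002
  },
  "skin": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.956,
    "m1": 0.0491,
    "m2": -0.00023
   },
   "sigma": 0.166,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 2.883,
    "a1": 0.528,
    "h1": 0.0405,
    "h2": 0.0097
   },
   "sigma": 0.117,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "adipose": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -3.52,
    "a1": -0.0105,
    "a2": 0.00015,
    "h1": 0.0235,
    "b1": 0.105
   },
   "sigma": 0.331,
   "flow_c1": 0.053,
   "flow_sigma": 0.016
  },
  "muscle": {
   "family": "lognormal",
   "coeffs": {
    "alpha": 1.476,
    "a1": 0.0077,
    "a2": -0.00011,
    "h1": 0.0078,
    "b1": 0.017
   },
   "sigma": 0.233,
   "flow_c1": 0.181,
   "flow_sigma": 0.048
  }
 }
}
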