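{
 "country": "US",
 "gender": "female",
 "ethnicity": "Black",
 "anthropometry": {
  "height": {
   "alpha": 162.3,
   "a1": 0.108,
   "a2": -0.0019,
   "sigma": 6.4
  },
  "log_body_mass": {
   "alpha": 3.87,
   "a1": 0.02,
   "a2": -0.0002,
   "sigma": 0.25
  },
  "rho": 0.46
 },
 "cardiac_output": {
  "form": "female_cubic",
  "alpha": 1.903,
  "h1": 0.0246,
  "a1": 0.0088,
  "a2": -0.000839,
  "a3": 6.25e-06,
  "sigma": 0.093
 },
 "rho_adipose_muscle": -0.87,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.83,
    "h1": 0.0053
   },
   "sigma": 0.322,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.367,
    "a1": -0.002
   },
   "sigma": 0.065,
   "flow_c1": 0.132,
   "flow_sigma": 0.033
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.108,
    "h1": 0.0015
   },
   "sigma": 0.088,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.086,
    "h1": 0.0021
   },
   "sigma": 0.11,
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
    "alpha": 0.033,
    "h1": 0.0009
   },
   "sigma": 0.053,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.402,
    "h1": 0.0055
   },
   "sigma": 0.367,
   "flow_c1": 0.031,
   "flow_sigma": 0.008
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.051,
    "h1": 0.00076
   },
   "sigma": 0.023,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.158,
    "h1": 0.0038
   },
   "sigma": 0.102,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.097,
    "h1": 0.0021
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
    "alpha": 0.564,
    "m1": 0.0462,
    "m2": -0.00024
   },
   "sigma": 0.182,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 2.11,
    "a1": 0.031,
    "a2": -0.00043,
    "h1": 0.047
   },
   "sigma": 0.107,
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
    "alpha": 1.9,
    "a1": 0.005,
    "a2": -8.5e-05,
    "h1": 0.0056,
    "b1": 0.0064
   },
   "sigma": 0.256,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  }
 }
}
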