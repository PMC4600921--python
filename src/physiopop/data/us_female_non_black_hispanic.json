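{
 "country": "US",
 "gender": "female",
 "ethnicity": "Non-Black Hispanic",
 "anthropometry": {
  "height": {
   "alpha": 159.3,
   "a1": -0.066,
   "a2": 0.0,
   "sigma": 6.0
  },
  "log_body_mass": {
   "alpha": 3.79,
   "a1": 0.02,
   "a2": -0.00021,
   "sigma": 0.21
  },
  "rho": 0.29
 },
 "cardiac_output": {
  "form": "female_cubic",
  "alpha": 1.792,
  "h1": 0.0257,
  "a1": 0.0166,
  "a2": -0.001015,
  "a3": 7.65e-06,
  "sigma": 0.092
 },
 "rho_adipose_muscle": -0.87,
 "organs": {
  "lung": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -0.75,
    "h1": 0.0044
   },
   "sigma": 0.321,
   "flow_c1": 0.025,
   "flow_sigma": 0.01
  },
  "brain": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.369,
    "a1": -0.002
   },
   "sigma": 0.064,
   "flow_c1": 0.132,
   "flow_sigma": 0.033
  },
  "heart": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.097,
    "h1": 0.0014
   },
   "sigma": 0.081,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "kidneys": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.112,
    "h1": 0.0018
   },
   "sigma": 0.097,
   "flow_c1": 0.204,
   "flow_sigma": 0.046
  },
  "liver": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.502,
    "h1": 0.0088
   },
   "sigma": 0.471,
   "flow_c1": 0.071,
   "flow_sigma": 0.019
  },
  "pancreas": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.054,
    "h1": 0.0007
   },
   "sigma": 0.048,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "spleen": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -2.349,
    "h1": 0.0049
   },
   "sigma": 0.366,
   "flow_c1": 0.031,
   "flow_sigma": 0.008
  },
  "stomach": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.047,
    "h1": 0.0007
   },
   "sigma": 0.021,
   "flow_c1": 0.01,
   "flow_sigma": 0.003
  },
  "small_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.153,
    "h1": 0.0035
   },
   "sigma": 0.092,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  },
  "large_intestine": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.117,
    "h1": 0.0018
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
   "sigma": 0.0008,
   "flow_c1": 0.0002,
   "flow_sigma": 6e-05
  },
  "skin": {
   "family": "normal",
   "coeffs": {
    "alpha": 0.545,
    "m1": 0.0477,
    "m2": -0.00027
   },
   "sigma": 0.174,
   "flow_c1": 0.051,
   "flow_sigma": 0.0139
  },
  "bone": {
   "family": "normal",
   "coeffs": {
    "alpha": 1.64,
    "a1": 0.04,
    "a2": -0.00042,
    "h1": 0.043
   },
   "sigma": 0.098,
   "flow_c1": 0.051,
   "flow_sigma": 0.014
  },
  "adipose": {
   "family": "lognormal",
   "coeffs": {
    "alpha": -3.161,
    "a1": -0.004,
    "a2": 7e-05,
    "h1": 0.0235,
    "b1": 0.1
   },
   "sigma": 0.258,
   "flow_c1": 0.092,
   "flow_sigma": 0.024
  },
  "muscle": {
   "family": "lognormal",
   "coeffs": {
    "alpha": 1.7,
    "a1": 0.0053,
    "a2": -8.7e-05,
    "h1": 0.0063,
    "b1": 0.0072
   },
   "sigma": 0.256,
   "flow_c1": 0.122,
   "flow_sigma": 0.031
  }
 }
}
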