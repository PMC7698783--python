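[
  {
    "name": "Sandri",
    "structural_order": 2,
    "cl_typical_L_h": 2.5,
    "cl_sd_L_h": 1.25,
    "covariate": "body_weight",
    "equation_type": "proportional",
    "equation_params": {"reference": 70.0},
    "reference": "Sandri 2013, intensive-care adults, two-compartment, CL scaled on total body weight. Dispersion and equation form are synthetic placeholders."
  },
  {
    "name": "Manchandani",
    "structural_order": 1,
    "cl_typical_L_h": 2.4,
    "cl_sd_L_h": 1.2,
    "covariate": "none",
    "equation_type": "constant",
    "equation_params": {},
    "reference": "Manchandani 2017, one-compartment, no clearance covariate. Typical CL from the published covariate-free set {2.4, 2.5, 2.6} L/h (assignment within the set arbitrary); dispersion is a synthetic placeholder."
  },
  {
    "name": "Kubin",
    "structural_order": 1,
    "cl_typical_L_h": 2.5,
    "cl_sd_L_h": 1.25,
    "covariate": "none",
    "equation_type": "constant",
    "equation_params": {},
    "reference": "Kubin 2018, one-compartment, no clearance covariate. Typical CL from the published covariate-free set {2.4, 2.5, 2.6} L/h (assignment within the set arbitrary); dispersion is a synthetic placeholder."
  },
  {
    "name": "Avedissian",
    "structural_order": 2,
    "cl_typical_L_h": 2.5,
    "cl_sd_L_h": 2.0,
    "covariate": "creatinine_clearance",
    "equation_type": "saturating",
    "equation_params": {"cl_max": 4.0, "x50": 50.0},
    "reference": "Avedissian 2018, cystic-fibrosis patients, two-compartment, CL linked to creatinine clearance with dispersion on the maximum-clearance parameter. Equation form and all values are synthetic placeholders."
  },
  {
    "name": "Miglis",
    "structural_order": 2,
    "cl_typical_L_h": 2.6,
    "cl_sd_L_h": 1.3,
    "covariate": "none",
    "equation_type": "constant",
    "equation_params": {},
    "reference": "Miglis 2018, acutely ill adults, two-compartment, no clearance covariate. Typical CL from the published covariate-free set {2.4, 2.5, 2.6} L/h (assignment within the set arbitrary); dispersion is a synthetic placeholder."
  }
]
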