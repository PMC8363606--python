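{
  "version": "1.0",
  "units": {"coefficients": "MPa", "yield_stress": "MPa", "density": "g/cm3", "alloy_modulus": "GPa", "alloy_strengths": "MPa", "elongation": "percent"},
  "hyperelastic": {
    "silicone": {"c": [0.154], "yield_stress": null, "density": 2.32},
    "normal_wall": {"c": [6.52e-3, 4.89e-2, 9.26e-3, 0.76, -0.43, 8.69e-2], "yield_stress": null, "density": null},
    "very_soft": {"c": [0.045, 0.17, -0.13, 0.11], "yield_stress": 0.12, "density": null},
    "soft": {"c": [0.01, 0.49, 4.13], "yield_stress": 0.71, "density": null},
    "neutral": {"c": [0.06, 4.28, -21.36, 69.36], "yield_stress": 1.37, "density": null},
    "stiff": {"c": [0.11, 9.06], "yield_stress": 1.81, "density": null},
    "very_stiff": {"c": [0.21, 64.86, -3.5e3, 1.999e5], "yield_stress": 627.0, "density": null}
  },
  "plaque_class_scores": {"very_soft": -2, "soft": -1, "neutral": 0, "stiff": 1, "very_stiff": 2},
  "alloys": {
    "MP35N": {"elastic_modulus_gpa": 233.0, "yield_strength_mpa": 414.0, "tensile_strength_mpa": 930.0, "elongation_pct": 45.0, "density": 8.40, "hardening": "isotropic"},
    "PtIr": {"elastic_modulus_gpa": 224.0, "yield_strength_mpa": 285.0, "tensile_strength_mpa": null, "elongation_pct": null, "density": 21.6, "hardening": "perfect"},
    "PtCr": {"elastic_modulus_gpa": 203.0, "yield_strength_mpa": 480.0, "tensile_strength_mpa": 834.0, "elongation_pct": 45.0, "density": 9.90, "hardening": "isotropic"}
  },
  "balloon_moduli_mpa": {"compliant": 300.0, "semi_compliant": 900.0, "non_compliant": 1500.0}
}
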