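{
  "specimens": [
    {"id": "R", "sex": "F", "age": 63, "location": "MCA", "thickness_mm": 0.05, "width_mm": 3.0, "area_mm2": 0.15, "status": "unruptured", "ultimate_strain": 1.27639, "ultimate_stress_MPa": 1.09936},
    {"id": "K2", "sex": "F", "age": 55, "location": "MCA", "thickness_mm": 0.05, "width_mm": 4.0, "area_mm2": 0.2, "status": "unruptured", "ultimate_strain": 1.5729, "ultimate_stress_MPa": 1.1314},
    {"id": "V", "sex": "F", "age": 63, "location": "AComA", "thickness_mm": 0.15, "width_mm": 3.75, "area_mm2": 0.56, "status": "ruptured", "ultimate_strain": 1.06323, "ultimate_stress_MPa": 1.05493},
    {"id": "Z", "sex": "F", "age": 48, "location": "MCA", "thickness_mm": 0.2, "width_mm": 3.3, "area_mm2": 0.66, "status": "ruptured", "ultimate_strain": 0.744889, "ultimate_stress_MPa": 1.00979},
    {"id": "U", "sex": "F", "age": 43, "location": "PICA(L)", "thickness_mm": 0.25, "width_mm": 3.56, "area_mm2": 0.91, "status": "ruptured", "ultimate_strain": 2.85794, "ultimate_stress_MPa": 1.00356},
    {"id": "K1", "sex": "F", "age": 63, "location": "MCA", "thickness_mm": 0.3, "width_mm": 5.0, "area_mm2": 1.5, "status": "unruptured", "ultimate_strain": 4.6129, "ultimate_stress_MPa": 1.75217},
    {"id": "M", "sex": "M", "age": 38, "location": "AComA", "thickness_mm": 0.7, "width_mm": 4.0, "area_mm2": 2.8, "status": "ruptured", "ultimate_strain": 1.30277, "ultimate_stress_MPa": 0.382825},
    {"id": "Ul", "sex": "M", "age": 44, "location": "AComA", "thickness_mm": 0.6, "width_mm": 3.85, "area_mm2": 2.31, "status": "ruptured", "ultimate_strain": 3.96535, "ultimate_stress_MPa": 0.33317},
    {"id": "A1", "sex": "M", "age": 60, "location": "TempA", "thickness_mm": 0.4, "width_mm": 3.0, "area_mm2": 1.2, "status": "not_applicable", "ultimate_strain": 1.41559, "ultimate_stress_MPa": 2.4794},
    {"id": "A2", "sex": "M", "age": 60, "location": "TempA", "thickness_mm": 0.2, "width_mm": 1.0, "area_mm2": 0.2, "status": "not_applicable", "ultimate_strain": 1.37917, "ultimate_stress_MPa": 0.141357}
  ],
  "coefficients_MPa": {
    "K2": {"MR3": [0.464950, -0.464947, 9.17e-7], "YEOH": [0.021704, 0.031802], "NEO_HOOKEAN": [0.0615], "MR5": [0.46492, -0.464896, 2.552e-6, 2.334e-7, -1.598e-6]},
    "R":  {"MR3": [0.313226, -0.313226, 1.863e-6], "YEOH": [2.678e-7, 0.032626], "NEO_HOOKEAN": [0.12038], "MR5": [0.12038, -0.12038, -0.040056, 0.040069, -0.000011]},
    "V":  {"MR3": [0.479274, -0.43089, 0.159734], "YEOH": [4.77e-7, 0.0379351], "NEO_HOOKEAN": [0.100453], "MR5": [0.618282, -0.51001, -0.205882, 0.205964, -0.000018]},
    "Z":  {"MR3": [0.204286, 0.070981, 0.068063], "YEOH": [1.12581, 0.172556], "NEO_HOOKEAN": [0.123172], "MR5": [0.2717, 0.0274076, -0.089769, 0.090082, -0.000059]},
    "U":  {"MR3": [0.085436, -0.07656, 0.028474], "YEOH": [7.85e-7, 0.007087], "NEO_HOOKEAN": [0.116763], "MR5": [0.075683, -0.034887, -0.022802, 0.024003, -9.154e-6]},
    "K1": {"MR3": [0.029655, 0.021101, 0.009883], "YEOH": [1.07937e-6, 0.007273], "NEO_HOOKEAN": [0.058434], "MR5": [0.056429, 0.005771, 0.008226, 0.000468, -0.00861]},
    "M":  {"MR3": [0.046188, -0.046162, 0.01539], "YEOH": [1.25635, 0.095805], "NEO_HOOKEAN": [0.045382], "MR5": [0.052108, -0.05119, -0.017356, 0.01736, -1.652e-6]},
    "Ul": {"MR3": [0.0263132, -0.00878, 0.0002], "YEOH": [0.017, 0.000229], "NEO_HOOKEAN": [0.0099307], "MR5": [0.021751, -0.004683, 0.0005, 0.000782, -0.000699]}
  },
  "max_valid_stretch": {
    "K1": {"MR3": 5.10488, "MR5": 5.10488, "YEOH": 5.10488, "NEO_HOOKEAN": 3.70363},
    "K2": {"MR3": 1.81725, "MR5": 1.81725, "YEOH": 1.81725, "NEO_HOOKEAN": 1.81725},
    "R":  {"MR3": 2.00078, "MR5": 2.00078, "YEOH": 2.00078, "NEO_HOOKEAN": 2.00078},
    "V":  {"MR3": 1.60622, "MR5": 2.003, "YEOH": 1.32909, "NEO_HOOKEAN": 1.32909},
    "Z":  {"MR3": 2.00094, "MR5": 2.00094, "YEOH": 2.00094, "NEO_HOOKEAN": 2.00094},
    "U":  {"MR3": 2.54697, "MR5": 2.80683, "YEOH": 2.54696, "NEO_HOOKEAN": 1.5161},
    "M":  {"MR3": 2.20088, "MR5": 2.20088, "YEOH": 1.90279, "NEO_HOOKEAN": 1.90279},
    "Ul": {"MR3": 2.53922, "MR5": 2.53922, "YEOH": 2.53922, "NEO_HOOKEAN": 2.53922}
  }
}
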