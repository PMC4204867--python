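{
  "comment": "Synthetic linear-component articulatory model (own construction, Maeda-style). Each component is a Gaussian area-deviation profile over normalized tract position s in [0,1] (0 = glottis, 1 = lips); area(s) = clip(neutral(s) + sum_j amp_j * G(s; c_j, w_j) * p_j, 0, inf). Length modifiers scale section lengths linearly with the parameter.",
  "n_sections": 20,
  "total_length_cm": 17.5,
  "neutral_areas_cm2": [2.6, 2.8, 3.0, 3.2, 3.2, 3.0, 2.8, 2.6, 2.4, 2.2,
                        2.0, 1.9, 1.8, 1.8, 1.7, 1.7, 1.6, 1.5, 1.4, 1.3],
  "area_components": [
    {"param": "p1_jaw",          "center": 0.78, "width": 0.22, "amplitude": 1.2},
    {"param": "p1_jaw",          "center": 0.35, "width": 0.15, "amplitude": -0.3},
    {"param": "p2_dorsum_pos",   "center": 0.65, "width": 0.12, "amplitude": -1.5},
    {"param": "p2_dorsum_pos",   "center": 0.30, "width": 0.12, "amplitude": 1.5},
    {"param": "p3_dorsum_shape", "center": 0.55, "width": 0.08, "amplitude": -2.4},
    {"param": "p4_apex",         "center": 0.82, "width": 0.06, "amplitude": -2.2},
    {"param": "p5_lip_aperture", "center": 1.00, "width": 0.05, "amplitude": 2.0}
  ],
  "length_modifiers": [
    {"param": "p6_lip_protrusion", "region": [0.9, 1.0], "gain": 0.30},
    {"param": "p7_larynx_height",  "region": [0.0, 0.2], "gain": -0.20}
  ]
}
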