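measurement,M,F
coxal_bone_height,0.49,0.37
coxal_bone_breadth,0.88,2.08
ala_breadth_superior_iliac_spines,0.68,0.76
ala_breadth_inferior_iliac_spines,-0.85,-0.13
ala_height,-1.26,-0.45
pubic_length,0.83,0.65
vertical_acetabular_diameter,0.72,0.60
transversal_acetabular_diameter,0.30,0.15
vertical_diameter_obturator_foramen,0.28,-0.34
transversal_diameter_obturator_foramen,0.42,0.27
greater_sciatic_notch_breadth,0.24,0.49
ischiopubic_ramus_length,-3.47,-2.85
ischial_tuberosity_length,1.23,1.01
intersciatic_distance,0.80,0.43
anterior_interspinal_distance,0.43,-0.66
posterior_interspinal_distance,1.72,1.50
spino_sciatic_distance,0.65,0.42
anterior_spino_auricular_distance,-0.36,-0.31
posterior_spino_auricular_distance,1.21,0.30
post_acetabular_ischium_distance,2.00,0.93
gluteo_sciatic_distance,-1.11,-1.21
pectineal_line_length,2.63,0.61
lunate_ramus_distance,0.66,0.17
greater_sciatic_acetabular_distance,-0.65,-0.56
lesser_sciatic_acetabular_distance,-1.14,-0.61
pubic_symphysis_height,0.15,-0.01
pubic_symphysis_width,0.32,0.28
greater_sciatic_notch_height,0.75,0.85
anterior_interspinal_height,0.41,0.03
posterior_interspinal_height,-0.81,-0.46
greater_sciatic_notch_angle,-1.61,-1.40
ischiopubic_angle,-0.20,-0.64
ischial_angle,-1.84,-1.63
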