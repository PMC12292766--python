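measurement,M_right,M_left,F_right,F_left
coxal_bone_height,3.35,2.31,3.31,4.41
coxal_bone_breadth,4.44,5.38,5.27,5.54
ala_breadth_superior_iliac_spines,6.04,5.67,4.49,5.38
ala_breadth_inferior_iliac_spines,2.15,3.19,1.54,2.61
ala_height,3.01,2.86,1.14,1.80
pubic_length,3.34,4.12,1.11,0.89
vertical_acetabular_diameter,1.42,0.88,1.04,0.97
transversal_acetabular_diameter,2.33,1.88,1.05,1.34
vertical_diameter_obturator_foramen,2.04,2.42,1.69,1.72
transversal_diameter_obturator_foramen,0.08,-0.21,1.09,1.22
greater_sciatic_notch_breadth,-0.04,-0.89,2.65,2.40
ischiopubic_ramus_length,-0.36,0.18,-0.30,-0.83
ischial_tuberosity_length,2.90,2.66,3.00,3.74
intersciatic_distance,1.62,0.22,1.60,1.98
anterior_interspinal_distance,0.41,-0.11,0.70,1.20
posterior_interspinal_distance,3.71,3.56,4.52,3.31
spino_sciatic_distance,3.18,2.62,1.53,1.57
anterior_spino_auricular_distance,0.40,0.58,-0.43,-0.12
posterior_spino_auricular_distance,2.23,2.42,0.62,1.53
post_acetabular_ischium_distance,3.25,2.73,1.07,3.49
gluteo_sciatic_distance,-0.42,1.15,1.46,1.28
pectineal_line_length,-1.09,0.80,-1.28,-0.14
lunate_ramus_distance,0.89,1.24,2.05,2.44
greater_sciatic_acetabular_distance,2.89,2.14,2.76,3.03
lesser_sciatic_acetabular_distance,1.30,1.07,0.94,0.87
pubic_symphysis_height,3.74,3.42,3.34,3.33
pubic_symphysis_width,1.87,2.00,1.67,1.93
greater_sciatic_notch_height,1.00,0.25,0.24,0.10
anterior_interspinal_height,0.99,0.70,0.75,0.64
posterior_interspinal_height,-0.27,0.28,0.42,0.40
greater_sciatic_notch_angle,-1.91,-0.89,1.61,1.96
ischiopubic_angle,0.98,2.10,1.19,2.06
ischial_angle,-0.61,-0.02,0.70,1.89
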