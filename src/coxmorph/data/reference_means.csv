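measurement,sex,side,mean,sd,min,max
coxal_bone_height,M,right,210.55,9.93,190.32,236.83
coxal_bone_height,M,left,210.06,9.61,191.13,236.08
coxal_bone_height,F,right,190.49,9.16,170.13,224.80
coxal_bone_height,F,left,190.11,9.31,167.82,222.64
coxal_bone_breadth,M,right,178.90,12.55,144.64,213.02
coxal_bone_breadth,M,left,178.02,12.22,144.57,211.65
coxal_bone_breadth,F,right,177.13,10.99,147.43,205.69
coxal_bone_breadth,F,left,175.04,10.97,149.95,198.92
ala_breadth_superior_iliac_spines,M,right,165.80,8.71,147.96,183.26
ala_breadth_superior_iliac_spines,M,left,165.12,8.87,146.12,184.27
ala_breadth_superior_iliac_spines,F,right,159.95,8.02,140.89,180.78
ala_breadth_superior_iliac_spines,F,left,159.18,7.82,137.13,177.29
ala_breadth_inferior_iliac_spines,M,right,124.57,8.58,106.31,143.26
ala_breadth_inferior_iliac_spines,M,left,125.42,7.54,108.36,145.23
ala_breadth_inferior_iliac_spines,F,right,120.50,8.27,102.39,141.65
ala_breadth_inferior_iliac_spines,F,left,120.63,8.28,99.40,140.04
ala_height,M,right,105.07,5.79,92.05,123.26
ala_height,M,left,106.33,6.05,92.17,125.42
ala_height,F,right,98.41,4.69,86.90,114.61
ala_height,F,left,98.85,4.59,89.37,110.36
pubic_length,M,right,84.04,5.84,64.98,97.24
pubic_length,M,left,83.21,5.98,68.03,99.71
pubic_length,F,right,84.00,5.31,71.81,99.54
pubic_length,F,left,83.36,5.42,71.08,99.91
vertical_acetabular_diameter,M,right,57.88,3.59,50.74,69.83
vertical_acetabular_diameter,M,left,57.17,3.53,48.45,66.98
vertical_acetabular_diameter,F,right,52.10,3.03,43.22,59.68
vertical_acetabular_diameter,F,left,51.50,2.79,44.73,59.59
transversal_acetabular_diameter,M,right,56.55,3.51,48.10,67.07
transversal_acetabular_diameter,M,left,56.25,3.64,45.16,66.72
transversal_acetabular_diameter,F,right,50.34,3.09,43.50,57.77
transversal_acetabular_diameter,F,left,50.19,3.22,40.39,60.98
vertical_diameter_obturator_foramen,M,right,57.87,4.66,48.38,74.63
vertical_diameter_obturator_foramen,M,left,57.60,4.55,48.61,69.72
vertical_diameter_obturator_foramen,F,right,52.19,3.68,43.14,61.36
vertical_diameter_obturator_foramen,F,left,52.53,3.80,42.97,65.05
transversal_diameter_obturator_foramen,M,right,35.94,3.51,24.40,48.44
transversal_diameter_obturator_foramen,M,left,35.51,3.50,26.85,49.21
transversal_diameter_obturator_foramen,F,right,35.82,2.66,30.60,42.82
transversal_diameter_obturator_foramen,F,left,35.55,2.93,29.92,44.75
greater_sciatic_notch_breadth,M,right,51.53,5.34,39.65,65.80
greater_sciatic_notch_breadth,M,left,51.28,5.38,40.21,64.99
greater_sciatic_notch_breadth,F,right,54.72,6.25,40.55,72.45
greater_sciatic_notch_breadth,F,left,54.23,5.95,41.98,68.30
ischiopubic_ramus_length,M,right,58.73,5.41,44.52,74.99
ischiopubic_ramus_length,M,left,62.21,5.91,44.21,76.69
ischiopubic_ramus_length,F,right,61.14,5.77,49.63,81.32
ischiopubic_ramus_length,F,left,64.00,5.54,51.17,82.14
ischial_tuberosity_length,M,right,68.39,4.98,57.11,86.69
ischial_tuberosity_length,M,left,67.15,4.94,50.56,81.80
ischial_tuberosity_length,F,right,62.50,4.82,52.52,75.62
ischial_tuberosity_length,F,left,61.49,4.61,50.41,73.23
intersciatic_distance,M,right,61.30,5.60,48.34,76.84
intersciatic_distance,M,left,60.50,5.17,46.96,71.90
intersciatic_distance,F,right,55.48,4.51,41.57,68.68
intersciatic_distance,F,left,55.04,4.40,43.70,69.34
anterior_interspinal_distance,M,right,43.52,5.92,23.21,59.66
anterior_interspinal_distance,M,left,43.09,5.89,23.93,57.88
anterior_interspinal_distance,F,right,42.21,5.05,27.56,54.29
anterior_interspinal_distance,F,left,42.87,5.48,25.87,55.80
posterior_interspinal_distance,M,right,39.52,9.34,19.14,63.48
posterior_interspinal_distance,M,left,37.79,8.46,17.70,62.51
posterior_interspinal_distance,F,right,33.45,7.93,16.62,53.52
posterior_interspinal_distance,F,left,31.94,7.51,15.17,50.85
spino_sciatic_distance,M,right,82.41,4.94,70.51,98.35
spino_sciatic_distance,M,left,81.76,4.97,69.92,96.44
spino_sciatic_distance,F,right,74.14,4.64,63.76,84.56
spino_sciatic_distance,F,left,73.71,4.69,63.70,83.83
anterior_spino_auricular_distance,M,right,81.34,5.43,67.13,93.98
anterior_spino_auricular_distance,M,left,81.71,6.50,67.87,107.48
anterior_spino_auricular_distance,F,right,79.65,5.82,64.67,92.30
anterior_spino_auricular_distance,F,left,79.96,5.59,64.82,96.52
posterior_spino_auricular_distance,M,right,55.35,6.14,41.61,69.94
posterior_spino_auricular_distance,M,left,54.14,5.89,37.03,69.41
posterior_spino_auricular_distance,F,right,49.08,6.15,33.56,64.13
posterior_spino_auricular_distance,F,left,48.78,6.32,31.55,65.09
post_acetabular_ischium_distance,M,right,98.24,6.73,85.12,120.92
post_acetabular_ischium_distance,M,left,96.24,6.42,81.24,114.91
post_acetabular_ischium_distance,F,right,86.32,5.31,74.73,100.45
post_acetabular_ischium_distance,F,left,85.39,5.95,69.92,101.88
gluteo_sciatic_distance,M,right,94.53,5.44,80.90,109.31
gluteo_sciatic_distance,M,left,95.63,5.59,81.52,115.81
gluteo_sciatic_distance,F,right,91.97,4.62,83.47,107.13
gluteo_sciatic_distance,F,left,93.18,4.79,79.46,105.08
pectineal_line_length,M,right,33.31,6.11,15.69,50.92
pectineal_line_length,M,left,30.68,6.39,14.80,44.64
pectineal_line_length,F,right,31.02,5.67,16.18,53.37
pectineal_line_length,F,left,30.41,5.94,16.14,50.13
lunate_ramus_distance,M,right,61.81,4.38,49.65,72.29
lunate_ramus_distance,M,left,61.15,4.72,49.30,76.08
lunate_ramus_distance,F,right,56.19,3.69,46.63,67.41
lunate_ramus_distance,F,left,56.02,3.70,45.80,64.80
greater_sciatic_acetabular_distance,M,right,49.64,4.16,40.39,64.07
greater_sciatic_acetabular_distance,M,left,50.29,4.64,40.12,67.70
greater_sciatic_acetabular_distance,F,right,46.17,4.07,36.56,56.94
greater_sciatic_acetabular_distance,F,left,46.73,4.18,37.92,57.54
lesser_sciatic_acetabular_distance,M,right,41.97,4.39,21.56,55.17
lesser_sciatic_acetabular_distance,M,left,43.11,3.58,34.06,56.23
lesser_sciatic_acetabular_distance,F,right,37.96,3.14,30.93,49.77
lesser_sciatic_acetabular_distance,F,left,38.58,2.85,32.40,50.99
pubic_symphysis_height,M,right,39.94,4.92,26.83,52.89
pubic_symphysis_height,M,left,39.78,4.60,26.68,52.07
pubic_symphysis_height,F,right,35.76,3.69,26.86,44.33
pubic_symphysis_height,F,left,35.77,3.88,26.63,44.61
pubic_symphysis_width,M,right,18.40,2.46,12.49,27.40
pubic_symphysis_width,M,left,18.08,2.47,11.56,26.25
pubic_symphysis_width,F,right,15.07,2.19,10.15,21.65
pubic_symphysis_width,F,left,14.79,2.34,8.59,21.72
greater_sciatic_notch_height,M,right,30.10,3.71,22.07,38.34
greater_sciatic_notch_height,M,left,29.36,3.51,19.57,38.25
greater_sciatic_notch_height,F,right,29.10,3.45,19.42,38.00
greater_sciatic_notch_height,F,left,28.25,3.09,21.48,35.70
anterior_interspinal_height,M,right,8.66,2.10,3.95,17.45
anterior_interspinal_height,M,left,8.26,1.98,3.63,16.42
anterior_interspinal_height,F,right,7.55,1.29,4.70,12.07
anterior_interspinal_height,F,left,7.52,1.47,4.62,11.70
posterior_interspinal_height,M,right,3.71,1.80,0.46,9.21
posterior_interspinal_height,M,left,4.51,2.63,0.81,16.32
posterior_interspinal_height,F,right,4.71,2.85,0.53,15.99
posterior_interspinal_height,F,left,5.17,2.62,0.35,14.63
greater_sciatic_notch_angle,M,right,68.61,6.55,50.29,85.93
greater_sciatic_notch_angle,M,left,70.22,6.77,49.76,85.19
greater_sciatic_notch_angle,F,right,80.51,7.97,59.59,101.83
greater_sciatic_notch_angle,F,left,81.91,7.60,60.53,100.36
ischiopubic_angle,M,right,142.65,4.46,129.78,154.57
ischiopubic_angle,M,left,142.85,4.62,130.63,156.49
ischiopubic_angle,F,right,132.64,4.12,117.74,143.30
ischiopubic_angle,F,left,133.28,4.09,123.01,148.16
ischial_angle,M,right,99.09,4.23,85.80,110.86
ischial_angle,M,left,100.92,4.91,87.91,114.59
ischial_angle,F,right,97.11,4.33,87.29,109.15
ischial_angle,F,left,98.74,4.33,87.39,112.57
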