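# Synthetic 2-D sagittal attachment coordinates for the four hip-spanning
# muscles (stand-in for unpublished cadaver-based line-of-action data; see
# docs/methods.md).  Both frames share the hip joint centre as origin.
# Pelvis frame: fixed to the HAT segment; +x anterior, +y cranial when the
#   trunk is vertical.  Femur frame: fixed to the thigh; +x anterior, +y
#   proximal (knee -> hip) when standing, so distal points carry negative y.
# Pelvic points are effective via points: iliopsoas wraps the iliopectineal
#   eminence, rectus femoris wraps the anterior hip capsule in flexion, and
#   gluteus maximus and the hamstrings share the ischial-tuberosity via
#   point.  For the biarticular muscles the femur-frame entry is the distal
#   path point near the knee.
# Calibration: at the mean seat-off posture (hip 120 deg, knee 109 deg,
#   ankle 35 deg) the perpendicular hip moment arms implied by these lines
#   are iliopsoas 0.022 m (flexion), gluteus maximus 0.028 m (extension) and
#   rectus femoris 0.016 m (flexion), matching the constant moment arms used
#   by the optimization; the hamstrings line (ischial tuberosity to distal
#   posterior thigh) is kept anatomical and implies a larger hip arm than the
#   0.011 m used for the moment constraints.
muscle,pelvis_x_m,pelvis_y_m,femur_x_m,femur_y_m
iliopsoas,0.034,0.018,-0.010,-0.050
gluteus_maximus,-0.060,-0.085,-0.015,-0.080
rectus_femoris,0.030,0.040,0.045,-0.400
hamstrings,-0.060,-0.085,-0.030,-0.440
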