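# Eight lower-limb muscles: physiological cross-sectional areas (Handsfield
# et al. means and SDs) and constant sagittal moment arm magnitudes evaluated
# at the mean seat-off posture (hip 120 deg flexion, knee 109 deg flexion,
# ankle 35 deg dorsiflexion).
# sign_*: anatomical action at each joint in the extension/plantarflexion-
#   positive moment convention (+1 extensor/plantarflexor, -1 flexor/
#   dorsiflexor, 0 = muscle does not span the joint).  A zero sign always
#   pairs with a zero arm.
# Fiber-length-ratio model (synthetic stand-in for unpublished model exports;
# see docs/methods.md): Lr(theta) = 1 + sum_j [c1_j*d_j + c2_j*d_j^2] with
# d_j = joint angle - reference angle (radians, flexion/dorsiflexion
# positive).  c1_j = sign_j*arm_j/lref so that d(Lr*lref)/d(theta_j) equals
# the signed moment arm (extensors lengthen under flexion); c2_j = -0.06*c1_j
# adds mild saturation.  lref_m is the normalising (optimal) fiber length;
# vmax is the maximum shortening velocity in lref/s.
name,pcsa_mean_cm2,pcsa_sd_cm2,arm_hip_m,arm_knee_m,arm_ankle_m,sign_hip,sign_knee,sign_ankle,lref_m,vmax_lref_per_s,ref_hip_deg,ref_knee_deg,ref_ankle_deg
iliopsoas,28.9,6.9,0.022,0,0,-1,0,0,0.12,10,60,55,17.5
gluteus_maximus,46.8,8.7,0.027,0,0,1,0,0,0.16,10,60,55,17.5
vastus,157.4,31.5,0,0.044,0,0,1,0,0.13,10,60,55,17.5
rectus_femoris,34.8,7.4,0.014,0.044,0,-1,1,0,0.13,10,60,55,17.5
hamstrings,73.0,16.3,0.011,0.028,0,1,-1,0,0.12,10,60,55,17.5
tibialis_anterior,15.8,2.9,0,0,0.043,0,0,-1,0.09,10,60,55,17.5
soleus,124.1,24.9,0,0,0.026,0,0,1,0.06,10,60,55,17.5
gastrocnemius,73.1,16.0,0,0.022,0.031,0,-1,1,0.09,10,60,55,17.5
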