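# Four-segment sagittal anthropometric table (Winter's classic fractions).
# length_fraction: segment length / body height
#   hat   : greater trochanter -> glenohumeral joint
#   thigh : hip -> knee joint centre
#   shank : knee -> ankle joint centre
#   foot  : heel -> toe (support-base length)
# mass_fraction: segment mass / body mass (hat includes head, arms and trunk;
#   bilateral leg segments are counted twice, so hat + 2*(thigh+shank+foot) = 1)
# com_ratio: centre-of-mass position / segment length, measured from the
#   proximal end (hip for hat and thigh, knee for shank, heel for foot)
# gyration_ratio: radius of gyration about the segment COM / segment length
segment,length_fraction,mass_fraction,com_ratio,gyration_ratio
hat,0.288,0.678,0.626,0.496
thigh,0.245,0.100,0.433,0.323
shank,0.246,0.0465,0.433,0.302
foot,0.152,0.0145,0.500,0.475
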