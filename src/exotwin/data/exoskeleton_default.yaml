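# Default exoskeleton geometry: as-constructed linkage dimensions.
# Angles in degrees at this boundary; the library works in radians.
r_fixed_m: 0.19
r_moving_m: 0.1
len_proximal_m: 0.34
len_distal_m: 0.656
joint_limit_low_deg: -90.0
joint_limit_high_deg: 45.0
offset_a1_m: 0.1
pivot_extension_a4_m: 0.25
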