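# Experiment-2 workspace with tuned set-up constants: the release circle
# passes through the point diametrically opposite the target (so the
# solution manifold is a near-vertical line at alpha = -82 deg) and the
# oscillator frequency puts the post-grazing boundary near v = 142 deg/s.
post_center:
- 0.0
- 0.0
post_radius: 25.0
target_center:
- 5.0
- 105.8
target_radius: 1.5
ball_radius: 2.5
penalty_error: 60.0
pivot:
- 0.0
- -120.0
arm_length: 15.054567413247053
angle_zero_direction:
- -0.9802787204596011
- -0.19761991350591995
rotation_sign: 1
omega: 1.256
damping_tau: .inf
horizon: null
angle_range:
- -165.0
- 0.0
velocity_range:
- 0.0
- 1000.0
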