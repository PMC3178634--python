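# Experiment-1 workspace with set-up constants tuned so the printed
# execution-space landmarks (manifold through (-44,161) and (-29,122))
# are reproduced; see calibrate_geometry.
post_center:
- 10.5
- -60.0
post_radius: 33.0
target_center:
- 35.0
- 125.0
target_radius: 1.5
ball_radius: 2.5
penalty_error: 60.0
pivot:
- 0.0
- -200.0
arm_length: 45.0
angle_zero_direction:
- 0.7624752604800336
- -0.6470173700573308
rotation_sign: 1
omega: 0.901029
damping_tau: .inf
horizon: null
angle_range:
- -165.0
- 0.0
velocity_range:
- 0.0
- 600.0
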