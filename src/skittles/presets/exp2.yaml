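# Experiment-2 workspace: post at the origin, target almost straight above,
# giving a solution manifold nearly parallel to the velocity axis.
post_center: [0.0, 0.0]
post_radius: 25.0
target_center: [5.0, 105.8]
target_radius: 1.5
ball_radius: 2.5
penalty_error: 60.0
pivot: [0.0, -120.0]
arm_length: 40.0
angle_zero_direction: [1.0, 0.0]
rotation_sign: 1
omega: 6.283185307179586
damping_tau: .inf
horizon: null
angle_range: [-165.0, 0.0]
velocity_range: [0.0, 1000.0]
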