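# Experiment-1 workspace: off-center post, target beyond it.
# Lengths cm, angles deg, angular velocities deg/s, time s.
post_center: [10.5, -60.0]
post_radius: 33.0
target_center: [35.0, 125.0]
target_radius: 1.5
ball_radius: 2.5
penalty_error: 60.0
pivot: [0.0, -120.0]
arm_length: 40.0
angle_zero_direction: [1.0, 0.0]
rotation_sign: 1
omega: 6.283185307179586
damping_tau: .inf
horizon: null          # one full oscillator period
angle_range: [-165.0, 0.0]
velocity_range: [0.0, 600.0]
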