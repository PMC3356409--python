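# Coulomb-directed pulse: 100 particles of -2 e released on a cell-membrane
# cap travel to the nuclear membrane under the nuclear field.
seed = 1

[scenario]
mode = "pulse"
count = 100
t_end_s = 0.2
ligand_direction = [0.0, 0.0, 1.0]
cap_half_angle_deg = 15.0
fixed_charge_e = -2.0

[output]
summary_json = "scratch/pulse_summary.json"
trajectory_csv = "scratch/pulse_trajectory.csv"
stride = 10
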