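# Continuous-EGF steady state of the RAF-MEK-ERK cascade with KSR1
# scaffolding, linear radial pH 7.2 (NM) -> 7.4 (CM).
seed = 2024

[ph]
profile = "linear_radial"
ph_nm = 7.2
ph_cm = 7.4

[[species]]
name = "RAF"
iep = 9.2
role = "RAF"
count = 100

[[species]]
name = "MEK"
iep = 6.1
role = "MEK"
count = 500

[[species]]
name = "ERK"
iep = 6.2
role = "ERK"
count = 500

[[species]]
name = "KSR1"
iep = 9.1
role = "KSR1"
count = 200
n_phospho_sites = 0

[scenario]
mode = "steady"
t_end_s = 60.0
ksr1_enabled = true
reaction_stride = 5

[output]
summary_json = "scratch/mapk_summary.json"
profile_csv = "scratch/mapk_radial_profile.csv"
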