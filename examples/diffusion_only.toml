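# Control experiment: the same release geometry with charges switched off;
# transport is pure Brownian motion.  Most particles do not reach the
# nucleus within the 10 s budget.
seed = 1

[scenario]
mode = "diffusion_only"
count = 100
t_end_s = 10.0

[output]
summary_json = "scratch/diffusion_summary.json"
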