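# Reference pipeline configuration with the full-scale defaults.
# Desk-scale runs typically override n_accept, screen_reps and burnin_scale.
panel_path: panel.tsv
out_dir: results
schedule_variant: modified     # burn-in N=14,448 for 10N generations;
                               # N_e=613,285 last 124 generations;
                               # N_e=5,000,000 last 50 (modified)
log10_s_bounds: [-6.0, 0.0]    # prior: log10(s) ~ U(-6, 0)
h_bounds: [0.0, 1.0]           # prior: h ~ U(0, 1)
n_accept: 50000                # particles per tolerance stage
screen_reps: 50000             # neutral simulations per gene for the screen
run_screen: true
dfe_thresholds: [0.01, 0.1]
seed: 0
burnin_scale: 1.0
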