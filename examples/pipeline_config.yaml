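# Pipeline configuration for `laminar-ephys run-all --config ...`
# Two programmed excitability phenotypes run through the full chain.

n_contacts: 16
spacing_um: 100.0

profiles:
  control: control-like   # paired-pulse depression in DG at 25-50 ms
  ad: ad-like             # facilitation + mid-train re-entrance

# Population-spike threshold relative to the unscaled DG response
# amplitude; 1.15 places it between the baseline response and the
# facilitated second pulse of the ad-like profile.
ps_threshold_rel:
  control: 1.5
  ad: 1.15

ppi_list_ms: [25, 50, 100, 200, 500, 1000]
pair_repeats: 20
io_currents_ua: [50, 100, 150, 200, 250, 300, 350, 400, 450, 500, 550, 600]
io_repeats: 3

noise_sd: 0.05        # mV, band-limited recording noise
amp_jitter_sd: 0.0    # multiplicative trial-to-trial amplitude jitter
artifact_amp: 5.0     # mV, 0.2 ms biphasic stimulus artifact
seed: 7

drift_tol_mv: 2.0     # baseline-stability screen
csd_smoothing_degree: 2
csd_interp_steps: 20
reentry_window_ms: [12.0, 25.0]
save_recordings: false
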