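# Named network presets for the synthetic generator.  Each entry maps to
# a NetworkPreset; values are the conditions the qualitative
# developmental contrasts are tested under:
#   * Lgdel-8div emits no network bursts (nb_rate_per_min: 0);
#   * Lgdel-16div has a higher mean electrode rate than WT-16div
#     (hyper-excitable at 16 DIV);
#   * rates grow and synchrony tightens from 8 to 16 DIV in all
#     genotypes.
WT-8div:
  n_active: 300
  rate_mu_log10: -0.7
  rate_sigma_log10: 0.3
  nb_rate_per_min: 3.0
  nb_participation: 0.5
  nb_spikes_per_electrode: 3.0
  nb_jitter_s: 0.008
  burst_trains_fraction: 0.3
WT-16div:
  n_active: 800
  rate_mu_log10: -0.3
  rate_sigma_log10: 0.3
  nb_rate_per_min: 8.0
  nb_participation: 0.6
  nb_spikes_per_electrode: 4.0
  nb_jitter_s: 0.005
  burst_trains_fraction: 0.5
Lgdel-8div:
  n_active: 150
  rate_mu_log10: -0.9
  rate_sigma_log10: 0.3
  nb_rate_per_min: 0.0
  nb_participation: 0.0
  nb_spikes_per_electrode: 0.0
  nb_jitter_s: 0.008
  burst_trains_fraction: 0.1
Lgdel-16div:
  n_active: 900
  rate_mu_log10: -0.1
  rate_sigma_log10: 0.3
  nb_rate_per_min: 8.0
  nb_participation: 0.5
  nb_spikes_per_electrode: 4.0
  nb_jitter_s: 0.005
  burst_trains_fraction: 0.4
Dgcr8-16div:
  n_active: 850
  rate_mu_log10: -0.15
  rate_sigma_log10: 0.3
  nb_rate_per_min: 12.0
  nb_participation: 0.6
  nb_spikes_per_electrode: 4.0
  nb_jitter_s: 0.005
  burst_trains_fraction: 0.45
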