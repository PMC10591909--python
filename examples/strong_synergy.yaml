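# Regular growth, strong Bliss synergy: single-agent TGI21 0.5 and 0.4,
# combination 0.8 (Bliss-additive would be 0.7). Doubling time 7 days.
doubling_time: 7
n_per_group: 6
t_obs: 21
tv_max: 3000
arms:
  A: {tgi21: 0.5}
  B: {tgi21: 0.4}
  AB: {tgi21: 0.8}
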