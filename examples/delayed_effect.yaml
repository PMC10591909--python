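# Delayed treatment effect: drug A and the combination kick in at day 10;
# follow-up extended to day 50 (twice-weekly schedule continues past day 21).
doubling_time: 7
n_per_group: 10
t_obs: 50
tv_max: 3000
arms:
  A: {tgi21: 0.5, t_ki: 10}
  B: {tgi21: 0.4}
  AB: {tgi21: 0.8, t_ki: 10}
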