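# Shipped cohort design: four between-subject conditions, three blocks of
# 15 rounds x 12 trials, adaptive meta-strategy learners with
# truncated-normal parameter heterogeneity.
conditions: [minus_giveup, minus_giveup_minus_trylow, plus_try, plus_try_explore]
n_per_condition: [53, 55, 54, 54]
agent_mixture:
  adaptive_learner: 1.0
learner_dists:
  learning_rate:   {mean: 0.25, sd: 0.10, lower: 0.02, upper: 0.80}
  temperature:     {mean: 5.0,  sd: 2.0,  lower: 1.0,  upper: 15.0}
  retention_decay: {mean: 0.5,  sd: 0.2,  lower: 0.05, upper: 0.95}
initial_propensities: [14.0, 10.0, 8.0]
master_seed: 12345
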