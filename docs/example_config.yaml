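# Run configuration for `cadi run-all --config docs/example_config.yaml`.
# Every key is optional; omitted keys use the defaults of cadi.io.RunConfig.
# JSON with the same structure is accepted too.

out_dir: cadi_output
seed: 7

# Input files. Any path left unset is generated by the synthetic scenario.
# corpus: data/corpus.csv          # columns: id, platform, date, text
# trends: data/trends.csv          # columns: region, word, date, value
#                                  # (region "NATIONAL" rows feed beta)
# population: data/population.csv  # columns: region, year, population
# penetration: data/penetration.csv  # columns: year, penetration
# covariates: data/covariates.csv  # region, year, DI..RU, gdp_pc
# survey: data/survey.csv          # columns: region, weight, disorder

# Index
tau: 40.0

# Dictionary construction
min_chars: 15
min_char_len: 2
min_frequency: 5
embedding_dim: 100
embedding_window: 5
embedding_epochs: 20
stopwords: []
# alpha_threshold: 0.5
# top_k: 50

# Association analysis
quantile: 0.5
n_boot: 200
survey_year: 2020
subgroups: true   # needs enough regions per subgroup for the 14-column design

# Synthetic scenario overrides (cadi.synthetic.ScenarioConfig fields)
scenario:
  n_regions: 31
  years: [2016, 2021]
  n_words: 20
  n_docs: 1200
  noise_sd: 0.1
  trend_freq: MS
  effect_sizes: {IE: -1.0, ACP: 1.0}

log_level: INFO
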