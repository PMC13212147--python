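# Default configuration for the synthetic cluster-randomized HFP trial
# generator.  These defaults define the study conditions the generator
# emulates: 96 settlements randomized 1:1, ~27 women per settlement,
# baseline covariate distributions matching the trial's descriptive table,
# and true path coefficients whose implied effect decomposition reproduces
# the published decomposition (a-paths from the total-effect table; b- and
# d-paths back-solved as component / a so that each a*b and a*d*b product
# equals the corresponding published component).

n_clusters: 96
allocation: [48, 48]
cluster_size_mean: 27
icc: 0.07              # cluster-level share of residual variance, per equation
round_noise_sd: 1.0    # sd of round-level DDS noise around the woman-level mean
n_diet_rounds: 4
ramadan_prob: 0.08
discretize_dds: false  # keep linear-Gaussian DDS (no rounding/clamping) by default

mediators: [crop_richness, garden_practices, n_poultry, n_eggs,
            fg_knowledge, dd_knowledge]
market: market_score
outcome: dds_mean
treatment: arm

true_paths:
  direct: -0.010
  a:
    crop_richness: 5.4
    garden_practices: 4.8
    n_poultry: 1.0
    n_eggs: 1.7
    fg_knowledge: 0.6
    dd_knowledge: 0.4
    market_score: 0.3
  b:   # mediator -> outcome; back-solved component / a
    crop_richness: 0.04185185185185185      # 0.226 / 5.4
    garden_practices: 0.019166666666666665  # 0.092 / 4.8
    n_poultry: 0.004                        # 0.004 / 1.0
    n_eggs: 0.007058823529411765            # 0.012 / 1.7
    fg_knowledge: 0.025                     # 0.015 / 0.6
    dd_knowledge: 0.14                      # 0.056 / 0.4
    market_score: 0.03                      # 0.009 / 0.3
  d:   # mediator -> market activity; back-solved component / (a * b_market)
    crop_richness: 0.12962962962962962      # 0.021 / (5.4 * 0.03)
    garden_practices: -0.0625               # -0.009 / (4.8 * 0.03)
    n_poultry: 0.06666666666666667          # 0.002 / (1.0 * 0.03)
    n_eggs: -0.0196078431372549             # -0.001 / (1.7 * 0.03)
    fg_knowledge: 0.2777777777777778        # 0.005 / (0.6 * 0.03)
    dd_knowledge: 0.08333333333333333       # 0.001 / (0.4 * 0.03)

# control-arm target means; structural intercepts are solved from these
control_means:
  crop_richness: 5.4
  garden_practices: 4.6
  n_poultry: 2.2
  n_eggs: 3.0
  fg_knowledge: 1.8
  dd_knowledge: 2.6
  market_score: 0.6
  dds_mean: 4.5

residual_sd:
  crop_richness: 4.0
  garden_practices: 3.0
  n_poultry: 2.5
  n_eggs: 4.0
  fg_knowledge: 1.0
  dd_knowledge: 0.9
  market_score: 0.6
  dds_mean: 0.9

residual_corr:
  garden_poultry: 0.2   # pairwise, within {crop, practices, poultry, eggs}
  knowledge: 0.3        # between the two knowledge scores
  empowerment: 0.2      # within the optional endline empowerment block

# covariate loadings (endogenous <- baseline covariate); unlisted pairs are 0
gamma:
  crop_richness: {crop_richness_baseline: 0.4}
  market_score: {market_score_baseline: 0.3, emp_mobility: 0.1}
  fg_knowledge: {education: 0.05}
  dd_knowledge: {education: 0.05}
  dds_mean: {dds_baseline: 0.25, education: 0.05, religion_muslim: 0.1}

covariates:
  religion_muslim: {dist: bernoulli, p: 0.68}
  wealth_quintile: {dist: categorical, levels: [1, 2, 3, 4, 5],
                    probs: [0.24, 0.22, 0.20, 0.18, 0.16]}
  log_homestead_land: {dist: normal, mean: 5.89, sd: 1.01}
  log_agri_land: {dist: normal, mean: 7.77, sd: 1.41}
  crop_richness_baseline: {dist: normal, mean: 6.2, sd: 4.5}
  market_score_baseline: {dist: normal, mean: 0.5, sd: 0.7}
  education: {dist: categorical, levels: [0, 1, 2, 3, 4],
              probs: [0.155, 0.22, 0.23, 0.34, 0.055]}
  emp_social_support: {dist: normal, mean: 1.7, sd: 0.4}
  emp_comm_husband: {dist: normal, mean: 1.8, sd: 0.4}
  emp_external_comm: {dist: normal, mean: 0.2, sd: 0.4}
  emp_decision: {dist: normal, mean: 0.65, sd: 0.6}
  emp_mobility: {dist: bernoulli, p: 0.31}
  emp_income: {dist: bernoulli, p: 0.105}
  dds_baseline: {dist: normal, mean: 3.9, sd: 1.35}

missingness:
  # distribution of the number of observed diet rounds (4, 3, 2, 1)
  diet_rounds: {4: 0.75, 3: 0.12, 2: 0.05, 1: 0.08}
  # per-variable woman-level missingness (MCAR), from observed per-indicator n
  variables:
    crop_richness: 0.056
    garden_practices: 0.085
    n_poultry: 0.063
    n_eggs: 0.063
    fg_knowledge: 0.324
    dd_knowledge: 0.095
    market_score: 0.105

# optional endline empowerment mediators (pipeline "empowerment_mediators"
# variant); null paths by default — the generator's truth is that empowerment
# carries no indirect effect
empowerment_mediators:
  emp_end_social_support: {a: 0.0, b: 0.0, mean: 1.7, sd: 0.4}
  emp_end_network: {a: 0.0, b: 0.0, mean: 1.0, sd: 0.5}
  emp_end_decision: {a: 0.0, b: 0.0, mean: 0.7, sd: 0.6}
  emp_end_mobility: {a: 0.0, b: 0.0, mean: 0.3, sd: 0.45}
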