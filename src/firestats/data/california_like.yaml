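# Canonical "california-like" synthetic scenario.
#
# A two-decade fire catalog with the record structure of a statewide
# fire-perimeter archive: heavy-tailed sizes spliced from a lognormal body
# below 500 acres and a Pareto tail above it, a July-peaked fire season,
# an empirical six-group cause mix, clustered ignition locations, and a
# 12-variable covariate stack driving a logistic ignition-presence model
# on 3 km cells.  All units: meters (coordinates), acres (sizes).
n_fires: 6336
period: [2000, 2019]
seed: 20

size_law:
  family: spliced_lognormal_pareto
  params:
    min_size: 10.0        # database inclusion floor, acres
    threshold: 500.0      # splice point = large-fire threshold, acres
    body_logmean: 5.0     # lognormal body (acres, log scale; median ~148 acres)
    body_logsd: 0.8
    tail_alpha: 2.0       # Pareto tail shape (finite mean, linear mean excess)
    p_tail: 0.1968        # share of fires at or above the splice point

# Share of each cause group (fractions of an empirical 6336-fire mix).
cause_mix:
  natural: 0.2414773
  human_transportation: 0.0661301
  human_activity: 0.2768308
  human_construction: 0.0476641
  miscellaneous: 0.1177399
  unknown: 0.2501578

# Monthly ignition probabilities, peaking in July.
month_weights: [0.01, 0.01, 0.02, 0.04, 0.08, 0.13, 0.22, 0.18, 0.13, 0.09, 0.05, 0.04]

# Rectangular study window, planar meters (roughly statewide scale).
window: [0.0, 0.0, 774000.0, 855000.0]

# Gaussian ignition hot spots: center x, center y, isotropic sd, weight.
hotspots:
  - {cx: 620000.0, cy: 120000.0, sd: 40000.0, weight: 0.45}
  - {cx: 150000.0, cy: 620000.0, sd: 60000.0, weight: 0.30}
  - {cx: 450000.0, cy: 400000.0, sd: 50000.0, weight: 0.25}

# Smooth Gaussian random fields: mean, sd, spatial correlation length (m).
stack_cell_size: 3000.0
covariate_fields:
  distance_to_roads: {mean: 2.0, sd: 1.5, corr_length: 60000.0}      # km
  distance_to_powerline: {mean: 3.0, sd: 2.0, corr_length: 60000.0}  # km
  housing_density: {mean: 50.0, sd: 80.0, corr_length: 45000.0}      # houses/km^2
  population_density: {mean: 100.0, sd: 150.0, corr_length: 45000.0} # persons/km^2
  elevation: {mean: 0.8, sd: 0.6, corr_length: 90000.0}              # km
  slope: {mean: 10.0, sd: 8.0, corr_length: 30000.0}                 # degrees
  aspect: {mean: 180.0, sd: 90.0, corr_length: 15000.0}              # degrees
  tree: {mean: 25.0, sd: 15.0, corr_length: 60000.0}                 # percent cover
  shrub: {mean: 30.0, sd: 15.0, corr_length: 60000.0}                # percent cover
  grass: {mean: 13.0, sd: 10.0, corr_length: 60000.0}                # percent cover
  tmax: {mean: 24.0, sd: 4.0, corr_length: 120000.0}                 # deg C
  vpdmax: {mean: 18.0, sd: 6.0, corr_length: 120000.0}               # hPa

# Target pairwise correlations (achieved exactly in the empirical sample):
# the two redundant human pairs and the elevation/climate block that the
# correlation screen is meant to resolve.  tmax-vpdmax is set to the
# smallest round value keeping the matrix positive definite given the two
# strong elevation correlations.
cross_correlation:
  - [distance_to_roads, distance_to_powerline, 0.5524]
  - [housing_density, population_density, 0.8132]
  - [elevation, tmax, -0.6086]
  - [elevation, vpdmax, -0.8359]
  - [tmax, vpdmax, 0.15]

# Ignition-presence logistic model on 3 km cell-averaged covariates.
# Intercept set so the mean presence probability is ~7% at the field means.
logistic_coefficients:
  intercept: -9.25
  distance_to_roads: -0.0354
  housing_density: -0.0017
  slope: 0.0059
  aspect: 0.0143
  tree: -0.0070
  shrub: 0.0009
  grass: 0.0230
  tmax: 0.0934
  vpdmax: 0.0655
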