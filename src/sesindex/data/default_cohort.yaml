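# Default synthetic-cohort calibration for the multi-site SES index.
#
# Per-site item prevalences (fractions) and one-factor loadings are transcribed
# from the published site-level tables of the index development study; the site
# mix matches the published enrolment counts (total N = 49,536).
#
# Site latent means are package calibration choices (reference site Nagpur at 0,
# SD 1 everywhere), set so that simulated site SES means reproduce the published
# site ordering; they are not published quantities. Loadings for
# more_than_one_room and bicycle outside DRC are unpublished (those items enter
# the index only at DRC) and default to 0.55, a mid-range calibration choice.
# Covariate links (education cutpoints, logistic intercepts/slopes) are
# calibration choices matching the published covariate marginals:
# education bands 18/22/52/7 %, antenatal care 97 %, facility delivery 45 %.

sites: [Guatemala, Belagavi, Nagpur, Pakistan, DRC, Kenya, Zambia]
site_weights:
  Guatemala: 0.207667
  Belagavi: 0.147549
  Nagpur: 0.156977
  Pakistan: 0.089147
  DRC: 0.141271
  Kenya: 0.143411
  Zambia: 0.113978

items: [finished_floor, flush_toilet, lpg_electricity_fuel, improved_water,
        more_than_one_room, electricity, television, refrigerator,
        smart_phone, car, motorbike, bicycle]

prevalences:
  Guatemala: {finished_floor: 0.756, flush_toilet: 0.427, lpg_electricity_fuel: 0.193,
              improved_water: 0.960, more_than_one_room: 0.954, electricity: 0.956,
              television: 0.793, refrigerator: 0.257, smart_phone: 0.648,
              car: 0.178, motorbike: 0.230, bicycle: 0.369}
  Belagavi:  {finished_floor: 0.805, flush_toilet: 0.322, lpg_electricity_fuel: 0.556,
              improved_water: 0.926, more_than_one_room: 0.964, electricity: 0.988,
              television: 0.866, refrigerator: 0.222, smart_phone: 0.544,
              car: 0.127, motorbike: 0.684, bicycle: 0.457}
  Nagpur:    {finished_floor: 0.690, flush_toilet: 0.593, lpg_electricity_fuel: 0.747,
              improved_water: 0.977, more_than_one_room: 0.955, electricity: 0.981,
              television: 0.906, refrigerator: 0.459, smart_phone: 0.295,
              car: 0.065, motorbike: 0.734, bicycle: 0.634}
  Pakistan:  {finished_floor: 0.496, flush_toilet: 0.257, lpg_electricity_fuel: 0.247,
              improved_water: 0.876, more_than_one_room: 0.580, electricity: 0.627,
              television: 0.333, refrigerator: 0.141, smart_phone: 0.136,
              car: 0.092, motorbike: 0.531, bicycle: 0.017}
  DRC:       {finished_floor: 0.004, flush_toilet: 0.001, lpg_electricity_fuel: 0.000,
              improved_water: 0.396, more_than_one_room: 0.527, electricity: 0.001,
              television: 0.004, refrigerator: 0.000, smart_phone: 0.002,
              car: 0.001, motorbike: 0.049, bicycle: 0.432}
  Kenya:     {finished_floor: 0.175, flush_toilet: 0.005, lpg_electricity_fuel: 0.012,
              improved_water: 0.744, more_than_one_room: 0.625, electricity: 0.086,
              television: 0.112, refrigerator: 0.014, smart_phone: 0.221,
              car: 0.012, motorbike: 0.155, bicycle: 0.371}
  Zambia:    {finished_floor: 0.669, flush_toilet: 0.065, lpg_electricity_fuel: 0.079,
              improved_water: 0.844, more_than_one_room: 0.920, electricity: 0.321,
              television: 0.443, refrigerator: 0.170, smart_phone: 0.279,
              car: 0.064, motorbike: 0.010, bicycle: 0.482}

loadings:
  Guatemala: {finished_floor: 0.73, flush_toilet: 0.69, lpg_electricity_fuel: 0.71,
              improved_water: 0.46, more_than_one_room: 0.55, electricity: 0.88,
              television: 0.81, refrigerator: 0.77, smart_phone: 0.58,
              car: 0.57, motorbike: 0.45, bicycle: 0.55}
  Belagavi:  {finished_floor: 0.48, flush_toilet: 0.62, lpg_electricity_fuel: 0.67,
              improved_water: 0.09, more_than_one_room: 0.55, electricity: 0.63,
              television: 0.80, refrigerator: 0.82, smart_phone: 0.73,
              car: 0.47, motorbike: 0.70, bicycle: 0.55}
  Nagpur:    {finished_floor: 0.77, flush_toilet: 0.25, lpg_electricity_fuel: 0.74,
              improved_water: 0.28, more_than_one_room: 0.55, electricity: 0.55,
              television: 0.77, refrigerator: 0.88, smart_phone: 0.75,
              car: 0.57, motorbike: 0.76, bicycle: 0.55}
  Pakistan:  {finished_floor: 0.85, flush_toilet: 0.83, lpg_electricity_fuel: 0.89,
              improved_water: 0.18, more_than_one_room: 0.55, electricity: 0.79,
              television: 0.92, refrigerator: 0.92, smart_phone: 0.59,
              car: 0.22, motorbike: 0.35, bicycle: 0.55}
  DRC:       {finished_floor: 0.57, flush_toilet: 0.83, lpg_electricity_fuel: 0.86,
              improved_water: 0.26, more_than_one_room: 0.61, electricity: 0.76,
              television: 0.97, refrigerator: 0.90, smart_phone: 0.59,
              car: 0.73, motorbike: 0.94, bicycle: 0.60}
  Kenya:     {finished_floor: 0.76, flush_toilet: 0.83, lpg_electricity_fuel: 0.86,
              improved_water: 0.26, more_than_one_room: 0.55, electricity: 0.92,
              television: 0.92, refrigerator: 0.90, smart_phone: 0.69,
              car: 0.73, motorbike: 0.53, bicycle: 0.55}
  Zambia:    {finished_floor: 0.77, flush_toilet: 0.88, lpg_electricity_fuel: 0.86,
              improved_water: 0.46, more_than_one_room: 0.55, electricity: 0.96,
              television: 0.90, refrigerator: 0.96, smart_phone: 0.42,
              car: 0.54, motorbike: 0.31, bicycle: 0.55}

# Pooled one-factor configuration (the "all sites" column of the published
# tables); used for single-group factor-structure simulations.
pooled:
  prevalences: {finished_floor: 0.530, flush_toilet: 0.260, lpg_electricity_fuel: 0.272,
                improved_water: 0.826, more_than_one_room: 0.811, electricity: 0.603,
                television: 0.532, refrigerator: 0.192, smart_phone: 0.337,
                car: 0.083, motorbike: 0.341, bicycle: 0.414}
  loadings:    {finished_floor: 0.82, flush_toilet: 0.79, lpg_electricity_fuel: 0.85,
                improved_water: 0.67, more_than_one_room: 0.55, electricity: 0.99,
                television: 0.95, refrigerator: 0.85, smart_phone: 0.64,
                car: 0.55, motorbike: 0.67, bicycle: 0.55}

latent:
  Guatemala: {mean: -0.23, sd: 1.0}
  Belagavi:  {mean: -0.04, sd: 1.0}
  Nagpur:    {mean:  0.00, sd: 1.0}
  Pakistan:  {mean: -0.87, sd: 1.0}
  DRC:       {mean: -1.82, sd: 1.0}
  Kenya:     {mean: -1.60, sd: 1.0}
  Zambia:    {mean: -0.95, sd: 1.0}

covariate_links:
  education_cutpoints: [-2.079, -1.0776, 1.3678]   # on theta + N(0, 0.8^2)
  education_noise_sd: 0.8
  antenatal_care: {slope: 1.0, intercept: 4.876}    # pooled marginal 97 %
  facility_delivery: {slope: 1.0, intercept: 0.4581}  # pooled marginal 45 %

missing_rate: 0.0
seed: 20201217
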