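# Frozen default parameters of the synthetic BTM panel generator.
#
# Structure mirrors the study population: 1580 northern and 1562 central
# farms sampled monthly over 24 months (Jan 2018 - Dec 2019), thinned to
# 37077 records.  Regional component means were set by a calibration
# search against the published marginal percentages (central SNF/SCC
# penalty shares 44 %/40 %, benefit-gain shares 88.7 % north /57.1 %
# central); SDs and seasonal terms are fixed at values realistic for
# monthly bulk-tank milk testing.  SCC parameters are on the log scale
# (log of thousands of cells/mL).
n_farms:
  north: 1580
  central: 1562
n_months: 24
start_year: 2018
start_month: 1
n_records: 37077
seed: 20180101
components:
  fat:
    north: {mean: 3.8667, farm_sd: 0.25, resid_sd: 0.28}
    central: {mean: 3.8685, farm_sd: 0.25, resid_sd: 0.28}
  snf:
    north: {mean: 8.50, farm_sd: 0.14, resid_sd: 0.17}
    central: {mean: 8.3803, farm_sd: 0.14, resid_sd: 0.17}
  scc:
    north: {mean: 5.15, farm_sd: 0.50, resid_sd: 0.45}
    central: {mean: 6.0403, farm_sd: 0.50, resid_sd: 0.45}
seasonal:
  fat: {amplitude: 0.10, phase: 1.5707963}
  snf: {amplitude: 0.05, phase: 1.5707963}
  scc: {amplitude: 0.12, phase: -1.5707963}
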