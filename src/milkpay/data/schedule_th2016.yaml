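# Thai milk-quality payment schedule (PPBMQ, in force since 2016).
#
# Adjustments are baht per 1000 kg of raw milk; `usd` is the fixed printed
# display conversion and is never used in computation.  Fat and SNF bounds
# are percentages at 2-decimal resolution; SCC bounds are cells/mL.
# Intervals are closed on both stated ends; null means unbounded.  Shared
# printed boundaries are resolved to the more severe (lower) class, so the
# bands below are non-overlapping and exhaustive.
currency: baht_per_1000kg
fat:
  - {lower: 4.00, upper: null, label: "A++", adjustment: 400, usd: 12.84}
  - {lower: 3.80, upper: 3.99, label: "A+", adjustment: 300, usd: 9.63}
  - {lower: 3.60, upper: 3.79, label: "A", adjustment: 200, usd: 6.42}
  - {lower: 3.40, upper: 3.59, label: "B", adjustment: 0, usd: 0.0}
  - {lower: 3.21, upper: 3.39, label: "C", adjustment: -200, usd: 6.42}
  - {lower: null, upper: 3.20, label: "D", adjustment: -400, usd: 12.84}
snf:
  - {lower: 8.70, upper: null, label: "A+", adjustment: 600, usd: 19.26}
  - {lower: 8.50, upper: 8.69, label: "A", adjustment: 300, usd: 9.63}
  - {lower: 8.35, upper: 8.49, label: "B", adjustment: 0, usd: 0.0}
  - {lower: 8.26, upper: 8.34, label: "C", adjustment: -300, usd: 9.63}
  - {lower: null, upper: 8.25, label: "D", adjustment: -600, usd: 19.26}
scc:
  - {lower: 0, upper: 200000, label: "A++", adjustment: 500, usd: 16.05}
  - {lower: 200001, upper: 300000, label: "A+", adjustment: 300, usd: 9.63}
  - {lower: 300001, upper: 400000, label: "A", adjustment: 200, usd: 6.42}
  - {lower: 400001, upper: 500000, label: "B", adjustment: 0, usd: 0.0}
  - {lower: 500001, upper: 700000, label: "C", adjustment: -200, usd: 6.42}
  - {lower: 700001, upper: 1000000, label: "D", adjustment: -300, usd: 9.63}
  - {lower: 1000001, upper: null, label: "E", adjustment: -500, usd: 16.05}
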