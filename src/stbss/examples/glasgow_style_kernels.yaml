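# The "Glasgow-style" kernel configuration: 16 kernels for a network that is
# sparse in space (station distances in meters) and dense in time (hourly
# stamps).  One sole-spatial ring at serial lag zero, three spatio-temporal
# rings at lags 1-3, and twelve sole-temporal kernels at lags 1-10, 12 and 24
# (the last two capture morning/evening traffic cycles).  Exercised on
# synthetic data only.
kernels:
  - {spatial: {type: ring, inner: 0, outer: 8000}, temporal: {type: exact_lag, lag: 0}}
  - {spatial: {type: ring, inner: 0, outer: 8000}, temporal: {type: exact_lag, lag: 1}}
  - {spatial: {type: ring, inner: 0, outer: 8000}, temporal: {type: exact_lag, lag: 2}}
  - {spatial: {type: ring, inner: 0, outer: 8000}, temporal: {type: exact_lag, lag: 3}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 1}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 2}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 3}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 4}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 5}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 6}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 7}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 8}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 9}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 10}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 12}}
  - {spatial: {type: ball, radius: 0}, temporal: {type: exact_lag, lag: 24}}
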