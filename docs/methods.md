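# Methods

## Model and estimators

The observable p-variate field follows the location–scatter model
x(s, t) = A z(s, t) + m on a spatio-temporal domain S × T ⊆ R^{d+1}.
The latent field z is second-order stationary with E z = 0,
Cov z(s, t) = I_p, and diagonal cross-covariance D(h, τ) at every lag —
its components are mutually uncorrelated over all of space-time. The
mixing matrix A is identifiable only up to permutation and sign of its
rows, which is the usual and harmless indeterminacy of blind source
separation.

Estimation diagonalizes local autocovariance matrices (LACFs): kernel
weighted averages of cross-products of centered observations over all
ordered pairs of the n sample locations, normalized by n·F with
F² = (1/n) Σ f². For indicator kernels F² is the average number of
neighbours the kernel selects, which puts LACFs of differently sized
kernels on a comparable scale. The f₀ kernel (zero-radius ball) yields
the ordinary divisor-n covariance used for whitening.

- stAMUSE solves the generalized eigenproblem exactly: whiten, then
  eigendecompose the single symmetrized whitened LACF. Identifiable iff
  the latent LACF diagonal values are pairwise distinct; a warning is
  emitted when consecutive diagonalized values are closer than 1e-8.
- stSOBI jointly diagonalizes L whitened LACFs by cyclic Givens sweeps.
  For the index pair (i, j) the rotation angle is the closed-form
  maximizer of the pairwise contribution to the summed squared
  diagonals, θ = ¼·atan2(2 Σ_l p_l q_l, Σ_l (p_l² − q_l²)) with
  p_l = M_l[i,i] − M_l[j,j] and q_l = 2 M_l[i,j]. The objective is
  checked to be non-decreasing after every sweep (an assertion, since a
  decrease would indicate a defect, not data trouble). Termination:
  all angles below 1e-10, or 100 sweeps with a convergence warning.
  Identifiable iff for every component pair some kernel separates the
  latent LACF diagonals — strictly weaker than the stAMUSE condition.

Whitening uses the symmetric inverse square root from an
eigendecomposition, with a rank guard (condition number above 1e12
raises, naming the offending eigenvalue) and an eigenvalue floor of
1e-12 times the largest. Each row of W is sign-fixed so its
largest-absolute entry is positive — the model fixes sign only up to
±1, and a deterministic convention makes runs reproducible. Components
are ordered by decreasing Σ_l λ²_{i,l} (stSOBI) or by the decreasing
diagonal of D_f (stAMUSE); these coincide when all diagonal values are
positive but can differ in sign-heterogeneous cases, which is why both
orderings are kept method-specific. Ties are resolved by original
component index (stable sort).

## Kernels

A kernel is the product of a spatial factor in ‖h‖ and a temporal
factor in |τ|: ball (closed), ring (half-open, strict at the inner
radius), Gauss (scaled so the weight at the nominal radius equals
exp(−½ q²) with q the 95% normal quantile), and — for equidistant time
stamps — the exact-lag indicator I(|τ| = ℓ) with a configurable
absolute tolerance (default 1e-9). A combined-metric Gauss kernel in
the distance (a₁‖h‖² + a₂τ²)^½ is also available; the Gauss family is
the only one for which the metric and separate-coordinates forms
coincide, which the tests exploit. Ring radii given in the wrong order
are swapped with a warning rather than rejected, since both orderings
appear in common usage.

The named presets pair three rings (0,1), (1,2), (2,3) at serial lag 0
(sole spatial), zero-radius spatial balls at serial lags 1–3 (sole
temporal), their nine ring × lag combinations (spatio-temporal), and
the 15-kernel union (`stSOBI.st2`). Sole-temporal presets use the
exact-lag adaptation rather than a temporal ball so that the τ = 0
pairs — whose LACF is the covariance already handled by whitening — do
not re-enter every scatter; on the benchmark models the two conventions
differ by well under the replication noise. A 16-kernel
`glasgow-style` example configuration (one 8000 m ring at lag 0, three
at lags 1–3, twelve sole-temporal lags 1–10, 12, 24) ships as a text
fixture for sparse hourly monitoring networks.

## LACF computation

Two paths produce identical estimates (verified to 1e-10 against an
independent double-loop oracle):

- a generic path that materializes the symmetric pair-weight structure
  — dense blockwise evaluation for n ≤ 2000 or unbounded kernels, a
  KD-tree neighbour index on per-axis normalized coordinates for larger
  n with finite-support kernels, stored sparse below a 25% fill;
- a fast path for sites × equidistant-times product designs with
  bounded temporal support, factorizing the double sum into site pairs
  and serial lags; this is what makes 50-replicate studies at
  n = 20 000 samples take seconds.

Rows with any missing variable are dropped before centering and pair
enumeration (complete-case); pairwise-available estimation is rejected
because it can break positive semi-definiteness of the covariance.
Duplicate space-time coordinates are allowed and simply contribute
zero-lag pairs. A kernel selecting no pairs raises an empty-kernel
error naming the kernel.

## Simulator

Latent components are centered Gaussian fields with covariance built
from: Matérn (σ², ν, ρ) in space; AR(1) exponential (σ², φ) in time; a
nugget; separable products; the product-sum class k₁·C_t·C_sp + k₂·C_sp
+ k₃·C_t; and the Gneiting class with ψ(u) = u^α/r₁ + 1 and
φ(h) = exp(−h^γ/r₂) in two spatial dimensions, i.e.
C(h, τ) = σ² (|τ|^{2α}/r₁ + 1)^{−1} exp(−h^{2γ} / (r₂ (|τ|^{2α}/r₁ + 1)^γ)).
The squared lags enter through the generating functions' |τ|² and ‖h‖²
arguments, and the single ψ power corresponds to d = 2. The six model
presets are three-component unit-variance configurations: Model 1 sole
spatial (Matérn × temporal nugget — fields redrawn independently per
time point), Model 2 its mirror in time, Models 3–4 separable
Matérn × AR(1) (Model 4 with deliberately shared marginals: components
1–2 share the spatial, 2–3 the temporal structure), Model 5
product-sum, Model 6 Gneiting.

The benchmark sampling design overlays (0, n_sp]² with a quarter-unit
grid, draws n_sp² distinct sites uniformly without replacement
(irregular spatial sampling, redrawn per replicate), and observes them
at n_t = 2·n_sp² integer times — sparse in space, dense in time, as in
monitoring networks. Bare Matérn/AR(1)/nugget blocks must be wrapped in
a Product to state the behaviour on the other axis explicitly; this
avoids a silent convention.

Sampling paths: separable models draw matrix-normal fields
L_sp G L_tᵀ from the spatial and temporal Cholesky factors; product-sum
models add √k₁ × (separable field) + √k₂ × (spatial field replicated
over times) + √k₃ × (time series replicated over sites), whose three
independent terms reproduce the covariance exactly; non-separable
models (Gneiting) use a dense Cholesky of the full n × n covariance,
guarded at n ≤ 6000. On factorization failure a diagonal jitter of
1e-10·trace/n is added, growing tenfold for up to three retries —
needed for near-singular Matérn matrices at quarter-unit spacing. The
Kronecker and dense paths agree in distribution (checked by matching
empirical moments over hundreds of replicates). Random draws derive all
per-replicate seeds deterministically from one root seed, so any
replicate is reproducible in isolation.

What the simulator does *not* emulate: non-Gaussian marginals,
trends/diurnal cycles (real monitoring data need deseasonalization
first), measurement gaps with structure, and anisotropy. Passing tests
therefore demonstrate correctness of the estimators under the stated
stationary Gaussian model, not robustness to those departures.

## Minimum Distance Index

MDI(Ŵ, A) = (p−1)^{−1/2} inf_C ‖C Ŵ A − I‖_F over matrices C with
exactly one nonzero per row and column. Writing C = P·diag(d), the
optimal scale for gain row g assigned to column j gives the residual
1 − g_j²/‖g‖², reducing the infimum to an assignment problem — solved
exhaustively for p ≤ 8 and by the Hungarian algorithm above (both paths
cross-checked). The closed-form row residual is validated against a
multi-start numerical minimization oracle in the test suite rather than
assumed. Values lie in [0, 1]; 0 means recovery up to order, sign and
scale.

The random-rotation baseline (whitening followed by a Haar-distributed
orthogonal matrix via sign-corrected QR of a standard normal matrix) is
the worst method that still shares the whitening step; every estimator
is compared against it in the study harness.

## Study harness and problem sizes

`run_study` simulates (model, n_sp) cells with redrawn designs per
replicate, estimates W with every requested method preset and scores
MDI against the true A. Whitening and each distinct whitened LACF are
computed once per dataset and shared across presets — the result is
identical to running the estimators stand-alone (tested). Per-replicate
failures are recorded as missing, not fatal.

Default study sizes are n_sp ∈ {6, 10} with 50 replicates, and 20–25
replicates in the acceptance script; these are deliberately scaled-down
settings that already resolve the qualitative ordering of the kernel
presets (spatial kernels win on Model 1, temporal on Model 2, only full
spatio-temporal kernels separate Model 4, the random baseline is worst
everywhere). On Model 4 the marginal presets partially separate — the
component with a distinct marginal is recovered while the degenerate
pair is not — so their MDI sits well below the random baseline yet far
above the separating spatio-temporal preset; full separation is
impossible for them at any sample size.

A practical note on Model 5 (product-sum): its pure-spatial and
pure-temporal variance shares are driven by only n_sp² sites and
2·n_sp² times respectively, not by the full n = 2·n_sp⁴ samples, so
MDI decays markedly more slowly in n_sp than for separable models;
mean MDI ≈ 0.19 for `stSOBI.st2` at n_sp = 10 over 50 replicates is
the faithful finite-sample value under these conditions.

## Numerical choices and limitations

- Whitened LACFs are symmetrized as (M + Mᵀ)/2 before diagonalization;
  finite-sample LACFs of whitened data need not be exactly symmetric
  after round-off.
- Exact-lag tolerance 1e-9 absolute; indicator comparisons carry a
  1e-12 guard against floating-point edge effects at radii.
- The Gauss kernel weight underflows to exactly 0 beyond ~38 standard
  units; mathematically it is positive everywhere.
- Only isotropic spatial kernels are provided (no directional rings);
  the methodology assumes weak spatial isotropy.
- The dense sampling guard (n ≤ 6000) limits non-separable simulation
  to moderate domains; circulant-embedding samplers are out of scope.
- Asymptotic inference for the unmixing estimates (tests, standard
  errors) is not implemented.
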