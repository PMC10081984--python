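# stbss — blind source separation for space-time random fields

Multivariate environmental monitoring data — say, hourly NO, NO₂ and PM₁₀
concentrations at a network of stations — are realizations of a
*p*-variate space-time random field x(**s**, t) with dependence across
space, across time and between variables. Modelling the full
(p × p)-matrix-valued covariance is hard; `stbss` instead assumes the
second-order stationary blind source separation model

    x(s, t) = A z(s, t) + m,

where **A** is an unknown full-rank mixing matrix, **m** a location
vector, and the latent field **z** has zero mean, unit variance and
*spatio-temporally uncorrelated* components: Cov(z(s, t), z(s′, t′)) =
D(h, τ) is diagonal at every spatial lag h = s − s′ and temporal lag
τ = t − t′. Estimating an unmixing matrix **W** with W A ≃ I (up to
order and sign) reduces every downstream task — variography, kriging,
visualization — to *p* univariate problems.

The package is aimed at spatio-temporal statisticians and
environmental-data analysts; it provides the estimators, the scatter
matrices they diagonalize, a Gaussian random-field simulator for the
standard benchmark covariance models, and the Minimum Distance Index
for validating recovery.

## Method

The scatter functional is the **local autocovariance matrix** (LACF) of
a spatio-temporal kernel f:

    LACF_f = 1/(n F_{n,f}) Σ_{i,j} f(s_i − s_j, t_i − t_j) (x_i − x̄)(x_j − x̄)ᵀ,
    F²_{n,f} = 1/n Σ_{i,j} f²(s_i − s_j, t_i − t_j),

with ball, ring, Gauss and (for equidistant times) exact-lag kernel
factors. The zero-radius ball kernel f₀ gives the ordinary covariance.
Two estimators recover W:

- **stAMUSE** — simultaneous diagonalization of LACF_{f₀} and one
  LACF_f via the exact generalized eigenproblem:
  W LACF_{f₀} Wᵀ = I and W LACF_f Wᵀ = D_f (decreasing diagonal);
- **stSOBI** — whitening followed by approximate joint diagonalization
  of L whitened LACFs with cyclic Givens rotations maximizing
  Σ_l ‖diag(Uᵀ M_l U)‖²_F; then W = Uᵀ LACF_{f₀}^{−1/2}.

Both are affine equivariant, so the recovered sources do not depend on
the mixing. Components are ordered by decreasing Σ_l λ²_{i,l} with
pseudo-eigenvalues λ_{i,l} = u_iᵀ M_l u_i. Performance is scored by the
Minimum Distance Index MDI(Ŵ, A) = (p−1)^{−1/2} inf_C ‖C Ŵ A − I‖_F ∈
[0, 1], zero iff recovery is exact up to order, sign and scale.

## Worked example

```python
import numpy as np
import stbss as st

locs = st.simulate_domain(6, seed=1)                    # 36 sites x 72 hours
latent = st.simulate_latent(locs, st.model_preset("model3"), seed=2)
A = st.DEFAULT_MIXING                                   # unknown in practice
observed = st.mix_field(latent, A)

result = st.stsobi(observed, locs, st.preset_kernels("stSOBI.st"))
print("gain matrix W @ A (should be a signed permutation):")
print(np.round(result.W @ A, 3))
print("MDI:", round(st.mdi(result.W, A).value, 3))
print(result.pseudo_eig_table().round(2).to_string(index=False))
```

prints

```
gain matrix W @ A (should be a signed permutation):
[[ 0.117  0.116  0.897]
 [ 0.042 -0.951  0.21 ]
 [ 1.008  0.067 -0.065]]
MDI: 0.211
Type        Par  Lag   z1   z2    z3
Ring (0.0, 1.0)  1.0 1.91 1.43  0.73
Ring (0.0, 1.0)  2.0 1.56 0.87  0.24
Ring (0.0, 1.0)  3.0 1.29 0.41  0.04
Ring (1.0, 2.0)  1.0 1.88 1.14  0.35
Ring (1.0, 2.0)  2.0 1.55 0.65  0.04
Ring (1.0, 2.0)  3.0 1.32 0.20  0.02
Ring (2.0, 3.0)  1.0 1.85 0.79  0.06
Ring (2.0, 3.0)  2.0 1.52 0.49 -0.12
Ring (2.0, 3.0)  3.0 1.29 0.18 -0.09
```

The three latent components were simulated with separable
Matérn × AR(1) covariances on an irregular 36-site design observed at
72 equidistant times, then mixed by a non-trivial 3 × 3 matrix. The
gain matrix W @ A is close to a signed permutation — each row has one
dominant entry near ±1 — and the MDI of 0.211 quantifies the remaining
estimation error at this small sample size (it decreases towards 0 as
the domain grows). The pseudo-eigenvalue table (one row per kernel,
one column per recovered component) shows how strongly each component
loads on each spatio-temporal kernel: z1 carries the most
spatio-temporal dependence, z3 the least — this ordering is how the
components are ranked.

## Command line

```sh
stbss simulate --preset model3 --n-sp 6 --seed 1 --out data.csv
stbss unmix --input data.csv --kernels stSOBI.st2 --method stsobi --out run/
stbss study --models 1,2,4 --methods stSOBI.s,stSOBI.t,stSOBI.st,random \
            --n-sp 6,10 --reps 50 --seed 7 --out study/
stbss mdi run/W.json A.json
```

Kernel settings can be named presets (`stAMUSE.t`, `stSOBI.t`,
`stAMUSE.s`, `stSOBI.s`, `stAMUSE.st`, `stSOBI.st`, `stSOBI.st2`), the
shipped 16-kernel `glasgow-style` example configuration for sparse
station networks with hourly data, or a YAML/JSON file of
`{spatial: ..., temporal: ...}` kernel mappings.

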