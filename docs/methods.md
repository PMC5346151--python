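# Methods

## The model

Chromatin is represented as a bead-spring chain of `N` monomers, each
covering 10 kbp of genome (one bead ≈ the content of a few nucleosome
arrays at this coarse-graining). Energies are measured in units of
`k_BT` and lengths in units of the bead diameter `l`; both are set to 1
internally. The Hamiltonian is

```
H = H_connectivity + H_ev + H_interaction

H_connectivity = (k/2) Σ_i r²_{i,i+1}                    k = 3 k_BT/l²
H_ev           = Σ_{i<j} U_ev exp(-r²_ij / (2 r_e²))     U_ev = 10 k_BT, r_e = 0.3 l
H_interaction  = Σ_{i<j} U_ij  exp(-r²_ij / (2 r_o²))    r_o = 0.5 l
```

with the pair amplitude `U_ij` collecting, depending on the variant:

* a non-specific term `U_ns` (confinement/solvent proxy; sign free);
* a "crumpling" term `U_crumpling(|i-j|)` depending only on genomic
  separation (see *Calibration*);
* a chromatin-state-specific term `U_s(e_i, e_j)` for the block
  copolymer, by default attractive between same-state monomers only and
  equal for every state;
* for the coupled epigenome–folding ("living chromatin") model,
  `-J_i (e_i e_j + 1)/2` with the states themselves dynamic.

Bonded neighbours also feel the Gaussian pair terms (the sums carry no
exclusion); this inclusive convention shifts the effective bond length
slightly but none of the scaling observables.

## Gaussian self-consistent (GSC) stationary states

The configurational distribution is approximated by a zero-mean
multivariate Gaussian, parameterised by the per-coordinate mean squared
distances `D_ij = ⟨(X_i − X_j)²⟩/3`. Under this ansatz every Gaussian
pair term averages in closed form, `⟨U e^{-r²/2σ²}⟩ = U (1 +
D/σ²)^{-3/2}`, and the chain becomes an effective harmonic network with
state-dependent couplings

```
J_ij = k·[|i-j|=1] − Σ_terms (U/σ²) (1 + D_ij/σ²)^{-5/2},
J_ii = −Σ_{k≠i} J_ik   (Laplacian convention),
```

which is the general contract `J_ij = (2/3) ∂⟨H_pair⟩/∂D_ij` (verified
in the tests against numerical differentiation, and against the exact
harmonic-chain equilibrium). Stationarity requires, for every pair,

```
0 = 4 k_BT − Σ_k (J_ik − J_jk)(D_ik − D_jk).
```

A key identity used by the solver: at fixed couplings this equation is
solved exactly by the equilibrium of the harmonic network itself,
`C = k_BT (L + 11ᵀ/N)^{-1}` with `L = −J` and
`D_ij = C_ii + C_jj − 2 C_ij` (the rank-one shift fills the
centre-of-mass null space and cancels in distances). The solver
therefore iterates the map `D → dist(C(J(D)))`.

Numerical choices:

* **Geometric mixing.** Old and new `D` are mixed in log space. `D`
  spans orders of magnitude between the bond scale and the coil scale,
  and the coil–globule collapse is a multiplicative contraction;
  logarithmic mixing is both faster and far more stable than linear
  mixing (measured: the post-collapse step at `N = 1000` converges in
  ~500 iterations vs. ~2000 with linear mixing).
* **Ratcheting trust damping.** The mixing fraction starts at
  `damping` (default 0.5), is halved whenever the residual grows, and
  the cap it may recover to shrinks on every such event and relaxes
  again after 30 consecutive monotone iterations. The iteration settles
  at the largest stably contractive fraction for the regime at hand.
* **Indefinite transients.** While strong repulsion dominates, `L` can
  transiently lose positive definiteness; the eigenvalue branch clips
  modes below 1% of the slowest bond-chain Rouse mode `k(π/N)²` (no
  physical mode is softer than connectivity allows) and reports the
  clipped mass. Near marginal swollen states where the inverse map
  stalls, a slow additive relaxation `D ← D + ε R` finishes the job.
* **Convergence** is certified on the stationarity residual,
  `max |R_ij| ≤ tol`, default `tol = 1e-4 k_BT`; `D` carries a
  positivity floor of `1e-6 l²` off the diagonal. The default
  initialisation is the exact ideal-chain `D`; parameter sweeps
  warm-start each point from its weaker-attraction neighbour, scanning
  from weak to strong attraction (collapse is first-order-like in
  appearance; warm starts keep the scan on one branch).
* Everything is deterministic; the optional random perturbation of the
  initial `D` is seeded.

Observables derive from `D` alone: the contact probability
`P_ij = erf(u) − (2/√π) u e^{-u²}` with `u = r_c/√(2 D_ij)` (isotropic
Gaussian within capture radius `r_c`, default `1.0 l`; scaling
exponents shift by < 0.1 between `r_c = 0.5` and `2 l`), the
sequence-averaged `P_c(s)`, log–log least-squares slopes over a window
(default `10 ≤ s ≤ N/3`, bond-scale and end effects excluded), and
radii of gyration `R_g² = (1/2n²) Σ_{ij∈subset} D_ij` for the whole
chain, each contiguous block, and each chromatin state.

## Folding regimes and the coil-regime slope

The long homopolymer (`N = 1000`) reproduces the canonical regimes:
repulsion/weak attraction gives an extended coil; at
`U_ns ≈ −2.2 k_BT` the radius of gyration drops steeply (the theta
collapse; the scan of the acceptance script locates the steepest
`R_g²` change at −2.2 on a 0.1 grid) with `P_c(s) ∝ s^{-3/2}` at the
transition (measured −1.37 over `10 ≤ s ≤ 300`); beyond it the
equilibrium globule shows a contact plateau.

One systematic deviation is worth stating plainly. In the coil regime
the GSC closure yields the Flory/uniform-expansion swelling exponent
`ν = 3/5` — measured directly as `D(s) ∝ s^{1.20}` — hence a contact
decay `P_c ∝ s^{-3ν} = s^{-1.80}` (measured −1.796, stable under
solver tolerance, fit window and capture radius). A real self-avoiding
walk decays as `≈ s^{-2.1}` (3ν with ν ≈ 0.588 plus the contact
correction); the commonly quoted coil label for this regime is `s^{-2}`.
The Gaussian closure has no contact-exponent correction, so its
coil-regime slope sits at 1.8, about 10% shallow of the label. All
other regimes are unaffected.

## Calibration of the crumpling attraction

Long chromosomes decay as `P_c(s) ∝ s^{-1}` (crumpled/fractal-globule
statistics), which no `s`-independent attraction reproduces at the GSC
level. The calibration fits an amplitude profile `U_crumpling(s)`:
piecewise-linear in `log s` through `n_bins = 12` log-spaced control
points between `s = 2` and `N/2`, with the `s = 1` amplitude pinned to
0 (bond scale) and flat extrapolation beyond the last control point.
The loop alternates a warm-started stationary solve with a proportional
update of each control amplitude by the local log-slope error at its
scale (gain 0.2 k_BT per slope unit). The fitted state sits close to
criticality at every scale, so the slope response is steep; three
stabilisers keep the loop contractive: updates are smoothed across
neighbouring control points, control points outside the diagnostic
window (`10 ≤ s ≤ N/3`) are tied to the nearest interior one, and an
overshoot of the slope error backs the amplitudes off halfway and
shrinks the gain. Convergence: all interior local slopes within
`slope_tol = 0.05` of −1.

The fitted profile is itself informative: the large-`s` amplitudes
converge to ≈ −2.2 k_BT, the critical strength of the collapse — the
crumpled state is a chain held near its theta point at every scale, so
small non-specific perturbations tip it to the coil (`U_ns > 0`,
steeper decay) or the globule (`U_ns < 0`, shallower decay); both
trends are asserted in the tests.

## Copolymer phases

For a two-state block copolymer (exemplar: a deterministic ~1.3 Mbp
active/null segmentation with mean block ≈ 100 kbp, built by the
fixture generator), each `(U_ns, U_s)` grid point is solved with warm
starts and classified from three radii-of-gyration families (whole
chain, per block, per state) relative to the zero-interaction reference
(`U_ns = U_s = 0`, crumpling kept), plus the checkerboard contrast
(mean same-state inter-block contact probability minus mean cross-state):

* *coil* — no unit collapsed; *globule* — whole chain collapsed, low
  contrast; *intermediate* — blocks (TADs) formed, same-state
  aggregates not collapsed / contrast moderate; *microphase* —
  same-state radii collapsed, high contrast.

Whole-chain and per-state collapse mean `R_g²` below θ = 0.5 of the
zero-interaction value. Block (TAD) formation needs a different
control: on a strongly repulsive backbone the blocks compact markedly
relative to *that backbone* while staying above any fixed fraction of
the crumpled reference, so the block signature is the mean per-block
`R_g²` ratio against the same-`U_ns`, `U_s = 0` solve. Its threshold,
like the contrast threshold separating microphase from intermediate,
is anchored at run time to the midpoints of the exemplar regimes
(contrast: `(1, −3.4)` vs `(3, −3.4)`; block ratio: `(3, −1)` vs
`(3, −3.4)`), tying the operational boundaries to the model's own
behaviour on the chain at hand rather than to arbitrary constants.
Because a single cold solve can land on the wrong branch where strong
specific attraction competes with non-specific repulsion, exemplar
points and sweep columns follow the adiabatic branch in `U_s` from 0
with warm starts.

## Interaction inference

Given a contact map and a TAD partition, the specific interaction is
blockwise constant, `U_s(i,j) = V[A(i), A(j)]`, and the `T(T+1)/2` free
amplitudes are fitted by coordinate-wise finite-difference descent with
backtracking (box `[−5, 5] k_BT`; convergence when the relative
objective change stays below `1e-4` for 5 sweeps). Every forward
evaluation is a stationary solve warm-started from the current best
state, so sweeps after the first are cheap. Pairs with `|i−j| ≤ 1` and
masked (zero-coverage) bins are excluded.

Two objectives are provided. For probability-scale maps, the weighted
least-squares form `χ² = Σ (P_model − P_exp)²/σ²` with
`σ = max(P_exp, 1e-4)`. For count-derived maps the Poisson deviance of
the implied counts is used instead: least squares with observed-based
weights is systematically biased low wherever expected counts are
small (zero-count pairs pull the fit toward maximal repulsion), while
the deviance handles zeros exactly. A small ridge on the *off-diagonal*
(inter-TAD) amplitudes (default 5 deviance units per k_BT²) restores a
usable gradient where saturated long-range repulsion flattens the data
term; intra-TAD amplitudes are unpenalised.

TAD calling, when no segmentation is supplied, is a deliberately simple
constrained agglomerative clustering: adjacent segments merge by
correlation distance between their mean log-contact profiles until the
smallest distance exceeds `linkage_threshold = 0.6`, and undersized
segments are absorbed into the more similar neighbour. It is meant for
maps with visible domain structure; production users with a preferred
caller supply their own BED.

## Living chromatin

Monomer states `e_i ∈ {−1, +1}` spread through 3D contacts
(`H_epi = −(J_e/N) Σ δ_ij e_i e_j`) while same-state attraction
(`−J_i (e_i e_j + 1)/2` at range `r_o`) feeds back into the fold. In the
mean-field mode the contact indicator is replaced by its annealed
average — the Gaussian contact probability `c_ij` of the current
stationary fold (self-coupling excluded) — and the magnetisations
follow damped updates `m_i ← tanh((J_e/N) Σ_j c_ij m_j)`, alternating
with GSC solves under the amplitudes implied by `m`, to joint
convergence. In the stochastic mode, Glauber single-spin-flip Monte
Carlo runs on discrete spins with couplings `(J_e/N) c_ij`, and the
fold (hence `c`) is refreshed every `structure_update_period` sweeps
from the current spin configuration; the global state `M = Σ e_i / N`
is recorded each sweep after burn-in, fully seeded.

The default region is `N = 100` beads (an insulated ~1 Mbp domain).
Above a critical spreading strength the region polarises into a
coherent (active or inactive) state: the histogram of `M` turns from
unimodal around 0 to bimodal near ±|M*|, and the boundary `J_e^c(J_i)`
— located as the first grid point whose converged `|M|` from a weakly
polarised init (`m_0 = 0.1`) exceeds 0.5 — decreases with `J_i`
(compaction concentrates contacts and helps spreading). At `J_i = 0`
the fold decouples and the bifurcation must match the linear-stability
condition `(J_e/N) λ_max(c) = 1`, which the tests verify against the
scan to one grid step.

## Synthetic data

The fixture generator emulates a simplified fly-like two-state
(active/null) segmentation: alternating blocks, geometric block lengths
with configurable mean (default 10 beads = 100 kbp, a typical fly TAD
scale) and minimum (truncation at the chain end never leaves a block
below the minimum), all seeded. Contact maps are forward-generated from
the model (so their "truth" is exact) and count noise is Poisson per
pair, `n_ij ~ Poisson(depth · P_ij)`, with `depth = 2000` expected
counts at a probability-1 contact by default — representative of
deeply sequenced 10-kb-bin maps — and an optional gamma-Poisson
overdispersion for robustness checks. What these fixtures do *not*
emulate: protocol coverage biases (a synthetic per-bin multiplier is
the supported test for the coverage normalisation), unmappable bins,
translocations, or inter-chromosomal contacts. Passing recovery tests
therefore demonstrate the estimator's correctness and noise behaviour,
not robustness to real Hi-C artefacts.

## Problem sizes used by the shipped checks

The test suite runs the homopolymer scan at `N = 1000` over
`U_ns ∈ [−2.6, −1.5]` (the collapse bracket), the calibration check at
`N = 600`, phase exemplars at `N = 130`, inference recovery on 20 one-megabase
genomes (`N = 100`, mean TAD 150 kbp), the living-chromatin properties
at `N = 100`, and
the Metropolis cross-check at `N = 16`. The acceptance script runs the
full `N = 1000` scan to −3.0 and the `N = 1000` calibration. These
sizes were chosen so a full run completes on a single CPU in well under
an hour while leaving every measured quantity at its plateau value
(checked by spot runs at larger sizes).

## Known limitations

* The Gaussian closure is variational, not exact: contact maps agree
  with direct simulation at the rank-correlation ~0.98 level for weak
  interactions, the coil-regime slope is 3ν = 1.8 rather than the SAW
  value ≈ 2.1 (see above), and fluctuation-dominated quantities
  (loop statistics, knotting) are outside its reach.
* Only stationary states are computed; no relaxational trajectories.
* The inference assumes block-constant interactions at the supplied TAD
  partition; boundary errors in the partition propagate into `V`.
* The mean-field living-chromatin mode replaces binary contacts by
  their annealed average; near the bifurcation this smooths the
  transition relative to the stochastic mode.
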