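# gscfold

Gaussian self-consistent (GSC) block-copolymer models of chromatin
folding: stationary states, contact-map observables, crumpling
calibration, copolymer phase diagrams, TAD-level interaction inference,
and a coupled epigenome–folding ("living chromatin") model.

## Who this is for

Researchers modelling 3D genome organisation at the 10-kbp scale who
want a fast, deterministic alternative to bead-spring molecular
dynamics: the GSC approximation replaces configurational sampling with
a self-consistent equation for the matrix of mean squared inter-monomer
distances, so a 10-Mbp chain solves in seconds to minutes on one CPU,
and every downstream observable (contact map, P_c(s) scaling, radii of
gyration) is a closed-form function of that matrix.

## The model in brief

A chain of N beads (10 kbp each; energies in k_BT, lengths in bead
diameters l) with Hamiltonian

    H = (k/2) Σ r²_{i,i+1}                           bonds, k = 3
      + Σ U_ev exp(-r²_ij/(2 r_e²))                  excluded volume, U_ev = 10, r_e = 0.3
      + Σ U_ij  exp(-r²_ij/(2 r_o²))                 interactions, r_o = 0.5

where U_ij can contain a non-specific amplitude U_ns, a
genomic-distance-dependent crumpling amplitude U_crumpling(|i-j|), and a
chromatin-state-specific amplitude U_s(e_i, e_j). Under the Gaussian
ansatz the chain is an effective harmonic network with couplings
J(D), and the stationary distance matrix D solves

    0 = 4 k_BT − Σ_k (J_ik − J_jk)(D_ik − D_jk).

Contact probabilities, their sequence-averaged decay P_c(s) and its
log–log slope (s⁻² coil, s⁻³ᐟ² theta, plateau globule, s⁻¹ crumpled),
and whole-chain / per-domain / per-state radii of gyration all follow
from D. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from gscfold import (ChainModel, PolymerParams, SolverSettings,
                     solve_stationary, contact_probability,
                     mean_contact_curve, fit_scaling_exponent,
                     radius_of_gyration)

# a 2-Mbp homopolymer just on the coil side of the collapse
model = ChainModel(params=PolymerParams(N=200, U_ns=-1.9))
res = solve_stationary(model, SolverSettings())
print(f"converged={res.converged} after {res.iterations} iterations, "
      f"max residual {res.residual_max:.1e} k_BT")

curve = mean_contact_curve(contact_probability(res.D, r_c=1.0))
fit = fit_scaling_exponent(curve, s_min=10, s_max=60)
print(f"P_c(s) ~ s^{fit.exponent:.2f} (+- {fit.stderr:.3f}), "
      f"R_g = {radius_of_gyration(res.D):.2f} l")
```

prints

    converged=True after 35 iterations, max residual 9.4e-05 k_BT
    P_c(s) ~ s^-1.74 (+- 0.000), R_g = 5.80 l

i.e. the chain reaches a stationary state whose contact decay is
coil-like (slope ≈ −1.8; slightly shallower here because a 200-bead
window mixes in the crossover) and whose radius of gyration (~6 bead
diameters for 200 beads) is far from the collapsed value — at
U_ns = −2.5 the same chain returns R_g ≈ 1.2 l and a flat contact
decay.

The same workflow is scriptable from the shell:

    gscfold solve -N 200 --u-ns -1.9 -o run
    gscfold observables run.D.tsv -o run.obs
    gscfold make-fixtures -N 60 --u-inactive -0.4 -o fixtures/
    gscfold infer fixtures/counts.tsv --u-ns 0 --bed fixtures/segmentation.bed -o fit

Subcommands: `solve`, `observables`, `calibrate-crumpling`,
`phase-diagram`, `infer`, `living-chromatin`, `make-fixtures`.
Exit codes: 0 success, 2 malformed input, 3 non-convergence.

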