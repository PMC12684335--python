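# Methods

This note documents the models implemented in `nmrkin`, their assumptions,
the defaults that matter, and the design choices made where several
reasonable options existed.  Nothing here reports an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Model-free relaxation and τ_c estimation (`nmrkin.relax`)

Backbone amide dynamics are described by the Lipari–Szabo spectral density

    J(ω) = (2/5) [ S² τ_c / (1 + (ω τ_c)²) + (1 − S²) τ′ / (1 + (ω τ′)²) ],
    1/τ′ = 1/τ_c + 1/τ_e,

assuming isotropic overall tumbling (a single τ_c) and a single internal
motion.  ¹⁵N R₁, R₂ and hetNOE follow from the standard dipolar + CSA
expressions with J evaluated at {0, ω_N, ω_H−ω_N, ω_H, ω_H+ω_N}.  Physical
constants: γ_H = 2.6752218744×10⁸, γ_N = −2.7126×10⁷ rad s⁻¹ T⁻¹ (the
negative ¹⁵N gyromagnetic ratio is carried throughout; spectral densities
only see |ω|).  Bond length r_NH = 1.02 Å and CSA Δσ = −172 ppm are the
community defaults for backbone amides; both are parameters of
`MotionParams`.

τ_c is estimated by numerically inverting the rigid-rotor (S² = 1, τ_e = 0)
R₂/R₁ ratio per residue — the ratio is strictly increasing in τ_c, so
bisection on [0.1, 100] ns is exact — after two filters:

1. residues with hetNOE below 0.7 are excluded (large-amplitude fast motion
   invalidates the rigid inversion); note the ratio itself is independent
   of S² when τ_e = 0, so moderate rigidity violations are benign;
2. the surviving per-residue τ_c values are trimmed to median ± 1.5·IQR,
   rejecting residues whose R₂ carries exchange contributions.

The trimming rule is this package's convention; which residues real
studies exclude is rarely reported, so the rule is explicit and
configurable.  The τ_c uncertainty is a Monte-Carlo estimate (default
1000 resamples of R₁/R₂ within their stated errors, fixed seed).

Screening statistics use strict inequalities: hetNOE < 0.7 flags fast
ps–ns motion, R₁·R₂ > 20 s⁻² flags µs–ms exchange (the product cancels the
tumbling-anisotropy sensitivity of R₂ alone).  CSPs use the conventional
amide weighting Δδ = √(Δδ_H² + (0.14 Δδ_N)²).

## CPMG dispersion (`nmrkin.cpmg`)

Convention: ν_CPMG = 1/(4 τ_cp); one echo element is [τ_cp–180°–τ_cp]
(duration 2τ_cp); an integer number N of echo elements fills the
constant-time relaxation period T_relax (default 40 ms, a common
experimental choice), so valid ν_CPMG are multiples of 1/(2 T_relax) =
12.5 Hz; off-grid requests snap to the nearest valid point with a warning.
180° pulses are ideal (instantaneous complex conjugation); off-resonance
effects, pulse imperfections and multiple-quantum pathways are not
modelled, and ¹³C methyl data are treated with the same single-quantum
machinery.

**Two-site closed form.**  `cr_r2eff` implements the Carver–Richards
expression for equal intrinsic R₂ under the major-state convention
(p_A ≥ 0.5, Δω ≥ 0, k_ex = k_AB + k_BA).  The cosh argument grows like
1/ν_CPMG; above η = 30 the arccosh(D₊ cosh η₊ − D₋ cos η₋) combination is
evaluated in its log-asymptotic form, so slow pulsing never overflows.
k_ex is labelled rad·s⁻¹, following the labelling convention common in
dispersion work, and is treated numerically as an s⁻¹ magnitude; note the
R_ex flag threshold of 5 is likewise applied to R₂,eff differences in
s⁻¹ (conventions that quote "5 Hz" and "5 rad·s⁻¹" for this threshold
differ by 2π; this package uses the s⁻¹ reading consistently).

**N-site Bloch–McConnell.**  `bm_r2eff` evolves one complex transverse
component per state, M(0) = π, under A = Kᵀ + iΩ − diag(R₂); each echo is
M → U·conj(U·M) with U = exp(A τ_cp) (computed by eigendecomposition with
a scaling-and-squaring fallback; two echoes form a linear map, so long
trains use matrix powers).  R₂,eff = −ln(|ΣM(T_relax)|/|ΣM(0)|)/T_relax.

**Two definitions of R₂,eff.**  The closed form is exactly the
dominant-eigenvalue decay rate of the two-echo propagator (`bm_r2eff_rate`
computes this rate numerically; the two routes agree to ~10⁻¹² across the
exchange-parameter space, which is the package's forward-model
cross-validation).  The finite-T_relax signal definition additionally
contains an O(1/T_relax) initial-condition transient — the magnetization
starts population-distributed rather than in the decaying eigenmode —
which is significant in deep slow exchange (up to tens of percent at
p_A ≈ 0.6, k_ex ≈ 100 s⁻¹, Δω ≈ 4 ppm) and is genuine physics of
constant-time experiments, not an implementation disagreement.  Fitting
uses the closed form; network-level prediction and augmentation use the
finite-time definition consistently for both data generation and fitting.
A related caveat: at slow pulsing with large Δω the dispersion curve shows
genuine refocusing oscillations (the cos η₋ term), so R₂,eff is strictly
non-increasing in ν_CPMG only once pulsing outruns the shift difference.

**Fitting.**  Weighted least squares, Δω (ppm) shared across fields, one
R₂⁰ per field; 20 seeded multistarts over a (p_A, log k_ex, Δω) grid;
model selection against a flat (no-exchange) model by AICc with ties
breaking to the flat model; parameter uncertainties from resampling points
with replacement (200 refits, 95% percentile intervals).  Points with
σ = 0 (noiseless synthetic data) receive unit weight.  R_ex is the model's
ν→0 limit minus its fast-pulsing asymptote (closed form for two-site fits;
a 1/(2 T_relax) vs 10 kHz numerical difference for networks), flagged
strictly above 5 s⁻¹.

## Markov state models and augmentation (`nmrkin.msm`)

Transition counts use the sliding window at a user-chosen lag (no
automatic lag selection; `implied_timescales` provides the plateau
diagnostic).  Reversible maximum-likelihood estimation uses the symmetric
flux fixed point x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j); because the
update preserves symmetry of x, the returned model satisfies detailed
balance to machine precision by construction.  Disconnected counts are
restricted to the largest strongly connected component with a warning.

Coarse-graining follows the PCCA idea: the n leading right eigenvectors of
the reversible transition matrix (computed through the π-symmetrized form,
so the spectrum is real) span a simplex whose vertices are located by
farthest-point deflation; memberships are the linear barycentric
coordinates, clipped and renormalized; reporting uses the crisp argmax
while fuzzy memberships stay available.  Rates come from the matrix
logarithm of the transition matrix divided by the lag time, with negative
off-diagonals clipped and diagonals repaired (a validity report records
how much was clipped).  When fast intra-macrostate mixing pushes
microstate eigenvalues below zero at the chosen lag, the generator of the
coarse-grained transition matrix is used instead, with a warning.

**Experiment-augmented network.**  Basin-limited sampling leaves mutually
disconnected blocks of states; the inter-block exchange rates are
unobservable in simulation but imprinted on CPMG data.
`augment_with_experiment` assembles all blocks' macrostates into one rate
matrix whose free parameters are (log) inter-block rates plus penalized
deviations of the intra-block rates from their simulation estimates, and
one exchange-free R₂ per field:

    objective = Σ_points ((R₂,eff^obs − R₂,eff^BM(K))/σ)²
              + λ Σ_intra (log k_ij − log k_ij^sim)².

Populations are the stationary distribution of the assembled K, which is
how the global population balance across blocks is re-established.  λ
defaults to 1 (equal weighting of the kinetic prior and the data misfit in
the absence of guidance); bounded, seeded multistart optimization
(default 8 starts, log-uniform inter-rate initializations).  Per-state
chemical-shift offsets may be supplied per residue or fitted jointly
(bounded ±6 ppm, first state pinned at 0 ppm per residue since an overall
reference shift is unobservable).  The edge set defaults to every ordered
cross-block pair; a known topology can be passed explicitly, and the
synthetic study's manifest declares its chain topology
(open ↔ partially-closed ↔ fully-closed) for exactly that purpose.  The
reported perturbation is Σ(log k − log k^sim)²; the diagnostics include
the best pre-optimization χ², so the no-worsening property is checkable.

## Ensemble observables (`nmrkin.observables`)

S² = (3/2) Σ_ab ⟨e_a e_b⟩² − 1/2 over normalized bond vectors, averaged
over the full trajectory (no time-windowing).  Vectors are assumed
expressed in a molecule-fixed frame; removing overall tumbling by
superposing frames on a rigid-core selection (via `nmrkin.structure`) is
the documented preprocessing path — the alignment selection is a user
choice.  NOE distances use ⟨r⁻⁶⟩^(−1/6); methyl pairs are measured to the
geometric centre of the two methyl carbons; NOE visibility is inclusive at
the 10 Å methyl–methyl cutoff.  Distance histograms are normalized
densities on user bins.

## Structure comparison (`nmrkin.structure`)

PDB/mmCIF reading via gemmi into a flat atom table (PDB v3 atom names).
Altloc policy: per (chain, residue, atom) keep the highest-occupancy
conformer, ties breaking alphabetically (blank beats 'A' beats 'B');
insertion codes are rejected.  Superposition is the SVD (Kabsch)
least-squares rotation with the determinant correction excluding
reflections; atoms are matched by (chain, author residue number, atom
name).  The shipped 58-Cα β-barrel fitting frame is constructed from the
strand segments lying between the variable loops (L1 38–51, L2 70–76,
L3 95–105, L4 125–132); the exact strand list is not published, so the
selection file is an explicit, overridable approximation, and Å-valued
results quoted against it carry a few-tenths-Å selection sensitivity.

## Synthetic study design (`nmrkin.synth`)

The generators emulate the inputs of a loop-gated ligand-binding study at
realistic scale; they do not emulate spectrometer artefacts (peak shapes,
ring-current shifts, pulse imperfections) or force-field physics, so
passing tests demonstrate correctness of the analysis chain, not fidelity
to any particular instrument.

Planted conditions: a three-state loop-exchange network with populations
(3%, 40%, 57%) for (binding-competent open, partially closed, fully
closed), chain topology, detailed-balanced rates built from total exchange
rates of 800 rad/s (open↔partial) and 700 rad/s (partial↔closed) — a rare
binding-competent state exchanging in the fast-millisecond regime.
Four loop reporter residues carry state offsets of 0–3 ppm chosen so the
open state is well separated while the two closed forms differ slightly.
Dispersion curves are generated at 600 and 950 MHz on a 25–1000 Hz
ν_CPMG grid (multiples of 12.5 Hz, commensurate with T_relax = 40 ms) with
Gaussian noise σ = 0.3 s⁻¹, typical of good dispersion data.  Relaxation
tables use τ_c = 13.24 ns (free) and 13.06 ns (bound) with 2% noise over
165 residues.  The ligand-bound arm replaces the network with a single
state (exchange quenched).

Simulation blocks delete the open↔closed-ensemble transitions —
emulating trajectories that never cross the slowest barrier — and split
each macrostate into two microstates with fast (10⁴ s⁻¹) internal
exchange; blocks are sampled as exact (Gillespie) jump processes observed
every 2 µs for 2×10⁵ (incompetent) and 5×10⁴ (competent) frames, sizes
chosen so intra-block kinetics are well determined (~100 sampled
partial↔closed transitions) while inter-block kinetics remain strictly
unobserved.  MSMs use lag 10 frames.  A single study seed fans out to
per-generator substreams (CRC-keyed child seeds), so any part regenerates
bit-identically.

## Known limitations

* Isotropic tumbling only; no anisotropic diffusion tensors, and no full
  per-residue model-free fitting (S², τ_e, R_ex jointly).
* Two-site closed-form fitting is per residue; no grouped/global fits.
* The finite-T_relax vs dominant-rate distinction above means closed-form
  fits of deeply slow exchange carry a model-definition bias that real
  studies share.
* PCCA memberships use the crisp argmax for rate projection; degenerate
  spectra (twin metastable blocks) can make a requested coarse-graining
  ill-posed (warned, and an error if a macrostate empties).
* The structural fitting frame is an approximation (see above); measured
  loop values on real structures are selection-sensitive at the ±0.3 Å
  level.
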