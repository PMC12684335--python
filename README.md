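# nmrkin

Quantifying protein conformational exchange by integrating solution-NMR
relaxation data with simulation-derived Markov state models.

Engineered lipocalins (anticalins) recognise their ligands through four
structurally variable loops at the open end of an eight-stranded β-barrel.
When a loop gates the binding pocket — closed in the free protein, displaced
in the complex — the binding mechanism hinges on µs–ms conformational
exchange that neither crystal structures nor unconverged MD trajectories can
quantify alone. `nmrkin` implements the complete quantitative workflow for
this problem, for NMR spectroscopists and computational biophysicists:

* **Fast (ps–ns) dynamics** — model-free (Lipari–Szabo) spectral densities
  J(ω), prediction of ¹⁵N R₁/R₂/hetNOE, rotational correlation time τ_c
  from R₂/R₁, and the screening statistics hetNOE < 0.7 (fast motion) and
  R₁·R₂ > 20 s⁻² (slow exchange), plus amide chemical-shift perturbations
  Δδ = √(Δδ_H² + (0.14·Δδ_N)²).
* **Slow (µs–ms) dynamics** — CPMG relaxation dispersion R₂,eff(ν_CPMG) at
  two static fields, fitted with the Carver–Richards two-site closed form
  against a no-exchange alternative (AICc selection), with exchange
  contributions flagged at R_ex > 5 s⁻¹; an N-site Bloch–McConnell echo
  propagator generalises the forward model to arbitrary kinetic networks.
* **Experiment-augmented kinetics** — reversible Markov state models
  estimated from discrete trajectories, PCCA-style coarse-graining to a few
  metastable states, and reconciliation of mutually *disconnected*
  simulation blocks with experimental dispersion data: the missing
  inter-block exchange rates are fitted while intra-block rates stay close
  to their simulation estimates through a log-space penalty

      min_K  χ²_exp(K) + λ Σ_intra (log k_ij − log k_ij^sim)²,

  yielding a single kinetic network (populations + rates in rad·s⁻¹) that
  is the smallest perturbation of the simulation consistent with the data.
* **Ensemble observables and structures** — S² order parameters from
  bond-vector series, ⟨r⁻⁶⟩^(−1/6) NOE distances, distance histograms,
  Kabsch superposition on a β-barrel Cα core, per-residue deviations and
  loop RMSDs.

A seeded synthetic-data module generates every input the pipeline consumes
(dispersion curves from planted exchange networks, relaxation tables at a
planted τ_c, jump trajectories, bond-vector wobble, toy structure pairs)
with machine-readable ground truth, so the whole workflow is testable
without any experimental download.

## Worked example

```python
import numpy as np
from nmrkin import cpmg, msm, synth
from nmrkin.relax import estimate_tau_c

study = synth.make_study_bundle(synth.GeneratorConfig(seed=20250101))

est = estimate_tau_c(study.relaxation["apo"][950.0], seed=1)
print(f"tau_c (apo, 950 MHz): {est.tau_c_ns:.2f} +/- {est.sigma_ns:.2f} ns  "
      f"(n={est.n_used})")

rec = cpmg.analyze_residue(study.curves_for("apo", 96), n_bootstrap=0)
print(f"residue 96: model={rec['model']}  pA={rec['pA']:.3f}  "
      f"kex={rec['kex_rad_s']:.0f} rad/s  dw={rec['dw_ppm']:.2f} ppm  "
      f"Rex(950)={rec['rex_by_field'][950.0]:.1f} s^-1")

offsets = {int(r): np.array(o) for r, o in study.manifest["offsets_ppm"].items()}
edges = [tuple(e) for e in study.manifest["network"]["inter_block_edges"]]
aug = msm.augment_with_experiment(study.blocks, study.block_macros,
                                  study.dispersion["apo"], offsets,
                                  inter_edges=edges, seed=1,
                                  state_names=synth.STATE_NAMES)
pops = ", ".join(f"{n}={100*p:.1f}%"
                 for n, p in zip(synth.STATE_NAMES, aug.network.populations))
print(f"augmented network populations: {pops}")
print(f"open->partial rate: {aug.network.K[0, 1]:.0f} rad/s   "
      f"chi2/point: {aug.chi2/96:.2f}")
```

prints

```
tau_c (apo, 950 MHz): 13.25 +/- 0.02 ns  (n=159)
residue 96: model=exchange  pA=0.960  kex=753 rad/s  dw=2.35 ppm  Rex(950)=24.3 s^-1
augmented network populations: open=3.0%, partial=38.6%, closed=58.4%
open->partial rate: 736 rad/s   chi2/point: 0.91
```

The ligand-free arm's loop reporters all fit the exchange model with
R_ex well above the 5 s⁻¹ threshold, while the ligand-bound arm is flat —
exchange quenched by binding.  The augmentation, given only two
basin-limited trajectory blocks (which never sample the open↔closed
transition) plus the two-field dispersion curves, recovers the planted
three-state network: a ~3% binding-competent state exchanging at hundreds
of rad·s⁻¹ with the dominant (~97%) binding-incompetent pair.

The same operations are available from a thin CLI:

```sh
nmrkin simulate --out study --seed 20250101
nmrkin tauc study/relax_apo_950.tsv
nmrkin fit-dispersion study/dispersion_apo.tsv --n-bootstrap 0
nmrkin augment --study study --out network.json
nmrkin compare-structures --ref apo.pdb --mobile bound.pdb --report-loops
```

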