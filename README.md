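# memorient

Orientational kinetics of membrane-anchored proteins from coarse-grained
trajectories: Markov state models, hidden Markov macrostate kinetics and
free-energy estimators for tilt/rotation order parameters.

## The problem

Lipid-anchored GTPases such as KRAS4b sit on the inner leaflet of the plasma
membrane with their globular G-domain tethered by a disordered linker and a
lipidated anchor. The G-domain reorients continuously between a small number
of metastable poses — an *exposed* state with the effector-binding site
facing solvent, an *occluded* state pressed against anionic lipids, and
short-lived membrane-detached transition states. Which pose dominates, and
how fast the protein exchanges between poses, controls effector access and
is modulated by lipid composition and nucleotide state.

Two angles capture the pose: the **tilt** θt of the G-domain body axis away
from the bilayer normal (the box *z* axis), and the **rotation** θr, the
azimuth of the membrane normal in the protein body frame. This package
provides the complete analysis chain from coordinates or angle tables to
state populations, exchange rates and free-energy surfaces:

1. **Order parameters** — θt/θr per frame, G-domain COM height above the
   bilayer midplane, normalized residue–lipid contact profiles (0.55 nm
   cutoff), lateral radial distribution functions and mean-square
   displacement, and the preferential lipid partitioning constant
   *P*ₐ = (*C*ₐ/*n*ₐ) / Σₓ(*C*ₓ/*n*ₓ).
2. **Markov state model** — k-means discretization of (θt, θr) into 400
   microstates (periodic-safe embedding of θr), sliding-window transition
   counts at a lag τ (450 ns by default, where implied timescales
   *t*ᵢ = −τ/ln λᵢ plateau), reversible maximum-likelihood transition
   matrix, and PCCA+ coarse-graining into M metastable states selected from
   the largest timescale gap.
3. **Hidden Markov model** — Baum–Welch estimation of the M-state hidden
   chain over microstate observations; stationary populations π from the
   left Perron eigenvector of the hidden transition matrix A, and rates
   *K*ᵢⱼ = *A*ᵢⱼ/τ (first-order) or log *A*/τ (generator estimate).
4. **Free energy** — Boltzmann histograms −k_BT ln(H/H_max) over a 70×70
   angle grid; WHAM for harmonic umbrella windows with three-block
   convergence assessment; well-tempered metadynamics bias accounting
   (height rule W = W₀ exp(−V/k_BΔT), bias factor γ = (T+ΔT)/T) and the
   parallel-tempering exchange rule corrected for the bias potentials.
5. **Synthetic generator** — exact continuous-time Markov jump processes
   with Gaussian angle emissions, rigid bead fixtures, exact biased
   umbrella sampling, an overdamped Langevin toy engine and planar lipid
   fields, so the whole pipeline is testable against known ground truth.

## Worked example

Recover the kinetics of the 2-state zwitterionic-membrane system from
synthetic trajectories (10 replicas × 2 ms at 15 ns stride, exposed state
occupying 91% of the stationary distribution, decay rate 0.0143 μs⁻¹):

```python
import numpy as np
from memorient import popc_scheme, popc_emission_spec, recover_from_scheme

result = recover_from_scheme(popc_scheme(), popc_emission_spec(),
                             duration_us=2000.0, n_replicas=10,
                             stride_ns=15.0, n_macrostates=2, seed=1)
print("populations:", np.round(result["populations_by_basin"], 3))
print("k(exposed->non-specific): %.4f /us"
      % result["rates_ratio_by_basin"][1, 0])
```

prints

```
populations: [0.091 0.909]
k(exposed->non-specific): 0.0143 /us
```

i.e. the pipeline (k-means → reversible MSM at 450 ns lag → PCCA+ →
Baum–Welch HMM) recovers the generator's 9/91 split and the 0.0143 μs⁻¹
slow rate from the angle trajectories alone. The same machinery is exposed
as a CLI:

```bash
memorient simulate --scheme anionic-gtp --duration-us 5000 --seed 1 --out run/
memorient msm run/orientation.tsv --n-microstates 400 --lag-ns 450
memorient analyze --config config.yaml --out run/
```

`memorient validate config.yaml` lists every defaulted parameter
(400 microstates, 450 ns lag, 70×70 bins, 0.55 nm cutoff, 310 K).

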