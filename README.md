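# hydrashell

Analysis of the first hydration shell of heavy divalent cations (Ra²⁺, Ba²⁺ and
kin) in molecular-dynamics trajectories, together with single-shell EXAFS
cumulant fitting.  Written for researchers who have AIMD or classical MD
trajectories of one ion in water and want the standard structural and dynamical
observables, and for EXAFS practitioners who fit extracted χ(k) oscillations to
a one-shell cumulant model.

## What it computes

**Structure** — the ion-centred radial distribution function g(r) with its
running integration number N(r); the first-shell boundary at the first minimum
of g(r); the coordination number CN and its histogram; the distance cumulants

- r̄ = ⟨r_M–O⟩, the mean ion–oxygen distance,
- σ² = ⟨(r_M–O − r̄)²⟩, the Debye–Waller-type second cumulant,
- C3 = ⟨(r_M–O − r̄)³⟩, the third cumulant (shell asymmetry);

the shell eccentricity ε = ⟨|r_M − r_CM|⟩ (mean distance from the ion to the
centre of mass of its shell waters — larger means a less symmetric shell); the
tilt angle ψ between each shell water's dipole direction and its O→ion vector,
with the distribution P(cos ψ); and the effective water radius r̄ − EIR
(ion–oxygen distance minus the cation's effective ionic radius).

**Dynamics** — water-exchange events and the "direct"-method mean residence
time

    MRT(t*) = t_samp · CN_av / N_ex(t*)

where N_ex(t*) counts boundary crossings whose neighbouring states both persist
longer than the threshold t* (t* = 0 counts every crossing; t* ≈ 0.5 ps
filters transient re-crossings), plus the lifetime spectrum of each
coordination number with optional bridging of short excursions.

**EXAFS** — a single-shell cumulant-expansion forward model

    χ(k) = S0²·CN·F(k')/(k'R²)·e^(−2k'²σ²)·e^(−2R/λ(k'))·sin(2k'R + φ(k') − (4/3)C3k'³),
    k' = √(k² − 0.2625·ΔE0)

with amplitude F and phase φ interpolated from a backscattering table,
Fourier filtering of k³χ through an R-space window, and weighted
least-squares fitting of (CN, R, σ², C3, ΔE0) with the residual factor
Rf = Σ(k³χ_data − k³χ_fit)² / Σ(k³χ_data)² × 100.

**Synthetic data** — every input with known ground truth: a two-state Markov
model of shell occupancy (the oracle for the residence-time estimator),
geometric shell constructions with controlled radius/tilt/offset, a small
Langevin toy simulator (flexible SPC-like water + LJ/Coulomb divalent ion)
that exercises the whole pipeline end-to-end, and synthetic χ(k) spectra.

## Worked example

```python
import numpy as np
from hydrashell import (
    assign_water_topology, compute_rdf, find_first_minimum, shell_occupancy,
    distance_cumulants, eccentricity, tilt_angle_distribution, mrt_direct,
)
from hydrashell.synthetic import (
    MarkovShellModel, gen_markov_occupancy, gen_shell_fixture,
)

# a jittered 8-water shell at 2.88 Å plus 20 outer waters, 80 frames / 50 fs
traj = gen_shell_fixture(n_shell=8, r_shell=2.88, jitter=0.06,
                         tilt_deg=132.0, tilt_spread_deg=15.0,
                         n_frames=80, n_outer=20, seed=31)
topo = assign_water_topology(traj)
rdf = compute_rdf(traj, "O", bin_width=0.02)
shell = find_first_minimum(rdf)
series = shell_occupancy(traj, topo, shell)
r_bar, sigma2, c3 = distance_cumulants(traj, topo, series)
psi, _, _ = tilt_angle_distribution(traj, topo, series)

# residence time on a stochastic exchange model (true dwell 1/k_out = 4 ps)
model = MarkovShellModel(n_waters=256, k_out=0.25, k_in=0.0,
                         dt=50.0, span=200.0, seed=1)
occupancy, truth = gen_markov_occupancy(model)
res = mrt_direct(occupancy, t_star=0.0)
```

prints (via the obvious f-strings):

```
shell boundary : 3.11 A
mean CN        : 8.0
r_bar          : 2.88 A
sigma^2        : 0.0035 A^2
tilt mean      : 132 deg
eccentricity   : 0.05 A
N_ex           : 256 (generator logged 256)
MRT(t*=0)      : 3.94 ps (true dwell 4 ps)
```

The detected boundary sits in the empty region between the constructed shell
and the outer waters; the recovered r̄, CN, tilt mean and σ² match the
generator's ground truth, and the direct-method MRT recovers the Markov
model's true 4 ps dwell from its 256 logged exchange events.

The same pipeline runs from the shell: `hydrashell analyze --config run.yaml`
writes `rdf.tsv`, `shell.json`, `dynamics.json` and a run manifest;
`hydrashell dynamics`, `hydrashell exafs fit` and `hydrashell synth
{markov,toymd,exafs}` expose the individual stages.

## Layout

- `src/hydrashell/trajectory_io.py` — extended-XYZ / XDATCAR readers and
  writers, periodic cells, minimum image, water topology
- `src/hydrashell/shell_structure.py` — g(r), N(r), shell boundary, CN,
  cumulants, eccentricity, tilt angles
- `src/hydrashell/shell_dynamics.py` — exchange events, direct-method MRT,
  CN lifetimes, ion comparison
- `src/hydrashell/exafs.py` — scattering tables, cumulant forward model,
  Fourier filter, single-shell fit
- `src/hydrashell/synthetic.py` — Markov occupancy, shell constructions,
  toy Langevin MD, synthetic spectra
- `src/hydrashell/pipeline.py`, `cli.py` — YAML-configured pipeline, reports,
  command-line interface

See `docs/methods.md` for the models, conventions and numerical choices.
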