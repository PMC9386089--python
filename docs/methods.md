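# Methods

This note records the models implemented in `hydrashell`, the conventions and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the known limitations.

## Units, indexing, periodicity

Internal units are Å for lengths, fs for times (residence times are reported
in ps), degrees for reported angles.  Atom and frame indices are 0-based in
code; user-facing messages are 1-based.  Periodic displacements are wrapped in
fractional coordinates to the interval (−0.5, 0.5] with the exact boundary
assigned to +0.5; for orthorhombic cells this is the true nearest image for
any distance below half the smallest cell width, and all RDF and shell
operations refuse radii beyond that limit.  For strongly skewed triclinic
cells the fractional wrap is not guaranteed minimal near the limit; the
package targets the (near-)orthorhombic cells typical of ion-in-water
simulations.

Water covalent topology is assigned once, in frame 0, by giving every H to
its nearest O (minimum image, bond cutoff 1.25 Å default) and is frozen for
the whole trajectory: the analysis treats waters as intact molecules and does
not track dissociation, which matches ambient-condition ion–water
trajectories.

## Radial distribution and shell definition

g(r) is ion-centred and normalized by the ideal-gas expectation at number
density ρ = N_target/V using **exact** spherical-shell volumes
4π/3·(r_out³ − r_in³) rather than 4πr²Δr, removing the O(Δr²) bias at small
r.  N(r) is accumulated by direct cumulative pair counting, so
N(r_i) = Σ_{j≤i} ρ·V_shell(j)·g(j) holds to round-off by construction — the
mean coordination number read from N(r) at the boundary and the one computed
from per-frame shell membership are the same count through two routes.

The first-shell boundary is the first local minimum of a centred moving
average of g (default window 5 bins, odd) after the first peak exceeding
g = 1.5, ties broken toward smaller r.  If no peak exceeds 1.5 (structureless
g), the detector raises and a fixed boundary must be supplied.  The threshold
1.5 is a heuristic separating genuine shell peaks from ideal-gas noise; with
very sparsely sampled RDFs, Poisson noise in nearly empty small-r bins can in
principle exceed it, so production analyses should use well-sampled
trajectories or a fixed boundary.  Membership uses "distance ≤ boundary
counts as inside" so that the exchange statistics below have a deterministic
membership function.

Default RDF bin width is 0.02 Å (resolves a ~2.9 Å first peak), default
r_max = 0.49 × the smallest cell width.

## Distance cumulants, eccentricity, tilt

All moments use the population (1/N) convention — the time/ensemble average
read literally — not sample-corrected estimators.  By default all
(frame, member) ion–O distances are **pooled** before taking central moments;
a per-frame variant (second/third moments per frame about the pooled mean,
then time-averaged) is exposed for comparison since the two differ when CN
fluctuates.

Eccentricity ε is the time average, over frames with a non-empty shell, of
the distance between the ion and the centre of mass of all first-shell water
atoms (O = 15.999 u, H = 1.008 u), built from minimum-image displacements
relative to the ion so shells straddling the cell boundary are handled
correctly.

The tilt angle ψ of a shell water is the angle between its dipole direction —
the unit vector from O to the midpoint of its two H — and the unit vector
from O to the ion.  The reported mean is the arithmetic mean of ψ in degrees
(not arccos of the mean cosine; the two differ and the literature rarely says
which it reports).  The histogram is a normalized density over cos ψ, the
variable in which an isotropic orientation distribution is flat.  Waters
whose H-midpoint coincides with O within 1e-6 Å are skipped with a warning.

The effective water radius is the plain difference r̄ − EIR between the mean
ion–oxygen distance and the cation's effective ionic radius.

## Exchange events and the direct residence-time method

Each water's inside/outside membership string is run-length encoded.  A
boundary crossing is a **genuine exchange** at threshold t* iff the durations
of both the state left behind and the state entered strictly exceed t*.
Requiring persistence on both sides makes a short dip out-and-back count as
zero events (neither the exit nor the return is genuine — no exchange
happened), keeps N_ex(t*) non-increasing in t*, and is symmetric under time
reversal.  At t* = 0 every crossing counts.  Entries and exits both count
toward N_ex.  A state run of m frames has duration m·dt everywhere, including
runs truncated by the trajectory ends; this uniform convention makes a
crossing into a single final frame still count at t* = 0.

The direct-method estimator is MRT(t*) = t_samp·CN_av/N_ex(t*), with t_samp
the analyzed span (n_frames·dt) and CN_av the mean coordination number over
the same span; the identity MRT·N_ex = t_samp·CN_av holds to machine
precision, and N_ex = 0 yields "undefined", never infinity.  Interpreting the
estimator: t_samp·CN_av is the total water-residence time observed, so with
one-directional counting (e.g. pure decay of an initially full shell) MRT is
exactly the sample-mean dwell time and converges to 1/k_out on the Markov
model.  In a stationary exchanging system entries ≈ exits, so with both
directions counted the estimator converges to 1/(2·k_out) — half the true
dwell.  This factor is inherent to the both-directions convention (which the
printed residence-time tables this package mirrors also use) and is asserted
as such in the property tests.

CN lifetimes: the CN time series is segmented into maximal constant-CN
episodes; with bridging (default) excursions away from a value lasting ≤ t*
are filled before segmentation, so brief interruptions do not split an
episode.  Bridging applies to the CN value as a whole, not to per-molecule
identity; the unbridged variant is exposed (`bridged=False`).  Episode
duration is again m·dt.  Default thresholds are t* = 0 and 0.5 ps.

Rounding to printed precision (whole ps, with .5 rounding up) happens only in
the reporting layer; machine-readable output keeps full precision.

## EXAFS model, filtering, fitting

The single-shell cumulant forward model is

χ(k) = S0²·CN·F(k′)/(k′R²)·exp(−2k′²σ²)·[exp(−2R/λ(k′))]·sin(2k′R + φ(k′) − (4/3)C3k′³)

with k′ = √(k² − 0.2625·ΔE0) (0.2625 Å⁻²·eV⁻¹ = 2mₑ/ħ²); grid points where
k′² ≤ 0 are dropped.  F, φ (and λ when the table provides it) are linearly
interpolated at k′.  The mean-free-path factor is included only when λ(k) is
present, so σ² and C3 keep purely structural meaning otherwise.  χ is exactly
linear in S0²·CN, so only the product is identifiable: fits always fix S0²
(default 1.0) and let CN absorb the amplitude.

Fourier filtering works on k³χ, which is odd in k, so the natural transform
pair is the type-I discrete sine transform on the grid k_n = n·dk with
conjugate distances r_j = π·j/(2·n_fft·dk).  The spectrum is tapered over the
k window (Hanning ramps over 10% of the window at each edge), embedded in a
zero-padded sine basis, coefficients outside the R window are zeroed (an
exact orthogonal projection), and the back-transform is divided by the taper
(window compensation) over the original k window.  With a rectangular window
spanning the spectrum's own full grid and n_fft = len(k)+1 the whole
operation is a pure projection — applying it twice equals applying it once to
machine precision — which is how the projection property is tested.  With
tapering and zero-padding the filter is only approximately idempotent
(re-application truncates leakage outside the window); this is a property of
any windowed band-restriction, not of the implementation.

Fitting minimises the k³-weighted residual over the chosen k range with
`scipy.optimize.least_squares` (bounds: CN ∈ [0.05, 50], R ∈ [1, 6] Å,
σ² ∈ [0, 1] Å², C3 ∈ ±0.05 Å³, ΔE0 ∈ ±15 eV).  Because the 2kR phase makes
the misfit multimodal in (R, ΔE0), the optimizer starts from the best point
of a coarse grid over R = init ± 0.3 Å (step 0.05) × ΔE0 ∈ [−10, 10] eV
(step 2.5), solving CN linearly at each grid point.  Parameter uncertainties
are 1σ from the covariance at the optimum with the noise variance estimated
from the fit residuals; they describe the local quadratic approximation only
and no claim is made that they reproduce any particular legacy package's
error bars.  The residual factor is Rf = Σ(w·(χ_d − χ_f))²/Σ(w·χ_d)²·100
with w = k^k_weight (weight 3 by default).

## Synthetic generators

All generators draw from `numpy.random.default_rng(seed)` (PCG64) and are
byte-deterministic given the seed.

**Markov occupancy.**  Each of n molecules is an independent two-state chain;
per frame of length dt it flips with probability 1 − exp(−k·dt) (k = k_out
inside, k_in outside).  Stationary mean CN is n·k_in/(k_in+k_out); dwell
times are geometric with mean 1/(1−exp(−k·dt)) frames ≈ 1/k + dt/2, so dt
must be small against 1/k (a warning fires above k·dt = 0.1).  The generator
returns its own transition log, the exact oracle for event counting.  Initial
states are stationary draws; with k_in = 0 all molecules start inside (pure
decay), the configuration in which the direct MRT estimator is exactly the
mean dwell and recovers 1/k_out = 4 ps at the default rates.

**Shell constructions.**  Rigid waters (O–H 0.9572 Å, H–O–H 104.52°) are
placed at an exact radius on near-uniform (Fibonacci) or exactly octahedral
directions, with optional per-frame Gaussian jitter, a prescribed tilt-angle
law (normal in ψ, truncated to [0°, 180°], random azimuth), a rigid offset of
the whole shell (which displaces the shell centre of mass by exactly that
vector), and diffuse outer waters kept ≥ 2.2 Å apart so topology assignment
stays unambiguous.  These provide exact ground truth for r̄, CN, σ², ε and ψ.

**Toy Langevin MD.**  Flexible SPC-like water (q_O = −0.82, q_H = +0.41, LJ
on O with σ 3.166 Å / ε 0.65 kJ/mol, a small LJ site on H (σ 1.2 Å,
ε 0.065 kJ/mol) that prevents the intermolecular H···O Coulomb collapse a
flexible model is otherwise prone to, harmonic bonds k = 1000 kJ/mol/Å² at
1.0 Å and angle k = 150 kJ/mol/rad² at 104.52°) around one divalent LJ/
Coulomb cation.  Nonbonded interactions use a shifted-force cutoff
(min(6 Å, half-box); no Ewald) so forces are continuous at the cutoff.
Integration is velocity Verlet with a BAOAB-style Langevin thermostat
(friction in fs⁻¹); friction 0 gives plain microcanonical Verlet.  The bond
and angle stiffness are deliberately softer than spectroscopic water so that
dt = 0.5 fs integrates with negligible secular energy drift; a
capped-displacement relaxation removes initial overlaps before dynamics, and
any force above 1e5 kJ/mol/Å aborts with the offending step.  Momentum is
conserved exactly by construction (pairwise forces); "energy drift" in the
tests means the secular difference between the first and last 10% of the
run, the bounded symplectic oscillation being a separate, larger scale.
This simulator exists to exercise file I/O, geometry and statistics
end-to-end on physically shaped data.  It is **not** a surrogate for
first-principles water: its structure, exchange kinetics and thermodynamics
are those of a crude classical toy, so pipeline tests assert ranges (a first
shell of 6–10 waters) rather than literature values.

**Synthetic spectra.**  χ(k) from the forward model at known truth
parameters, plus Gaussian noise drawn in the k³-weighted domain scaled to a
stated fraction of the RMS of k³χ.  The backscattering table is analytic and
fixed (amplitude 2.8·(0.2+k²/4)/(1+(k/2.4)²)², phase 2.6 − 0.85k + 0.018k²,
λ = 3.5 + 0.9k), so spectra are reproducible anywhere without external
tables; it is a synthetic stand-in shaped like a heavy-backscatterer table,
not a computed one.

## What the tests show — and what they do not

Passing tests demonstrate that every estimator recovers the ground truth of
the synthetic models at the stated statistical tolerances (3 standard errors
for stochastic recoveries, machine precision for identities and round trips,
< 1% for the noiseless EXAFS round trip), and that the pipeline is a pure
function of (input bytes, config, seed).  They do not demonstrate anything
about real water around real ions: the synthetic trajectories lack
polarization, charge transfer, many-body effects, realistic exchange
pathways and second-shell structure, and the synthetic spectra lack
multiple-scattering paths, background-removal artifacts and correlated
experimental noise.  Statistical sizes were chosen so the full suite runs in
about a minute on one core: e.g. 200 ps Markov spans, a few thousand
toy-MD steps, 40–250-frame constructed shells.

## Known limitations

* Single solute per trajectory; no NPT (variable-cell) support; no binary
  trajectory formats.
* Exchange statistics assume uniformly spaced frames.
* EXAFS fitting is single-shell, single-scattering; multi-shell data must be
  Fourier-isolated first, and heavily overlapping shells will not isolate
  cleanly.
* The covariance-based fit uncertainties assume independent homoscedastic
  residuals; filtered spectra violate independence, so treat them as lower
  bounds.
* C3 is weakly determined over short k ranges (its phase term grows as k′³);
  freezing it (`fit_c3=False`) is often appropriate for noisy data.
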