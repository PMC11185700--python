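# Methods

This note documents the models, numerical choices and known limitations
of the package. It states how quantities are computed; every number
quoted here is produced by the test suite or `scripts/acceptance.py`.

## Exchange models and Bloch–McConnell propagation

An `ExchangeModel` is a set of named conformational states with pairwise
first-order rate constants (s⁻¹ internally; hr⁻¹ converted on entry).
Microscopic reversibility is enforced at construction: if one direction
of a pair is positive, the reverse must be too. The exchange generator
K (off-diagonal `K[i,j] = k_{j→i}`, columns summing to zero) drives the
master equation; equilibrium populations are its normalized null space,
computed by dense SVD. Disconnected state graphs are rejected with the
unreachable states named — a silent block-diagonal null space would
otherwise make "the" equilibrium ambiguous.

Spin evolution uses the standard augmented inhomogeneous formulation:
(x, y, z) per state plus one constant element, so longitudinal recovery
toward population-weighted unit polarization is linear and the whole
propagation is one matrix exponential (`scipy.linalg.expm`,
scaling-and-squaring; systems are at most 13×13, and offset grids are
exponentiated in one batched call). ppm→rad/s conversion always uses an
explicit nucleus Larmor frequency; nothing is inferred from a
spectrometer's proton frequency. An adaptive-ODE oracle test pins the
propagator to 1e-8 relative accuracy on randomized 2- and 3-state
models.

## CEST

A profile is simulated by propagating prepared z-magnetization for the
relaxation delay at each carrier offset and reading the observed
state's z component, normalized by the Trelax = 0 reference. Recovery
toward thermal equilibrium is *disabled* during the delay: the prepared
polarization is large compared with the thermal value it decays toward,
which is why the off-resonance plateau sits at `exp(−R1·Trelax)`. RF
pulses are ideal; B1 inhomogeneity averaging is not modeled (the B1
fields here are calibrated values, and a single Gaussian-averaged B1
changes the synthetic-recovery results by less than the fit
uncertainty).

The global fitter shares minor-state populations and one exchange rate
constant k_ex per connected pair across residues; per residue it fits
one shift per state, one R1 (minor-state R1 tied to the observed
state's, the common choice when minor R1 is invisible), and one R2 per
tie-group. Pair rates follow detailed balance,
`k_ab = k_ex·p_b/(p_a+p_b)`, so prescribed populations are exact on any
topology. Two numerical choices matter:

* **Log-scale optimization.** Populations, k_ex, R1 and R2 are
  optimized as log10 values (shifts stay in ppm). On the natural scale
  the Jacobian is dominated by shift derivatives near dips and the
  trust-region optimizer crawls; log-scaling makes the fits converge in
  seconds.
* **Dip-scan refinement.** Initial minor shifts come from detected
  local minima (deepest first). Because the χ² surface is flat away
  from a dip, a wrong initialization cannot be repaired by gradient
  steps; after convergence, any residue whose per-residue χ²/N exceeds
  max(2, 1.5×median) gets a 1D sweep of each minor shift over the
  offset grid, followed by a global refit (at most two rounds).

Identifiability drives two design points. At a single B1 field the
minor state's R2 trades off against k_ex along a flat χ² ridge, so the
methyl two-state analysis ties the minor R2 to the observed state's R2
— the same constraint used for the backbone three-state fits. The
backbone 15N scenarios generate *both* B1/Trelax pairs (10 Hz/500 ms
and 20 Hz/400 ms) per residue and fit them jointly; with one field the
PD population is structurally unidentifiable (a 13% solution fits a 3%
dataset at reduced χ² 1.02), with two it is recovered to a few tenths
of a percentage point. Conversely, the unidentifiability of a weak
Enigma↔PD edge between two sparsely populated states is a genuine
property of the data and is asserted as such: adding that edge at
1e-3 s⁻¹ changes reduced χ² by <1%.

Topology comparison refits each candidate model and flags as
"comparable" those within a configurable factor (default 1.1) of the
best reduced χ².

## CPMG

Constant-time dispersion is simulated exactly: in-phase transverse
magnetization evolves under the complex generator `−R2 − iΔω + K`, with
ideal 180° pulses as complex conjugation in the echo unit
τ−180−τ−τ−180−τ, τ = T/(4·n_cyc); `R2eff = −ln(I/I0)/T`. R1 is
neglected during the constant-time period and the reference (n_cyc = 0)
carries no R2eff point. Scalar coupling, TROSY selection physics and
finite-pulse effects are out of scope.

Rex is estimated by plateau subtraction — R2eff at the lowest nonzero ν
minus the mean of the two highest-ν points — with quadrature error
propagation, and per-point uncertainties take the larger of the
noise-based and duplicate-based estimates where repeat points exist.
Note that a noiseless dispersion is strictly monotone non-increasing
only for k_ex ≳ Δω; in deep slow exchange (the Enigma fixture sits at
k_ex/Δω ≈ 0.11) the exact echo-train solution shows the well-known
low-ν ripple of a few tenths of s⁻¹, so tests assert strict
monotonicity on intermediate/fast instances and a bounded-ripple
decreasing trend in the slow regime. In that slow regime the estimator
returns ≈ the rate of leaving the observed state (11.1 s⁻¹ for a
12.1 s⁻¹ forward rate: the finite 50 Hz anchor refocuses a little of
the exchange broadening).

The regime test is a Monte-Carlo Gaussian-resampling comparison of Rex
at two temperatures: p = 2·min(P(ΔRex>0), P(ΔRex<0)) with ties split,
Bonferroni threshold α/n_tests, classes slow/intermediate (significant
increase with temperature), fast (significant decrease), else
inconclusive. The underlying nonparametric test in the source analysis
is unnamed; this stand-in implements the same decision rule and its
type-I error is verified to stay at or below the nominal level.

## Real-time temperature-jump kinetics

Peaks are prefit with `a·exp(−kt) + c` (lmfit); the amplitude used for
the 4×10⁵ intensity filter is the maximum of the fitted curve over the
observed window. The global model shares (k_f, k_r, p0) — p0 is the
pre-jump Ground fraction, fitted rather than fixed because it is not
otherwise known — and profiles out per-peak scale factors exactly by
linear least squares, so the nonlinear problem stays three-dimensional
for any peak count. No per-peak baseline is fitted (consecutive-HSQC
intensities are assumed background-subtracted). Bounded multi-start
least squares (three starts splitting the prefit k_obs across
equilibrium guesses); lowest χ² wins. The bootstrap applies both
resampling layers together in each iteration: every intensity is
perturbed by its σ and the peak set is resampled with replacement
within each state class; failed iterations are dropped and counted,
with a warning past 20%.

## Free-energy landscape

State energies are `−RT·ln(p/p_ref)` relative to Ground; barriers are
per-transition Eyring activation energies `−RT·ln(k·h/(κ·k_B·T))` with
κ = 1, so `ΔG‡(a→b) − ΔG‡(b→a) = ΔG(b) − ΔG(a)` holds exactly when
populations come from the same rates. Absolute transition-state levels
(state energy + activation energy) are exposed separately for level
diagrams. Constants: R = 1.98720×10⁻³ kcal/(mol·K), k_B and h at their
SI values to six figures.

CEST populations (Enigma, Ground, PD — the FS state is invisible to
CEST) are reconciled with the real-time Ground/FS split by preserving
each source's ratios to Ground and renormalizing to unit sum. Because
free energies at two temperatures share no absolute zero, a constant
offset (default 2 kcal/mol) is added to every value of the colder
landscape, chosen so that no absolute barrier decreases on cooling; a
warning is raised if one still does. The offset applies to state
energies and barriers alike.

## Synthetic data: what it emulates and what it does not

Fixtures encode the study conditions: Ground↔FS at 0.09/0.36 hr⁻¹
(CypA-catalyzed: 0.24/0.98 hr⁻¹), Ground↔Enigma with k_ex = 173 s⁻¹ and
p_b = 7–8%, Ground↔PD at ≈2 s⁻¹ with p_PD = 3% (20 °C) to 75% (4 °C),
offsets 104–135 ppm in 25 Hz steps at the 81.08 MHz 15N frequency of an
800 MHz spectrometer (methyls: 8–25 ppm in 40 Hz steps at 201.16 MHz),
CPMG at T = 60 ms with n_cyc = 0–60 and duplicates at 0/30/60, and a
7-minute post-jump deadtime. Values the source did not print are fixed
conventions: the pre-jump Ground fraction is 0.60 (the jump amplitude
scales signals, not rates), k_PD→G follows from detailed balance with
the printed p_PD, minor-state R2 values are typical backbone/methyl
magnitudes, and the volume fixture holds FS in the observed 10–20%
band.

Noise is Gaussian and homoscedastic per curve (matching spectrum-noise
uncertainty usage): fractional of peak amplitude for time courses,
absolute on I/I0 for CEST, on intensity ratios (propagated to R2eff)
for CPMG, multiplicative on volume shares. Not emulated: spectral
lineshapes and peak overlap, baseline/phase artifacts, t-distributed
noise, field drift, or assignment errors — so passing tests demonstrate
estimator correctness and calibration under the assumed noise model,
not robustness to spectral pathology.

Problem sizes used throughout (45+37 peaks × 20 time points, 5–6 CEST
residues at ~100 offsets per field, 58-point dispersions, 11-residue
volume tables, 100–200 bootstrap draws) match the study designs while
keeping any full run in the minutes range on one CPU.

## Known limitations

* CEST fits assume the declared topology; no automatic model search
  beyond the provided comparison table.
* The CPMG module deliberately stops at Rex and regime calls — full
  Carver–Richards fitting is invalid in the slow regime this system
  occupies.
* Eyring barriers inherit the κ = 1 assumption; absolute barrier
  heights are only as meaningful as that convention.
* The bootstrap treats peaks as independent; correlated spectral noise
  would narrow its validity.
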