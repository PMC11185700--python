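# foldswitch-nmr

Multi-timescale NMR chemical-exchange kinetics for fold-switching
proteins, built around the four-state conformational landscape of the
circadian clock protein KaiB: a Ground fold, a fold-switched (FS,
binding-competent) state, a partially disordered (PD) state with an
unfolded C-terminus, and a β-strand register-shifted "Enigma" state.

The package is for NMR spectroscopists and kinetic modelers who want to
turn peak-intensity tables from three kinds of experiment into one
quantitative free-energy landscape:

* **hours** — real-time temperature-jump NMR: consecutive 2D spectra
  after a jump, fit globally to the two-state relaxation
  `p_G(t) = p_eq + (p0 − p_eq)·exp(−(k_f + k_r)·t)`, `p_eq = k_r/(k_f + k_r)`,
  with a double bootstrap (intensity noise + residue resampling) for
  uncertainties;
* **milliseconds** — CEST: Bloch–McConnell simulation of saturation
  profiles and global 2-/3-state fitting (shared populations and
  exchange rates across residues, per-residue shifts and relaxation
  rates, R2-tying constraints, reduced-χ² topology comparison), and
  CPMG relaxation dispersion with the plateau-subtraction estimator
  `Rex = R2,eff(ν_min) − R2,eff(ν→∞)` plus a Bonferroni-corrected
  two-temperature test that classifies each residue's exchange regime
  (in slow exchange Rex ≈ the rate of leaving the observed state; in
  fast exchange Rex ≈ p_A·p_B·Δω²/k_ex);
* **thermodynamics** — Boltzmann inversion of populations
  (`ΔG = −RT·ln(p/p_ref)`) and Eyring barriers
  (`ΔG‡ = −RT·ln(k·h/(κ·k_B·T))`, κ = 1), with reconciliation of
  CEST-derived and real-time-derived populations and a constant cold
  offset so no absolute barrier decreases with temperature.

A synthetic-data module generates every input — pseudo-3D peak-intensity
time courses, 15N/13C CEST profiles at the study's B1/Trelax settings,
constant-time CPMG curves, per-temperature peak-volume tables — so the
whole pipeline is testable without spectrometer data, and synthetic
tables are interchangeable with real ones through the same delimited-text
formats.

## Worked example

```python
import foldswitch_nmr as fn

fixture = fn.kaib_fixture("tjump_20C")          # k_G→FS = 0.09, k_FS→G = 0.36 hr⁻¹
tcs = fn.gen_tjump(fixture, 45, 37, noise_frac=0.02, seed=1)
tcs = fn.filter_peaks(tcs)                      # amplitude > 4e5
fit = fn.fit_global_rates(tcs)
boot = fn.bootstrap_rates(tcs, n_iterations=200, seed=1)
print(f"k(Ground->FS) = {fit.k_forward:.3f} +/- {boot.se_k_forward:.3f} hr^-1")
print(f"Ground-state lifetime = {fn.lifetime(fit.k_forward):.1f} hr")
```

prints

```
k(Ground->FS) = 0.089 +/- 0.004 hr^-1
Ground-state lifetime = 11.2 hr
```

i.e. the global fit of 82 noisy synthetic peaks recovers the generating
forward rate within one standard error; its reciprocal is the mean time
the protein spends in the Ground fold before switching (~11 h).
The scripts in `examples/` walk through each capability the same way:
temperature-jump fitting, CEST fitting (recovering k_ex = 173 s⁻¹ and a
7% invisible-state population from methyl profiles), CPMG regime
classification, and landscape assembly (Ground lowest at 20 °C, PD
lowest at 4 °C).

A thin CLI mirrors the library:
`fsnmr simulate|fit-realtime|fit-cest|analyze-cpmg|landscape|run`, with
the all-in-one `run` driven by a YAML config (see
`examples/demo_config.yaml`).

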