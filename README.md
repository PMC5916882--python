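# relaxnet

Quantitative analysis of protein dynamics and energetics for
solid-state-NMR/ensemble-simulation studies of microcrystalline proteins
(the motivating system is a β-sandwich amyloidogenic protein and a
single-point charge mutant of it). The package turns raw per-residue
measurements into the four quantities such a study reports:

1. **¹⁵N relaxation rates** — per-residue R₁ and R₁ρ from mono-exponential
   intensity decays, fitted by minimising
   χ² = (1/N) Σₖ (I_exp(tₖ) − I₀e^(−R tₖ))²/σ², with uncertainties from
   1000 Monte-Carlo refits of noise-perturbed back-calculated curves.
2. **Model-free dynamics** — inversion of each (R₁, R₁ρ) pair to an order
   parameter S² and effective correlation time τ_eff through the
   Lipari–Szabo simple model-free spectral density
   J(ω) = (2/5)(1−S²)τ/(1+(ωτ)²), using the closed-form rate expressions
   for dipolar (d = μ₀ħγ_Nγ_H/4πr³_NH, r_NH = 1.02 Å) and ¹⁵N CSA
   (Δσ = 170 ppm) relaxation.
3. **Relaxation dispersion** — R₁ρ(ν_SL) profiles over spin-lock amplitudes
   3–20 kHz fitted with a Lorentzian
   R(ν_SL) = R_inf + A·ν½²/(ν½²+ν_SL²); the exchange amplitude
   ΔRex = R(3 kHz) − R_fit(20 kHz) quantifies µs–ms conformational
   exchange.
4. **Ensemble energetics and free-energy surfaces** — residue-pair
   nonbonded energy matrices (Coulomb + 12-6 LJ, 10 Å cutoff) averaged over
   weighted conformational ensembles; a difference network thresholded at
   the largest gap in the |ΔE| distribution; a side-chain
   charge-removal/inversion scan correlated with melting temperatures; and
   weighted-histogram free-energy surfaces F = −ln P (kT units) over
   collective variables, with substate populations.

Because studies of this kind deposit spectra and trajectories rather than
machine-readable tables, every stage is exercisable on synthetic inputs
with planted ground truth (`relaxnet.synthetic`), so the whole pipeline is
testable end to end.

## Worked example

```python
from relaxnet import (SpinSystem, SpinLock, estimate_rate,
                      fit_model_free, fit_lorentzian)
from relaxnet.synthetic import gen_relaxation_dataset

decays, profiles, truth = gen_relaxation_dataset(n_residues=3, seed=42)
spin, lock = SpinSystem(), SpinLock(20.0)       # 800 MHz, 20 kHz spin lock

by_res = {}
for d in decays:                                 # R1 and R1rho decays
    est = estimate_rate(d, n_mc=1000, seed=7)
    by_res.setdefault(d.residue_id, {})[d.experiment] = est
for res, p in sorted(by_res.items()):
    mf = fit_model_free(p["R1"], p["R1rho"], spin, lock, n_mc=500, seed=7)
    print(res, round(mf.params.s2, 3), round(mf.params.tau_eff * 1e9, 1))
```

prints (with the planted truth shown for comparison):

```
R1: R1 = 0.0491 ± 0.0018 1/s, R1rho = 3.205 ± 0.125 1/s,
    S2 = 0.904 ± 0.002 (true 0.903), tau = 19.4 ± 0.5 ns (true 19.3)
R2: S2 = 0.892 ± 0.003 (true 0.894), tau = 15.3 ± 0.4 ns (true 15.2)
R3: S2 = 0.900 ± 0.003 (true 0.900), tau = 83.6 ± 2.9 ns (true 80.3)
```

i.e. order parameters near 0.9 (a rigid β-sheet core) with tens-of-ns
effective correlation times, each with Monte-Carlo error bars. A residue
with planted exchange shows up in the dispersion stage:

```python
f = fit_lorentzian(profiles[0])   # seed=1 dataset, residue R1
# flagged=True, amp = 24.5 ± 1.0 1/s, nu_half = 11.1 kHz, delta_rex = 17.3 1/s
```

ΔRex ≈ 17 s⁻¹ means the rotating-frame rate at a 3 kHz lock exceeds the
fitted 20 kHz plateau by that amount — the signature of µs–ms exchange,
quenched at strong spin-lock fields.

The same library drives a deterministic CLI pipeline:

```bash
relaxnet --seed 1 --outdir run1 all
# run1/: rates.tsv, modelfree.tsv, dispersion.tsv, network_edges.tsv,
#        fes.tsv, populations.tsv, summary.json  (+ config hash in headers)
```

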