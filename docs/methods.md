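# Methods

This note documents the models implemented in `relaxnet`, the numerical
choices behind the fits, what the synthetic-data generators emulate, and
the known limitations. Units throughout: coordinates in Å, residues
1-based, rates in s⁻¹, energies in kJ/mol, free energies in kT.

## Relaxation forward model

Amide ¹⁵N relaxation is assumed to be dominated by the ¹⁵N–¹H dipolar
coupling and the ¹⁵N CSA:

R₁ = (d²/4)[J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H+ω_N)] + (ω_N²Δσ²/3)·J(ω_N)

R₁ρ = (d²/8)[4J(ω_SL) + J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H) + 6J(ω_H+ω_N)]
    + (ω_N²Δσ²/18)[4J(ω_SL) + 3J(ω_N)]

with d = μ₀ħγ_Nγ_H/(4π r³_NH). Defaults: r_NH = 1.02 Å, Δσ = 170 ppm,
static field 800 MHz (¹H). The CSA in ppm enters as the dimensionless
fraction Δσ·10⁻⁶ multiplying ω_N, which keeps ω_N²Δσ² in rad²/s². γ_N is
negative; frequency combinations are composed from the signed values and
the spectral density — even in ω — is evaluated on the result. The
simple model-free (SMF) spectral density
J(ω) = (2/5)(1−S²)τ_eff/(1+(ωτ_eff)²) is the same for every interaction
index. The spin lock is treated as on-resonance; no MAS-rate or
off-resonance corrections and no anisotropic overall motion are modelled.

Implications used elsewhere: both rates are *linear in (1−S²)* at fixed τ,
R₁ρ(ν_SL) is non-increasing in ν_SL, and both rates vanish at S² = 1.

## Rate fitting

Decays are mono-exponential, I(t) = I₀e^(−Rt), fitted by minimising the
reduced chi-square (1/N)Σ(I_exp−I_calc)²/σ² with σ the spectrum RMSD. Both
I₀ and R are free: the zero delay is part of the acquisition grid but is
as noisy as any other point. For any trial R the optimal I₀ has a closed
form, so the search is one-dimensional in R: a log-linear regression on
positive intensities seeds an adaptive scan-and-shrink bracket search
(33-point grid, bracket shrunk ×8 per iteration, expanded when the minimum
sits on an edge) that converges to ~1e−12 relative precision and is fully
vectorised across Monte-Carlo replicates. The same code path serves single
fits and the MC refits, which keeps them bit-consistent.

Monte-Carlo errors follow the standard recipe: Gaussian noise of width σ
is added to the *back-calculated* curve, each synthetic dataset is refit,
and the error is the standard deviation (ddof=1) of the refit rates; the
default replicate count is 1000. Negative fitted rates are reported with a
warning, never clamped, so the MC distribution stays symmetric. One master
seed yields per-residue child seeds via `numpy` `SeedSequence` spawn keys,
making every table reproducible byte-for-byte.

## Model-free inversion

Each residue contributes two observables (R₁ and R₁ρ at the measurement
lock, 20 kHz by default) and the model has two parameters (S², τ_eff), so
fitting is per-residue and per-field. The residual surface is bimodal in
τ, so the fit is grid-then-refine: a 600-point log-spaced τ grid spanning
10 ps–1 µs, with the amplitude a = 1−S² profiled out in closed form at
every τ (exactly equivalent to the 2-D grid because the rates are linear
in a; a is clipped to [0, 1]); every local minimum of the τ profile is
then polished by a bounded scalar minimiser on log τ. Noiseless round
trips recover (S², τ) to better than 1e−6 relative.

Flags:

* `unconverged` — τ pinned at a grid boundary;
* `exchange_suspect` — χ² above a threshold (default 9 ≈ 3σ) with
  variance-scaled residuals. Note the physics: with two observables and
  two parameters, a moderate exchange contribution to R₁ρ is usually
  *absorbed* by the (S², τ) degeneracy (the fit drifts to smaller S² and
  larger τ) and leaves no residual; only pairs outside the model's
  reachable set are flagged. Exchange detection therefore belongs to the
  dispersion analysis, and the pipeline excludes dispersion-flagged
  residues from model-free interpretation.
* `degenerate` — a second τ branch within Δχ² < 1 of the best one (the
  lower-χ² branch is always reported). This check runs only when real
  rate uncertainties are supplied: with unit weights the Δχ² scale is
  arbitrary and the criterion meaningless.

Parameter uncertainties come from Monte-Carlo resampling of the two rates
from N(rate, rate_sd), refit vectorised over replicates (grid argmin plus
parabolic refinement in log τ).

## Relaxation dispersion

The on-resonance fast-exchange limit motivates the three-parameter
Lorentzian R(ν_SL) = R_inf + A·ν½²/(ν½²+ν_SL²), parameterised directly in
ν_SL (kHz) to match the measured axis. The weighted least-squares fit uses
trust-region optimisation from four ν½ starting points (2, 5, 10, 20 kHz)
because the profile can be locally flat in ν½. Exchange is declared when
the Lorentzian beats the inverse-variance-weighted flat model by
Δχ² > 9 (two extra parameters, ≈3σ); ties break toward flat, which keeps
the false-positive rate on flat noisy profiles near 1%. Parameter
uncertainties come from the Gauss–Newton covariance of the weighted fit.

ΔRex is the measured rate at the lowest lock (3 kHz, when a usable point
exists; otherwise the fitted value, recorded in the fit's notes) minus the
fitted rate at 20 kHz. Profiles where no exchange is detected report
ΔRex = 0; a negative difference (possible through noise) is reported as-is
with a note. Censored points — residues whose signal decays within the
shortest relaxation delay at low lock — are carried in the profile but
excluded from fitting.

One caveat the tests respect: the exchange-free forward model itself has a
tiny intrinsic ν_SL dependence through 4J(ω_SL). At realistic noise it is
invisible, but at exactly zero noise it is statistically resolvable and a
noiseless "no-exchange" profile will legitimately be flagged; false-positive
statements therefore use the study-like 5% rate noise.

## Ensemble energetics

Residue-pair nonbonded energies are Coulomb (relative dielectric,
default 1) plus 12-6 Lennard-Jones with Lorentz–Berthelot combining, summed
over atom pairs within a 10 Å cutoff — the convention of the force-field
setup this analysis descends from. Sequence neighbours (|i−j| ≤ 1) are
excluded because their "nonbonded" energy is dominated by fixed covalent
geometry. Matrices are statistical-weight averages over the ensemble
models; they are invariant under model reordering and rigid-body motion of
any model. Atom pairs closer than 0.1 Å abort the calculation (broken
input geometry).

The difference network takes ΔE = E_perturbed − E_reference on all
non-neighbour pairs and keeps pairs beyond the largest gap in the |ΔE|
order statistics. Candidate split points keep the top k elements,
k = 1…max(2, ⌈0.1·n⌉): the decile cap keeps the near-zero bulk from
defining the gap, the floor of 2 lets small distributions (as in the
documented example) split below the second element, and ties break toward
the larger threshold (the sparser network). A gap-free distribution (e.g.
identical matrices) yields an empty network with a warning rather than an
error. Edges are `strengthened` when the interaction energy decreased
(more favourable in the perturbed ensemble), `weakened` otherwise.

The charge scan edits one residue's side-chain charges (removal or
inversion; backbone atoms are never touched, glycine is rejected) and
recomputes the total ensemble-averaged nonbonded energy. Only Coulomb
terms change, so the scan reduces to E(q) = ½qᵀAq with A the
ensemble-averaged masked Coulomb kernel — removal of one partner of an
isolated ±1 salt bridge at 3 Å changes the total by exactly
1389.3546/3 kJ/mol, and inversion by exactly twice that. Predicted ΔE
values are correlated with melting temperatures by both Pearson and
Spearman coefficients (no p-value interpretation at these n).

PQR is the native input (charges + radii; radii are read as van-der-Waals
radii and converted to LJ σ, with per-element default well depths); a
multi-model PDB plus a per-atom charge table is accepted as an equivalent
path.

## Free-energy surfaces

Samples arrive with statistical weights (any enhanced-sampling reweighting
happens upstream). The CV space is divided into a homogeneous grid and
F_cell = −ln(weight share), shifted so the sampled minimum is 0; unsampled
cells are masked, never reported as 0. Lower-dimensional surfaces
integrate out CVs in probability space — implemented as re-histogramming
the kept dimensions, which is identical to summing cell probabilities over
the dropped axes. Basins are user-declared rectangles over any subset of
the CVs (unmentioned CVs are unbounded); cells are assigned at their
centres, first matching basin wins, and sampled cells outside every basin
raise an error listing them. Populations are weight shares and sum to 1
over the basins. kT units throughout; ×2.311 converts to kJ/mol at 278 K
at the reporting layer.

## Synthetic data: what it emulates, and what it does not

`gen_relaxation_dataset` back-calculates decays from the forward model on
the study's acquisition grids (R₁ delays 0, 0.5, 1, 2.5, 5, 10, 20, 40 s;
R₁ρ delays 1, 3, 8, 20, 45, 100, 180, 300 ms; spin-lock grid 3, 4, 5, 6,
7, 10, 15, 20 kHz) and adds Gaussian noise per intensity point (default
2% of I₀, reported as σ). S² is drawn near 0.9 for core residues
(N(0.9, 0.02)) and U(0.70, 0.85) for a 20% flexible-loop fraction,
mirroring a rigid β-sandwich with mobile loops; τ_eff is log-uniform on
5–100 ns. A 30% fraction of residues carries a planted Lorentzian exchange
term (amplitude U(5, 30) s⁻¹, ν½ U(3, 10) kHz) added to R₁ρ; dispersion
profiles get 5% relative Gaussian noise on the rates.

`gen_charged_ensemble` builds a toy Cα-plus-charged-site geometry on an
8 Å lattice with small random side-chain charges, wires planted ±1 pairs
at exact distances around a shared charged hub (a salt-bridge analogue at
3 Å and a long-range partner at 4.5 Å), and produces a "mutant" sharing
every coordinate and differing only in the declared side-chain charge
edit. `gen_cv_samples` draws stratified Gaussian-mixture samples in 4-D CV
space with per-sample weights chosen so each basin's total weight is
exactly its declared share (0.85/0.15 by default).

What passing these tests does *not* show about real data: the generators
share the forward models with the fits, so they validate inversion,
calibration and bookkeeping — not model adequacy. Real spectra add peak
overlap, non-Gaussian baseline artefacts, MAS- and off-resonance effects,
anisotropic motion, multi-exponential decays, and force-field error; none
of these are emulated.

## Problem sizes and statistical tolerances

The shipped studies use 500 residues × 1000 MC replicates for coverage
(the ±1.96σ band is checked against a 93–97% window), 200 planted
dispersion profiles plus 1000 flat ones, 20 network seeds, and 10⁵
CV samples. Free-energy accuracy is judged against the analytic *cell
mass* of the mixture (erf differences), not the centre density, so the
residual error is pure counting noise (s.e. ≈ 1/√N_eff per cell); the
accuracy statement is an RMS < 0.2 kT over cells with ≥ 100 effective
samples, since a max-norm bound at N = 100 would be violated by ~2σ
counting fluctuations alone.

## Known limitations

* Single-field data only; no global τ or multi-field model selection.
* The SMF model ignores anisotropy and exchange; exchange-affected
  residues must be screened by dispersion before interpretation.
* The dispersion functional form is the fast-exchange on-resonance limit;
  slow exchange or off-resonance locks would need the full
  Bloch–McConnell treatment.
* Pair energies use a hard cutoff with no long-range electrostatics
  correction and a uniform dielectric; the charge scan perturbs charges
  on a frozen ensemble (no relaxation of the structure).
* Metadynamics reweighting is out of scope: FES inputs must already carry
  correct statistical weights.
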