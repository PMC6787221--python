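# Methods

`flexlink` implements an integrative solution-state analysis of a
two-domain protein joined by a disordered linker — the STAM2 UIM-SH3
dual domain is the motivating system — combining NMR chemical-shift
titrations, ¹⁵N spin relaxation, and small-angle X-ray scattering
(SAXS), together with a synthetic-data generator that emulates the
statistical structure of each measurement so every stage can be
validated against known ground truth.

Units throughout: Å for distances, Å⁻¹ for momentum transfer q, µM for
concentrations, ppm for shifts, s⁻¹ for rates, ns for correlation
times; magnetic field stated as the ¹H resonance frequency (default
600 MHz).

## Titration analysis

Amide chemical-shift perturbations are combined as
Δδ = [((ΔδH)² + (ΔδN/5)²)/2]^½, the ¹⁵N term scaled by 1/5 for its
larger dispersion. In the fast-exchange limit the observed Δδ is the
population-weighted average between free (Δδ = 0) and bound
(Δδ = Δδ_bound) states. Two isotherms are provided:

* **1:1** — Δδ = Δδ_b (L₀+P₀+K_d − √((L₀+P₀+K_d)² − 4L₀P₀)) / 2P₀
* **2:1** — for a bivalent ligand (Lys63-linked diubiquitin) whose two
  moieties each engage one site, the ligand-site concentration doubles:
  Δδ = Δδ_b (2L₀+P₀+K_d − √((2L₀+P₀+K_d)² − 8L₀P₀)) / 2P₀

Both are monotone in L₀, bounded by Δδ_bound, and consistent: the 2:1
curve at L₀/2 equals the 1:1 curve at L₀ (asserted numerically in the
tests, against an independent equilibrium root-finding oracle).

Fitting uses damped least squares (scipy `least_squares`, TRF) with
K_d initialised at the ladder median, Δδ_bound at 1.2× the largest
observed CSP, and K_d bounded in (0, 10⁵] µM. The default mode fits
each residue independently and aggregates per domain as mean ± SD
across residues — the SD is the reported error, matching the
convention of per-residue titration studies. A global shared-K_d mode
(residue-specific amplitudes) is provided because either convention is
defensible; the default is a package choice, not a claim about any
particular study. Residues whose endpoint CSP stays below 0.02 ppm
(configurable) are excluded from aggregation: below typical shift
precision the isotherm is unidentifiable. Broadened residues
(disappearing peaks, < 4 observed points) are excluded from fitting but
counted in reports. The CSP significance threshold defaults to 0.4 ppm
with an inclusive boundary; it is unusually large for combined CSPs and
deliberately configurable.

Design identifiability: when the ladder saturates the site poorly, the
per-residue K_d estimates disperse and the aggregate SD widens; the
tests assert a ≥ 3× inflation when the ladder stops near 20 %
saturation.

## ¹⁵N relaxation

Rates are extracted from peak-intensity decays by two-parameter
monoexponential fits (I₀, R), errors from the fit covariance;
non-decaying series are flagged not-determined. The steady-state NOE is
the saturated/reference intensity ratio with quadrature error
propagation.

Reduced spectral density mapping collapses the high-frequency dipolar
terms onto 0.87 ω_H, making (R₁, R₂, σ_NH) ↔ (J(0), J(ω_N), J(0.87ω_H))
an exactly invertible 3×3 linear system — no rotational-diffusion model
is assumed. Constants: r_NH = 1.02 Å, Δσ_N = −160 ppm (standard
backbone-amide values, configurable; J(ω_N) scales roughly with
(1.02/r_NH)⁶ and with the CSA term, so alternative conventions shift
absolute J values by a few percent without affecting the per-residue
patterns the analysis relies on). R_ex is assumed zero; a negative
J(0) is reported but flagged, as it signals exchange or noise.

Per-domain rotational correlation times replace a full anisotropic
diffusion-tensor treatment with an isotropic estimate: each rigid
residue's R₂/R₁ ratio is inverted through the rigid Lorentzian spectral
density J(ω) = (2/5)τ_c/(1+(ωτ_c)²) by bisection on τ_c ∈ [0.5, 50] ns,
and the domain value is the trimmed mean ± SD after excluding flexible
residues (NOE < 0.65) and the 10 % most median-distant R₂/R₁ ratios.
The headline observation this supports — the two domains tumble with
different but coupled correlation times, and the gap narrows with
linker shortening — is expressible isotropically; anisotropy is a
documented fidelity limit. The R₂-vs-mass "molecular ruler" is an
ordinary least-squares line through ≥ 3 calibrant proteins with
extrapolation flagged.

## SAXS

Concentration series are merged by scaling the high-concentration curve
onto the low-concentration one over a stated overlap window (weighted
least squares), splicing at the window midpoint.

The Guinier fit is a weighted linear fit of ln I vs q², iterated to
self-consistency on the window bound q_max·R_g ≤ 1.3. Two adaptive
trims both use the Wald–Wolfowitz runs statistic of the fit residuals
(threshold z < −2): leading points are dropped while they betray
beam-stop-like curvature, and the high-q edge of the window is shrunk
while systematic curvature persists — for compact particles (worst
case: a homogeneous sphere) the plain 1.3 window overestimates R_g by
~2 %, and the runs-based shrink recovers the analytic R_g = √(3/5)·R
to ≲ 0.2 % on clean data while leaving noisy data (noise masks the
curvature) at the full window.

The dimensionless Kratky transform (qR_g)²·I/I₀ vs qR_g is
parameter-free; the interior maximum is located on the grid and refined
by parabolic interpolation. An ideal compact particle peaks at
(√3, 3/e) ≈ (1.73, 1.104); disordered chains rise monotonically and are
reported as having no interior peak.

P(r) inversion minimises ‖(I − T·P)/σ‖² + λ‖Δ²P‖² subject to P ≥ 0 and
P(0) = P(D_max) = 0, with T the trapezoid-integrated Fourier kernel
4π·sin(qr)/(qr) on a uniform 101-point r grid. Non-negativity comes
from solving the stacked system with NNLS (active-set), with a
bounded-variable least-squares fallback if the active set cycles at
extreme λ. λ defaults to the corner of the (log residual,
log roughness) L-curve over a 21-point λ grid, selected as the point of
maximum chord distance; a fixed λ can be forced. Real-space quantities
come from moments of P: I(0) = 4π∫P dr, R_g² = ∫r²P dr / 2∫P dr.
D_max is chosen as the smallest candidate whose back-fit χ is within
5 % of the large-D_max plateau (median χ of the upper half of the
scan); a χ still falling steeply at the widest candidate triggers a
range warning.

## Ensemble selection

Conformer profiles use the Debye formula with a uniform per-residue
form factor (f = 1), so I(0⁺) = n². This drops residue-specific form
factors and the hydration layer; the downstream uses — χ ranking of
conformers and the shape of the R_g distribution — are comparative and
survive the simplification, but absolute χ values are not comparable to
atomic-resolution profile calculators, and no absolute-χ targets are
asserted anywhere.

Conformers are sampled by random pivot rotations at flexible residues
(rigid domains internally fixed), rejecting moves that bring the moved
and fixed segments within 4.0 Å at sequence separation ≥ 3 — the
static hard-core for an already-built model is 3.0 Å, because a compact
globule legitimately packs non-adjacent beads near one bond length; the
stricter 4.0 Å rule applies only to pairs whose relative geometry a
move changes. Snapshots are taken every |flexible set| accepted moves
for decorrelation. Sampling is deterministic per seed and aborts if
acceptance falls below 1 %.

The N-state fit (N = 1..5) evaluates candidate member subsets by
non-negative least squares on σ-weighted intensities, normalises the
weights (the scale folds into the χ scale factor
c = Σ(I_e·I_m/σ²)/Σ(I_m²/σ²)), and ranks by
χ = √(⟨((I_e − c·I_m)/σ)²⟩). Subsets are enumerated exhaustively up to
10⁶ combinations, beyond which a seeded multi-restart greedy swap
search is used. Ties break by smaller N, then lexicographic member
indices, for bit-reproducible rankings. Nested-search monotonicity
(χ of the best N+1-state ≤ best N-state) is asserted on exhaustive
enumeration. The R_g distribution weights each reported model uniformly
and each member by its fitted weight (1 Å bins).

## Synthetic data

The generator builds helix (ideal geometry: 1.5 Å rise, 2.3 Å radius,
100°/residue) + self-avoiding linker (3.8 Å bonds) + globular domain.
The globule packs beads along concentric spherical spirals ("yarn
ball") with one bond between consecutive beads and 4.0 Å between
shells and turns: this guarantees the chain-geometry invariant
(consecutive beads within [2.9, 4.1] Å) deterministically, where an
FCC site cloud would need a heuristic path search that can fail. The
geometric construction runs globule → linker → helix and reverses the
chain, so the helix is N-terminal as in the UIM-SH3 architecture.

Titrations: per-residue random baselines, CSP from the chosen isotherm,
split into components with the fixed convention Δδ_N = 2Δδ_H (so
Δδ_H = Δδ·√(50/29); the CSP combination inverts the split exactly), and
Gaussian noise of 0.005 ppm (¹H) / 5× that (¹⁵N) — about the precision
of peak positions in a well-resolved HSQC. Relaxation: rates from the
full five-frequency dipolar+CSA expressions with Lipari–Szabo spectral
densities (per-domain τ_c, per-residue S², shared τ_e = 50 ps default),
rendered as intensity decays on standard delay ladders (R₁ 40–2400 ms,
R₂ 8–224 ms) with 2 % intensity noise. SAXS: weighted Debye mixtures
with σ(q) = a·√(I(0)·I(q)) + b, a = 0.01 by default — roughly a
synchrotron-quality reduced curve. Noise defaults were chosen once to
make recovery tests meaningful but not fragile.

Every generator serialises a `SyntheticTruth` (parameters + seed)
sufficient to regenerate the dataset bit-exactly, and integration tests
write generated data to real files consumed through the readers.

What the generators do **not** emulate: spectrometer artifacts (t₁
noise, peak overlap), exchange broadening lineshapes, interparticle
structure factors, buffer subtraction, anisotropic tumbling, hydration.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated statistical model, not robustness to every
systematic error of real data.

## Problem sizes and determinism

Test-suite simulations use desk-scale sizes chosen as the smallest that
make the statistical assertions stable: conformer pools of ~30 (the
production default is 10000, as in RRT-style pipelines), 20-residue
titrations over 50 seeds, 95-residue relaxation sets, 2000-bead sphere
discretisations. All stochastic stages take explicit seeds and are
bit-reproducible under them.

## Known limitations

* Uniform form factors and no hydration: absolute SAXS χ values are
  pipeline-internal.
* Isotropic per-domain τ_c; no model-free (S², τ_e, R_ex) fitting and
  no field-dependent exchange analysis.
* 1:1 and 2:1 isotherms only; no cooperative (Hill) or competition
  models, no exchange-regime lineshape analysis.
* Single-chain bead models; no mmCIF, no multi-chain assemblies.
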