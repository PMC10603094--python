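# Methods

This note documents the models, parameter choices and numerical decisions
behind `scarmech`, and what the synthetic-data suite does and does not
establish about real data.

## Problem setting

After spinal cord injury, zebrafish larvae regenerate axons across an
ECM-rich, non-neural lesion site, while mammals form an inhibitory scar.
The package implements the quantitative arms used to characterise that
lesion environment: (i) label-free shotgun proteomics of lesioned versus
unlesioned tissue, with matrisome annotation and a cross-species regulation
screen; (ii) tissue mechanics by Brillouin microscopy (longitudinal
modulus), cross-polarized OCT (structural polarization contrast) and
AFM nanoindentation (apparent Young's modulus and viscosity); and (iii) the
effect-size statistics layer that gates all group comparisons.

## Differential proteomics

**Input model.** MaxQuant-style proteinGroups tables: one row per protein
group, `LFQ intensity <sample>` columns, `+`-marked flags for reverse
(decoy), contaminant and identified-by-site rows. Intensities are
log2-transformed; zeros are missing.

**Valid-value rule.** For the lesioned-vs-unlesioned design, rows with any
missing value are removed, *except* rows fully missing in exactly one
condition and fully observed in the other. These presence/absence rows are
biologically the most interesting (proteins undetectable before injury) and
are retained, flagged, and imputed per sample from a down-shifted normal
N(mean − 1.8·SD, (0.3·SD)²) — the Perseus-style convention for
missing-not-at-random dropout. A strict mode (all-valid rows only) matches
the rule used for the SLRP-overexpression comparisons. The down-shift (1.8)
and width (0.3) are in per-sample SD units; for very sparse columns the
matrix-wide SD is used as the scale.

**Moderated statistic.** For each protein,
`t_s0 = (mean_B − mean_A) / (s + s0)` with `s` the pooled two-sample
standard error and `s0 = 0.1`. The offset damps the spuriously large
statistics of low-variance proteins; at `s0 = 0` the statistic is exactly
the classical pooled t (verified to 1e−12).

**Permutation FDR.** Label splits of the samples are enumerated
exhaustively when few enough (a 3-vs-3 design has C(6,3) = 20), otherwise a
seeded random subset is drawn. Two splits are excluded from the null: the
observed labeling and, in balanced designs, its mirror image — both
reproduce |t_obs| exactly and belong to the alternative, not the null; with
them included no protein could ever reach FDR < 0.1 in a 3-vs-3 design.
For each candidate cut on the observed |t| ranking, the estimated FDR is
the mean number of permuted statistics above the cut (pooled over
permutations) divided by the observed count; the observed counts are
re-appended as one pseudo-permutation (add-one smoothing) so that no
estimated FDR is exactly zero. A protein's q-value is the smallest
estimated FDR over cuts that call it; `q < 0.1` is significant. The
classical per-permutation *median* count rule is available
(`estimator="median"`) but is not the default: with only 18 informative
splits the median collapses to zero too easily, and on simulated complete
nulls it produced a false call in 46% of runs, versus 18% for the pooled
mean with smoothing (50 runs, 1000 proteins each; the per-protein false
call rate is ~2·10⁻⁴). That residual inflation above the nominal 10% is a
known small-permutation limitation of SAM-type counting estimators, driven
by the minimisation over cuts; it shrinks as the number of distinct label
splits grows.

**Classification and screens.** Regulation classes use the linear-scale
fold-change threshold applied on log2 data: up iff significant and
log2FC ≥ log2(1.3), down symmetric, else n.s. The cross-species screen
joins two results over a curated ortholog map and partitions pairs into
{A-up ∧ B-down/n.s., B-up ∧ A-down/n.s., concordant, other}; many-to-many
orthology is resolved to the highest-|t| representative, with discarded
pairs reported. Over-representation analysis is a one-sided hypergeometric
upper tail with Bonferroni correction over tested sets — a deliberately
exact, reproducible stand-in for g:Profiler's proprietary g:SCS
correction, which is generally less conservative; results are therefore
comparable only in direction, not in exact adjusted p.

## Brillouin mechanics

In backscattering geometry (ϑ = 180°, sin ϑ/2 = 1) the Brillouin shift
relates to the longitudinal modulus via
`ν_B = 2 n √(M′/ρ) / λ₀`, inverted as
`M′ = ρ · (ν_B λ₀ / 2n)²` with λ₀ = 780.24 nm.

Density comes from the refractive index through a two-component model: the
dry-mass concentration is `c = (n − n_f)/α` with α = 0.1919 mL/g (the
standard refraction increment of proteins and nucleic acids), and
`ρ = ρ_f + (1 − θ_v ρ_f) · c`, where θ_v is the partial specific volume of
the dry mass (each gram displaces θ_v mL of fluid).

**Calibration of the fluid constants.** With ρ_f fixed at 1000 kg/m³
(aqueous interstitial fluid), the remaining constants were fitted once by
requiring the four measured lesion-condition pairs (ν̄_B, n̄) for the
lumican/prolargin transgenics and their controls to map jointly onto their
reported moduli (2.396/2.373/2.394/2.370 GPa). The fit gives
n_f = 1.3387 and θ_v = 0.7482 mL/g — physically plausible values
(protein partial specific volumes cluster near 0.73 mL/g) — and reproduces
all four moduli to better than 0.01%. These are the `DensityModel`
defaults; all are overridable.

**Uncertainty.** First-order Gaussian propagation with analytic partial
derivatives over (ν_B, n, α, θ_v, n_f, ρ_f); the returned budget lists each
input's variance share, and a seeded Monte-Carlo mode cross-checks the
linearisation (agreement is ≲0.1% at 1% input CVs, comfortably inside the
2% band asserted in tests; the linearisation degrades only for much larger
input CVs than occur here). For the study-scale uncertainties the ν_B term
dominates the budget, consistent with the reported conclusion that modulus
differences stem from shift differences rather than refractive-index
differences. The compressibility is reported as κ_L = 1/M′ exactly.

**ROI convention.** The quantification rectangle (default 40 µm × 20 µm,
matching bridge thickness and stump gap) includes a pixel iff its centre
falls in the closed rectangle — unambiguous and stable under sub-pixel grid
shifts. A notochord landmark may anchor the ventral edge 5 µm dorsal to it.
Invalid (NaN) pixels are excluded from the mean and counted. No
low-SNR/saturation exclusion rule is applied beyond NaN masking, since none
is specified for the source data.

## Cross-polarized OCT

Per pixel, reflectivity `R = √(A_co² + A_cross²)` and co-polarization ratio
`δ = A_co/(A_co + A_cross)`; zero-total-amplitude pixels carry no
polarization information and are masked. Ratios are computed on the
averaged intensity projection of the stack (project-first, matching the
quantification of projected images); a per-slice-then-average option
exists. Formulas operate on amplitudes, not intensities — the
amplitude-squared reading would change δ values and is deliberately not the
default. Area quantification thresholds at the ROI mean grey level with a
strictly-greater tie rule, so a uniform image yields zero foreground
deterministically; the measure is invariant under additive intensity
shifts.

## AFM viscoelastic fitting

Hertz sphere contact: `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}` with ν = 0.5
(incompressible) and R = 18.5 µm (37 µm polystyrene bead). The
Kelvin–Voigt–Maxwell fit uses the elastic–viscoelastic correspondence,
replacing the modulus with the operator `E + η·d/dt` acting on δ^{3/2},
giving for a constant approach speed v
`F = (4√R)/(3(1−ν²)) · (E δ^{3/2} + 1.5 η v √δ)`,
which reduces to Hertz as η → 0. The synthetic generator uses the same
forward model, so round-trip tests probe the estimator, not model
agreement; published KVM variants with an additional Maxwell relaxation arm
are not separately identifiable from a constant-speed approach segment and
are not modelled. Only the approach segment is fitted.

**Estimation.** Contact point and force baseline are free parameters. The
model is linear in (E, η, baseline) once the contact point is fixed, so the
fit profiles the residual sum of squares over the contact point (dense grid
plus bounded scalar refinement, one linear solve per candidate) — a
variable-projection scheme immune to the local minima created by
contact/modulus coupling and to parameter-scale conditioning. A
Levenberg–Marquardt polish at the profiled optimum supplies standard
errors. Negative-amplitude solutions are rejected by re-solving with η
pinned to zero. The Hertz fit restricts data to ≤3 µm beyond the fitted
contact point (small-strain validity), iterating the restriction twice.
Curves whose force never rises above baseline noise, or with fewer than 10
post-contact samples, are rejected.

At the simulated measurement conditions (7 µm/s, 12 nN setpoint, 500
samples, 0.1 nN Gaussian force noise) modulus recovery is tight (median
error ~0.2% both models) while the apparent viscosity is
information-limited per curve: its force contribution peaks below 1 nN, so
single-curve η scatter is ~15–20% even for the exact-likelihood estimator,
but the ensemble estimate is unbiased (measured bias ≈ −1 to −3% over 50
curves). Per-animal medians over several curves, as used in practice,
inherit the unbiasedness.

## Statistics layer

Every group passes a Shapiro–Wilk gate at α = 0.05 (n ≥ 3 per group
required); two-group designs use Student's t (all groups normal) or
Mann–Whitney (exact for n ≤ 8), with paired variants when pairing ids
exist; >2 groups use Kruskal–Wallis followed by Dunn's rank comparisons
(normal-approximation z with tie correction, Bonferroni over performed
comparisons — all pairs by default, all-vs-control available since the
original comparison families are not stated).

Effect sizes: Cohen's d (pooled SD, no small-sample correction by default)
with the asymptotic SE √((n_a+n_b)/(n_a n_b) + d²/(2(n_a+n_b))); the
common-language effect size θ = P(A > B) + ½P(A = B) with a
placement-based (DeLong-type) SE. A comparison is called significant only
if p < 0.05 *and* the effect-size interval (estimate ± SE) excludes the
boundary (d_c = 1 applied on the side of the observed sign, θ_c = 0.5).
The source phrasing of the boundary rule is ambiguous; the alternative
reading — point estimate beyond the boundary, uncertainty ignored — is
available via `rule="beyond"`, and neither is asserted as the original
intent. ΔΔCt fold changes are `2^−ΔΔCt` with the reference-gene
normalisation convention; percent change is 100·(control − treated)/control.

## Synthetic data: what it emulates, and what it does not

Generators draw from independent RNG streams derived from the master seed
(`SeedSequence(seed, spawn_key)`), so outputs are reproducible and mutually
independent. Defaults encode the study-scale conditions: 3 replicates per
proteomics condition over a ~4800-protein inventory with ~19% regulated;
0.5 µm Brillouin pixels with lesion/background shifts of 5.324/5.40 GHz and
RI 1.3636/1.3680; co-polarization ratios 0.709/0.750; the AFM probe
settings above on 300–500 Pa tissue (contact at 2 µm, ~500-point approach);
12 animals per group for measurement tables. Where the source provides no
value (baseline log2 LFQ level 25 ± 2.5 with 0.25 replicate SD; 0.02 GHz
and 0.001 RI pixel noise; exponential speckle amplitudes around 100 with
2-unit additive noise), values typical of the respective instruments were
chosen once.

The LFQ generator produces log-normal baselines, symmetric up/down
regulation of an exactly-sized subset, logistic missing-not-at-random
dropout centred 1.8 sample-SDs below the sample mean, and a ~1% flagged
decoy/contaminant fraction. It does *not* emulate correlated peptide-level
noise, shared-peptide ambiguity, batch effects or intensity-dependent
variance, so passing tests demonstrate correctness of the statistical
machinery under the stated model, not robustness to every real-data
pathology. Similarly the imaging scenes are two-region blocks with i.i.d.
Gaussian pixel noise (no speckle correlation, optical sectioning or
registration error), and force curves have i.i.d. force noise (no drift,
adhesion or hydrodynamic drag).

## Problem sizes in tests and the acceptance script

Null-FDR control uses 50 seeded tables of 1000 proteins (3 vs 3, exhaustive
20 splits); uncertainty propagation is cross-checked against 10⁶ Monte-Carlo
samples; viscoelastic recovery uses 50 seeded curves per model; the SAM
identity uses 1000 random draws. These sizes give Monte-Carlo standard
errors well inside the asserted bands while keeping the full suite around
ten seconds.
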