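# Methods

This note documents the models and procedures the package implements, the
defaults it ships, the numerical choices behind them, and what the
synthetic-data generators do and do not emulate.

## Secondary chemical shifts and disorder classification

For each residue *i* and atom X ∈ {¹³Cα, ¹³Cβ, ¹³CO} the secondary shift
is Δδ_X(i) = δ_obs(i, X) − δ_rc(type(i), X), where δ_rc is a
residue-type-dependent random-coil reference. The package bundles a
Wishart-style random-coil table (`data/random_coil_wishart.tsv`) as a
versioned resource; sequence-neighbor corrections (e.g. pre-proline) are
**not** applied — the classification windows below are wide relative to
those corrections (~0.1–0.5 ppm), and applying them would require a
specific correction table as an additional input. Glycine has no Cβ and is
marked not-applicable.

A residue is **coil** when every available Δδ lies inside its window:
±0.7 ppm for Cα/Cβ and ±0.5 ppm for CO of non-prolines, ±4 ppm for all
three carbons of prolines (their shifts are strongly perturbed by
cis/trans isomerism, so only gross deviations are meaningful). Outside the
window, the sign pattern decides: Δδ_Cα > 0 or Δδ_CO > 0 or Δδ_Cβ < 0 is
helix-sense; the mirror pattern is strand-sense. A residue showing both
senses simultaneously is classified coil with a conflict flag — a
conservative tie-break, since a genuine transient element produces a
coherent sign pattern. A residue with no observed carbon shift at all is
`insufficient_data` and breaks runs.

Candidate structured elements are maximal runs of ≥ `min_run` consecutive
same-sense residues. `min_run` defaults to 3 and counts **residues**, not
individual atom values: a 3-residue window already contributes many
out-of-range atom values, and shorter stretches are indistinguishable from
noise. It is configurable for stricter analyses.

The CD heuristic flags a far-UV spectrum as disorder-like iff its global
minimum (after a fixed 3-point moving-average smooth — minimal noise
suppression that cannot displace a genuine band) lies in 195–205 nm with
negative signal and no negative local minimum exists above 210 nm, where
the helix (208/222 nm) and strand (~217 nm) bands would appear. It is a
screening heuristic, not a secondary-structure deconvolution.

## Heteronuclear NOE

NOE(i) = I_sat(i)/I_ref(i) from interleaved saturated/reference spectra.
Residues with non-positive reference intensity are flagged invalid and
excluded from summaries. The summary reports the arithmetic mean over all
evaluable residues, per-region means, and the count below a reporting
threshold (default 0.44 — the level below which every residue of a fully
flexible chain fell in the motivating dataset; it is a reporting aid, not
a classifier). No uncertainty propagation is attempted because peak-height
noise estimates are not part of the input tables.

## Titration attenuation and site delineation

Ratios r(i, c) = I(i, c)/I(i, 0) are computed against the zero-ligand
condition. Bins are assigned from the percent reduction 100·(1 − r) at a
single reference point, by default the first substoichiometric point
(ligand ratio 1:0.25), where site contrast is sharpest; later points serve
monotonicity displays. Boundary conventions: reduction must *exceed* 80 %
for red; exactly 80 % is yellow; exactly 60 % and exactly 40 % are green.
Reductions are clipped to [0, 100] (a ratio > 1 is measurement noise).
Prolines, unassigned and overlapped residues, and residues with
non-positive zero-ligand intensity are not evaluable.

A site is a maximal run of attenuated residues (green/yellow/red)
containing at least one red residue, in which up to `max_gap = 3`
consecutive minimal or non-evaluable residues are bridged when attenuation
resumes; boundaries are trimmed to the outermost attenuated residues. The
gap default covers the proline/unassigned stretches that typically
interrupt an IDP footprint without merging genuinely separate sites; the
delineation is tested against an independent brute-force window
enumeration on random profiles. Requiring a red core prevents a shoulder
of moderate attenuation from being reported as a site of its own.

CSP = √(Δδ_H² + (w_N·Δδ_N)²) with w_N = 0.14, the common convention for
scaling ¹⁵N shift dispersion to ¹H; no dissociation constant is estimated
from the titration (the intensity-loss regime of a multimeric partner does
not support a simple 1:1 binding isotherm).

## Dissociation and turnover kinetics

Anisotropy traces (1 Hz sampling) are truncated at the first index where
the **trailing** 20-point moving average (current plus 19 preceding
points — causal and reproducible, since no alignment convention was given
for the published rule) reaches 0.106, the free-DNA anisotropy. The
3-parameter model A(t) = amplitude·e^(−k_off·(t−t0)) + floor is fitted by
bounded least squares (k_off ∈ (0, 10] s⁻¹, floor ∈ [0, 0.5], amplitude
∈ [−1, 1]) with analytic-free initial guesses (floor = last value,
amplitude = first − last, k_off = ln2 / half-decay time) and up to 5
jittered restarts; a non-positive fitted amplitude raises a
degenerate-fit warning. By default the truncated trace is fitted; fitting
the full trace is a caller choice.

ATPase: A620 readings are baselined by subtracting the t = 0 value; the
standard curve is fitted with a free intercept (the intercept absorbs
reagent-blank bias without tilting the slope) but only the slope enters
the conversion, so Pi(t=0) = 0 exactly. k_cat = OLS slope of Pi(t) (µM/min)
divided by [Rad51] (µM), giving min⁻¹; a fold change is reported against a
supplied reference.

## Gel quantification

corrected(band) = max(raw − background, 0) (over-subtraction clips to zero
with a warning), JM additionally divided by 1.5 to compensate for the
extra stain carried by a three-stranded molecule, then lds + JM + NC
normalized to 100 %. The circular single-stranded substrate is excluded
from the normalization sum. Total yield = %JM + %NC. EMSA lanes:
(band − blank background)/total lane signal, relative to the identically
computed no-protein control (= 100 % unbound).

## Survival statistics and the studentized range

Survival % = 100·actual/expected colonies (untreated control = 100 %).
Only balanced designs are supported (the motivating design is n = 3
throughout); MSE is the pooled within-group variance with df = k(n−1).
Tukey HSD uses SE_diff = √(2·MSE/n), Q = |Δmean|·√2/SE_diff, simultaneous
CIs Δmean ∓ q_crit(α, k, df)·SE_diff/√2 and p_adj = P(Q_{k,df} > Q).
`tukey_from_summary` reconstructs MSE = SE_diff²·n/2 so a published
comparison table can be reproduced from its printed inputs; an
inconsistent printed df is honored with a warning. MSE = 0 yields
infinite Q and a floored p (1e−16) with an explicit flag.

The studentized-range survival function is computed from its defining
double integral: the inner integral is the range CDF of k standard
normals, k∫φ(z)[Φ(z) − Φ(z−w)]^{k−1}dz, evaluated with 192-node
Gauss–Legendre quadrature over |z| ≤ 10; the outer integral averages over
the scaled-chi density of the pooled SD with 64-node panels concentrated
around its peak at 1 (panel edges 0, 0.5, 1, 1.5, 2.5, 4, 8). Both
integrands are smooth, so the fixed-order panels converge far below the
1e−5 documentation guarantee; the test suite verifies ~1e−14 agreement
with `scipy.stats.studentized_range` (used strictly as an oracle) and the
exact k = 2 reduction to a two-sided t tail. q_crit inverts the survival
function by bracketed Brent root-finding (xtol 1e−6). p-values are kept at
full precision; display rounding is the caller's concern.

## Synthetic-data generators

Each generator draws from an independent stream seeded by
`(seed, generator id)`, so outputs are reproducible and adding generators
never perturbs existing ones. Defaults mirror the motivating study's
printed magnitudes: a 176-residue chain, titration ratios 1:0 … 1:1 with
planted sites at residues 84–114 and 152–168 (core reduction 90 %, flank
50 % over a 5-residue ramp), an NOE baseline of 0.15 with 0.32 regions at
27–33 and 91–99 (σ = 0.03), anisotropy decays with k_off = 0.01 s⁻¹,
amplitude 0.08 and floor 0.105 (just below the 0.106 truncation level so
the truncation rule is always exercised), a 0.37 min⁻¹ turnover over 5 µM
recombinase, and survival group means 25.14/1.337/14.98 % with
within-group SD 4.154 (chosen so the pooled SE of difference lands near
the published 3.392 at n = 3). Shift noise defaults to σ = 0.2 ppm;
planted helix segments use offsets (+2.8, −0.9, +1.2) ppm and strands the
mirrored signs — magnitudes typical of fully formed secondary structure,
so partial population corresponds to proportionally smaller offsets.

The chain sequence itself is synthetic (uniform over the 20 letters with
prolines forced at a few positions); the real protein's sequence is not
modelled, so sequence-specific features (charge clustering, hydrophobic
patches) are absent. The generators emulate only the tabular observables:
no line shapes, relaxation, exchange broadening, chemical-shift overlap,
gel smearing or plating variability beyond Gaussian/lognormal noise.
Passing the recovery tests therefore demonstrates correctness of the
*quantification pipeline* under the stated noise models — not robustness
to every pathology of real spectra, which enter this pipeline only after
upstream processing and peak picking.

## Problem sizes

The test suite and drivers use the study-scale problem sizes throughout:
176-residue tables, 5-point titrations, 600 s traces, 6-point ATPase
courses, 3 replicates per strain; Monte-Carlo recovery checks use 100
seeds. The brute-force site-delineation oracle is exercised on 200 random
profiles up to length 200.

## Known limitations

* Unbalanced ANOVA designs and Tukey–Kramer are out of scope.
* NMR-STAR support is a read-only subset (first `Atom_chem_shift` loop,
  single entity, author numbering taken verbatim); writing NMR-STAR is not
  supported.
* Attenuation bins are hard categories; residues near a bin edge can flip
  categories under noise, which is why site delineation, not the bin
  counts, is the supported endpoint.
* The run rule counts residues, not atom values; with the configurable
  `min_run` this covers the plausible readings of "more than three
  consecutive values" used informally in the field.
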