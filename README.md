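# idpsitemap

Quantitative analysis pipeline for characterizing an intrinsically
disordered protein (IDP) domain and mapping where it binds a large partner
protein. The motivating system is the disordered N-terminal half of the
fission-yeast recombination mediator Sfr1 (Sfr1N, residues 1–176), which
binds the Rad51 recombinase through two short sequence sites, and the
battery of experiments used to characterize it: NMR chemical-shift and
heteronuclear-NOE analysis, HSQC titrations against Rad51, fluorescence
anisotropy filament-dissociation kinetics, malachite-green ATPase assays,
strand-exchange/EMSA gel densitometry, and clonogenic-survival statistics.

The package consumes the *tabular* outputs of those experiments (peak
lists, intensity tables, traces, densitometry values, colony counts) — not
raw spectra or gel images — and turns them into the derived quantities a
paper reports.

## What it computes

* **Disorder profiling** (`idpsitemap.disorder`): secondary chemical shifts
  Δδ = δ_obs − δ_rc for ¹³Cα/¹³Cβ/¹³CO against a bundled random-coil
  reference; residue-level coil/helix/strand calls (coil window ±0.7 ppm
  for Cα/Cβ, ±0.5 ppm for CO, ±4 ppm for prolines); detection of runs of
  ≥ 3 consecutive same-sense residues as candidate transient structure; and
  a far-UV CD heuristic (disorder-like ⇔ single negative trough near
  200 nm, no negative local minima above 210 nm).
* **Backbone flexibility** (`idpsitemap.hetnoe`): steady-state {¹H}-¹⁵N NOE
  = I_sat/I_ref per residue, protein-wide and per-region means.
* **Binding-site mapping** (`idpsitemap.titration`): per-residue HSQC
  intensity ratios across a titration, attenuation bins at the 1:0.25
  reference point (red > 80 % reduction, yellow 60–80 %, green 40–60 %),
  delineation of contiguous interaction sites (attenuated runs containing
  ≥ 1 red residue, bridging up to 3 non-evaluable/minimal residues), and
  combined ¹H/¹⁵N chemical-shift perturbations
  (√(Δδ_H² + (0.14·Δδ_N)²)).
* **Kinetics** (`idpsitemap.kinetics`): anisotropy decays truncated where a
  trailing 20-point moving average reaches the free-DNA level (0.106), then
  fitted to A(t) = amplitude·e^(−k_off·t) + floor; ATPase courses baselined
  at t=0, converted to [Pi] via a linear standard curve, with
  k_cat = slope/[Rad51].
* **Gel quantification** (`idpsitemap.gel`): background-subtracted lds/JM/NC
  band signals with the JM band divided by 1.5 (three-stranded molecules
  stain ~1.5×), normalized to 100 %; EMSA unbound fractions relative to the
  no-protein control.
* **Survival statistics** (`idpsitemap.survival`): survival % =
  100·actual/expected colonies, balanced one-way ANOVA
  (MSE, df = k(n−1)), and Tukey's HSD — Q = |Δmean|·√2/SE_diff,
  simultaneous CIs Δmean ∓ q_crit·SE_diff/√2, adjusted p from a
  **from-scratch studentized-range distribution** evaluated by
  Gauss–Legendre quadrature of its defining double integral (verified
  against `scipy.stats.studentized_range` to ~1e−14).
* **Synthetic data** (`idpsitemap.synth`): seeded generators for every input
  class with known ground truth (planted structured segments, planted
  binding sites, true rate constants, planted group means), so the whole
  pipeline is testable without any experimental download.

## Worked example

The numbered drivers under `analysis/` run the whole chain on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_disorder_profile.py
python analysis/03_map_interaction_sites.py
python analysis/04_fit_kinetics.py
python analysis/05_quantify_gels.py
python analysis/06_survival_statistics.py
```

With seed 1 this prints (abridged):

```
162/176 residues called coil
  candidate helix_like run: residues 27-33 (length 7)
  candidate strand_like run: residues 103-106 (length 4)
protein-wide mean NOE 0.166 (157/157 residues below 0.44)
  Site 1: residues 84-114 (21 red / 4 yellow / 4 green)
  Site 2: residues 152-168 (7 red / 4 yellow / 4 green)
  k_off 0.01002 /s, amplitude 0.0801, floor 0.1050
ATPase: slope 1.852 uM/min over 5 uM recombinase -> k_cat 0.370 /min
  (1.85-fold vs basal 0.2 /min)
Tukey HSD (published summary inputs):
      WT vs sfr1d  diff 23.80  Q 9.924  CI [13.395, 34.211]  p_adj 0.0010 *
      WT vs 7A     diff 10.16  Q 4.236  CI [-0.248, 20.568]  p_adj 0.0547 ns
   sfr1d vs 7A     diff -13.64 Q 5.688  CI [-24.051, -3.235] p_adj 0.0163 *
```

Reading: the planted transient-helix (27–33) and strand (103–106) segments
are recovered from the noisy shifts while the rest of the chain is called
coil; the two planted Rad51-binding sites are delineated exactly; the
dissociation and turnover fits recover the planted k_off = 0.01 s⁻¹ and
k_cat = 0.37 min⁻¹ (a 1.85-fold stimulation over the basal reference); and
the survival comparison table is reproduced from its summary statistics —
only the WT vs disordered-domain-deletion (sfr1Δ) and sfr1Δ vs 7A
differences are significant at α = 0.05.

A `idpsitemap` console script exposes the same stages as subcommands
(`convert`, `disorder`, `noe`, `titrate`, `koff`, `kcat`, `gel`, `tukey`,
`synth`); see `idpsitemap --help`.

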