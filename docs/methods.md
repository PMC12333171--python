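# Methods

## NPX data model and quality filters

NPX values are log2-scale relative abundances from proximity-extension-assay
panels; a difference of NPX means is a log2 fold-change. The data model is a
protein × sample matrix with NaN encoding missingness and a sample→condition
design over the five supernatant conditions (Medium, PBMC, rMSC, Coculture,
D3-cMSC). Inputs may use decimal commas (as European instrument exports do);
they are normalized at parse time.

Two filters precede analysis, in order:

* **LOD filter** — a cell strictly below its protein's limit of detection
  becomes missing; a cell exactly at the LOD is retained. The strict rule is
  a deterministic reading of "below LOD"; the boundary case is exercised in
  tests. Proteins without an LOD entry pass through.
* **Missingness filter** — proteins missing in strictly more than 50% of all
  samples (jointly, not per condition) are dropped and reported. 50.0%
  exactly is retained.

Both filters are idempotent. Threshold comparisons use an absolute tolerance
of 1e-9 throughout the package.

**Differential secretion** is per-protein classical one-way ANOVA across
condition groups (the replicate design is unbalanced: 2/3/4/4/4 supernatants
per condition), computed on individual samples, not condition means. A Welch
variant is available (`welch=True`) but is not the default. A protein is
testable when ≥2 conditions have ≥2 non-missing values; untestable proteins
are reported as such and excluded from the Benjamini–Hochberg family, which
is applied across tested proteins only. A protein with identical values
everywhere is assigned p = 1 by convention. Significance is padj < α
(default α = 0.01).

## Six-way secretome categorization

Each protein's unit of analysis is its vector of per-condition NPX means
(med, pbmc, rmsc, coc, d3). The six rules, with default thresholds in log2
NPX units:

| rule | definition | default |
|---|---|---|
| consumed | min(med−rmsc, med−coc, med−d3) ≥ τ_cons | τ_cons = 0.4 |
| conditioning | pbmc − med > 0 **and** min(coc−med, coc−rmsc, coc−d3) ≥ τ_cond | τ_cond = 0.3 |
| inhibited | min(rmsc−d3, coc−d3) ≥ τ_inh | τ_inh = 0.2 |
| immunomodulatory | d3 − max(med, pbmc, rmsc) ≥ τ_imm **and** d3 − coc ≥ −δ_coc | τ_imm = 0.25, δ_coc = 0.25 |
| constitutive | min(rmsc, coc, d3) − max(med, pbmc) ≥ τ_const **and** spread(rmsc, coc, d3) ≤ ε | τ_const = 0.4, ε = 0.75 |
| unclassified | nothing fired | — |

Precedence and multi-labelling: *consumed* is terminal (growth factors such
as EGF also satisfy the inhibited margins numerically, but depletion by the
cells is the parsimonious single explanation); *conditioning*, *inhibited*
and *immunomodulatory* may co-occur (CCL17 legitimately carries both the
conditioning and inhibited labels); *constitutive* is evaluated only when no
depletion/enrichment rule fired, since "equally present in all MSC
conditions" is meaningful only absent those patterns.

**Threshold derivation.** The reference table states the rule *directions*
("positive values retained after subtraction") but not numeric margins. The
defaults are the largest round values below the smallest margin observed in
the table for each rule: the weakest consumed protein (SRC) clears 0.46, the
weakest conditioning one (MSR1) 0.34, the weakest inhibited one (SAA4) 0.24,
the weakest immunomodulatory one (ADA) 0.29, and the largest tolerated
D3-vs-coculture deficit among immunomodulatory proteins (C1QTNF1) is 0.10
while the smallest excluded deficit (STC1) is 0.55. All seven thresholds are
configuration-exposed; with the defaults the packaged table reproduces its
printed section sizes exactly (7 consumed, 22 conditioning, 40
immunomodulatory; all 10 inhibited-section rows satisfy the inhibited rule).

The strict `pbmc > med` clause in the conditioning rule is load-bearing: it
is what excludes ADM (an inhibited protein whose coculture level is also
high) from the conditioning set, and it encodes "more abundant in PBMC
supernatants" literally. Four conditioning chemokines (CCL3, CCL4, CCL24,
GNLY) satisfy the inhibited margins as well and receive both labels; no
single threshold configuration can suppress those co-labels without also
breaking genuine inhibited members, so the multi-label output is reported
as-is rather than curated.

The packaged fixture stores the printed means verbatim (two decimals, dot
decimals); classification operates on these rounded means. The printed
subtraction columns are stored separately for QC only: 83 of 316 printed
differences disagree with subtraction of the rounded means by exactly 0.01,
indicating the original differences were computed from unrounded inputs. The
QC routine flags, and deliberately never corrects, these cells.

**Calibration** (`calibrate_thresholds`) grid-searches threshold
combinations maximizing exact label-set agreement with annotated profiles,
breaking ties toward larger (more conservative) thresholds.

## Composite clinical score

Four weekly tests map to ordinal sub-scores (all interval boundaries are
half-open, matching the printed two-decimal bin edges without gaps):

* weight loss % vs reference: [−∞,5)→0, [5,10)→1, [10,15)→2, [15,∞) or
  death→3. The reference defaults to the sham-arm weekly mean when a sham
  arm exists, else each animal's baseline-week weight.
* grip-strength loss % vs habituation: ≤0 (training gain)→0, (0,10)→1,
  [10,20)→2, [20,30)→3, [30,∞) or death→4.
* inverted-grid time Tr (s, capped at 60): 60→0, [45,60)→1, [30,45)→2,
  [0,30) or death→3. Tr outside [0,60] is an error.
* behavior grade ∈ {0, 0.5, 1, 1.5, 2, 3} (2.5 does not exist on the scale
  and is rejected); death→3.

`GCS = weight + strength + (behavior + grid)/2 ∈ [0, 10]`; a dead animal
scores exactly 10. How deaths propagate into later weeks is configurable:
the default carries the terminal maximal score forward; `drop_after_death`
removes post-death rows instead.

Per-animal normalization to the injection-week (default week 2) score uses a
ratio by default — the natural reading of "normalized to" — with a
difference mode available because a zero baseline leaves the ratio
undefined (the error message points there). Group comparison drops excluded
weeks (the study design motivates excluding weeks 3 and 7), summarises
arm × week means ± SEM, fits a two-way ANOVA (arm, week, interaction) and
runs Tukey's multiple-comparison test between arms within each week. A week
with zero variance (e.g. the baseline week under ratio normalization, where
every animal is exactly 1) is reported with p = 1 rather than NaN.

Humanization filtering removes animals whose last recorded human-CD45⁺
percentage is strictly below 0.4% of live blood cells.

## Combinatorial surface barcoding

Code books are the first n k-subsets of the m channels in lexicographic
order — deterministic, so a (m, k, n) triple always yields the same scheme.
The default m = 6 is the smallest channel count whose C(m,3) ≥ 15, the
per-tube sample load the barcoding was designed for; the actual isotope
list is an experimental detail the user supplies as channel names.

Debarcoding methods:

* **rank** — per event, scheme channels are ranked by intensity (ties broken
  by channel order); the top-k set is the candidate code. Assignment
  requires the candidate to be in the code book **and** the k/(k+1)
  intensity gap (the separation) to reach `min_separation`. A tie exactly at
  the boundary (separation 0) is never assignable: the top-k set is then
  ill-defined. This separation gap is the standard doublet guard — a doublet
  of two codes has >k elevated channels and hence a small gap.
* **threshold** — Boolean gating: the set of channels above per-channel
  cutoffs must equal a code exactly.

The two methods agree on events whose positive set equals the top-k set and
clears the separation requirement. Yield is non-increasing and
assigned-event accuracy non-decreasing in `min_separation`. Intensities are
consumed on a transformed scale (arcsinh with cofactor 5 by convention);
transformation of raw counts is out of scope for the debarcoder.

## CFSE analysis

Intensities are handled in log10 space; one division halves fluorescence,
i.e. a shift of log10(2) ≈ 0.301 decades. The undivided gate is derived from
the non-activated control as `mode − k·MAD_normal` (density mode from a
0.01-decade histogram smoothed with a 0.02-decade Gaussian kernel; MAD
scaled to be σ-consistent for a normal peak; k = 2.5 by default). The gate
construction is this package's own rule — instrument software typically
gates manually — and k is configuration-exposed. A multimodal control is
rejected with advice to pass the non-activated sample. Events exactly at
the gate count as undivided (strict inequality), a deterministic tie rule.

Generation counting walks density peaks downward from the undivided peak
(the topmost peak), accepting each next peak when its gap to the previous
accepted peak is within spacing × (1 ± 0.2); the walk stops, with a
warning, at the first out-of-window peak. The inhibition index is
100 × (1 − treated% / activated%), undefined when the activated control
shows no proliferation.

## Synthetic-data generators

All generators take a single integer seed feeding one `numpy` Generator; no
global state. Identical seeds give bit-identical outputs.

* **NPX panel** — 609 proteins by default over the study's replicate design
  (2/3/4/4/4 samples). Planted category counts mirror the study's split
  (7/65/22/10/40 of 609; the remainder null). Each protein draws a baseline
  level U(1,8) and category-specific offsets with margins U(1.0, 2.5) —
  comfortably above the classification thresholds, as in the reference
  table, where most margins exceed 1 — scaled by `margin_scale` (0 yields a
  pure null panel). The constitutive near-equality jitter is ±0.08, below
  half the inhibited threshold, so noiseless recovery is exact by
  construction. Per-sample Gaussian noise σ = 0.15 is a plausible
  within-condition spread (the study reports replicate counts, not
  variances) and is configuration-exposed.
* **Cohort** — a latent weekly severity s (0 = healthy) follows the placebo
  curve (0, 0.1, 0.3, 0.45, 0.6, 0.75, 0.9 over weeks 0–6); treatment at
  week 2 multiplies severity at later weeks by the arm's effect multiplier
  (defaults 1.0/0.9/0.5 for placebo/rMSC/cMSC, the cMSC value encoding a
  halving of disease severity). Each test observes s with independent
  Gaussian noise (σ = 0.08) and maps linearly with saturation: weight
  loss% = 20·s, grip loss% = 40·s − 4 (so a healthy animal shows a small
  training gain), Tr = 66 − 60·s clipped to [0, 60], behavior = nearest
  allowed grade of 3·s. The constants were chosen so the expected GCS is
  approximately proportional to severity over the operating range, which
  makes the arm-vs-placebo ratio of baseline-normalized GCS a consistent
  estimator of the planted multiplier (recovered to within ~2% at
  800 animals/arm). Deaths are Bernoulli per week with probability
  hazard × severity; humanization failures are planted at a rate or exactly
  per arm.
* **Barcoded events** — singlet code channels ~ N(6, 0.8²), background
  ~ N(1, 0.8²) on the transformed scale; doublets (an extra 5% by default)
  are channel-wise maxima of two random singlets, labelled `DOUBLET`.
* **CFSE** — a mixture over generations g with means undivided − g·log10(2)
  and peak σ = 0.05; the experiment generator emits matched non-activated,
  activated (60% divided) and treated arms with planted inhibition
  (defaults 0.30/0.35/0.70 for rMSC/γMSC/D3-cMSC supernatants, encoding the
  expected ordering with the conditioned secretome most suppressive).

What the generators deliberately do **not** model: assay-specific
inter-plate effects and bridging normalization, non-Gaussian NPX error,
antibody-binding chemistry and spillover in cytometry, cell-intrinsic
division-destiny heterogeneity in CFSE, and any pharmacokinetics (the
saxagliptin arm is a plain condition tag). Passing tests therefore
demonstrate correctness of the estimators under their stated statistical
assumptions, not robustness to those unmodelled features of real data.

## Problem sizes and numerical conventions

The test suite and acceptance script run at the sizes the analyses are
designed for: 609-protein panels, 500-protein null panels, 10,000-event
debarcoding and CFSE samples, cohorts of 9/arm (study scale) and 50/arm
(effect-recovery checks, with the planted-multiplier ratio averaged over
three seeded replicates, since its single-replicate sampling spread at
50/arm is ±0.02–0.03). Stochastic checks fix their seeds. Floating-point
threshold comparisons use a 1e-9 absolute tolerance; rank ties break by
channel order; interval boundaries are half-open as specified above.

## Known limitations

* The constitutive category cannot be validated against the printed table
  (its members were not published); it is tested synthetically only.
* The classifier reproduces the printed sections' sizes but is honestly
  multi-label: four conditioning chemokines also satisfy the inhibited
  margins. The printed single-label assignment of those proteins appears
  partly curated and is not reproduced by thresholding alone.
* ANOVA assumes independent supernatants; shared-donor correlation between
  coculture and D3-cMSC samples is not modelled.
* The debarcoder consumes event tables (CSV); binary FCS ingestion is out
  of scope.
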