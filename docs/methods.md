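# Methods

This note documents the models and procedures implemented in `senflux`,
the defaults and why they are what they are, what the synthetic
benchmark does and does not establish, and the numerical choices a
maintainer would otherwise have to reverse-engineer.

## Constraint-based flux model

A metabolic state is a flux vector `v` satisfying steady-state mass
balance `S·v = 0` and box bounds `lb ≤ v ≤ ub`, with `S` the
stoichiometric matrix. Flux balance analysis (FBA) maximises one
reaction's flux (here: the biomass pseudo-reaction, a surrogate for
proliferative capacity) over this polytope.

**Expression constraints.** Enzyme abundance per reaction is computed
from the GPR boolean rule: AND-nodes (subunits of one complex) take the
minimum of their children, OR-nodes (isozymes) take the sum. This is the
standard enzyme-complex/isozyme convention. The capacity bound is
`Vmax_j = kcat_j · E_j · σ`. σ, the abundance→flux conversion, is a
single global constant (default 1): expression units (FPKM-like) are
arbitrary, and a global constant preserves every ratio and rank the
downstream statistics consume. Reactions without a kinetic entry, or
without a GPR (transports, exchanges, pseudo-reactions), keep their
default bounds. Genes absent from a sample's profile contribute
abundance 0 — the reaction may become blocked — with a logged warning
rather than an error, since real expression matrices routinely lack a
few model genes.

**Medium.** Exchanges are written `met → ∅`; uptake is the negative
flux direction, so a medium entry `u` sets `lb = −u`. Exchanges not in
the medium get uptake 0; secretion is never restricted.

**Maintenance.** ATP production is essential regardless of growth, so
the ATP demand flux is maximised first and its lower bound fixed at
90 % of the optimum; biomass is then maximised under that constraint
and likewise bounded at 90 %. The fraction (0.9) is configurable, and
the biomass bound can be switched off. Both bounds are applied uniformly
in all workflows. If a later perturbation makes the model infeasible,
the biomass bound is relaxed to 0 first, then the ATP bound, and the
relaxation is recorded in flags — a lethal knockout must yield a defined
flux vector, not an exception.

**The per-sample flux.** Reversible reactions are split into
irreversible forward/backward pairs (so all fluxes are nonnegative,
which the log-ratio statistics require), and flux variability analysis
(FVA) computes each reaction's attainable `[min, max]` under all
constraints. The reported flux is the interval midpoint: it is
symmetric, deterministic, and immune to the arbitrary-vertex problem of
a single FBA solution. The FBA vertex is available as an alternative
summary (`summary="fba_vertex"`).

**Numerics.** All LPs are solved with HiGHS dual simplex, single
thread — deterministic for fixed input, so whole-pipeline reruns are
bit-identical. A persistent solver instance is reused across the
objective changes of FVA and knockout scans (warm starts); a
`scipy.optimize.linprog` fallback path solves the identical LP if the
incremental interface is unavailable. Feasibility/optimality tolerances
are HiGHS defaults (~1e−9); fluxes with `|v| < τ = 1e−6` are snapped to
zero, and the same τ is the dead-band for knockout effect signs.

## Differential statistics

**Case–control.** Per reaction, a two-group comparison of
`log2(flux + ε)` with pooled empirical-Bayes variance moderation: the
per-reaction variance is shrunk toward the across-reaction mean with
prior df d₀ = 4 (`t` with d₀ + n₁ + n₂ − 2 df), mimicking moderated-t
behaviour at small n; a plain t-test is available (`moderated=False`).
The reported log2FC is `log2((mean_sen + ε)/(mean_pro + ε))` on the raw
flux scale; ε = 1e−6 × the mean nonzero flux, which makes the
pseudocount scale-free. Senescent is always the case group. Swapping
group labels negates log2FC exactly; constant-zero reactions get
log2FC 0, p 1.

**Time series.** Ordinary least squares `flux ~ passage` per reaction
(raw flux scale; the slope β has units of flux per passage). The design
assumes one linear trend; the per-passage DA trajectory (below) is the
tool for non-linear structure.

**Meta-analysis.** Per-study standardized effects are combined with the
inverse-variance fixed-effects model: `Z = d̄√(Σwᵢ)`, `wᵢ = 1/vᵢ`,
two-sided normal p, BH-FDR across reactions. For case–control studies
the standardized effect is a Hedges-g-like standardized mean difference
`g = Δlog2/s_pooled` with the classical SMD variance
`(n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂))`; the small-sample J correction is off
by default (configurable). For time series, `d = β/se` with unit
variance. The exact internals of fixed-effects combiners differ across
implementations; this choice is the textbook SMD convention and is
documented here precisely because it is a genuine degree of freedom.
At n = 5 per group the g statistic has slightly heavy tails, so the
pipeline-level null is validated through its FDR rate (≤ 7 % of null
reactions at FDR < 0.05) while exact standard-normal calibration of the
combiner is validated at the combiner level. A reaction observed in
fewer than two studies is reported but never classified. The meta
log2FC is the arithmetic mean of per-study log2FCs.

## DA pathway scores

`DA_i = (n_up − n_down)/n_total ∈ [−1, 1]` per subsystem. Significance
is a bootstrap without replacement that conditions on the observed
totals: each of B iterations draws `n_up + n_down` reactions from the
universe without replacement and randomly splits them into an up set of
size `n_up` and a down set of size `n_down`, recomputing all DA scores.
Two-sided p-values use |DA| with the plus-one rule, so `min p =
1/(B+1)`; B defaults to 1000. Subsystems with fewer than 3 reactions
are reported with their DA but p = NaN — the resampling null is
degenerate below that size. Whether such a bootstrap should resample
reaction identities or significance labels is a genuine open choice;
conditioning on the observed up/down split (joint draw, fixed split) is
implemented because it holds the margins of the observed table fixed.

## Knockout effective scores

A gene knockout zeroes the bounds of every reaction whose GPR evaluates
to 0 once the gene's abundance is set to 0 (an expressed isozyme rescues
the reaction through the OR-sum). A metabolite knockout zeroes every
reaction whose stoichiometry involves the metabolite, exchanges
included — equivalent to removing the species from the network, so
deleting an extracellular metabolite also disables its transport and
exchange. The perturbed profile is recomputed with the same FVA-midpoint
summary as the baseline (sign consistency), on the study's *reference
model* — the model constrained by the mean expression of the
proliferative (or first-passage) samples, since perturbations are scored
against the unperturbed baseline state. Effects are ternary signs with
dead-band τ; transport reactions carry no enzymatic constraint in this
framework and their columns are dropped.

`GES_i = Σ_j G^KO_ij · sign(log2FC_j) · L_j` with
`L_j = 1{p_j < 0.05 and |log2FC_j| > 0.5}` for case–control studies.
For time series the slope sign substitutes for the fold-change sign and
`L_j = 1{fdr_j < 0.05}`, because a per-passage slope has no natural
magnitude threshold. Scores are integers when effects are ternary, and
a positive score means the deletion reproduces the senescence-direction
flux shift (an agonist); the sign convention is reported as-is without
asserting a biological direction. Entity significance fits a Normal to
all entity scores of the run (mean/sd; median/MAD available) and takes
two-sided tail probabilities; the background therefore includes the true
hits, which makes the per-study p conservative when many entities are
effective. Meta: mean score across studies, signed Stouffer
(`zᵢ = Φ⁻¹(1−pᵢ/2)·sign(scoreᵢ)`, `Z = Σzᵢ/√k`), BH-FDR.

The scan is validated against an independent brute-force oracle that
*physically deletes* the affected reactions, rebuilds each LP from
scratch as a dense `linprog` problem, and re-derives the midpoints; the
ternary matrices must match exactly.

## Time-series workflow

Besides the per-reaction slopes, each passage is contrasted against the
first passage with the case–control machinery, giving a DA trajectory
per subsystem (the first contrast is identically zero by construction).
The biomass trajectory statistic is the Spearman correlation of the
*per-passage mean* biomass midpoint against passage — with duplicate
cultures per passage the correlation is over the passage points, which
is the convention for published passage-course correlations and keeps
the statistic insensitive to within-passage replicate noise.

## Synthetic benchmark

The generator builds a ~60-reaction toy network whose topology contains
exactly the structure the method is designed to detect:

* a trunk with **two redundant hexose sources** (glucose, fructose, each
  with its own transporter and catabolic gene) feeding pyruvate and ATP;
  redundant carbon sources are standard in culture media, and the
  redundancy means no single hexose route is essential;
* pyruvate → acetyl-CoA (PDH), an oxidation reaction (acetyl-CoA →
  10 ATP) and a lactate-like overflow secretion, so that energy and
  carbon disposal are decoupled — without an overflow valve the ATP
  maintenance bound would artificially throttle biomass through
  pyruvate disposal;
* a **six-step mevalonate-like chain** (one gene per step, the planted
  targets) from acetyl-CoA, feeding an eight-reaction **lipid branch**
  that is biomass-essential, plus a small isoprenoid secretion branch
  off the chain end (the branch point is what distinguishes chain genes,
  whose loss kills everything downstream, from lipid-branch genes);
* three independent six-gene decoy pathways and a biomass reaction
  consuming pyruvate, a nucleotide precursor, lipid and ATP.

Baseline gene means are log-uniform within role bands chosen so the
chain is the enzyme-limited step for lipid synthesis (chain genes 2–3,
lipid 5–10, trunk 10–20, decoys 3–6, isoprenoid 0.5–1 expression
units); kcat is 1 everywhere so expression alone drives capacity.
Samples are `mean · 2^shift · lognormal(0, noise_sd)` with
`noise_sd = 0.3` — multiplicative noise with positive support, matching
FPKM behaviour. Case–control mode plants `effect_lfc = −1` (a 2×
knockdown) on the six chain genes of senescent samples, with per-study
jitter sd 0.1 modelling between-study heterogeneity; the default design
is 5 studies of 5 vs 5 samples. Time-series mode uses 9 passages
(13…37) with 2 replicates each and a planted decline growing linearly
in passage to a total of log2(3) ≈ 1.585 — a ≈3-fold drop across the
course, the magnitude typical of fibroblast passage series.

What the benchmark does **not** emulate: read-level RNA-seq (counts,
library size, mapping noise), genome-scale network redundancy (the
human model has thousands of reactions and extensive isozyme/pathway
redundancy that dilutes knockout effects), kinetic saturation (no Km
terms), batch effects between platforms, and any metabolomics
measurement process. Passing the recovery tests therefore shows the
statistics and the LP machinery are correct and well-calibrated under
the model's own assumptions — not that the pipeline will recover
targets at genome scale with the same margins.

## Problem sizes used in checks

The recovery checks run the full default benchmark (5 studies × 10
samples, ~60 reactions, ~40 genes, ~45 metabolites). Calibration checks
use 2000-reaction simulated matrices at the statistics level; the
knockout-vs-removal oracle uses 100 random networks of ≤ 20 reactions;
growth-arrest detection uses 20 seeded single-study replicates; the
null-safety check uses 20 replicates of a reduced 2-study, 3 vs 3
design with B = 300, which if anything is noisier (more false-positive
prone) than the default design.

## Known limitations

* The FVA midpoint is one defensible flux summary among several; rank
  statistics downstream are stable to this choice, absolute fold
  changes less so.
* The norm-background p assumes most entities are null; in the toy
  network a third of genes are genuinely effective, inflating the
  background sd and making per-study p conservative (the meta
  combination restores power).
* The fixed-effects combiner assumes one common true effect per
  reaction; between-study heterogeneity beyond the planted jitter would
  call for a random-effects model, which is out of scope.
* Single deletions only; no double knockouts, no flux-coupling
  pre-reduction.
* GPR AND/OR semantics (min/sum) ignore stoichiometric subunit ratios
  and regulatory effects.
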