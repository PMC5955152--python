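# Methods

## The synergy statistic

`synercurve` quantifies how a fixed-dose pretreatment (an EZH2 inhibitor,
dosed in µM) changes the dose–response of a secondary drug (the HDAC
inhibitor panobinostat, dosed in nM) in a cell-line panel.  Classical
combination-index methods (Chou–Talalay) need a full single-agent
dose–response for *both* drugs; many myeloma lines show no single-agent
response to EZH2 inhibition at all, which makes those methods inapplicable.
The statistic used instead is the relative decrease in the area under the
survival curve (AUSC):

1. **Control normalization.** Every well signal is divided by the pooled
   mean of the untreated (media-only) control wells of the same line,
   giving survival fractions.  Replicates are normalized individually
   before averaging, and the per-dose SEM is taken across these normalized
   biological replicates.
2. **Anchor normalization.** Each curve (single-agent arm and each
   pretreatment arm) is divided by its own value at zero secondary dose.
   The anchored curve starts at exactly 1, so any uniform viability loss
   caused by the pretreatment alone cancels and only the *shape* of the
   secondary-drug response remains.  This operation is idempotent and, for
   a multiplicative pretreatment kill, cancels it exactly (verified to
   1e-12 in the test suite).
3. **Integration.** AUSC is the composite trapezoid integral of survival
   against an x axis that is either `log10(dose)` (the default — serial
   dilutions are log-spaced, so this weights each dilution step equally)
   or the point index.  Under the log axis the zero-dose point is excluded
   from the grid (its information already lives in the anchor).  For
   uniform serial dilutions the two axis modes differ only by a constant
   factor, which cancels in the relative score; the chosen mode is recorded
   in every `SynergyScore`.
4. **Score.** `delta_ausc_rel = (AUSC_single − AUSC_combo) / AUSC_single`,
   dimensionless in (−∞, 1].  Positive values mean the combination curve
   lies below the single-agent curve (synergy); negative values mean
   apparent antagonism, which anchor normalization can manufacture for
   lines that are strongly sensitive to the pretreatment alone.  The
   absolute decrease is stored alongside.  Survival values above 1 after
   normalization are retained (clipping would bias the integral).

Panel screens report one score per (line, pretreatment) pair, sorted by
descending synergy, plus the count of lines exceeding a *reporting*
threshold (default 0.1).  The threshold is a labeling convenience for
summaries, not a statistical test, and is configurable.

## Differential-expression set analysis

DE tables (gene id, control FPKM, treated FPKM, log2 fold change, p, FDR)
come from upstream quantification (e.g. Cuffdiff `gene_exp.diff`, which the
reader parses directly).  A gene is called differentially expressed when

* `FDR < 0.05` (strict inequality),
* `max(FPKM_control, FPKM_treated) ≥ 1` (inclusive — at least one
  condition must express the gene), and
* `|FC| ≥ 2` on the linear scale (`|log2FC| ≥ 1`); a lenient 1.5-fold
  threshold is always reported alongside.  Infinite fold changes (exactly
  zero FPKM on one side) always satisfy the fold-change criterion.

Genes with zero FPKM in both conditions are dropped up front (undefined
fold change, cannot pass the expression filter); genes passing
FDR/FPKM with log2FC exactly 0 have no direction and are excluded with a
log message.  The sign of log2FC routes each call to the up- or
down-regulated set, and every operation preserves up/down disjointness.

Set algebra on the calls:

* **Venn regions** for 2–3 conditions, by exact per-gene region assignment.
  Direction-agnostic by default (region counts partition the union);
  direction-aware mode decomposes up- and down-calls separately, so a gene
  moving in opposite directions in two conditions does not count as shared.
* **Unique-to-combination**: combination calls absent from the union of
  both single-agent call sets (membership tested direction-agnostically),
  with direction labels inherited from the combination.
* **Persistence** between time points: direction-aware shared counts and
  the fraction of the earlier set retained later (reported as `None` for
  an empty earlier set).

## Synthetic data

The generators provide ground-truth test beds; they emulate the
*statistical structure* the analysis assumes, not any particular dataset.

**Viability panels.**  Survival follows a Hill kill model,
`S(d) = (1 − k_pre·[combo]) · (1 − Emax·d^h/(d^h + EC50_eff^h)) · e^ε`,
with multiplicative lognormal well noise `ε ~ N(0, σ²)` (luminescence
readouts are positive and scale-proportional).  Synergy is planted as a
potency shift — `EC50_eff = EC50/shift` in the combination arm of selected
lines — because the observed combination effect is a left-shift of the
secondary-drug curve; the pretreatment's own toxicity is a uniform kill
fraction `k_pre`, which the anchor step must cancel.  Defaults: Emax 0.95,
EC50 10 nM, Hill slope 1.5, σ 0.05, 3 replicates, 8 doses (0–100 nM,
roughly half-log spaced), shift 4, `k_pre` 0.2.  The generator draws all
randomness from one `numpy` Generator seeded explicitly; identical seeds
give bit-identical panels.

**DE tables.**  Baseline FPKM per gene is lognormal (ln-mean 1.0, ln-sd
1.5).  Effect genes are drawn from the clearly expressed fraction
(baseline ≥ 2 FPKM): an effect planted below the expression floor can
never be called by a filter requiring FPKM ≥ 1, so such genes stay null by
construction.  Agent A perturbs 5.5% of genes (4% up, 1.5% down — a bias
toward upregulation, as expected when inhibiting a transcriptional
repressor), agent B 1% (the weak-single-agent regime), the combination
retains 80% of each single agent's effects and adds a 10% unique block
(75% up).  Planted |log2FC| is uniform in `effect ± 25%` around a mean of
2.  Observed FPKM values get lognormal measurement noise (σ 0.2);
p-values come from a z-model in which the planted effect shifts the test
statistic by `effect / sd(log2FC estimate)`, so null genes are
uniform-distributed and planted genes concentrate near zero.  The FDR
column is Benjamini–Hochberg within each table (via
`statsmodels.stats.multitest`; an independently coded sorted-rank BH
serves as the oracle in the tests).

With these defaults the downstream pipeline sees the regime the analysis
targets: the combination set is ~2–3× the dominant single agent and about
two thirds of combination calls are unique to the combination; across 20
seeds the pipeline recovers ≥ 94% of planted unique genes with ~4% mean
contamination.

**What the generators do not model:** plate edge/drift effects, shared
per-plate noise, count-based (negative-binomial) expression noise,
correlated genes, multi-gene loci and identifier collisions, or
time-course kinetics.  Passing tests therefore demonstrate correctness of
the *computational procedure* under its stated assumptions, not robustness
to every artifact of real screens or real RNA-seq.

## Numerical choices and edge cases

* Trapezoid integration uses `numpy.trapezoid`; the suite checks agreement
  with an explicit pairwise-sum implementation to 1e-12 on random curves.
* Anchoring a curve whose zero-dose survival is ≤ 0, integrating fewer
  than 2 usable points, and mismatched dose grids are hard errors, not
  silent repairs; a panel screen downgrades them to per-line skips with a
  warning so one bad line cannot abort a screen.
* Duplicate gene ids in a DE table keep the first row and warn
  (deterministic and auditable); `inf`/`-inf` round-trip as literal text.
* All tables are UTF-8, comma/tab auto-detected, decimal point only.

## Known limitations

* The relative AUSC decrease is a ratio of noisy integrals of
  anchor-divided curves, so it carries a small negative bias of order σ²
  under the null (≈ −0.003 at σ = 0.05 with 3 replicates).  The bias is
  far below the score differences of interest (planted synergy scores
  ≈ 0.5) but would become visible when averaging thousands of null
  scores.  No bias correction is applied: the score is reported exactly as
  defined.
* Direction handling of cross-condition overlaps is ambiguous in general;
  both modes are implemented and the choice is recorded in the output.
* The panel call threshold (0.1) is a reporting convention with no
  inferential content.
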