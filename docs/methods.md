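# Methods

## The analysis model

`traplate` analyzes a TRAP-Seq experiment given as a dense genes ×
samples TPM matrix plus a sample sheet mapping each library to a
fraction (IN = input transcriptome, IP = immunoprecipitated
translatome) and a group (control vs condition), with at least two —
by design three — biological replicates per (fraction, group) cell.
TPM values are treated as the unit of analysis throughout; the package
deliberately contains no count-model machinery, because the procedure
it implements is rank- and threshold-based rather than
likelihood-based.

### Percentile ranks and the two gene universes

Within each sample, gene *i* receives the percentile rank
`100·(r_i − 1)/(N − 1)` where `r_i` is its 1-based midrank among the
sample's values. This maps every sample onto [0, 100] regardless of
sequencing depth or TPM scale, with tied values sharing a rank; ranks
are invariant under any strictly monotone transform of a column.

Filtering is nested and asymmetric by construction:

* **Transcriptome universe** — genes with rank *strictly above* the
  30th percentile in *every* IN sample. The strict inequality means a
  gene sitting exactly at the threshold in one sample is excluded.
* **Translatome universe** — percentile ranks are *recomputed within
  the transcriptome universe* for each IP sample (so "15th percentile"
  means 15% of the consistently transcribed genes, not of all genes),
  and genes *at or above* the 15th percentile in every IP sample are
  kept. The translatome is therefore always a subset of the
  transcriptome.

Requiring the criterion in *every* sample makes the filter an
intersection over samples: adding samples can only shrink a universe.

### Quantile normalization

Applied per fraction (IN samples together, IP samples together) over
the transcriptome universe: each sample's sorted values are replaced by
the position-wise mean of the per-sample sorted values; ties within a
sample receive the mean of the reference values their sorted positions
span. IN and IP libraries have systematically different compositions
(the IP is dominated by one cell type), so forcing them onto a common
distribution would distort both; all group contrasts are within one
fraction, which is what normalization must make comparable. Whether to
pool fractions was a genuinely open choice; per-fraction is this
package's decision.

### The three DE statistics and the call rule

For each gene in the analysis universe (translatome for IP, transcriptome
for IN), with quantile-normalized values `x` and percentile ranks `q`
recomputed on the normalized matrix within that universe:

* `log2fc = log2((median(x_cond) + c) / (median(x_ctrl) + c))` with
  pseudocount `c = 0.01` TPM (configurable). The pseudocount prevents
  infinities at zero medians while being far below any expressed
  gene's TPM.
* `SSMD = (mean(q_cond) − mean(q_ctrl)) / sqrt(var(q_cond) + var(q_ctrl))`
  with unbiased (n−1) variances. Operating on ranks makes SSMD capture
  *systematic shifts in a gene's position* within the expression
  distribution, insensitive to the heavy tail of TPM. If both groups
  are exactly constant the statistic is 0 for equal means and a ±1e9
  sentinel otherwise (keeps degenerate synthetic inputs total).
* Signed overlap: each group's normalized TPM values are summarized as
  a normal distribution (sample mean, unbiased variance floored at
  1e−8); the Gaussian closed-form Bhattacharyya distance
  `D_B = ¼·ln(¼·(σ₀²/σ₁² + σ₁²/σ₀² + 2)) + ¼·(μ₀−μ₁)²/(σ₀²+σ₁²)`
  gives the classical overlap coefficient `BC = exp(−D_B) ∈ (0, 1]`,
  and the reported statistic is `sign(log2fc)·(1 − BC)`: 0 for
  identical group distributions, approaching ±1 for disjoint ones.
  With n = 3 per group a nonparametric overlap estimate is impossible;
  the two-moment Gaussian summary is the only estimator the design
  supports and reproduces the statistic's stated range and limits.

Call rule: **increased** iff `SSMD ≥ 0.9` and signed overlap `≥ 0.5`
and `2^log2fc ≥ 1.33` with `log2fc > 0`; **decreased** iff all three
mirrored (`≤ −0.9`, `≤ −0.5`, ratio `≤ 1/1.33`); otherwise
**unchanged**. The decreased side is the sign-mirrored reading of the
thresholds — the only reading consistent with applying them to
absolute values. The fold-change bound is applied to the linear ratio,
so 1.33 means "at least a third more (or 1/1.33 less) than control".

All three statistics are oriented condition minus control; exchanging
group labels negates each one and swaps increased↔decreased. The
production path is vectorized across genes but is tested to be
numerically identical to the per-gene scalar functions.

### Translational efficiency

`(median(IP) + c)/(median(IN) + c)` per gene serves as a proxy for
translational status: a gene whose IP signal changes while IN does not
is translationally, not transcriptionally, regulated. The package
computes the ratio; interpreting condition/control TE ratios is left to
the caller, and the algebraic identity
`TE_cond/TE_ctrl = 2^(log2FC_IP − log2FC_IN)` (at zero pseudocount) is
enforced in tests.

### QC

Replicate correlation is Pearson r on `log2(TPM + 1)`; raw-TPM
correlations are dominated by a handful of very abundant genes, so the
log scale is used by default (configurable). The gate requires every
within-(fraction, group) replicate pair to reach r ≥ 0.97 —
the reproducibility level a pooled-replicate TRAP experiment should
achieve — and, for fraction specificity, positive IP/IN set-level
enrichment (median of per-gene `log2((IP median + c)/(IN median + c))`)
for microglial markers and negative for neuronal and other
non-neuronal sets. The default marker sets are the standard mouse
symbols: microglial {Tmem119, Aif1, Cx3cr1, P2ry12}, neuronal {Gad2,
Camk2a, Calca, Calcb}, other non-neuronal {Sox10, Olig1, Gfap, Mog,
Mbp, Olig2}. Marker files must use the same gene-identifier space as
the matrix; no symbol mapping is attempted.

### Group statistics

The behavioral-endpoint stage wraps classical tests: pooled-variance
unpaired two-tailed t test, one-way ANOVA, 2×2 (sex × genotype)
ANOVA with **type-II sums of squares** (robust to the unbalanced group
sizes typical of behavioral cohorts; with a balanced design type II
equals the textbook decomposition, which the tests verify), and Tukey
HSD with studentized-range adjusted p-values. These are delegated to
statsmodels/scipy; the module adds the design validation and the
stable tabular interface.

## The synthetic generator

Per gene, a baseline log₂ abundance is drawn from
`Normal(baseline_log_mean = 4, baseline_log_sd = 2)` — TPM spanning
roughly 0.1 to 10⁴ over ~15,000 genes. Each library's value is
`2^(baseline + fraction_effect + group_effect + ε)` with
`ε ~ Normal(0, replicate_noise_sd)` drawn independently per gene and
library. The IP fraction effect carries +3 log₂ (8×) for microglial
markers, −3 log₂ for neuronal/other markers, and full suppression
(floored at 0.01 TPM) for a configurable fraction (default 10%) of
unplanted genes, emulating transcripts present in the tissue but not
translated in the captured cell type. The group effect, ±`de_log2fc`
(default 2), is applied only in IP-condition samples for the planted
up/down genes (default 100 + 100). One `numpy` Generator seeded from
`GeneratorConfig.seed` drives everything; identical seeds give
bit-identical datasets.

Parameter choices that matter:

* `replicate_noise_sd = 0.12` log₂ units (≈ 8.5% CV). Two constraints
  pin this scale: within-group replicate correlation on log₂(TPM+1)
  must reach the r ≥ 0.97 a pooled-replicate experiment exhibits
  (analytically r = σ²_baseline/(σ²_baseline + σ²_noise) ≈ 0.996
  here), and the triple-threshold rule must stay quiet under the null,
  as it does on real data where only ~2% of translatome genes are
  called. The second constraint is the binding one: at noise ≈ 0.25
  the chance fluctuation of a median-of-3 difference crosses the
  1.33× fold-change bound for several percent of null genes, a regime
  in which no threshold-based screen could have produced the sparse
  hit lists this design yields. 0.12 satisfies both constraints with
  margin and corresponds to the low biological variability expected
  when each replicate pools multiple animals.
* Planting windows. Up-regulated genes and markers are drawn from the
  50th–95th baseline percentile (expressed genes, avoiding the extreme
  top). Down-regulated genes come from the 80th–95th percentile: a
  −2 log₂ shift moves a gene far down the IP rank distribution, and
  only genes starting in the top quintile are guaranteed to remain
  inside the inclusive 15th-percentile translatome filter after the
  shift — below that, a planted decrease is unrecoverable by
  construction, just as a real translationally silenced gene would
  drop out of the detected translatome.
* Silenced genes are drawn only from unplanted genes, keeping the
  truth sets disjoint.

What the generator does **not** emulate: sequencing-depth and
gene-length biases, count noise at low abundance (values are
log-normal at every abundance), batch effects, correlated gene
modules, compositional renormalization of TPM after the planted
shifts, and partial (rather than all-or-none) IP silencing. Passing
tests therefore demonstrate that the pipeline's statistics and
thresholds behave as specified under the model the analysis itself
assumes — not that the thresholds have any particular error rate on
real sequencing data.

## Numerical and interface choices

* Percentile formula `100·(r−1)/(N−1)` with midranks: "30th
  percentile"-style thresholds become scale-free cutoffs on [0, 100];
  minimum maps to 0, maximum to 100. At least 2 genes are required.
* Quantile-normalization ties: a run of equal values receives the mean
  of the reference entries its sorted span occupies (so the output is
  a function of the value, not of the arbitrary sort order).
* Variance floor 1e−8 in the overlap statistic and the ±1e9 SSMD
  sentinel keep every gene's statistics finite on degenerate inputs.
* The on-disk dialect is UTF-8 TSV with a header row and gene IDs in
  the first column; missing values are rejected (TPM quantifier output
  is dense), negatives and non-numeric cells are reported with their
  gene/sample coordinates. DE tables print 6 significant digits and
  sort by gene ID, making reruns byte-identical.
* The run manifest embeds the fully resolved configuration and a
  timestamp; all other outputs are deterministic functions of the
  inputs, and the test suite checks byte-for-byte reproducibility of
  the tables (manifest compared modulo timestamp).
* Problem sizes in the tests: most properties are exercised on
  1,000–2,000-gene matrices, chosen because every statistic here is
  per-gene and scale enters only through rank granularity; the
  planted-recovery and QC-target checks run on the full 15,000-gene
  default configuration.

## Known limitations

* FC, overlap, and medians are computed on quantile-normalized TPM by
  default (raw TPM remains available through the library API); which
  scale the original procedure used is not fully determined, and the
  choice shifts borderline fold changes.
* With n = 3 per group, SSMD and the overlap statistic are extremely
  noisy per gene; the triple threshold controls false calls only
  because all three criteria must agree. No error-rate guarantee is
  implied and none is computed.
* The benchmark-scale comparison against a reprocessed public dataset
  (re-quantifying the deposited FASTQ data) is out of scope here: the
  resulting universe sizes and call counts depend on upstream
  alignment and quantification choices that this package deliberately
  does not contain.
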