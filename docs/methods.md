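# Methods

## The evolutionary model

A transcription factor (TF) is a vector of abstract expression levels in
[0, 1], one per gene; any functional relationship between genes is
deliberately ignored, so results speak only to the *structural* advantage
of a modular genome. A uniform-random target TF is approached by classic
differential evolution (DE/rand/1/bin): each population member is
challenged once per generation by a trial vector built from three other,
mutually distinct members as `x_r1 + F * (x_r2 - x_r3)`, taken per
coordinate with probability `CR` (one randomly chosen coordinate is always
taken, so a trial never trivially equals its parent), clipped to [0, 1],
with greedy selection and ties resolved in favour of the trial. The
fitness readout is the quality index (QI): the mean absolute per-gene
distance between a candidate and the target — an error expressed as a
fraction of the expression range, so the success criterion "QI < 0.001"
reads as agreement to within 0.1% of range, averaged over genes.

Termination: success (best QI < `qi_success_threshold`, default 0.001),
stagnation (best QI improved by less than `stagnation_min_decrease`,
default 1e-6, over the trailing `stagnation_window` generations, default
1000), or a hard generation cap. Generation-0 entries in trajectories are
the initial random population.

Two strategies are compared on identical targets. *Genome-based*: one DE
run over all G coordinates. *Sigma-factor-based*: independent DE runs
inside each block of a partition of the genome into 11 mutually exclusive,
covering "sigma-factor regulons"; the block winners are concatenated. The
mean absolute distance decomposes exactly over a partition, so the
genome-wide QI of the assembled candidate is the size-weighted mean of the
per-block QIs, and if every block succeeds at threshold t the whole genome
is below t as well. Both cost accountings are recorded: the *sum* of
per-block generations/evaluations (serial-CPU reading, used for headline
comparisons) and the *maximum* over blocks (parallel reading). Coordinate
evaluations — one per gene per trial — are the hardware-independent cost
unit reported alongside wall time.

## Choice of the population size NP

This is the one genuinely load-bearing free parameter. For rand/1/bin the
population variance contracts each generation by a factor that depends on
F, CR and NP (Zaharie's variance analysis); below the critical size
`NP* = (2 - CR) / (2 F^2)` — exactly 80 at the CR=0.4, F=0.1 used here —
contraction outruns selection and the population collapses prematurely far
above the success threshold, for *any* problem dimension beyond a few
genes. Just above NP*, convergence is reliable only up to a
dimension-dependent ceiling: empirically ~250 genes at NP=100 and ~400
genes at NP=120, while 500- and 1000-gene problems stagnate around QI
2e-3–2e-2. The package default is NP=100; the G=1000 success-probability
experiment uses NP=120 so every block of a random 11-block partition of
1000 genes is individually solvable while the whole genome is not. This
dimension ceiling is precisely the regime in which the modular question is
interesting: per-block subproblems sit inside the solvable range, the
joint problem outside it.

## Targets, regulons and bias

Hypothetical TFs draw all G target entries uniform(0, 1) — evolution never
happens in isolation from the rest of the genome, so selection and
termination always use the whole transcriptome — while a designated
regulon (the genes the TF "regulates") is only *monitored*: its restricted
QI series yields Δn, the first generation at which the monitored QI drops
below 0.01. In real-data mode, measured expression is max-normalised into
the target and the regulon comes from a membership column of the gene
table.

Regulon membership is sampled without replacement, either uniformly or
with a geometric bias: blocks are ranked by size (ascending for
small-factor preference, descending for large), rank k gets weight
`(1-p)^k * p`, and every gene carries its block's weight (a flag divides
the weight among block members instead). Sampling uses
Efraimidis–Spirakis keys in log space, which renormalises automatically as
blocks empty. The geometric parameter p defaults to 0.5 and is a config
knob; no canonical value exists for it. Block-size ties rank in
declaration order.

Random partitions draw sizes by placing `n_blocks - 1` uniform cut points
among the `n_genes - n_blocks` free genes and adding one gene to every
block (each block nonempty by construction); alternatively a supplied size
pool is randomly permuted. Genes without a sigma assignment in real data
form an implicit extra block labelled `unassigned`.

## Enrichment statistics

The enrichment factor EF = (k/n)/(K/N) compares a category's share of a
detected gene set with its genome share; EF ≥ 1.5 is called
over-representation and EF ≤ 0.66 under-representation (inclusive
thresholds, both configurable). When the categories partition the genome,
the K/N-weighted mean of EFs over categories is exactly 1 — asserted in
tests. Unassigned genes form no category but count, by default, in both
totals (toggleable). Upstream, the regulated-gene filter keeps genes with
fold change ≥ 2 or ≤ 0.5 *and* FDR-adjusted p ≤ 0.05; the
differential-expression fit that produces those tables is out of scope, so
adjusted p-values are inputs. No significance test is attached to EF
itself; the stats module is available to callers who want one.

## Statistical procedures

Fisher's exact test (2×2 success tables), the Wilcoxon–Mann–Whitney
rank-sum test (exact permutation null when the combined sample is ≤ 12 and
tie-free, otherwise normal approximation with tie and continuity
correction — the route taken is flagged on the result), the Wilcoxon
signed-rank test for paired strategy comparisons, and Holm–Bonferroni
step-down adjustment. Alternatives default to two-sided; experiment code
states its sidedness explicitly. In the hypothetical-TF sweep the Holm
family is the set of pairwise bias comparisons within one
(strategy, regulon size) panel.

## Synthetic data

The generator emulates the *statistical structure* the analysis assumes,
not any real organism. A 6000-gene genome is split into 11 sigma regulons
(default illustrative sizes 950…270, spanning a ~3.5-fold range; gene-to-
block assignment is a seeded random permutation; PA14-style locus tags).
Expression is log-normal with a shared per-block latent activity scaled by
`modular_correlation` (default 0.8), so within-block correlation exceeds
between-block correlation — the co-expression signature of modular
regulons. TF-mutant experiments give true regulon members log2 fold
changes of magnitude 1.5 + Exp(0.5) with random sign and adjusted p-values
uniform on (0, 0.01); background genes have true fold change 0 and uniform
p-values; Gaussian noise of `noise_sd` (default 0.3) log2 units is added
to all genes. At these defaults the two-fold filter recovers a size-200
regulon with ~0.99 sensitivity and ~0.9999 specificity. What passing
tests do **not** show: real profiles have correlated errors, library-size
effects and regulon overlap that this generator deliberately omits;
conclusions about the pipeline's behaviour on real data are limited
accordingly.

## Scales of the shipped experiments

The test suite and `scripts/acceptance.py` run the designs at reduced
scale, chosen as the smallest sizes at which the compared effects are
statistically unambiguous: paired cost comparison at G=500 with 20 paired
seeds; success probabilities at G=1000 with 10 repeated 2-replicate
comparisons under a 2000-generation budget; the F=0 variant with 12 pairs;
the bias sweep with regulon sizes {30, 200} × three bias modes × 5 TFs per
class; 50 seeds for the synthetic enrichment pipeline; 2000 simulations
for the rank-sum null calibration. Paper-scale parameters (G=2000,
regulon sizes up to 1200, 10 TFs per class, 200 replicates) remain
reachable through the same configs.

## The F=0 robustness variant

With F=0 the mutation step only copies coordinates of existing members, so
the population can never generate values absent from the initial sample
and no run reaches QI < 0.001; both strategies stop by stagnation, and
comparing raw stop-time generation counts would only measure the number of
stagnation windows paid (11 versus 1). The preserved advantage is
therefore measured where it is well defined: coordinate evaluations needed
to reach QI 0.1 — a level both strategies attain — and the final QI under
the same stopping rule. Both favour the sigma strategy, with roughly 3×
fewer evaluations and half the final error.

## Numerical and design choices

- Distance metric: mean absolute difference (interpretable as % of range);
  pluggable in principle, fixed in the implementation.
- Boundary handling: clip to [0, 1] (expression levels are defined there).
- RNG: one `numpy` Generator per DE run with a documented consumption
  order (donor permutations, forced crossover index, crossover uniforms),
  which is what makes the loop-based reference oracle able to reproduce
  the vectorized engine bit-for-bit. Strategies derive one substream per
  block from the seed; block 0's substream is the genome strategy's, so a
  one-block partition reproduces the genome run exactly.
- Per-block budgets: the stagnation rule and generation cap apply to each
  block independently; sigma-strategy success requires *every* block to
  succeed (the fraction of successful blocks is also reported).
- Monitored (regulon) QI tracks the member that is best genome-wide, so
  the monitored series need not be monotone; Δn is its first crossing.
- Degenerate inputs are validation errors, not silent defaults: empty
  monitored sets, all-zero expression, inconsistent enrichment counts,
  zero-margin tables.

## Known limitations

- Absolute generation counts and CPU seconds depend on NP, the stagnation
  parameters and hardware; only orderings, ratios and significance are
  meaningful, and no attempt is made to match any particular absolute
  figure.
- The DE variant is fixed (rand/1/bin, parent-keeping binomial crossover);
  base-vector crossover and per-gene bias weights are exposed as flags but
  not part of the headline experiments.
- The exact rank-sum route switches to the normal approximation at
  combined n > 12 or in the presence of ties; p-values near that boundary
  change by up to ~0.02.
- The enrichment module does not fit differential expression; it consumes
  fold-change/adjusted-p tables produced elsewhere (or synthetically).
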