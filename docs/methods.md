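# Methods

## Model and procedure

The pipeline treats regulation as linear in log2 expression space. For
every candidate (regulator, target) pair a single-regressor OLS screen is
run first; the multivariate model of each target is then selected from the
screen's survivors. The screen exists for two reasons: it removes the bulk
of spurious forward predictions cheaply, and it keeps the multivariate
problem well-posed when a target has more candidate regulators than there
are samples. Assumptions worth stating explicitly:

* **Linearity and additivity** — regulator effects add; no interactions or
  saturation.
* **miRNA action by degradation** — a miRNA can only lower its target's
  mRNA level, so miRNA efficacies are constrained negative twice: at the
  screen (a significantly *positive* pairwise slope disqualifies the pair)
  and after selection (a positive miRNA coefficient in a final model voids
  **all** of that target's edges, the strictest reading of the rule).
* **TF effects of either sign** — activation and repression are both legal.
* **TF self-regulation pairs are excluded** before the screen; regressing a
  row on itself is degenerate.

The screen uses the two-sided slope p value with a closed boundary
(p = α₁ is kept) and then gates miRNA slopes by sign, so on null data TF
candidates survive at rate ≈ α₁ and miRNA candidates at ≈ α₁/2. Both rates
are verified on 10⁴ independent Gaussian pairs in the test suite.

## Selection variants and their operating points

Two selection methods are first-class and deliberately occupy different
points on the precision/recall curve:

* **`step`** — bidirectional stepwise selection from the intercept-only
  model, minimising AIC (verified to reproduce R's `step()` selections on
  shared fixtures). AIC retains any term whose partial p value is below
  ≈ 0.16, which is precisely what produces retained edges with p > 0.05
  (the "low" credibility tier). Consequently, with T planted edges among D
  decoy candidates its edge precision is bounded near T/(T + α₁·D·c), c ≈
  0.75 accounting for the miRNA sign gate: on the default benchmark (20
  truths, 180 decoys, n = 59, σ = 0.1) it measures ≈ 0.78–0.80 precision at
  ≈ 0.99 recall, and its permutation FDR under strong signal sits near the
  same decoy-retention rate (≈ 25–30%).
* **`lasso`** — LASSO path with the penalty chosen by 10-fold
  cross-validation at the 1-SE rule (the sparsest model within one standard
  error of the CV optimum), support refit by OLS for efficacies, t and p
  values. This is the conservative mode: ≈ 0.95 precision, ≈ 0.99 recall,
  strong-signal permutation FDR ≈ 2% on the same benchmark.

Term p values are always the partial t-test p values of the final refitted
OLS model; intercepts are refit at every step. Exactly collinear regressor
duplicates are dropped deterministically in identifier order before
selection.

Two intrinsic limitations of the marginal screen are worth knowing. First,
a true regulator can be *swamped*: if a target's other regulator
contributes much larger variance, the weak regulator's marginal slope may
be insignificant and the edge is lost (a recall, not a numerical, failure).
Second, in the exactly noise-free limit a regulated regulator is exactly
collinear with its own driver, making attribution between them
unidentifiable; efficacy-convergence checks therefore run at σ = 10⁻⁸,
where recovered efficacies match planted ones to ≈ 10⁻⁹.

## Preprocessing

Rows are kept when their value exceeds a platform floor (defaults 2.3 for
miRNA, 7.0 for mRNA arrays) in strictly more than `min_samples` arrays
(default 47 of 59) — both inequalities strict. Order of operations is
filter → centre → average synonymous probes; averaging centred rows keeps
them centred. Probes missing from the probe map are retained under their
own identifier with a warning. Missing values are a parse error by design:
silently imputing them would corrupt the regressions downstream. A
config-level sample drop-list handles panels with excluded samples.

## TF→miRNA candidate construction

Coordinates are 0-based half-open throughout (BED convention; the UCSC
wgRna dialect is converted on read). "Embedded" means fully contained:
a miRNA partially overlapping a gene, or inside one on the opposite
strand, is intergenic. When several genes contain a miRNA the longest
container is the host. Intergenic clustering is single-linkage per
chromosome and strand with an inclusive 7.5-kb gap. The cluster promoter is
−3000/+1000 bp around the 5'-most member's TSS; on the minus strand the TSS
is the interval end and the window is mirrored; windows are clipped at
coordinate 0. A binding site overlapping the promoter by ≥ 1 bp makes its
TF a candidate for *every* cluster member (co-transcription assumption).
The window sizes and gap are parameters, not discoveries of this package.

## Permutation FDR

Expression values are shuffled *within each dataset* — by default cell-wise
across the whole matrix (destroying both row and column structure;
`permutation_granularity: row` switches to within-row shuffling), always
preserving the dataset's value multiset exactly. The full pipeline is rerun
per permutation and every resulting edge is a false discovery by
construction; FDR(type) = mean shuffled count / real count, reported with
the across-permutation SD. With no planted signal the real count follows
the same distribution as the shuffled counts, so the ratio concentrates at
100% — but it is a ratio of small counts: a default-size scenario yields
only ~7 null edges, giving the ratio a ±35% sampling SD. Calibration checks
therefore use a 1000-candidate scenario averaged over 6 scenario draws with
20 permutations each (ratio SE ≈ 7%), which is also the configuration the
acceptance script reports.

## Jackknife predictability

For each sample the entire chain — screen and selection — is refit on the
other n−1 samples and the held-out value is predicted; the reported score
is the Pearson correlation between measured and predicted vectors (NaN if
either is constant). When a fold selects no regulator the prediction is the
fitted intercept, i.e. the training mean. A caution for interpretation:
leave-one-out training means are *exactly* anti-correlated with the
held-out values, so targets with no real signal score strongly negative
PCCs, not zero. Predictability is therefore meaningful relative to a
permuted-expression baseline (planted targets score > 0.9 while their
permuted versions score below zero), never against an absolute zero line.

## Topology and motifs

* Betweenness is directed, unweighted, unnormalized, endpoints excluded,
  with tied geodesics counted fractionally.
* The Krackhardt hierarchy score is 1 − (mutually reachable ordered pairs)
  / (reachable ordered pairs) over directed reachability; 1 for a DAG.
* The out-degree power-law slope is an OLS fit of log₁₀ frequency on log₁₀
  degree over raw (unbinned) nonzero out-degrees — the simplest reading of
  a "slope", chosen deliberately over maximum-likelihood exponent fitting.
* Coordinating pairs use a one-sided Fisher exact test on the 2×2 target-
  membership table; the default universe is every distinct target in the
  inferred network (configurable to the pair's candidate-target union).
* The circuit catalogue contains exactly 18 types. Feed-forward loops
  (A→B, B→C, A→C) take every kind assignment with legal edges whose sink C
  is an ultimate target (miRNA or non-TF gene) and that contains at least
  one TF and one miRNA: 8 (TF,TF,miR) + 4 (TF,miR,gene) + 2 (miR,TF,gene)
  = 14 once TF-outgoing edges carry either sign and miRNA edges are fixed
  repressing. Feed-back loops (A→B→C→A) admit a single kind-legal mixed
  cycle, miR→TF→TF→miR, whose two TF edges carry free signs: 4 types,
  anchored at the miRNA for canonical orientation. An instance is a vertex
  triple whose induced edges are exactly the three circuit edges with
  matching kinds and signs.
* Null networks for motif significance preserve every vertex's in- and
  out-degree per regulation type (regulator kind × miRNA-vs-mRNA target
  class) by within-type pair swaps; edge signs travel with the source, so
  each regulator keeps its sign multiset. Empirical p values use the
  add-one estimator (1 + exceedances)/(n_rand + 1), never exactly zero.

## Synthetic scenarios

The generator emulates a 59-sample parallel panel at desk scale. The
planted truth is layered (TF indices ascending, then miRNAs, then genes) so
it is acyclic by construction; TF efficacies are uniform on ±[0.5, 2] with
random sign, miRNA efficacies on −[0.5, 2]. Defaults plant 20 edges
(10 TF→gene, 7 miRNA→gene, 2 TF→miRNA, 1 TF→TF) among 12 TFs, 15 miRNAs
and 50 genes, and add 9 decoys per truth drawn uniformly from the kind-legal
non-true pairs, giving a 200-edge candidate superset. Root molecules are
i.i.d. N(0,1) per sample; regulated molecules are their efficacy-weighted
parents plus N(0, σ²), σ = 0.1 by default, evaluated in topological order
(if motif planting introduced a cycle, the generative pass severs the last
cycle-closing edge; the emitted truth table is untouched). Per-row
baselines (uniform 4–6 for miRNA, 9–12 for mRNA) place values above the
default platform floors so the frequent-expression filter passes active
rows and drops the optional injected inactive rows. The toy genome is a
single chromosome with evenly spaced genes, ≈ 35% of miRNAs embedded in
hosts, intergenic miRNAs partly paired within the clustering gap, and one
binding site per cluster promoter.

What the generator does **not** emulate: probe-level noise, batch and
tissue effects, non-linear or saturating regulation, translational
repression without degradation, and the heavy-tailed degree structure of
real regulatory networks. Passing the recovery benchmarks therefore
demonstrates correctness of the machinery under the model's own
assumptions, not performance on real panels.

## Numerical choices and degenerate inputs

Zero-variance regulators are flagged degenerate and never kept; a
zero-variance target yields an untestable pair, likewise dropped. AIC
comparisons use a 10⁻¹⁰ improvement threshold to avoid tie cycling.
Stepwise never adds beyond n − 2 terms. The LASSO penalty grid is
scikit-learn's 100-point default; folds are shuffled with the configured
seed, making runs reproducible. Sample sets of the two matrices must match
exactly (order may differ); candidates whose molecules lack expression rows
are counted and logged, not errors. Empty candidate sets, empty filter
results and empty networks are legal and propagate as empty outputs.

## Known limitations

* Precision of the `step` mode is capped by AIC's liberal retention (see
  operating points above); users wanting high-precision edge lists should
  use `lasso` or restrict to the high-credibility tier.
* The marginal prefilter can drop weak true regulators of strongly
  regulated targets (swamping), and with few samples its α₁ boundary is
  the dominant source of decoy edges.
* Motif counting is exhaustive over triangles of the underlying undirected
  graph; it is intended for networks up to a few thousand edges, not for
  dense graphs.
* The permutation FDR reruns the full pipeline per permutation; its cost is
  n_perm × one inference run.
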