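# Methods

`grninfer` infers gene regulatory networks (GRNs) from a gene-expression
matrix alone, following the data-driven paradigm: every candidate link from
a transcription factor (TF) to a target gene (TG) receives a real-valued
score, the scored links are ranked, the top of the ranking defines the
predicted network, and — when a gold standard exists — the prediction is
judged as a binary classifier. This note records the models, the defaults,
and the choices made where the design was genuinely open.

## Preprocessing

**RNA-seq normalization.** `rpm` rescales each library (column) to a sum of
10⁶ reads; `rpk` divides counts by gene length in kilobases; `rpkm` applies
both; `tpm` divides by length first and then rescales each column to 10⁶, so
TPM values are comparable across libraries. `mor` computes median-of-ratios
size factors: for each condition, the median over genes (restricted to genes
with positive counts in every condition) of the ratio between the count and
the gene's geometric mean across conditions; columns are divided by their
factor. This removes a pure depth effect exactly and is robust to a minority
of differentially expressed genes. It is implemented natively rather than by
delegating to an external differential-expression package, because only the
size-factor statistic is needed.

**Discretization** (levels `0..L-1`): `efd` assigns per-row equal-frequency
bins by rank, ties broken stably by column position, so bin occupancies
differ by at most one whenever values are distinct; `ewd` uses equal-width
bins on `[min, max]` per row, with constant rows mapped to level 0 (a legal
input for discretization, unlike for z-scoring); `kmr`/`kmc` run 1-D K-means
per row/column; `bkm` alternates row-wise and column-wise K-means
re-assignment on the current label matrix until the joint labels are stable
or 50 alternations elapse. The 1-D K-means is a hand-written Lloyd iteration
initialized at evenly spaced quantile centres (midpoints of L equal-mass
slices), run to convergence with at most 300 iterations, and relabelled so a
higher level always means a higher cluster centre. This initialization makes
every discretizer deterministic; the `seed` argument is kept for interface
stability but no randomness remains. When a row holds fewer distinct values
than levels, each distinct value becomes its own level (ties collapse).
The alternating realization of bidirectional K-means is a documented design
choice; a simultaneous co-clustering variant would be equally defensible but
is harder to make deterministic and to test.

**Standardization.** `zr`/`zc` are row-/column-wise z-scores with the
*population* standard deviation (divide by n) — one convention had to be
fixed for bit-reproducible outputs and this is it; `zr` is idempotent to
1e-9. Constant rows/columns are an error naming the offending gene or
condition: flat genes must be filtered before z-scoring. `polish`
alternately removes row and column means until every absolute marginal mean
falls below 1e-8 or 100 sweeps elapse; only means are polished, not
variances (mean-polishing is the conservative reading of the technique and
the variance-normalizing variant can be recovered by composing with `zr`).

## Link scoring

All scorers return a TFs × targets matrix wrapped in `ScoreMatrix`: higher
means stronger evidence, and self-links carry NaN (a sentinel for
"excluded", never a score). A gene that is both TF and target is removed
from its own predictor set, for the same reason. Every stochastic scorer is
deterministic given its seed: the base seed fans out to per-method and
per-target sub-seeds through a splitmix64-style hash keyed by strings, so
adding a method or target never shifts another's stream.

**Co-expression** (`pr`, `sr`, `kt`): the absolute Pearson, Spearman or
Kendall-tau statistic between the two profiles, in [0, 1]. Constant genes
score 0 with a warning rather than raising — real matrices contain flat
genes and a scorer should not abort. These scores are symmetric and
undirected; direction comes only from restricting rows to annotated TFs.

**CLR** (`clr`): mutual information background-corrected per gene. Profiles
are discretized by equal-frequency binning into `ceil(log2(c)+1)` bins (a
Sturges-like rule in the number of conditions c — a deterministic,
assumption-light MI estimator); MI is the plug-in estimate on the joint
histogram. For a pair (t, g), MI(t, g) is z-scored against TF t's MI
distribution over all targets, and against target g's distribution over all
TFs; negative z-scores are truncated at zero (the standard CLR convention —
being *less* related than background is not evidence) and the score is
`sqrt(z_t² + z_g²)`. A zero-variance background contributes 0.

**Feature importance** (regressors `abr`, `gbr`, `rfr`, `xrtr`, `svmr`,
`brsr`; classifiers `abc`, `gbc`, `rfc`, `xrtc`, `svmc`, `cnbc`): one
supervised model per target predicts its expression (regressors) or its
discretized expression level (classifiers; 1-D K-means with 5 levels by
default) from the TF profiles; the per-TF importance of the fitted model is
the link score. Tree ensembles (100 estimators by default) use
impurity-based importances, which sum to 1 per target when nonzero. SVMs
use a linear kernel and the absolute coefficient (class-averaged for the
classifier) — nonlinear kernels have no native per-feature importance.
Bayesian ridge uses the absolute posterior-mean coefficient. Complement
naive Bayes requires nonnegative features, so predictors are shifted by the
matrix minimum; its importance is the spread (max minus min) of the
per-class feature log-weights, i.e. how strongly a TF discriminates between
expression levels. The SVM and CNB extraction rules are this package's own
documented choices. A target whose discretized labels collapse to one class
gets an all-zero score row and a warning.

**Stability selection** (`tigress`, `srl`): for each target, R = 256
resamples each draw ⌊c/2⌋ conditions without replacement and multiply each
TF column by an independent uniform(α, 1) weight with α = 0.3; TIGRESS fits
least-angle regression and records the TFs entering within the first L = 2
steps (the *frequency* variant: the score is the plain selection frequency,
not the area under the selection curve), SRL fits the lasso at penalty
λ = 0.1·λ_max (λ_max computed per target on the full standardized data as
`max|Xᵀy|/n`, the smallest penalty that zeroes all coefficients) and records
the TFs with nonzero coefficients. Scores are selection counts divided by
R — exact multiples of 1/R in [0, 1]. Predictors are centred and scaled
within each resample. L larger than the predictor count is clamped with a
warning.

## Ensemble integration

Scores from different methods live on incomparable scales. Before
averaging, each member matrix is standardized by one of six schemes: a
z-score or a rank transform, computed over the full matrix (`z-full` /
`rank-full`), per target column (`z-tg` / `rank-tg`) or per TF row (`z-tf` /
`rank-tf`). Ranks assign 1 to the highest score, with mid-ranks on ties
(keeping rank sums invariant), and are then negated so that every scheme
shares the "higher = better" polarity required by downstream selection —
averaging raw ranks and flipping at selection time would give the identical
end-to-end order; flipping per member keeps one polarity throughout the
code. Excluded self-links never enter any stratum statistic (they are
non-links, not evidence). The ensemble is the unweighted arithmetic mean of
the standardized members, hence invariant to member order. Zero-variance
strata standardize to all zeros with a warning.

## Selection and evaluation

`select_top_k` keeps the k best links globally or around one gene.
`evaluate` treats inference as binary classification over the *evaluable
universe*: ordered pairs (t, g) with both genes experimentally studied and
t ≠ g. Gold edges are positives; universe pairs absent from the gold
standard are negatives; predicted links touching an unstudied gene are
excluded and provably cannot change any metric. Because AUROC/AUPR need a
complete ranking of the universe, universe pairs missing from the
prediction are appended below every predicted link (internally: one unit
below the lowest predicted score, in deterministic (tf, tg) order) — the
completion convention mirrors how community benchmarks fill unranked
pairs. AUPR uses step-wise interpolation of the precision–recall curve
(linear/trapezoidal PR interpolation is known to be optimistic); AUROC is
the trapezoid over the tie-grouped ROC curve. Both are verified against an
explicit threshold-sweep oracle to 1e-9 in the test suite.
Precision/recall/F1 are set metrics on whatever edge list is passed — pass
a top-k selection to get thresholded numbers. When no explicit studied
lists are given, the genes appearing in the gold-standard file define them.
Method comparison is unsupervised: pairwise Jaccard of top-k edge sets, and
PCA over the methods' flattened, standardized score vectors.

## Synthetic benchmark

The generator draws a bipartite linear-Gaussian GRN: TF profiles are i.i.d.
standard normal across conditions; each target is a linear combination of
exactly `regulators_per_tg` TFs (weights with random sign, magnitude
uniform in [0.5, 2] — strong enough to be detectable, spread enough that
regulators differ in difficulty) plus N(0, noise_sd²) noise. Defaults — 20
TFs, 100 targets, 3 regulators per target, 200 conditions, noise sd 0.5,
seed 7 — are sized so the whole recovery benchmark, including tree
ensembles and 256-resample stability selection, runs in about a minute on
one CPU while leaving plenty of headroom between signal and chance. A
linear-Gaussian simulator was chosen over a kinetic/ODE one because it is
the setting in which feature-importance recovery is provable and fast; the
flag `tf_targets` adds acyclic TF→TF edges (each TF after the first driven
by earlier TFs) for experiments where regulators are themselves regulated.

What passing the recovery tests shows — and what it does not: on this
generator, correlation, random-forest, Bayesian-ridge and TIGRESS scorers
reach AUROC ≥ 0.85 and the Z-TG ensemble of {BRSr, SVMr, RFr} is at least
as good as its best member within 0.05. Real expression data are
non-Gaussian, nonlinear, confounded and feedback-ridden; the synthetic
result validates the *implementation* (the scorers recover a network that
is recoverable in principle, the metrics measure what they claim), not the
biological accuracy of any method on a given organism. Mean AUROC of the
correlation scorer degrades monotonically as noise rises through
{0.25, 1.0, 4.0}, which the suite also checks.

## Numerical and degenerate-input conventions

- Population (ddof = 0) standard deviations everywhere a z-score appears.
- Ranked edge lists sort by descending score with ties broken by (tf, tg)
  lexical order; every downstream consumer inherits this order, so equal
  scores never introduce run-to-run variation.
- Floats are written with `repr`, making write/read round-trips bit-exact
  and repeated pipeline runs byte-identical.
- Zero library size, missing gene lengths, no all-positive gene
  (median-of-ratios), constant rows under z-scoring, empty regulator lists,
  labels outside {0, 1}, axis mismatches between ensemble members, and an
  empty or positive-free evaluation universe are all explicit errors naming
  the offending entity; degenerate strata and single-class targets degrade
  to zeros with warnings instead, because they arise routinely inside
  otherwise healthy matrices.

## Known limitations

- Scores are unsigned strengths; activation is not distinguished from
  repression.
- Co-expression scorers are undirected and will score TF–TF pairs
  symmetrically.
- The MI estimator is a fixed-grid plug-in; no bias correction is applied,
  which is adequate for ranking but not for absolute MI values.
- No time-series, probabilistic-graphical or deep-learning scorers, and no
  motif-based refinement — the adjacency output (`TF`, `target`,
  `importance`) is formatted so SCENIC-style tools can consume it directly.
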