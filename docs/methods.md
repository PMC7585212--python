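# Methods

## Model and procedure

The selector treats marker finding for one cluster as recovery of a sparse
separating hyperplane through the origin. With `X̄` the column-wise
rank-standardized counts and `τ̄` the ranked, centered ±1 cluster indicator,
the coefficient vector solves

    max_ω Σ_i τ̄_i ⟨x̄_i, ω⟩   s.t.  ‖ω‖₂ ≤ 1, ‖ω‖₁ ≤ √s.

Three facts drive the implementation:

1. The objective is linear, `⟨v, ω⟩` with `v = X̄ᵀ τ̄`, so the maximizer is a
   normalized soft-thresholding `T_β(v)/‖T_β(v)‖₂` of the score vector. The
   entries of `v` are `n·σ(Φ(τ))` times the Spearman correlations of each gene
   with the indicator, so the per-cluster selection is exactly "the top-k genes
   by |Spearman ρ|", with k determined by the budget rather than chosen by the
   user.
2. `f(β) = ‖T_β(v)‖₁/‖T_β(v)‖₂` is continuous and non-increasing on
   `[0, max|v|)`, so the budget-saturating threshold is unique when it exists.
3. On the interval of β where the support has size k (between consecutive
   distinct magnitudes of |v|), `f(β) = √s` is the quadratic
   `k(k−s)β² − 2S₁(k−s)β + (S₁² − sS₂) = 0` with `S₁, S₂` the sum and sum of
   squares of the top-k magnitudes. Scanning k upward and keeping the first
   root inside its interval solves the problem in closed form.

Degenerate paths: if `(‖v'‖₁/‖v'‖₂)² ≤ s` on the nonzero coordinates the
budget never binds (β\* = 0, all nonzero-score genes are returned,
`constraint_active = False`). Squaring the ratio equation introduces an
artifact double root where `T_β(v)` vanishes; every analytic root is therefore
verified against `f` directly (tolerance 1e-8 relative) with per-interval
bisection (width 1e-12·max|v|) as a fallback. Tied magnitudes enter or leave
the support together; when the top tie group alone already exceeds the budget
(t tied maxima, s < t) the optimizer is non-unique and the solver returns the
full tie group with equal weights — the deterministic, conservative choice.
In that one case the reported ‖ω̂‖₁ is √t > √s; everywhere else ‖ω̂‖₂ = 1 and
‖ω̂‖₁ = √s hold to 1e-9/1e-6.

Multi-class selection fixes one s, computes `X̄` once, runs the binary
selector per cluster, and unions the lists (duplicates across clusters are
reported per cluster and removed only in the union; no smarter merging is
attempted). Within a cluster, markers are ordered by |coefficient| descending
with ties broken by gene index; the union preserves ascending class order and
within-class order, so output files are reproducible byte for byte.

### How many markers a cluster gets

The support size at fixed s depends only on the *shape* of |v| (the solver is
scale-equivariant). A flat profile of near-equal correlations yields a support
of roughly s genes; a spiky profile (one dominant gene over a wide low floor)
forces the threshold deep into the floor before the ℓ1 sphere is reached, and
can produce a *large* support of mostly tiny coefficients. The clean
"one perfect marker ⇒ one-gene list" behaviour occurs when the remaining
genes are uncorrelated enough that the budget never binds. No sharper
characterization of per-cluster counts is claimed; only monotonicity —
supports are nested and counts non-decreasing in s — is guaranteed and tested.

## Parameters that matter

| Parameter | Where | Default | Meaning |
|---|---|---|---|
| `s` | selection | user-set, ≥ 1 | ℓ1 budget is √s; larger admits more markers |
| `target_sum` | evaluation normalization | 10,000 | per-cell library size before log2(1+x) |
| `K` | cross-validation | 5 | folds; selection/training on K−1, scoring on the held-out fold |
| `k_neighbors` | clustering metric | 15 | k-NN graph on the marker space (no PCA — the markers are the retained dimensions) |
| resolutions | clustering metric | 0.1–3.0 step 0.1 | grid over which each of ARI/AMI/FMS is maximized separately |

Evaluation conventions chosen where the procedure is underdetermined:
nearest-centroid distance is Euclidean in log-normalized marker space (ties to
the lowest class id); per-class precision with zero predicted positives is 0;
multi-class MCC is the Gorodkin R_K form; AMI uses the arithmetic-mean
normalizer; error-type metrics are flipped to 1 − value before AoM averaging
so larger is uniformly better, and AoM ranks share the minimum rank on ties.
Random-forest or other external classifiers plug into the same selector/CV
harness as injected callables; they are not part of the deterministic test
surface because of their run-to-run variance. Graph community detection is
likewise injected; the provided backend uses leidenalg's
resolution-parameterized modularity partition.

## Synthetic data: what it emulates and what it does not

The generator is a Splat-style gamma-Poisson sampler, not Splat itself: gene
relative abundances are Gamma(shape 0.6) (scale cancels under per-cell
normalization); exactly `round(de_fraction·p)` genes — default 10% — carry a
multiplicative DE factor on the group-1 mean drawn LogNormal(0.1, 0.4), applied
as f or 1/f with probability ½ each; library sizes are LogNormal(7.3, 0.35)
(~1500 counts/cell); counts are negative binomial with dispersion 0.4. The
DE-gene count is fixed rather than Bernoulli so the ground truth matches the
configuration exactly. No dropout is layered on top: zero inflation (roughly
90% zeros at the default 12,000 genes) already emerges from the small means,
and independent random zeroing is not a realistic dropout model. Defaults for
the library-size and dispersion parameters are free choices set once to match
that sparsity level.

Not emulated: mean–variance (BCV) trends, batch effects, trajectories or
doublets, and the correlation structure of real transcriptomes. Passing the
recovery tests therefore shows the selector finds planted monotone
mean-shifts under realistic sparsity — not that it resolves subtler real-data
structure. Because factors concentrate near 1, many flagged genes are nearly
undetectable in principle; precision over long selection prefixes is bounded
well below 1 by design, while the random baseline's expected precision equals
the DE fraction.

The dispersion filter (highly-variable-gene selection) normalizes cells to the
median library size, bins genes into 20 equal-occupancy bins by mean, and
standardizes dispersion (variance/mean) within bins by median/MAD — the robust,
median-based flavor — returning a nested top-k with ties to the lower index.

## Numerical and design choices

- Ranks are tie-averaged (scipy `rankdata`, method "average"), computed per
  gene column, never across genes; the standardization divides by the
  population (1/n) standard deviation.
- Constant genes have zero rank variance and are dropped before selection with
  their indices recorded; they can never be markers and would otherwise divide
  by zero. An all-constant matrix is an error.
- All-zero cells pass through library-size normalization unchanged (0/0 must
  not poison the matrix; filtering cells is the caller's responsibility).
- The printed soft-threshold form used throughout is
  `sign(x)(|x| − β)` for `|x| > β`, else 0 — the form consistent with the
  support property `{|v_j| > β}` and with the normalized-soft-thresholding
  solution of the optimization.
- Gene identity is carried by string id across every subsetting step; MTX
  input defaults to the on-disk genes × cells orientation and is transposed
  to cells × genes in memory.
- All randomness (folds, simulation, random baselines) flows from explicit
  integer seeds through `numpy.random.default_rng`; equal configuration gives
  bit-identical outputs.

## Test and verification strategy

The solver is validated against an independent convex program (SLSQP on the
split formulation ω = w⁺ − w⁻, which makes both constraints smooth) on
hundreds of random instances, against a dense grid search for β, and against
1000-point random feasible sampling for objective dominance. Correlation
scores are checked to 1e-9 against an off-the-shelf Spearman routine. The
evaluation harness is exercised with injected fake clusterers, poisoned
held-out folds (leakage check), and hand-computed confusion matrices. Test
and calibration runs use scaled-down simulations (≤ 1200 cells, ≤ 2000
genes, 10 seeds) — sizes chosen so the full suite runs in well under a
minute of simulation time while keeping Monte-Carlo error far below the
asserted margins.

## Known limitations

- Hyperplanes pass through the origin by construction; there is no offset
  term, and no general sparse-SVM fallback.
- `s` is the user's knob; the package does not choose it automatically and
  computes no p-values.
- The per-cluster marker-count behaviour on spiky score profiles (see above)
  means very easy clusters can still receive long tails of near-zero
  coefficients at large s; users wanting short lists should keep s small or
  truncate by coefficient magnitude.
- The SPA quasi-standardization variant is provided for comparison but has two
  hyperparameters (α, λ) the rank path exists to avoid; no tuning logic ships.
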