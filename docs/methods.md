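# Methods

This note documents the statistical model, the fixed parameters and why they
have the values they do, what the simulator does and does not emulate, the
numerical choices, and the known limitations. It makes no empirical claims
beyond what the test suite and `scripts/acceptance.py` actually compute.

## Model

### Substitution process

Each alignment column evolves down a fixed tree under a reversible
continuous-time Markov chain with generator `Q = S·diag(π)` (S symmetric
exchangeabilities, π stationary frequencies), normalized so that
`-Σ_i π_i Q_ii = 1`, i.e. branch lengths are in expected substitutions per
site. Proteins use the JTT exchangeabilities and frequencies; nucleotides use
Jukes–Cantor (uniform exchangeabilities and frequencies). Transition matrices
`P(t) = exp(Qt)` are computed from the π-symmetrized eigendecomposition,
which is done once per model and cached; `P(t)` rows are clipped at zero and
renormalized to guard against eigen-round-off at extreme `t`.

### Rate variation and empirical Bayes

Site rates are i.i.d. draws from a gamma distribution with shape `α` and
mean 1, discretized into `K` equal-probability categories; category `k`'s
representative rate is the mean of the gamma density over its inter-quantile
bin, computed from the regularized incomplete gamma function:
`r_k = K·(I(α+1, α·q_{k+1}) − I(α+1, α·q_k))` where `q_k` are the quantile
boundaries. The weights `Σ w_k r_k` therefore average to exactly 1.

`α` is fitted by maximizing `Σ_i log Σ_k (1/K) L_i(r_k)` with bounded scalar
minimization on `log α` (see parameters below). The per-site estimate is the
posterior mean over the category grid, and the credible interval is the
central discrete interval: the lower bound is the largest category whose
cumulative posterior stays below `(1−ci)/2` plus one, the upper bound the
smallest category whose cumulative posterior reaches `1−(1−ci)/2`. The
interval is a grid interval — it can only be as fine as the `K` categories.

### Site likelihoods

Felsenstein pruning with per-node rescaling: at every internal node the
partial-likelihood vector is divided by its maximum, and the logs of the
scalers are accumulated, so alignments with hundreds of taxa do not
underflow. Gaps, `X` (protein) and `N` (nucleotide) contribute all-ones
partials (missing data). A site where fewer than 2 sequences are informative
carries no rate signal; it is assigned the prior (posterior = prior weights)
and flagged `prior_only`.

### Trees

If no tree is given, one is built by neighbor joining (Saitou–Nei, with the
standard Q-criterion) on corrected pairwise distances: `−ln(1−p)` (Poisson)
for proteins and `−(3/4)·ln(1−4p/3)` (Jukes–Cantor) for nucleotides, with
pairwise deletion of gapped columns. Negative NJ branch estimates are clamped
to zero. The tree is used as-is: branch lengths are *not* re-optimized under
the likelihood model, which is a deliberate speed/simplicity trade-off.

### Grading

Rates over the query's ungapped positions are standardized to z-scores
(population standard deviation; all-zero if constant). Each sign of the score
vector is scaled by its own extreme — the most conserved site maps to −1 and
the most variable to +1 — and nine equal-width bins are laid over [−1, +1]:
`grade = clamp(9 − floor((s+1)/(2/9)), 1, 9)`. This pins all the anchor
semantics simultaneously: score 0 → grade 5, the minimum-score site → grade
9, the maximum-score site → grade 1, for any non-degenerate score vector,
however skewed. The scheme is invariant to affine rescaling of the rates and
reduces to plain symmetric binning when the score distribution is symmetric.
The credible-interval bounds are pushed through the same standardization and
binning, giving a contiguous grade interval per site.

A grade is *unreliable* when the interval spans more than 3 grades or fewer
than 6 sequences are informative at the site. Unreliable grades are reported
but marked (`*` in the TSV).

### Homolog selection (hit-table mode)

Hits are sorted by ascending E-value (ties by subject id, so selection is
deterministic under input permutation), filtered to identity within
[0.35, 0.95] and query coverage ≥ 0.60 (the query itself is exempt), then
clustered greedily: each hit joins the first existing cluster whose
representative it matches at ≥ 0.95 identity (global alignment matches
divided by the shorter ungapped length), else founds a new cluster. A
character-multiset intersection bound is used to skip alignments that cannot
reach the threshold; this prefilter is exact (it only skips true negatives),
so results are unchanged. Representatives are sampled across the
E-value-ordered cluster list by stride (`i·m//n`), preserving the diversity
spectrum, and the query is always included.

### Structure mapping

Structures are parsed with gemmi (PDB and mmCIF; only the first model).
Polymer residues include HETATM-flagged modified residues via a shipped
three-letter → one-letter table (MSE→M, SEP→S, …); waters and non-polymer
ligands are excluded from chain sequences but retained in the output file.
Alternate locations are collapsed to the highest-occupancy atom. The query is
aligned globally onto the chosen chain (BLOSUM62, gap open −10, extend −0.5);
mapping fails below 60% identity and warns below 95%. Grades are written into
the temperature-factor column of every atom of a mapped residue (0.00 for
unmapped residues, ligands, waters), and are propagated by residue rank to
every chain whose sequence is byte-identical to the mapped chain. PyMOL and
ChimeraX coloring scripts are emitted alongside.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `K` (gamma categories) | 16 | – | grid fine enough for meaningful discrete CIs; likelihood cost is linear in K |
| `α` search bounds | [0.05, 20] | – | covers extreme among-site heterogeneity to near-homogeneity; optimized on log α (xatol 1e−3), fallback α = 1 with a warning if the optimizer fails |
| `ci` level | 0.95 | – | conventional central credible interval |
| distance cap | 5.0 | subst./site | corrected distances diverge as p → saturation; the cap keeps NJ finite (also used when two sequences share no columns) |
| identity window | [0.35, 0.95] | fraction | below 0.35 alignment/homology is unreliable; above 0.95 hits are redundant |
| coverage minimum | 0.60 | fraction of query | fragments shorter than this distort column rates |
| redundancy threshold | 0.95 | identity | greedy clustering threshold for representative selection |
| representatives | 150 | sequences | balance between rate-estimation power and run time |
| hard minimum | 5 | sequences | below this the rate model is meaningless; run refuses |
| warning thresholds | <50, >300 | sequences | advisory only: low power below 50, heavy computation above 300 |
| reliability rule | span ≤ 3 grades AND ≥ 6 informative | – | grade-level precision statement; both thresholds configurable in code |
| mapping identity | fail <0.60, warn <0.95 | fraction | a chain under 60% identity is likely the wrong molecule |

## What the simulator emulates — and what it does not

`evorate.simulate` generates Yule trees (uniform random leaf splitting) with
i.i.d. exponential branch lengths, draws per-site rates from gamma(α, 1/α),
and evolves characters down the tree from stationary root states using the
exact model transition probabilities. This matches the inference model by
construction, which is the point: it enables parameter-recovery tests with a
known truth. It does **not** emulate alignment error, indels (simulated
alignments are gapless), composition drift across the tree, site-specific
amino-acid profiles, or correlation between sites. `simulate_hit_set`
generates synthetic homolog-search tables (redundancy families of
byte-identical sequences at controlled divergences with E-values tied to
identity) for exercising the selection machinery; it is not a model of any
real search tool's statistics.

## Numerical choices

- Eigendecomposition of the π-symmetrized generator, cached per model;
  `P(t)` clipped at 0 and row-renormalized.
- Per-node max-rescaling in pruning with log-scale accumulation.
- Bin-edge snap in grading: values within 1e−9 of a bin boundary are snapped
  to it before `floor`, so float round-off cannot flip the grade of a score
  that is mathematically on an edge.
- NJ tie-break: the pair with smallest (i, j) indices wins among equal
  Q-criteria (strict improvement threshold 1e−12), making tree construction
  deterministic.
- Derived seeds everywhere: simulation and the acceptance script derive all
  RNG seeds from a single integer, kept below 2³¹.

## Open design decisions

- NJ branch lengths feed the likelihood directly; a likelihood-based branch
  re-optimization stage could be added in front of the rate estimation.
- The gamma discretization uses bin means (mean-preserving); bin medians are
  a common alternative with slightly different tail behavior.
- The grades TSV column layout is this package's own; downstream parsers
  should treat it as such.
- The greedy clustering is order-dependent by design (E-value order), which
  makes it deterministic but not identical to a globally optimal clustering.

## Limitations

- Rates are relative (alignment mean ≈ 1); they are not calibrated to
  absolute time.
- A single fixed topology is assumed; tree uncertainty is not propagated
  into the credible intervals, which are conditional on the tree.
- Protein models are limited to JTT and nucleotide models to Jukes–Cantor;
  no among-site model mixtures or codon models.
- Homology search itself is out of scope: the pipeline only ingests search
  result files (plus the corresponding sequences) produced elsewhere.
- Credible intervals live on the discrete category grid, so they widen in
  jumps; with very few informative sequences they span the whole grid and
  the site is flagged accordingly.
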