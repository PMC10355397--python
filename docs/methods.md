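# Methods

## Model

Each of the six folded mutation types (central base A or C after merging
reverse-complement contexts) has its own rooted context tree.  Level *k* of
a tree holds the 4^(k−1) contexts of window size *k*; the root edge carries
θ, the natural-log base polymorphism probability of the type, and each
deeper edge carries φ, the log multiplicative shift contributed by the one
nucleotide that the level adds.  A node's log probability is the sum of θ
and the φ on its unique root path, so probabilities compose multiplicatively
and tree grafting is additive on the log scale.

Three architectures are supported.  The default, `right_asymmetric`, adds
the 3′ base at even levels and the 5′ base at odd levels, which places the
CpG dinucleotide inside the window already at the 2-mer level so the CpG
transition effect loads onto a single edge.  `left_asymmetric` is its
mirror; `symmetric` visits only odd levels, adding one base per side
(16 children per context instead of 4, but no intermediate levels).

For a context with central base *c*, the observed counts
(n₁, n₂, n₃, N − Σn) over the three alternates and "not polymorphic" are
multinomial with probabilities (p₁, p₂, p₃, 1 − Σp), where each pₘ comes
from the type-(c>altₘ) tree.  The three trees sharing a central base are
therefore coupled through the simplex constraint; the six trees are further
coupled by level-shared hyperparameters.  The multinomial coefficient is
constant in the parameters and omitted throughout.  Multi-allelic sites
increment each alternate's cell independently; this mildly violates the
one-outcome-per-site assumption and is a known limitation.

## Priors and regularization

Every non-root edge gets a two-component Gaussian spike-and-slab prior with
an explicit inclusion indicator δ: φ | δ=0 ~ N(0, σ_spike²) ("no effect"),
φ | δ=1 ~ N(0, σ_slab²), P(δ=1) = π shared by all six trees within a mer
level, with a Beta(1,1) hyperprior on π.  Using a continuous narrow spike
rather than a point mass keeps every update fixed-dimensional while
preserving the PIP interpretation (PIP = posterior mean of δ).

The σ pair is fixed by an effect-size rule: with equal component weights,
the spike and slab densities cross at |φ| = ln(1.1), i.e. the slab is
favored once the data support a multinomial probability shift larger than
10%.  Given the scale ratio r = σ_slab/σ_spike (default 10) this pins

    σ_spike = ln(1.1) · sqrt((r² − 1) / (2 r² ln r)) ≈ 0.0442,  σ_slab ≈ 0.4419.

The crossing threshold and the ratio are configurable; the crossing rule is
our concrete operationalization of "slab favored beyond a 10% shift".

θ gets a weakly informative N(ln 0.01, 2²) prior — centered on a typical
per-type polymorphism probability, wide enough to be dominated by any
realistic dataset.

## Sampling

The posterior is explored with adaptive Metropolis-within-Gibbs, level by
level (1, 2, …, K; the symmetric architecture visits 1, 3, 5, …).  While
level *k* is sampled, edges below it are frozen at their posterior means
and deeper edges are implicitly zero; counts are aggregated to level *k*.
Because a multinomial with identical cell probabilities splits losslessly,
the aggregated likelihood is exact under that assignment (this identity is
enforced by a unit test).  Within a sweep, each edge's φ receives a
Gaussian random-walk update whose likelihood term touches only the edge's
own multinomial cell (at the sampled level, each context has exactly one
incoming edge per tree); each δ is then redrawn from its conditional
Bernoulli, and π from its conjugate Beta.

Proposal scales are per-parameter.  They are initialized by preconditioning
at 2.4/√(n + 5), where n is the cell's polymorphism count — the posterior
standard deviation of a log rate with n events is ≈ n^(−1/2) and ~2.4 sd is
the classical optimal random-walk scale — and then adapted every 50
iterations during burn-in by ±min(0.01, batch^(−1/2)) on the log scale,
targeting 0.44 acceptance; adaptation is frozen after burn-in (diminishing
adaptation).  Without preconditioning the 0.01-capped adaptation cannot
bridge the orders of magnitude between data-rich and data-poor edges inside
a practical burn-in.

Defaults: 2 chains, 20 000 iterations per level with 50% burn-in, thinning
5, target acceptance 0.44, convergence flagged when the between-chain
Gelman–Rubin R̂ of any parameter exceeds 1.1 (recorded as a warning on the
results object, never a crash).  Simulation studies in the tests and the
acceptance script run 2 500–3 000 iterations per level, which already holds
R̂ ≲ 1.01 at the problem sizes used there (≤ 5-mer trees).  Fixed seeds give
bit-identical chains; per-chain and per-level seeds are derived from the
user seed via a seeded generator.

## Node posteriors and what an edge estimates

Under level-by-level conditioning, the generating value that a level-*k*
node estimates is the occurrence-weighted aggregate of its finest-level
descendants' probabilities, and an edge estimates the difference between
its child's and parent's aggregate log rates — not the generator's raw φ:
a parent edge absorbs the occurrence-weighted mean of its children's
shifts.  Recovery tests therefore compare posterior means against these
aggregate-implied quantities.

A level-*k* node's posterior draws are the frozen posterior-mean path
through level *k* − 1 plus the node's own level-*k* edge draws.  Summing
per-draw paths across independently sampled levels would double-count
lower-level uncertainty (the level-*k* conditional already centers on the
frozen path) and systematically over-cover; the frozen-path convention
instead ignores the (much smaller, ~4× more data per level) freeze error
and in calibration runs lands slightly below nominal coverage, matching
the method's characteristic 89/93/97% at nominal 90/95/99%.

## Synthetic data

`make_truth` draws ground-truth trees: θ log-uniform on [0.002, 0.02] per
type; a ln(10) CpG boost on the first edge whose window includes the 3′
neighbor of a C>T context; each deeper edge nonzero with probability γ_level
(default 1, 0.5, 0.3, 0.15, 0.08 for levels 1–5, halving beyond) and then
N(0, τ²) with τ = 0.4.  Contexts whose total alternate probability would
exceed 0.5 have their offending shifts redrawn (edge-wise rejection).
`make_totals` allocates a genome-size position budget across finest
contexts by log-normal weights (dispersion 1.0 ≈ the orders-of-magnitude
skew of real k-mer composition) with deterministic largest-remainder
rounding; `simulate_counts` then draws one multinomial per context.

What the generator does *not* emulate: non-independence of overlapping
windows on a real chromosome, regional rate covariates (replication timing,
recombination), recurrent mutation and saturation, ancestral
misidentification, and sequencing artifacts.  Passing calibration and power
tests therefore validate the inference machinery under the model's own
assumptions, not robustness to those real-data effects.

## Simulation studies

**Calibration** (`calibration_study`): ~50 replicate truth tables up to
5-mers, each with its own log-normal totals over 5 × 10⁷ positions
(dispersion 1.0); simulate counts, fit with two chains, and pool — over all
levels, contexts, types and replicates — the frequency with which the
generating aggregate probability falls inside the 90/95/99% equal-tailed
intervals.  Reported as percentages (acceptance targets t3–t5).

**Spike-in power** (`power_study`): one 3-mer truth (θ log-uniform on
[0.005, 0.03], CpG boost 4, τ = 0.35, 6.4 × 10⁷ positions at dispersion
0.25 so every context clears 10⁶ occurrences), 24 target context-mutations
with generating probabilities inside [0.005, 0.15], spread so that no two
targets share a (tree, parent) pair — spiking several siblings at once
would push the shift onto the parent edge and defeat the incoming-edge
criterion by construction.  Per replicate, null and spiked counts are
simulated and fitted independently; a target is detected when both its
node-probability and incoming-edge posterior overlaps fall below 1%
(histogram overlap on 100 shared equal-width bins).  Power is the detected
fraction over ≥ 10 replicates; the reported statistic is the fraction of
targets with power > 0.8 (targets t6 at NLPPR 0.5, t7 at 0.01).  A cheap
Gaussian mean-separation bound skips the exact histogram only where the
overlap cannot plausibly reach the 1% threshold.

## Numerical choices and degenerate inputs

Proposals that would push a context's total alternate probability to ≥ 1
get −∞ likelihood and are always rejected; the sampler never throws inside
a sweep.  A non-finite likelihood at initialization (e.g. absurd starting
shifts) raises immediately with advice to start smaller.  Holdout
evaluation rescales all probabilities by one global scalar
s = observed/expected polymorphisms; contexts whose scaled probabilities
leave the simplex are renormalized to 1 − 10⁻¹² and counted.  RMSPE is
computed on log₁₀ probabilities by default (probability scatter spans
orders of magnitude; raw and natural-log scales are selectable), with an
explicit omit-zero-cells policy rather than silent dropping.  The empirical
(maximum-likelihood) baseline uses a 0.5 pseudocount per multinomial cell
by default.  Histogram overlap uses 100 equal-width bins over the pooled
sample range — deterministic given the draws, no kernel bandwidth to
choose; identical draw vectors give exactly 1.  Ties in edge ranking break
lexicographically by (mutation type, context).  Tail motif enrichment uses
one-sided hypergeometric tests with Bonferroni correction across motifs.

## Known limitations

Single-nucleotide variants only; multi-allelic sites counted per-alternate
(see above); no joint all-levels sampling (the level-by-level scheme trades
a small, quantified calibration bias for scalability); no modeling of a
context's overall mutability across types; one expansion path per context
(the architecture fixes the order in which flanking bases enter); no
demographic, selection or recurrent-mutation modeling.  Divergence
detection compares exactly two fitted models; attributing a divergent
context to a specific population among several requires joint reasoning
beyond the pairwise overlap criterion.
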