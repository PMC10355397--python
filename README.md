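# mertree

Bayesian hierarchical sequence-context ("mer") tree models of polymorphism
probability.

The probability that a genomic site is polymorphic depends strongly on its
local sequence context — most famously the ~10-fold elevated C>T rate at CpG
dinucleotides — and expanding the context window (3-mers, 5-mers, … 9-mers)
keeps adding signal long after naive per-context counting has overfit.
`mertree` models this with one rooted tree per folded mutation type (A>C,
A>G, A>T, C>A, C>G, C>T).  The root edge carries the log base polymorphism
probability θ of the type; every deeper edge carries φ, the natural-log
multiplicative shift in probability gained by adding one flanking
nucleotide.  A context's polymorphism probability is the product of the
edges on its root path:

    log p(context, type) = θ_type + Σ φ_edge  (over the root path)

Observed per-context counts are modelled as independent multinomials over
the three alternate alleles plus "not polymorphic".  Edges are regularized
with a spike-and-slab prior — a narrow "no effect" spike and a wide slab,
tuned so the slab is favored once the evidence supports a multinomial
probability shift larger than 10% — and the posterior slab-membership
frequency of an edge is its posterior inclusion probability (PIP).  The
posterior is sampled with an adaptive Metropolis-within-Gibbs scheme, level
by level: while level *k* is sampled, shallower edges are frozen at their
posterior means and deeper edges are implicitly zero, so counts aggregated
to level *k* give an exact likelihood.

Beyond fitting, the package provides the surrounding workflow: context
counting from FASTA + BED + VCF with reverse-complement folding and
even/odd coordinate-parity genome splits; holdout evaluation (scaled
multinomial likelihood, Spearman ρ, perpendicular RMSPE); credible-interval
calibration; cross-population divergence detection via posterior-overlap
(dual node + incoming-edge criterion, effect sizes as NLPPR — the natural
log of the polymorphism probability ratio); tree grafting (shallow levels
from one model, deep levels from another); and a synthetic-data module with
spike-in power experiments.

## Worked example

```python
import numpy as np
from mertree import (SamplerConfig, ContextTreeModel,
                     make_totals, make_truth)

# a synthetic 3-mer genome: ~32M sites, known sparse context effects
totals = make_totals(seed=2, K=3, total_positions=32_000_000, dispersion=0.3)
truth = make_truth(seed=1, K=3, totals=totals,
                   base_range=(0.005, 0.05), cpg_boost=1.0)
counts = truth.simulate_counts(seed=3)

cfg = SamplerConfig(iterations=3000, thin=5)
result = ContextTreeModel(counts, config=cfg).fit(seed=42)
print(result.summary())
```

prints

```
Sequence-context tree model (adaptive Metropolis-within-Gibbs)
architecture: right_asymmetric   K: 3   chains: 2
iterations/level: 3000 (burn-in 1500, thin 5)
seed: 42   converged: True

level   edges  PIP>0.95  mean pi  accept  max Rhat
    1       6       nan      nan   0.441     1.009
    2      24     0.583    0.716   0.438     1.005
    3      96     0.406    0.636   0.439     1.008

base polymorphism probabilities exp(theta):
  A>C: 0.0187
  A>G: 0.0445
  A>T: 0.0082
  C>A: 0.0456
  C>G: 0.0102
  C>T: 0.0126
```

Reading the table: each level's sweep hit its 0.44 target acceptance rate
and converged (R̂ ≤ 1.01 across two chains); 58% of 2-mer edges and 41% of
3-mer edges are included with high confidence (PIP > 0.95); `mean pi` is
the posterior slab probability shared by all six trees at that level.  The
recovered base probabilities match the simulated θ values, and per-context
posteriors are available as

```python
result.credible_interval("ACG", "C>T", 0.95)   # (0.016048, 0.016496)
result.node_probabilities(3)                   # posterior-mean table
result.edge_summary()                          # per-edge mean/quantiles/PIP
```

The same workflow is scriptable from the shell: `mertree count | fit |
evaluate | compare | graft | simulate | power` (see `mertree --help`).

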