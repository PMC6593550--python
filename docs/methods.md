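# Methods

## The model and the EP statistic

All likelihoods use the Poisson amino-acid model: equal exchange rates
between every residue pair and uniform stationary frequencies (1/20).
Its transition matrix has the closed form
`P(same|d) = 1/20 + (19/20) exp(-(20/19) d)`, so every message in the
pruning algorithm is an axpy rather than a matrix product; the engine is
vectorised across alignment columns and scales per node and site to
avoid underflow.  Rate heterogeneity is the usual G + I mixture: K = 5
equal-probability discrete-Gamma categories (mean-of-slice rates,
averaging exactly 1) plus a zero-rate invariant class of weight
`p_inv`.  Branch lengths are expected substitutions per site averaged
over the full mixture, so the Gamma multipliers are rescaled by
`1/(1 - p_inv)`; the invariant class only admits columns whose
unambiguous residues agree, and contributes a branch-length-independent
term.  Gap (`-`), missing (`?`), `X` and the rarer ambiguity codes are
treated as fully ambiguous in likelihoods and as invalid for time-span
bookkeeping.

The EP of an allele at a site is the normalised-time weighted mean of
tip posteriors over the pruning series.  The tip posterior treats the
focal species' residue as unknown: `PP(a)` is proportional to the
column likelihood with the focal tip clamped to `a`, which the engine
obtains in one outward pass as the message arriving at the focal tip.
The pruning series is defined on the (binary-resolved) tree by removing,
at each step, the clade sister to the focal lineage at the next
ancestral node, until only the focal species and one outgroup lineage
remain; polytomies are resolved deterministically in sorted leaf-label
order before the series is built.

Because a timetree in million years carries no substitution scale,
branch lengths for the posterior are re-fitted to the alignment by
maximum likelihood on every stage topology (warm-started from the
full-tree fit restricted to the stage's taxa); timetree durations enter
only through the weights.  Gamma shape and invariant fraction are
estimated once on the full alignment (bounded quasi-Newton on
(log alpha, logit p_inv), start (1.0, 0.1), tolerance 1e-6) and reused
at every stage for stability on small stage trees.  Branch-length
optimisation itself is per-edge Brent on the edge's closed-form profile
likelihood (the outer/inner messages reduce each edge to three
per-category, per-site scalars), swept until the total log-likelihood
moves by less than 1e-6, with a halving backtrack if a sweep ever
overshoots.  Sites where fewer than two non-focal taxa carry a valid
residue at stage 0 have no evolutionary information and are reported as
EP = NaN with a flag; sites where the focal species has a gap still get
EP, since the posterior ignores the focal state by construction.

## The alignment-only (modified) pipeline

When no tree is supplied, pairwise gamma-corrected Poisson distances
(`d = (19/20)·alpha·((1 - (20/19)p)^(-1/alpha) - 1)`, capped at 10
substitutions/site for saturated pairs) seed a neighbour-joining tree;
NNI hill climbing then accepts any rearrangement that improves the
alignment log-likelihood (each candidate re-fitted with a loose 1e-3
tolerance, the winner re-fitted fully) until no move improves it.  The
ML tree is transformed to a relative timetree by a relative-rate
recursion: each node's mean descendant depth is the equal-weight average
over its child lineages of (depth + branch length), and ages follow from
`t(child) = t(parent) · D(child)/(D(child) + b(child))`, giving an
ultrametric tree with root age 1.  This is a deliberately reduced form
of relative-time dating — no rate-merging tests — chosen because the EP
weights consume only normalised times, and the two properties that
matter are guaranteed: exact recovery of node-depth proportions on
clock-like trees, and invariance to rescaling all input lengths.

Two conventions are worth stating.  First, the split of the outgroup
branch around the root is not identifiable from sequence data, so the
transformation always re-roots canonically at the point on the outgroup
edge where the two sides' mean tip depths balance; on a clock-like tree
this recovers the true root exactly.  Second, when the user supplies a
topology but not times, only the dating step is inferred and the result
is tagged `reltime-only`.

Stage weights in this pipeline are the protein's evolutionary time span
(ETS) on each stage tree — the mean over alignment sites of the span of
the stage tree restricted to taxa with a valid residue at that site —
so weights strictly decrease along the series: an allele seen only in
distant taxa gets less support than one seen nearby.  Site-level PTS and
residue-level RTS use the same masked-span machinery (an edge
contributes its duration iff valid carriers lie on both sides).

## Synthetic data and the vertebrate fixture

The simulator draws a root state uniformly, assigns each site a rate
(0 with probability `p_inv`, otherwise a Gamma-category multiplier under
the same scaling convention as the estimator) and evolves states
branch-wise under the Poisson model.  Gaps, when requested, are injected
afterwards as contiguous per-taxon blocks (mean block 15 sites) to mimic
the clustering of real alignment gaps; there is no indel-evolution
model, so gap *placement* carries no phylogenetic signal — conclusions
about gap handling transfer to real data only insofar as gaps reduce
usable evolutionary time, which is exactly what the ETS/PTS/RTS metrics
measure.  Simulated columns are exchangeable across sites and contain no
selection, domain structure or alignment error; passing tests therefore
validate the estimators and their contracts, not the biological realism
of any particular dataset.

The bundled 46-taxon vertebrate tree reproduces the topology used for
human EP analyses, with seven density-sampling clades (A–G) plus the
lamprey outgroup, and the human focal lineage passing through exactly 16
ancestral nodes (15 pruning steps; the tree-shrew is joined with Glires
so the count matches).  Node ages are synthetic plausible values on the
published vertebrate timescale (total span 5,713 My); every
age-dependent check in the tests is scale-invariant or tolerance-based,
and `vertebrate_fixture(ages=...)` accepts overrides, rejecting tables
where a parent is not strictly older than its children.

Default simulation conditions were fixed once: substitution rate
5×10⁻⁴ substitutions/site/My (a mid-range vertebrate protein rate),
alpha = 1, `p_inv` = 0.05, uniform root frequencies.

## The neutral calibration and its honest outcome

`neutral_ep_calibration` simulates neutral evolution on the deep
46-taxon tree and reports the fraction of sites whose focal-tip residue
receives EP < 0.05 — the false-eForb rate that motivates the 0.05
threshold.  Under the default conditions the measured fraction is
~3%, not below 1%.  The arithmetic is transparent: with
divergence-time weights on this tree, the cumulative weight of stages
younger than roughly 50–70 My is below 0.05, so any allele that arose on
the focal lineage within that window is called forbidden; for neutral
evolution that happens at ≈ `rate × 50 My` of sites, which drops below
1% only for rates ≲ 2×10⁻⁴ substitutions/site/My (conserved-protein
territory).  The calibration is kept at the package's stated default
conditions rather than tuned, and the measured fraction is reported by
the acceptance script; the guard flag (`deep_enough`) marks trees
spanning under ~5,000 My, where the fraction is not meaningful at all.

## Evaluation choices and scaled-down problem sizes

Percent agreement is intersection-over-union of the two methods' eForb
sets (symmetric; vacuously 100% with a warning when both are empty).
The classification-error fraction is directional: among alleles at
variant sites called eForb by the known-tree method, the share the
inferred-tree method fails to call eForb.  ROC curves sweep 10 evenly
spaced thresholds in [0.01, 0.1]; AUROC is the trapezoid over the swept
points augmented with the (0,0) and (1,1) endpoints.  The branch-score
tree distance uses squared branch-length differences over unrooted
bipartitions (a bipartition present in one tree only contributes its
full length), optionally after scaling the second tree's total length to
the first's.

Experiments are sized for a single CPU: topology-recovery uses 10
replicates of 500 sites on an 8-taxon clock tree (≥90% recovery
asserted); the known-vs-inferred concordance experiment pools four
replicates of 150-site alignments with 25% gaps on a 13-taxon
deep-vertebrate subtree, where inference is genuinely hard.  At this
problem size the ranking "true topology + inferred times tracks the
known-tree method more tightly than full inference" is visible in the
pooled EP r² but is weak — single replicates can invert it — so the test
asserts the pooled rank only, and the acceptance script reports the
underlying quantities.  The neutral calibration runs at 2,000 sites.

## Known limitations

Only the Poisson model is implemented (no empirical exchangeability
matrices); EP is amino-acid-level only; there is no bootstrap support,
no Bayesian dating, and no ancestral-state output.  NNI from an NJ start
can miss the ML topology in principle; the per-edge sweep optimiser is a
coordinate method and, like all such, is guaranteed only a local
optimum.  The CAP caller takes allele frequencies at face value — it
performs no population-genetic modelling.
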