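# Methods

## Model and assumptions

The package operates on an undirected simple graph of gene/protein
identifiers (the interactome). Distances are unweighted hop counts: the
method's claims are topological, and interaction confidence weights are
deliberately out of scope. A drug is represented by its target module *T*,
a disease by its gene module *S*; both are plain node sets after mapping
input identifiers onto the graph (unmapped identifiers are dropped with a
warning and recorded per module; a module that maps to nothing is excluded).
By default the interactome is restricted to its largest connected component,
since closest-distance proximity over a disconnected graph produces
infinities; both this restriction and the handling of residual unreachable
pairs (targets with no path to the disease module are excluded from the
average, with the count kept in `t_used`) are configurable and recorded.

The statistic is the closest-distance proximity
`p(T,S) = mean_t min_s d(t,s)`. Its null model must control for degree:
high-degree nodes are close to everything, so raw proximity rewards drugs
that target hubs. The null resamples, per repeat, a random counterpart of
*T* and a disjoint random counterpart of *S* with the same sizes and the
same degree profile, where "same degree" means "same degree bin": nodes are
partitioned into ascending-degree bins greedily merged until each holds at
least `min_bin_size` nodes (default 100; a trailing undersized bin merges
backward). Small bins would make sampling degenerate — with a singleton bin
the "random" counterpart of a hub is always the hub itself — which is why
the bin size floor, not exact-degree matching, is the default. The two
random groups of one repeat are drawn disjointly; on realistically sized
graphs overlap would be rare anyway, and disjoint draws keep the null
distribution exactly degenerate in limiting cases (e.g. on a complete graph
all null proximities equal 1), which makes degeneracy detectable rather
than noise-masked.

The observed proximity is standardized by the null sample mean and standard
deviation (ddof = 1) over `n_random` repeats (default 1,000), and the
p-value is the one-sided lower-tail normal probability Φ(z): only "closer
than chance" counts as signal, matching the z ≤ −1.65 ↔ p ≤ 0.05
correspondence. An empirical p-value (add-one-corrected rank of the observed
value among the null samples) is available as `p_method="empirical"` for
sensitivity analysis. A null with zero standard deviation is flagged
`degenerate` and the p-value collapses to 0 (observed beats the constant
null) or 1 (it does not); such pairs are reported, never silently dropped.
No multiple-testing correction is applied: the method's operating point is
the raw per-pair α (default 0.05), and the filter is inclusive (p ≤ α).

## From proximities to the output network

Significant pairs are mapped to similarities `(max(p) − p)/max(p)`. The
scope of `max(p)` is the significant set by default (the network that is
actually output), with an `all_pairs` option that freezes the normalizer
across filtering choices; scores are therefore run-relative and not
comparable across runs by construction. Communities are detected on the
similarity-weighted bipartite graph by greedy (CNM) modularity maximization
with resolution 1, drugs and diseases as ordinary nodes; nodes are
namespaced internally as (type, name) so a drug and a disease sharing an
identifier cannot collide. The networkx implementation is deterministic
under its fixed internal ordering, and cluster labels are reassigned in
lexicographic order of each cluster's smallest member, so partitions are
reproducible without a random stream. Each community is scored
`QC = W_in/(W_in + W_out + P)` with P the community's fraction of network
nodes. P makes QC scale-sensitive: multiplying all weights by λ changes QC
(the W terms scale, P does not). This is a documented property of the
score, not a defect; QC is always in [0, 1) and is 0 for a community with
no internal weight. Same-community edges are rewarded by (1 + QC) — the
adjusted weights live in [0, 2) — and cross-community edges pass through
unchanged, with the adjustment applied literally (no rescaling of QC).

The final normalization is the logistic sigmoid with steepness `c` and
midpoint `d`. Neither constant has a canonical value, so both are mandatory
entries of the resolved run config: the defaults are `c = 25`, which spreads
the typical [0, 1.5] adjusted-similarity range across (0, 1) without
saturating it, and `d = None`, which resolves at run time to the median
adjusted similarity (centring the sigmoid on the score distribution) and is
written back into the serialized config so every run is self-documenting.
Outputs saturate to the nearest representable values inside the open
interval (0, 1).

## Evaluation protocol

Predictions are ranked by ascending p-value; ties — common when normal
p-values underflow or coincide — are broken by descending normalized
similarity, then lexicographically, so rankings are total and reproducible.
Labels come from a gold standard of known (drug, disease) pairs; gold pairs
matching no prediction are counted and logged. The ROC curve is swept down
the ranking with equal-key groups admitted together, which makes the
trapezoidal AUC equal the Mann–Whitney U concordance probability (verified
against scikit-learn and a brute-force pairwise oracle in the tests).
Evaluation pools all pairs globally rather than per disease. The pipeline
ranks all scored pairs by default (`roc_scope="all_scored"`): ranking only
the significant subset is available (`"significant"`) but typically leaves
almost no negative class, making the AUC uninformative.

## Synthetic benchmark generator

`drugprox.fixtures` generates complete, self-consistent inputs: a
Barabási–Albert interactome (n = 2,000, attachment 3 by default) whose
heavy-tailed degrees exercise the degree-binned null non-trivially; disease
modules grown as connected random-expansion neighborhoods of 15–30 nodes
(the disease-module hypothesis made literal); and drugs of 3–8 targets, of
which a `planted_fraction` (default 0.3) are true candidates drawing ≥ 80%
of their targets from within `planting_radius` hops (default 1) of their
round-robin-assigned disease module, the rest sampling targets uniformly.
The gold standard is exactly the planted pairs, and a JSON manifest records
every parameter and planted pair for assertions. What the generator does
*not* emulate: correlated drug polypharmacology, overlapping or polygenic
disease etiologies, interactome noise/ascertainment bias, and literature-
biased gold standards. Passing recovery tests therefore demonstrates that
the statistical machinery recovers geometric planted signal on a
heavy-tailed graph — not that real repurposing screens will reach the same
AUC.

## Numerical and design choices

- Hot-path distances run through `scipy.sparse.csgraph.dijkstra`
  (`unweighted=True, min_only=True`) on a cached CSR adjacency; tests check
  them against per-source BFS and textbook Floyd–Warshall oracles.
- Per-pair null seeds derive from the master seed plus a stable hash of the
  (drug, disease) names, so adding pairs to a run never reshuffles the
  draws of existing pairs, and every output is byte-reproducible from
  (inputs, resolved config).
- Ties on component size at load are broken by the lexicographically
  smallest node set; degree-bin contents and sampling pools are sorted
  before drawing, removing any dependence on set iteration order.
- Test and validation problem sizes are scaled to desk hardware as the
  package's own benchmark design: null-model calibration uses a 2,000-node
  generated interactome with 300 random module pairs at 200 randomizations
  each; end-to-end recovery uses twenty 800-node fixtures at 100
  randomizations. The defaults shipped in `RunConfig` (`n_random=1000`,
  `min_bin_size=100`, `alpha=0.05`) are the method's stated operating
  point.

## Known limitations

- The normal approximation for p-values is only as good as the null's
  near-normality; on very small or lattice-like graphs the null proximity
  distribution is lumpy and the empirical p option is more defensible.
- Degree-binned sampling matches bin profiles, not exact degrees; extreme
  hubs are replaced by typical members of the top bin, so null modules are
  slightly less extreme than templates containing such hubs.
- QC's scale sensitivity means the adjustment's strength depends on the
  similarity scale entering clustering; clustering is run on the
  similarity-stage weights (before adjustment) for exactly that reason.
- Scores are not calibrated probabilities; the bipartite output network is
  a prioritization device, and AUC against incomplete gold standards
  underestimates true performance when unknown-but-real associations are
  counted as negatives.
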