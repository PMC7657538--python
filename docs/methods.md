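# Methods

## Model and assumptions

`phylomint` treats a genome-scale metabolic reconstruction purely as a
directed reachability structure over metabolites. No stoichiometry, flux
bounds or media are used: a reaction with substrates S and products P
contributes every edge s → p (s ∈ S, p ∈ P), plus the reverse edges if the
reaction is reversible. This full bipartite expansion is the standard
reverse-ecology construction; reversibility must produce both directions
so that interconvertible metabolite pools collapse into one strongly
connected component (SCC).

The **seed set** operationalizes "compounds the organism must acquire
exogenously" as the members of source SCCs — SCCs with no incoming edge in
the condensation DAG. Every node of the graph is reachable from the seed
union (a property the test suite asserts), but seeds are *not* a growth
requirement: they bound what the network could produce, not what the cell
needs. Confidence C = 1/|SCC| expresses that within a source SCC any one
member renders the rest producible; thresholding at C ≥ 0.2 (i.e. source
SCCs of at most 5 metabolites) discards large, weakly resolved source
components whole — C is constant within an SCC, so retention is
all-or-none.

The **competition index** is confidence-weighted (a shared seed in a large
SCC counts for less); the **complementarity index** is an unweighted
ratio of cardinalities. That asymmetry is deliberate and follows the
definitions of the two indices; both are computed with
`fractions.Fraction` so toy-scale results are exact rationals and no
equality test depends on float rounding. When none of A's seeds occur in
B's network the complementarity denominator is zero; we return 0 and set a
`shared_namespace` flag on the record, keeping the [0, 1] contract while
marking the pair as "not measurably interacting" rather than erroring or
dropping it.

Metabolite identity across models is string equality after normalization
(optional stripping of the SBML `M_` prefix and trailing compartment tags
such as `_c`, `_e`, `_p`). There is no ontology mapping; models built with
different namespaces will silently share nothing, which is why the
per-pair namespace flag exists. No currency-metabolite blacklist is
applied by default, but `GraphOptions.exclude_metabolites` accepts one.

## Phylogenetic normalization

Raw indices correlate strongly with relatedness, so outliers are detected
*locally* in phylogenetic distance. Distances are patristic (sum of branch
lengths on the leaf-to-leaf path, computed via dendropy and checked
against a shortest-path oracle). Ordered pairs land in half-open bins
[k·w, (k+1)·w) of width w = 0.01 branch-length units; a distance exactly
on a boundary goes up. The half-open convention is our choice — either
convention moves only measure-zero boundary cases.

Bin merging uses the first (lowest-distance) bin's pre-merge size as the
minimum: scanning in increasing distance, an undersized bin merges into
the closest preceding bin currently at or above the minimum. Because the
reference bin trivially meets its own minimum, a qualifying predecessor
always exists under the default; the forward-merge fallback (merge a
leading undersized run into the first qualifying later bin) only
activates when a caller passes an explicit larger minimum.

Z-scores use the sample standard deviation (n−1); `ddof=0` is available
as a switch. Singleton and constant bins yield z = 0 for all members — no
outlier is detectable there, which is conservative. Both metrics are
binned on the same assignment and Z-scored independently. Outlier fences
are strict inequalities at ±2.698, the normal-theory equivalent of
Tukey's 1.5×IQR rule; the calibration test draws 10⁵ standard normals and
checks the flagged fraction against 2(1 − Φ(2.698)) ≈ 0.697% within 3
Monte-Carlo standard errors.

The cooperation-network edge rule intentionally uses an asymmetric pair of
fences: complementarity must clear +2.698 while competition only needs to
fall below −1.000, focusing the network on strongly complementary pairs
under merely low (not extreme) competition. Both thresholds are
parameters.

## Robustness simulator

The block subsampler models incomplete MAGs: genes vanish in runs, not
independently. Block start positions are drawn uniformly with replacement
over all full in-bounds windows (no wraparound — contigs are linear), each
draw deletes the not-yet-deleted positions in its window, and sampling
stops at the first draw where the retained fraction is ≤ the target. The
retained count therefore always lies in (target − block/n, target] of the
catalog, e.g. {83, 84, 85} of 100 at target 0.85 with block 3. The model
builder is an injectable callable: production users wrap a reconstruction
tool (a subprocess hook is provided); the test suite uses synthetic
builders with closed-form expected Jaccard values. The comparison baseline
is the identity line (retain fraction f of genes → expect fraction f of
the network).

## Synthetic data

`fixtures` generates three kinds of input. The toy network pair is the
canonical worked example: its exact edge topology is underdetermined by
the constraints that define it (seed memberships, SCC memberships, which
seeds of A occur in B and as what), so we instantiate the minimal graph
satisfying all of them and additionally test a second, rewired
instantiation to confirm the indices depend only on the constraints.
Random models plant source SCCs as directed cycles that nothing else feeds
into, so ground-truth seeds and confidences are emitted alongside; random
remaining reactions involve only non-planted metabolites. Random trees are
built by iteratively joining subtrees with uniform(0.01, 1) branch
lengths. Synthetic models have no realistic stoichiometry, namespace
collisions, or reaction reversibility structure: passing tests demonstrate
algorithmic correctness on the defined graph semantics, not reconstruction
quality on real genomes.

Default scales (10–40 node digraphs, 10–20 models per collection, 100–300
CDS catalogs, 50 degradation replicates) keep the full suite under a few
seconds while exercising every code path; the statistics being checked
(oracle equality, exact rationals, stop-window arithmetic) do not sharpen
with larger inputs.

## Numerical and I/O choices

- TSVs have fixed column order, a header line, and floats at 6 significant
  digits; combined with deterministic (sorted) iteration everywhere,
  pipeline reruns are byte-identical, which the tests assert.
- SCC indices are assigned by sorted smallest member, so seed detection is
  independent of node iteration order.
- The pipeline validates model/tree label agreement before writing
  anything: configuration errors never leave partial outputs.
- Infomap is external and stochastic; the package guarantees only correct
  link-list/id-map generation and `.tree` parsing, with an optional
  subprocess wrapper using `--directed --zero-based-numbering
  --num-trials 10`.

## Known limitations

- Indices are only as good as the reconstructions; model incompleteness
  propagates directly into seed sets (hence the robustness module).
- String-equality metabolite matching requires a shared namespace across
  models (automated reconstruction pipelines with one database satisfy
  this).
- Seed sets ignore reaction directionality subtleties encoded in flux
  bounds rather than the reversibility flag.
- The degradation simulator treats the genome as a single linear contig;
  real MAGs fragment into many contigs, which would slightly change block
  boundary effects.
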