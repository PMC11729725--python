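# Methods

## Graph model

A GFAv1 file is read into segments (id, DNA sequence or `*` with an `LN:i:`
length tag), links and paths. The graph is bidirected: a link record
`a,oa -> b,ob` and its reverse complement `b,flip(ob) -> a,flip(oa)` denote
the same edge. Every link is stored in canonical form — the lexicographically
smaller of the two writings under (id ascending, `+` before `-`), numeric ids
compared numerically — and duplicates of the same canonical edge are dropped
silently, so `edge_count` counts distinct bidirected edges. `W` (walk)
records are converted to paths named `sample#hap#seqid`; `C` and unknown
record types are skipped with a warning. The sample of a path is its PanSN
prefix (the name up to the first `#`, or the whole name without one); a
`--by-haplotype` switch on the partition subcommand reinterprets the unit as
`sample#haplotype`.

Links whose overlap is neither `*` nor `0M` are accepted but trigger a
one-time warning: all bp statistics treat the graph as blunt-ended, with no
overlap subtraction. Sequence content is never inspected beyond its length,
which is why `*`+`LN` segments are fully supported. Coordinates are 0-based,
half-open everywhere.

`node2int` relabels segments 1..N in order of first appearance as S records
(the tie-break the format itself suggests; the order is recorded in the
emitted two-column TSV map), rewrites paths, and re-canonicalizes links —
relabeling can swap which side of an edge is canonical.

## The 108-metric catalog

The graph-level report is a frozen, ordered list of 108 named metrics in ten
groups: size/composition (12), orientation/loops (6), node length (7),
degree (15), depth (6), node similarity (5), pangenome partition (9), jumps
(8), per-path distributions (7 features x 5 summaries = 35) and edge depth
(5). The order and names in `graph_stats.METRIC_NAMES` are a compatibility
contract guarded by a golden test; adding a metric is a breaking change.

Numeric conventions, chosen once and applied everywhere:

- standard deviations use the population (n) denominator — the catalog
  describes the whole graph, not a sample from it;
- the median of an even count is the mean of the two central values;
- `graph_density` uses the undirected simple-graph denominator
  N(N-1)/2 with self-loops excluded from the numerator, keeping the value
  bounded and comparable across graphs;
- N50/N90 are the usual assembly statistics on node lengths: the length at
  which the descending cumulative sum first reaches 50% (90%) of the total;
- degree counts canonical-link attachments: a self-loop contributes two
  attachments to its node, preserving the handshake sum(degree) = 2E.

Metrics that are undefined for a particular graph keep their row with a
missing value (`NA` in TSV, `null` in JSON): jump metrics on non-numeric
ids, and distribution summaries of empty sets (an empty graph is fully
NA-safe). Nodes traversed by no path count in size/length/degree groups and
in `zero_depth_node_count`, but are excluded from the similarity summaries
and the occupancy partition — they belong to no sample.

### Jumps and the id space

A jump is the absolute difference of numeric node ids between consecutive
steps, the raw |Δid| (not |Δ|−1); the threshold separating local bubbles
from long-range links defaults to 1000 ids and is configurable, since on
SGD-sorted graphs local variation stays within a few hundred ids. Jump
statistics are only meaningful when the id space is sorted along the paths;
`id_sortedness` (fraction of adjacent pairs with increasing ids) is exposed
as the diagnostic for exactly that.

Two caveats discovered while hardening the relabeling tests, both inherent
to any id-based statistic:

- the per-path jump totals summarized in the path-distribution group are as
  id-dependent as the jump group itself;
- the ff/rr split of parallel links follows the *canonical representation*
  of each edge, so an id permutation can move a `++` link into the `--`
  count (their sum is invariant).

`node2int` assigns ids by first appearance in S-record order, so for a file
whose S records are already in first-appearance order the operation is the
identity on relabeled-then-normalized graphs and every metric, including the
id-dependent ones, is restored.

## Pangenome partition and growth

Occupancy s_v counts distinct samples (48 samples vs 96 haplotypes vs 1072
paths are genuinely different things in published human pangenomes; paths
and haplotypes of one sample do not inflate s_v). Classes: core (s_v = S),
private (s_v = 1), shell (everything between), absent (s_v = 0). In the
degenerate S = 1 graph a visited node satisfies both the core and the
private rule; core wins, because "core" is defined relative to all samples
present. Softcore (s_v >= ceil(0.95 S), core included) is reported as a
count alongside the partition, not as a class; 0.95 is the package default
for the softcore fraction.

The exact growth curve is the hypergeometric closed form over all k-subsets
of samples (see README); it needs only the occupancy histogram, so it costs
O(#distinct occupancies x S) after one pass over the steps. The permutation
variant shuffles the sample order with a single seeded NumPy generator
consumed across replicates and averages cumulative-union / running-
intersection contents; identical seeds give identical curves, and the seed
and replicate count are recorded in the output header. Both node and bp
units are reported; bp is the better plotting unit since node counts are
construction-dependent.

Sample similarity is the length-weighted Jaccard index over distinct node
sets; it is invariant under relabeling, symmetric, 1 on the diagonal, and 0
against a sample with an empty node set (warned).

## Sliding windows

Windows slide along one path in step units or in bp (each base inheriting
its step's node statistic). The window value is the unweighted mean of the
statistic over the steps (bases) inside; `private_frac` is the fraction on
occupancy-1 nodes. For the `jump` statistic the window averages the jumps
whose left step lies in the window, so step-mode jump tracks have one fewer
position than other statistics on the same path. Reverse-orientation steps
contribute identically to forward ones. Trailing partial windows are
dropped by default so every value averages the same amount of signal;
`--keep-tail` emits the final short window flagged in an extra column. A
path shorter than one window yields an empty track plus a warning.

## Synthetic graphs and what they do (not) show

The simulator emits an alternating chain of backbone nodes and biallelic
bubbles — SNP (two 1 bp alternatives), insertion (optional node vs skip
link), deletion (node skipped by carriers), inversion (node traversed in
reverse by carriers) — with one path per sample and every sample choosing
each bubble's alternative allele independently with that bubble's frequency
(fixed, default 0.5, or drawn per bubble from a stated Beta). Defaults:
4 samples, 20 bubbles, backbone segments 5–20 bp, bubble mix 60% SNP / 15%
insertion / 15% deletion / 10% inversion — SNP-dominant with a minority of
small structural events, as in real short-scale pangenome variation. Node
ids are assigned 1..N along the chain, so jumps are small by construction;
`shuffle_ids` permutes the labels (S-record order preserved) to create
high-jump and relabeling test cases. The truth sheet records every node's
occupancy as constructed, the implied classes and counts, and per-sample
path lengths; regeneration from the same configuration is byte-identical.

The generator validates the statistics' bookkeeping, not their biology: it
produces no nested or overlapping bubbles, no shared-ancestry correlation
between samples, no repeat collapse (depth > 1 per path), and uniform random
sequence. Passing tests therefore demonstrate correctness of the counting
and the closed forms on well-formed graphs, not robustness to the full
structural complexity of PGGB- or Minigraph-Cactus-built graphs.

## Problem sizes and numerical tolerances

The exact growth curve is checked against explicit subset enumeration for
graphs with up to 6 samples at 1e-9 absolute tolerance; the permutation
estimator at 2000 replicates is required to stay within 2% of pan(S) of the
closed form. The scaling check compares the catalog runtime on ~10k-node and
~100k-node simulated graphs (same configuration family, 4 samples) and
asserts the 10x size costs at most 20x the time; observed ratios are ~12.
Conservation laws (sum of depth = total steps, sum of edge depth = total
adjacent pairs, degree handshake, partition summing to node count) are
asserted on every fixture and a hundred random simulated graphs.

## Known limitations

GFAv2, containment records and overlap-aware (non-blunt) bp accounting are
out of scope. Bubble/superbubble decomposition and graph layout are not
attempted. The metric catalog is this package's own normative set; other
toolkits' catalogs overlap but are not guaranteed to match metric-for-
metric. Jump statistics are reported as missing rather than guessed when
node ids are non-numeric.
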