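# vgstats

Statistics and pangenome analytics for GFAv1 variation graphs.

Pangenome variation graphs condense the genomes of many samples into a single
bidirected sequence graph: nodes carry DNA segments, links join oriented node
ends, and each input haplotype is embedded as a path of oriented node
traversals. Graph shape depends strongly on the construction pipeline and its
parameters, so evaluating a freshly built graph — how collapsed it is, how
interconnected, how the sequence is shared between samples — is a routine
need for anyone building or comparing pangenomes. `vgstats` answers it with
fast, tabular, scriptable summaries: a frozen catalog of **108 graph-level
metrics**, per-path (sample-centric) statistics, core/shell/private pangenome
partitions, genome-growth curves, sample similarity matrices, sliding-window
profiles along paths, and numeric node-id normalization.

## The quantities at the core

For a graph with node set $V$, canonical edge set $E$, paths $P$ and samples
$S$ (a sample is the PanSN prefix `sample#…` of its path names):

- **depth** of node $v$: number of path steps on $v$ (multiplicity counted);
  high average depth indicates collapsed repeats.
- **node similarity / occupancy** $s_v$: number of *distinct samples* whose
  paths traverse $v$. Nodes partition into **core** ($s_v = |S|$), **shell**
  ($2 \le s_v < |S|$), **private** ($s_v = 1$) and absent ($s_v = 0$).
- **compression ratio**: total path length in bp over total node length in
  bp — how much shared sequence the graph collapses.
- **growth curves**: the expected pangenome (union) and core (intersection)
  content of $k$ samples, averaged over all $\binom{|S|}{k}$ subsets. The
  exact closed form is hypergeometric:
  $\mathbb{E}[\mathrm{pan}(k)] = \sum_v \left(1 - \binom{|S|-s_v}{k}/\binom{|S|}{k}\right)$,
  $\mathbb{E}[\mathrm{core}(k)] = \sum_v \binom{s_v}{k}/\binom{|S|}{k}$,
  optionally length-weighted; a seeded permutation estimator is also provided.
- **jumps**: $|\,\mathrm{id}(v_{i+1}) - \mathrm{id}(v_i)\,|$ along a path's
  numeric node ids. On a sorted id space (e.g. after path-guided 1D SGD
  ordering) large jumps flag long-range links; the `id_sortedness` diagnostic
  (fraction of increasing adjacent pairs) says whether jump statistics are
  meaningful at all.
- **sample similarity**: length-weighted Jaccard index between two samples'
  node sets.

Everything needing numeric ids works after `node2int`, which relabels nodes
1..N in first-appearance order.

## Worked example

The repository's four-node toy graph (two haplotypes `x` and `y` sharing a
4 bp start node and a 2 bp end node, split by a 1 bp bubble):

```sh
python -c "from vgstats.synthetic import TOY1; open('toy1.gfa','w').write(TOY1)"
vgstats stats -g toy1.gfa | head -8
```

```
metric	value
node_count	4
edge_count	4
path_count	2
sample_count	2
graph_length_bp	8
total_path_length_bp	14
compression_ratio	1.7500
```

14 bp of haplotype sequence live in 8 bp of graph: compression ratio 1.75.
The growth curve and similarity matrix:

```sh
vgstats growth -g toy1.gfa --mode exact
```
```
# mode=exact
k	pan_nodes	pan_bp	core_nodes	core_bp
1	3	7	3	7
2	4	8	2	6
```

One average haplotype touches 3 nodes (7 bp); both together cover all 4 nodes
(8 bp) but share only 2 core nodes (6 bp) — each path carries 1 bp of private
sequence.

```sh
vgstats similarity -g toy1.gfa
```
```
sample	x	y
x	1	0.7500
y	0.7500	1
```

Samples `x` and `y` share 6 of the 8 union bp: weighted Jaccard 0.75.

Other subcommands: `path-stats` (16-column per-path table), `core` (per-node
occupancy and class), `pan-profile` (per-path bp by occupancy level),
`window` (BED-like sliding-window tracks), `node2int`, and `simulate`, which
generates a bubble-chain pangenome graph with a ground-truth JSON for
testing. `vgstats --help` lists every flag; a YAML file passed via
`--config` can supply defaults for any of them.

As a library, the same analyses are plain functions returning NumPy arrays
and pandas DataFrames (`vgstats.graph_stats_report`, `vgstats.growth_exact`,
…). Thin plotting scripts under `examples/` turn the TSV outputs into
growth-curve and similarity-heatmap figures.

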