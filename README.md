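# priorank

Candidate gene prioritization and composite network construction by
criteria-based filtering, qualitative integration and reoccurrence
ranking of heterogeneous tabular sources.

## The problem

High-throughput screens produce far more candidate genes (or candidate
gene–gene relationships) than a laboratory can follow up. A biologist
typically holds several heterogeneous result tables — differential
expression lists, co-expression lists, interaction edge lists, database
queries — and a set of domain-specific criteria that a good candidate
should satisfy in each of them. `priorank` automates exactly that
procedure without hard-coding data sources or criteria:

1. every source is a tab-delimited *named matrix*: one identifier column
   (a **list**) or two node columns (a **network**), plus optional
   attribute columns, each typed as a numeric `value` or a tag `label`;
2. each source gets its own filter set — comparison operators
   (`<, <=, >, >=, ==`) on value attributes, OR-combined tag sets on
   label attributes, AND across attributes, and explicit `all`/`any`
   logic within an attribute (so an absolute-value cutoff is
   `r > 0.9 OR r < -0.9`);
3. filtered sources are merged qualitatively and every surviving element
   or edge is ranked by its **reoccurrence** — the number of distinct
   sources that still contain it:

   `reoccurrence(x) = |{ s : x ∈ filter_s(source_s) }|`, with
   `1 ≤ reoccurrence(x) ≤ #sources`.

Blank attribute cells are permitted (missing data) and fail every
criterion. For networks, an edge is identified by its unordered node
pair; edges supported by both undirected and directed observations are
flagged `merged`, node degree is the number of distinct incident edges,
and cumulative statistics (items at-or-above each degree/reoccurrence
level) support thresholded re-rendering of the integrated network.
A one-sided Fisher (hypergeometric tail) test asks whether genes of
interest are overrepresented among the prioritized candidates.

## Worked example

Generate the built-in synthetic case-study fixture — eight gene lists
over a 272-gene universe, shaped like a retinal-development candidate
screen: six co-expression lists with a correlation attribute filtered at
|r| > 0.9 and two differentially-expressed-gene lists with a
developmental-age tag filtered to {P6, P10}, with five planted genes
that pass all eight filters — then integrate and inspect:

```sh
priorank fixtures --out-dir demo --seed 1
priorank integrate --config demo/run.yaml
# report written to demo/report.tsv
head -4 demo/report.tsv | grep -v '^#'
```

The report's top tier is exactly the five planted candidates at
reoccurrence 8 (seed 1):

```
element reoccurrence    sources
g010    8       coexpr_1;coexpr_2;coexpr_3;coexpr_4;coexpr_5;coexpr_6;deg_1;deg_2
g127    8       coexpr_1;coexpr_2;coexpr_3;coexpr_4;coexpr_5;coexpr_6;deg_1;deg_2
g138    8       coexpr_1;coexpr_2;coexpr_3;coexpr_4;coexpr_5;coexpr_6;deg_1;deg_2
```

Every line carries the element, its reoccurrence across the eight
filtered lists, and full source provenance. Network runs work the same
way and add static rendering:

```sh
priorank fixtures --kind network --out-dir netdemo --seed 1
priorank integrate --config netdemo/run.yaml
priorank render --config netdemo/run.yaml --min-reoccurrence 2 --seed 1
# wrote netdemo/report.network.png and netdemo/report.stats.png
```

The network report contains four tables (node statistics, edge
statistics, nodes, edges); the edges table is a plain five-column edge
list (`node_a  node_b  direction_status  reoccurrence  sources`)
importable directly into Cytoscape. Images encode degree as node size,
reoccurrence as stroke width, and the undirected/directed/merged edge
classes as blue lines, pink lines with arrows, and blue lines with pink
arrows respectively.

From Python, the same pipeline is:

```python
from priorank import fixtures, integrate_lists, rank_candidates

tables, filters, truth = fixtures.generate_case_study_fixture(seed=1)
ranked = rank_candidates(integrate_lists(tables, filters, mode="defined"))
top = [e.element for e in ranked if e.reoccurrence == 8]
assert sorted(top) == sorted(truth["planted"])   # 5 genes recovered
```

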