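# Methods

## The integration model

`priorank` implements qualitative (unweighted) integration of
heterogeneous evidence. Each input file is one *source*; a source is
either a list (one identifier column) or a network (two node columns),
plus optional attribute columns typed `value` (numeric) or `label`
(tag). The pipeline is

    read → (filter, in defined mode) → merge → rank → report → render

and its single ranking statistic is **reoccurrence**: the number of
distinct sources in which an element or edge survives its source's
filter. The model deliberately carries no source weights, edge
probabilities or score propagation — the claim an integrated result
makes is only "this item independently satisfied the stated criteria in
k of n datasets", which keeps every output auditable back to its
sources. Source provenance (the sorted set of supporting source names)
is therefore preserved through filtering, integration, ranking and into
every written report.

Assumptions worth stating:

- identifiers are comparable across sources as plain strings
  (case-sensitive, surrounding whitespace trimmed); no orthology or
  synonym mapping is attempted;
- duplicate rows inside one source are one observation — reoccurrence
  counts datasets, not rows;
- within a run all sources are lists or all are networks; the two result
  shapes never mix;
- an edge is identified by its unordered node pair. Opposite directed
  orientations (A→B, B→A) support the same edge; all observed
  orientations are retained, and an edge with both undirected and
  directed support is classed `merged` (drawn as an undirected-colour
  line carrying direction arrows). Directedness is a per-source
  declaration in the run config, since a two-column node-pair file
  carries no direction marker.

## Filter semantics

A criterion is either a comparison (`attr OP number`,
OP ∈ {<, <=, >, >=, ==}) on a value attribute or a tag set
(`attr == t1 | t2 | ...`, OR between tags) on a label attribute.
Criteria on one attribute form a group with explicit logic:
`all` (AND — e.g. a cutoff range `x >= 0.4 AND x <= 0.6`) or
`any` (OR — e.g. the absolute-value cutoff `r > 0.9 OR r < -0.9`).
Groups for different attributes always combine with AND. Decisions the
underlying description left open:

- **Blank cells fail every criterion.** Blanks are legal (missing
  data), but a filter should never pass a record on evidence it does
  not have. This is the conservative reading and is logged.
- **`==` on value attributes** compares within a fixed absolute
  tolerance of 1e-9, since attribute values are parsed floats.
- **Numeric literals** accept decimal and scientific notation only
  (regex-validated); `nan`, `inf`, underscores and locale separators
  are rejected so that `label` inference never misfires on them.
- Filters apply to attributes only, never to identifier columns.

## Input format decisions

The original description of the named-matrix format does not say
whether files carry headers or how value/label kinds are declared. Here
a header row is mandatory (filters address attributes by name), and
attribute kinds are declared in the run config whenever filters
reference them — inference (`value` iff every non-blank cell parses
numeric; entirely-blank columns default to `label`) is a convenience
for unfiltered browsing only, so a run's meaning cannot drift with its
data. Malformed rows (wrong field count, blank key, non-numeric cell in
a declared value column) are all collected and reported together with
their file line numbers; nothing is silently dropped.

## Statistics and reports

Cumulative statistics tables list, for every *observed* level v, the
number of items whose degree (nodes) or reoccurrence (edges) is ≥ v —
observed levels only, not a dense integer range, matching the paired
plot points a user thresholds from. Network reports contain exactly
four tables (node statistics, edge statistics, nodes, edges) behind a
`#`-prefixed provenance header naming the integrated files and the
applied filters; the edges table is a five-column edge list
(`node_a, node_b, direction_status, reoccurrence, sources`; sources
semicolon-joined and sorted) usable directly as a Cytoscape import.

`enrichment_test(hits_selected, selected, hits_total, universe)` is the
one-sided overrepresentation Fisher test, i.e. the hypergeometric tail
P(X ≥ hits_selected) (scipy `hypergeom.sf`). The universe and hit
definitions are the caller's: all four counts are explicit arguments
rather than guessed from context.

## Rendering

The interactive click-to-redraw viewer this package replaces is mapped
to a deterministic batch equivalent: `threshold_network` +
`layout_network` + `render_network`. Degree thresholds are evaluated
against degrees in the **pre-threshold** network (the values the user
read off the statistics plot); degrees are then recomputed on the
result, and edge-less nodes are dropped. When both thresholds are
given they apply simultaneously to the original network. Layout is a
seeded Fruchterman–Reingold run (networkx, 60 iterations); identical
(network, seed) pairs give identical positions, a single node sits at
the canvas centre. Styling: node size affine in degree, stroke width
affine in reoccurrence, undirected/directed/merged classes in blue /
pink-with-arrow / blue-with-pink-arrow; output is PNG or TIFF
(matplotlib Agg + Pillow), plus a companion chart of the two cumulative
statistics plots. Reproducibility is asserted on decoded pixels, not
file bytes, since container metadata may differ between backend
versions.

## Synthetic fixtures

The fixture generators emulate the *structure* of a real candidate
screen, not its biology: identifiers are synthetic, and no expression
matrices, correlation estimation or differential-expression testing are
simulated — the generators produce the lists those analyses would
output. The case-study-shaped fixture defaults to 8 sources over a
272-gene universe with 5 planted candidates: six correlation lists
(attribute `corr`, filter `corr > 0.9 OR corr < -0.9`) and two
developmental-age lists (attribute `age` over {E16, P2, P6, P10, 4wk},
filter `age == P6 | P10`). Planted genes draw attribute values inside
every filter's passing region; each background gene passes any single
filter with probability 0.25 (a fixture choice — per-list pass rates of
a real screen are analysis-dependent), and a background gene that would
pass all eight by chance is resampled to fail one randomly chosen
source. Ground truth is therefore exact by construction, which is what
lets the planted-recovery tests assert equality rather than a rate.
Values are sampled with a small margin off each cutoff (e.g. |r| ∈
(0.9005, 1] vs |r| ≤ 0.8995) so float formatting at 6 decimals can
never move a record across a boundary.

What passing fixture tests do **not** show about real data: robustness
to identifier mismatches across platforms, to correlated filters, or to
attribute noise near the cutoffs — in real screens the filter
thresholds themselves are the analyst's responsibility.

## Problem sizes and numerical notes

Property suites run on randomized tables of ≤ 25 rows across hundreds
of replicates (1000 table/filter pairs for the filter oracle), the
direction-merge check enumerates all 27 three-source orientation
combinations, the enrichment oracle enumerates every consistent
configuration with universe ≤ 30, and planted recovery runs the full
eight-list, 272-gene fixture through the CLI for 20 seeds — sizes
chosen so the whole suite settles in well under a minute while still
covering the full case-study-scale run exactly. Ties in ranking break by
ascending lexicographic label so every output is deterministic;
degenerate inputs (empty filter sets, all-fail filters, empty
thresholded networks) are legal and produce empty-but-valid results,
except rendering, which refuses an empty network rather than emit a
blank image.

## Known limitations

- No weighted or probabilistic integration; reliability of a source is
  expressed only through its filter.
- No identifier normalization across sources.
- One layout scheme, static images only; no SVG.
- Very large files are read whole; the format is not streamed.
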