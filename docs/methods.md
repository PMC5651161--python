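# Methods

## Network model

A regulatory network is a simple directed graph: genes as nodes, at most
one edge per ordered pair, each edge carrying a real interaction strength
(Z-score units; positive = activation, negative = repression, 0 = neutral
"dual" effect). Curated sources report promoter-level duplicates for one
gene pair; every submitted record passes through a max-weight rule, so the
stored weight is the maximum over all records seen for that pair.

Two aggregation modes exist. The default, `signed-max`, keeps the largest
signed value — "biggest value" read literally, and the only reading
exercised by the curated example we reproduce (three positive duplicates
4.857 / 0.834 / 0.845 → 4.857). `abs-max` keeps the record of largest
magnitude with its sign; it exists because a signed maximum discards a
strong repression when any weak activation is present for the same pair,
which a user may not want. Mixed-sign duplicates do not occur in the
curated examples, so the default follows the literal rule.

Conventions where the sources are silent:

* self-loops are allowed and count once toward in- and out-degree;
* gene symbols are whitespace-trimmed and matched case-sensitively;
* duplicate rows with identical endpoints and weight collapse silently;
* the TF subnetwork is a **single pass**: membership is out-degree > 0 in
  the parent network, and the induced graph may itself contain new
  zero-out-degree nodes (a second application can shrink it further —
  this is expected behaviour, not a bug).

## Relative influence

    RI = out / (in + out) − (ε + in) / (ε + out),   negative values → 0

* ε > 0 guards the division; default 10⁻³. The ε in the *numerator* of
  the subtracted term matters: without it an unregulated hub would score
  exactly 1 regardless of out-degree, and the published 8-decimal values
  (e.g. 0.99999954 at out-degree 2175) would not reproduce.
* The isolated-gene case in = out = 0 is defined as RI = 0 (the first
  term is 0/0; an isolated gene exerts no influence).
* Raw RI is strictly increasing in out-degree and strictly decreasing in
  in-degree (verified exhaustively on the [0,200]² grid); clipped RI lies
  in [0, 1).
* Rankings sort by RI descending with ties broken by gene symbol, so
  tables are reproducible. Top/bottom-k selection can exclude effectors
  first (out-degree 0), which is the default for TF tables.

**ε inconsistency in the source data.** The human-network table values
reproduce from their printed degrees only at ε = 10⁻³, the *E. coli*
table only at ε = 10⁻⁴, although a single ε = 10⁻³ is stated. ε is
therefore a per-run parameter; the regression suite pins each table at
the ε that reproduces it. A further inconsistency: the human
*bottom*-of-table values do not follow from their printed degrees at
either ε (ADNP with degrees (132, 292) computes to ≈0.2366 at ε = 10⁻³
against a printed 0.256880007); the degrees actually used there are
unrecoverable, so those values are asserted as *mismatching* in the test
suite and excluded from the reproduction script.

## Polarity

A TF's polarity sums over its **outgoing** edges only. Sign mode counts
positively minus negatively weighted targets; weight mode sums raw
weights. Sign mode is the default because the source's only worked
arithmetic is a target count (965 − 687 = 278); the two modes can
disagree when few strong edges oppose many weak ones, and the CLI reports
both. Weight-0 edges contribute to degree but to neither mode's score.
Labels: score > 0 → overall activator, < 0 → overall repressor, 0 →
neutral. These are summaries of one network in one cellular context, not
intrinsic protein properties.

## Crawler

The breadth-first crawler reconstructs a network from a gene-centric edge
database (`regulators_of` / `targets_of` queries, possibly returning
promoter-level duplicates). It keeps a FIFO queue and an explored-set;
each discovered gene is queried exactly once for each direction (≤ 2
provider calls per gene), and every reported interaction goes through the
max-weight rule. The result is the weakly connected component of the seed
and is provably order-independent because aggregation is order-independent;
`crawl_all` unions crawls over several seeds to cover databases with
disconnected components. Exploration order within a level follows the
provider's delivery order; the bundled mock provider sorts
lexicographically for determinism. A live HTTP backend is out of scope;
the provider interface is the seam where one would plug in.

## Serialization

Edge-TSV: UTF-8, tab-separated, header `source target weight`, rows
sorted by (source, target), weights printed with 9 significant digits,
`#` comments. Zero-degree genes are carried as `#!node <symbol>`
directive lines (still comments to third-party readers), so read-back is
the identity for any network whose weights carry ≤ 9 significant digits —
which includes everything the generator emits, since it quantizes weights
to that precision at creation. SIF (`source reg target`) drops weights
and reads back with weight +1. GraphML stores the weight as an edge
attribute and node annotations (e.g. average transcript count) as node
attributes.

## Synthetic generator

The generator emulates the three-tier hierarchy of curated transcriptional
networks: `n_master` unregulated master TFs (in-degree 0), `n_tf`
regulated TFs, `n_effector` zero-out-degree effectors. Defaults and
rationale:

| parameter | default | why |
|---|---|---|
| `out_degree_exponent` | 2.0 | heavy-tailed out-degrees — a few TFs control most genes; the sources fit no distribution, so the exponent is configurable |
| `max_out_degree` | all possible targets | no artificial cap |
| `activator_bias` | Beta(2, 2) | per-TF positive-edge fraction centred on a balanced mix while allowing strong overall activators/repressors |
| `weight_scale` | 2.0 | half-normal magnitudes, truncated to the stated Z-score range [−10, 12] |
| `duplicate_rate` | 0.2 | a minority of pairs carry promoter-level duplicates, enough to exercise aggregation without dominating the stream |
| `manifest_epsilon` | 10⁻³ | ε at which the manifest's true RI is stated |

Every regulated TF — and, beyond the minimum needed, every effector — is
guaranteed at least one regulator, so no spurious isolated genes arise; a
regulated TF needs a possible regulator other than itself, hence configs
with `n_tf ≥ 1` and `n_master + n_tf < 2` are rejected. Duplicate records
are drawn at or below the primary weight (1–3 extras per selected edge),
so max-aggregation provably recovers the primary and the manifest remains
exact ground truth; mixed-sign duplicates are available behind a flag to
exercise the signed-max rule. All randomness flows from one integer seed
through `numpy.random.default_rng`; identical config + seed reproduces the
record stream and manifest byte for byte.

What the generator does **not** emulate: real gene symbols and biology,
correlated regulation (motifs, feedback loops beyond what random wiring
produces), in-degree structure beyond the tier constraints, expression
time series, or database-scale sizes (the defaults produce ~10²-gene
instances; the real catalogs have 10³–10⁴ genes and 10⁵ links).
Passing tests therefore demonstrate correctness of the graph algebra,
statistics and plumbing under the assumed structural model — not that the
statistics are biologically informative on any particular real dataset.

## Problem sizes and numerical choices

The test and reproduction workloads use desk-scale instances: the
monotonicity grid is the exhaustive [0,200]² degree square; the
crawl-vs-bulk-load equivalence runs 100 random instances of 14–77 genes;
manifest agreement runs 20 seeded instances. Published-value regressions
compare at the printed precision (round to the printed number of
decimals); the one worked example whose printed value reflects different
intermediate rounding (in 232 / out 2829 → printed 0.842196754, recomputed
0.842199674) is compared at 1×10⁻⁵ absolute; all other floating
comparisons use 1×10⁻⁸ or tighter. RI values are printed with 9
significant digits, matching the precision of the published tables.

## Known limitations

* Network-scale published counts (9090 genes, ~235k links, 295 TFs; the
  1988-gene / 4414-interaction *E. coli* snapshot) depend on external
  database snapshots and are not reproducible here; the source itself is
  internally inconsistent about two of them (234,913 vs 234,970 links;
  295 vs 298 TFs).
* SIF export is lossy (no weights).
* The crawler assumes a pure provider (stable answers within a session);
  a changing backend would need snapshotting upstream of `tfnet`.
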