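# Methods

`scboolnet` models tumor transcriptomes as Boolean gene regulatory
networks: each gene is a binary variable, each regulatory interaction is a
signed directed edge, and each gene's next value is a fixed Boolean
function of the current network state. A cell's binarized expression
profile is the initial condition of a deterministic trajectory; the cycle
that trajectory ends in is the cell's attractor, interpreted as the stable
expression program the cell's regulatory logic would settle into.

## The network model

The network is an ordered gene list `x_1 … x_n` with one update rule
`f_i: B^n -> B` per gene. All genes update synchronously:
`x_i(t+1) = f_i(x(t))`. Synchronous updating makes the dynamics a
deterministic map on a finite state space, so every trajectory must enter
a cycle — a singleton (fixed point) or a longer attractor. Asynchronous
schemes are out of scope here; the package exposes only the synchronous
map and is structured so an alternative stepper could be added.

Rules are **nested canalyzing**: the regulators are ranked, and each
regulator at its canalyzing value fixes the output regardless of the
regulators below it. Given a gene's activators `a_1 … a_k` and inhibitors
`i_1 … i_m`, the default *inhibitor-dominant* scheme builds

    f = (¬i_1 ∧ … ∧ ¬i_m) ∧ (a_1 ∨ … ∨ a_k)

so any active inhibitor silences the gene and otherwise any active
activator turns it on. An *activator-dominant* variant
(`(a_1 ∨ …) ∨ ¬(i_1 ∨ …)`) is a configuration switch. With only one
regulator class the rule degenerates to the OR of activators or the AND of
negated inhibitors. Genes with no regulators are **frozen inputs**
(`x* = x`): they hold their binarized value for the whole simulation
rather than acquiring invented regulation. Dominant repression is the
common convention for signed GRN logic; the per-node clause grouping of
any particular published network is generally not recoverable from edge
evidence alone, which is why the scheme is a parameter rather than a fact.

Rules serialize to a line-oriented text dialect (`GENE* = expr`, ASCII
`and/or/not`, unicode connectives accepted on parse). The writer emits a
`genes:` order directive so that parse∘write is the identity on networks
and write∘parse is the identity on canonical text; every bit vector is
therefore reproducible across runs from the serialized artifact alone.

## Network construction

Construction turns flat-file evidence into the signed network:

1. **Pathway filter** — pathway gene lists (plain text or GMT) are
   intersected with the genes present in the tumor / control cell-line
   expression tables.
2. **Differential expression** — only genes with status `up` or `down` in
   the DE table survive; missing genes default to `ns` with a warning.
3. **Hub selection** — a gene is kept iff it has at least
   `min_hub_degree` (default 50, boundary inclusive) distinct interactome
   partners. Degree counts distinct neighbors after collapsing redundant
   evidence lines; a self-interaction counts once. Genes absent from the
   interactome have degree 0.
4. **Intermediary insertion** — for every seed pair without a direct
   interactome edge, the shortest path whose internal vertices are all
   (a) non-seed, (b) present in the expression table and (c) above the
   low-expression threshold in the reference sample is admitted, provided
   it has at most `max_intermediaries` (default 3) internal vertices.
   Among equal-length paths the lexicographically smallest internal tuple
   wins — an arbitrary but reproducible tie-break. Paths through another
   seed are skipped because those links are covered by the other pairwise
   searches. The low-expression threshold defaults to the 10th percentile
   of the nonzero reference-sample values when not set explicitly.
5. **TF enrichment** — every transcription factor with at least one
   target among current vertices is added with a directed edge per target;
   the TF table's mode is carried as a provisional sign.
6. **Sign resolution and assembly** — each directed edge takes its sign
   from the sign table first, then (configurably) from the TF mode, then
   optionally defaults to activation; otherwise assembly fails listing the
   offending pairs. Undirected interactome edges contribute both
   directions. Per gene, regulators are ordered by descending interactome
   degree (ties alphabetical) and fed to the NCF builder; regulator-less
   genes become frozen inputs. Gene order is seeds, then intermediaries,
   then TFs, alphabetical within each class, which fixes the bit-vector
   layout.

Manually curated genes (`seed_genes`) join the seed set without passing
the DE/hub filters. Whether intermediary admissibility should consult the
tumor line only or both lines is genuinely open; the reference sample is a
configuration value defaulting to the tumor column.

## Binarization

Each gene's expression vector across cells is binarized independently.
The values are sorted ascending into `u_1 ≤ … ≤ u_N`; for every
discontinuity count `j ∈ {1, …, N−2}` the algorithm finds the monotone
step function with exactly `j` discontinuities minimizing total squared
deviation, levels equal to interval means. This is solved exactly by
dynamic programming over breakpoint placements (suffix DP with forward
reconstruction, which also yields the lexicographically smallest
breakpoint tuple on exact ties — matched by the brute-force enumeration
oracle in the tests). Each family member reports its strongest
discontinuity, scored as level-jump height divided by (approximation error
+ ε), ε = 1e−12 guarding exact fits; ties go to the smallest location.
The binarization location is the median of those locations (lower median
for even counts); the threshold `t` is the midpoint of the two sorted
values flanking it, and a cell's bit is 1 iff its value is ≥ `t`. Because
`t` falls strictly between two consecutive sorted values on non-degenerate
data, the ≥/≤ ambiguity at `u = t` never arises in practice. The reported
`quality` is the median absolute deviation of the family's locations
divided by `N−1` (0 means every family member agrees on the cut).

This is the plain step-function construction; a scale-space-smoothed
variant is left as an engine hook (`engine` parameter) and no bootstrap
robustness test is applied. Constant genes carry no threshold information
and default to all-0 ("not expressed"), switchable to dropping the row.
Binarization scope defaults to per-sample (each patient's cells binarized
against their own distribution), with a global mode available; per-sample
matches the premise that the threshold describes one tumor's cell
population.

## Attractor search and consensus calls

Each cell's binarized profile seeds one trajectory. States are recorded in
a first-seen map; on the first revisit the cycle is cut out and rotated so
its lexicographically smallest state comes first, making attractors
comparable across cells. If `max_steps` (default 10,000, always logged)
passes without a revisit the cell is a **no-result** — a value, not an
error, so its frequency is a reported outcome. A brute-force enumerator
walks all `2^n` states (guarded to n ≤ 22) and serves as the exact oracle
for the trajectory path in the tests; basin sizes must partition `2^n`.

Per attractor, each gene is labeled `True`/`False` when its value is
constant across at least `cycle_fraction` of the cycle states (default
1.0 = strict constancy; a "most states" mode, e.g. 0.8, is available and
recorded in output metadata — the two readings of constancy are both
defensible, so the choice is surfaced as a parameter). Otherwise the gene
is `X`.

Cells group by (sample, cell type); pooled-sample cells are excluded
up front. A group calls a gene `True` (resp. `False`) when at least
`min_cell_fraction` (default 0.95, boundary inclusive: 19 of 20 cells
suffices) of its attractor-bearing cells carry that label; otherwise
no-call. No-result cells are excluded from the denominator — they have no
attractor to label — and their count is logged per group. Cross-group
summaries order columns by tumor subtype then sample and flag patterns
such as a gene never expressed in any group of one subtype. The
group-level summary matrix uses malignant-cell groups by default
(configurable), since the question it answers is about tumor-cell
programs.

## Synthetic data

The generator produces every input with known ground truth, at the scale
of the emulated cohort: 103 network genes and 549 cells over 14 sample
groups (11 patients; two lymph-node samples and one re-biopsy are separate
groups), four tumor subtypes, and malignant / stromal / immune-B /
immune-T / myeloid cell types with fixed per-group counts.

*Expression* is a per-gene two-component mixture. Components are
log-normal with (μ, σ) moment-matched to the requested arithmetic mean and
sd (defaults 2 and 8, sd 0.5) — log-normality gives scRNA-seq-like
positivity and right skew while keeping the stated component separation
meaningful on the raw scale. The per-gene, per-group probability of the
high component defaults to Beta(0.3, 0.3) draws, so most gene/group pairs
are clearly on or off. Dropout is zero-inflation applied after sampling
(default 0.1; recovery checks use 0). The generator records the true
component of every value; binarization is validated against those labels.
What this does *not* emulate: UMI counting noise, library-size variation,
gene–gene correlation, batch effects — so passing recovery tests show the
thresholding works where a gap exists, not that real data always offers
one.

*Networks*: random NCF networks (Poisson in-degrees, random
activator/inhibitor splits) exercise the dynamics; planted networks
construct rules that provably hold a chosen state fixed (or cycle through
it with period 2 when a fraction of genes is designated non-constant,
driven by a clock gene), verified by one synchronous step before return.
An anchored variant draws all regulators from a small frozen anchor set,
making the planted state globally attracting given the anchor values —
the substrate for basin-recovery tests.

*Knowledge base*: a deterministic evidence set (hub-structured interactome
with filler partners pushing hubs past the 50-partner threshold, pathway
lists with absent and non-DE padding, dedicated one-intermediary paths,
TF and sign tables) whose construction yields exactly 15 hubs + 5 manual
genes + 53 intermediaries + 30 TFs = 103 network genes.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is a pure function of (parameters, seed).
- The segment-cost matrix uses prefix sums of `v` and `v²`; costs are
  clipped at 0 to absorb negative rounding residue.
- DP/brute-force agreement is asserted to 1e−9 absolute on squared error.
- Pipeline outputs are written with fixed float formats and sorted JSON
  keys; reruns of an identical configuration are byte-identical, and the
  report embeds a SHA-256 of the configuration.
- Default problem sizes (103 genes × 549 cells end to end; n ≤ 10 for
  exhaustive dynamics oracles; 500-vector binarization oracle sweeps) keep
  a full validation run in the tens of seconds on one CPU.

## Known limitations

- Synchronous semantics only; asynchronous updating can change attractor
  structure and is not modeled.
- The nested canalyzing scheme applies one uniform construction per node;
  node-specific curated logic can only enter via a ready-made rule file.
- Binarization assumes a single threshold per gene vector; genes with more
  than two expression regimes are forced into two.
- Intermediary search optimizes path length, not evidence quality; an
  interactome with dense hub neighborhoods can admit biologically dubious
  shortcuts.
- The consensus rule treats cells as exchangeable within a group; it does
  not model per-cell uncertainty or correct for group size.
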