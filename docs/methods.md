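# Methods

## Scope and data model

The package operates on two primary inputs: a COBRA-style SBML model and
an enumeration of elementary flux modes (EFMs) produced elsewhere. The
model's *reaction order* — document order in the SBML file — defines the
index space that EFM files address; every downstream structure
(`EfmSet`, yields, enrichment, backbone) speaks in those 1-based indices.
Index base of the input files is an explicit parameter (`index_base`,
default 1, matching the MATLAB/COBRA heritage of most enumeration
toolchains); 0-based files are normalized on parsing. EFM files are
whitespace-delimited, one mode per row; any run of spaces/tabs is one
delimiter, blank rows are skipped, duplicate indices within a row are
collapsed with a warning. Flux files carry one row per mode, normally one
value per active reaction in the row's token order; a row whose width
equals the model's reaction count is interpreted as a full-length vector
(both conventions exist in the wild, and the two shapes are unambiguous
except when a mode touches every reaction, in which case the full-length
reading is used).

SBML reading accepts Level 2 and Level 3, GPRs from FBC v2 gene-product
associations or legacy `GENE_ASSOCIATION` note strings (standard
precedence: `and` binds tighter than `or`, parentheses honored),
subsystems from the groups package or `SUBSYSTEM` notes. Writing targets
L3V1 + FBC v2 + groups. Reaction bounds in written documents are
wide-open defaults (±1000, or 0..1000 for irreversible reactions): the
extracted submodels are visualization artifacts, not simulation-ready
models, and no bound information survives mode enumeration anyway.
Identifiers are preserved verbatim; FBC gene products are written with a
sanitized `G_`-prefixed SId and the verbatim gene id in the `label`
attribute, which is also what the reader prefers.

## Yield analysis

For a chosen substrate-uptake reaction and product-release reaction, the
yield of a mode is `Y = |v_out| / |v_in|` over its relative fluxes.
Magnitudes are used deliberately: exchange-reaction sign conventions
(signed net flux vs. forward/backward split reactions) differ between
enumeration tools, and the ratio is the quantity with meaning. Yield is
invariant under rescaling of a mode's flux vector, so the arbitrary
normalization of the enumeration tool drops out. Extreme-yield selection
returns *all* modes within relative tolerance 1e-9 of the extreme,
ordered by ascending reaction count and then mode id, so the first
element is "the shortest mode" at that extreme — the usual choice for
visualization. A mode must contain both designated reactions; apply the
presence filter first.

## GPR mapping and enrichment

Gene-level statistics (p-value, log2 fold change, an expression value)
are resolved to reaction level through each reaction's GPR tree: an `AND`
node (enzyme complex — the least-expressed subunit limits the complex)
takes the child with minimum ranking value, an `OR` node (isozymes — the
strongest isozyme suffices) the maximum; children without data are
ignored at both node kinds, and a tree with no data at all flags the
reaction as uncovered. The ranking quantity is a parameter (`key`):
`expression` by default, `abs_log2_fc` for tables without a meaningful
expression column — differential-statistics tables vary, and the choice
is surfaced rather than guessed. Ties keep the first child in rule order,
a deterministic tie-break that matters only for exactly equal ranking
values.

Enrichment is a one-sided over-representation test per mode: with N
covered reactions in the background (default: all covered reactions in
the model; configurable), K of them significant in the tested direction
(covered, raw p below `sig_p`, log2FC strictly positive for "up" /
negative for "down"), and a mode containing n covered reactions of which
k are significant, the raw p is the hypergeometric upper tail
`P(X ≥ k)`. Modes with n = 0 receive p = 1, as does everything when
K = 0 (with a warning). Adjustment is Benjamini–Hochberg across all
tested modes. A convenience wrapper runs both directions and labels each
mode with the direction of smaller adjusted p (ties to "up"). The test is
a deliberate methodological simplification relative to gene-set packages
with richer null models: it is exact, dependency-free, and checkable
against enumeration — the acceptance suite verifies it against rational-
arithmetic combinatorial counting over every contingency shape with
N ≤ 25 to 1e-12.

## Submodel extraction and ubiquitous metabolites

Extracting a mode keeps exactly its reactions (model order preserved),
the metabolites participating in at least one kept reaction, and the
genes appearing in at least one kept GPR; GPR trees are never pruned, so
isozyme structure stays visible even when only part of it is expressed.
Ubiquitous currency metabolites (default list shipped as a config file:
ATP, ADP, AMP, Pi, PPi, H⁺, H₂O, CO₂, O₂, NAD(H), NADP(H), CoA, expanded
per model compartment; fully overridable) may be removed during
extraction to declutter the network. Removal deletes species and their
edges but never reactions — a reaction emptied of all participants (e.g.
ATP maintenance after ATP/ADP removal) survives as a species-free node,
because reaction nodes carry the flux annotations mapped downstream.
Designated input/output species can be marked protected; a list that
tries to remove a protected species is rejected outright.

## Subsystem occurrence, backbone, overlap

Subsystem occurrence is the row-normalized share of a mode's reactions
per subsystem label; reactions without a label pool under
`(unassigned)`, and multi-label reactions (possible with groups
annotations) count 1/m per label so rows still sum to 1. Fractions are
stored at full precision and formatted (one decimal) only at export.

The backbone of a mode collection is `{r : f_r > τ}` where `f_r` is the
fraction of modes containing r. The cutoff is strict by default —
"present in *more than* τ" — with an inclusive `≥` mode behind a flag,
since both conventions appear in practice. Selection is downward-
monotone in τ by construction (raising the cutoff can only shrink the
backbone), and a reaction present in every mode survives any valid τ;
both facts are enforced as property tests. The occurrence histogram bins
`f_r` over right-closed bins on (0, 1] so omnipresent reactions land in
the top bin.

## Network export

A (sub)model becomes a directed typed graph: substrate edges
metabolite→reaction, product edges reaction→metabolite, catalysis edges
gene→reaction. Node ids are namespaced (`m:`, `r:`, `g:`) because SBML
keeps species/reactions/genes in separate id spaces while flat graph
formats do not. A reaction is flagged `is_exchange` when it touches a
boundary species or has at most one participant. Reversible reactions
export as a single node with a `reversible` attribute; edge direction
follows stoichiometry sign. Data mapping attaches a mode's |flux| to
every substrate/product edge of the corresponding reaction (one flux per
reaction — all its edges agree), occurrence percentages to reaction
nodes, and log2FC/p to gene nodes. Serialization: GraphML (typed
attributes, round-trips through networkx), SIF plus node/edge attribute
TSVs (edge type is the interaction token), or a flat JSON document.

## Synthetic study design

The fixture generator stands in for a real model + enumeration + omics
triplet. The network is a fixed 19-reaction, 16-metabolite, 16-gene
overflow-metabolism motif: glucose uptake and transport, lumped
glycolysis (hexokinase step plus a pyruvate-producing lump with net ATP
gain), three alternative pyruvate-dissipating routes — dehydrogenase →
acetyl-phosphate → acetate, decarboxylase → acetaldehyde → acetate, and
formate-lyase → acetate + formate — plus pyruvate overflow, exchanges
for every released product, and an ATP maintenance sink. GPRs cover the
standard shapes (single gene, `or` isozyme pair, `and` complexes);
subsystems span exchange, transport, glycolysis, pyruvate metabolism,
acetate metabolism and maintenance.

Four modes are planted, each balancing every internal metabolite exactly
(|S·v| = 0): the dehydrogenase route (2 acetate per glucose, the maximum
yield), the decarboxylase route with pyruvate overflow (1 acetate per
glucose, the minimum), the formate-lyase route (yield 2, tying the
maximum so extreme-selection ordering is exercised), and a pure pyruvate
overflow mode releasing no acetate (exercising the presence filter). Per
seed, each mode's fluxes are scaled by a dyadic factor in [0.5, 2]
(multiples of 1/8) — dyadic so that products and ratios remain exact in
binary floating point and the planted yields are recovered *exactly*,
not approximately. The gene table plants p = 0.001 and log2FC ±2 on the
dehydrogenase-route genes (up) and decarboxylase-route genes (down),
null genes with p uniform in [0.2, 0.95] and |log2FC| ≤ 0.1, and omits
one transporter gene entirely to exercise missing-data handling; these
choices make exactly one mode the most enriched per direction, by
construction. Parameter validation rejects configurations that would
break the planted structure (e.g. planted p above the significance
cutoff).

What the generator does *not* emulate: genome-scale size (thousands of
reactions), RNA-seq sampling noise (only gene-level summary statistics
are produced), modes that are provably elementary (the planted modes are
steady-state routes by construction; minimality is not certified), or
realistic p-value distributions under the null. Passing tests therefore
demonstrate correctness of the bookkeeping, the statistics and the file
handling — not statistical power on real data, where background sizes of
thousands of mapped reactions make the same hypergeometric machinery far
more sensitive than on the 12-reaction fixture background (where the
planted route's smallest raw p is ~0.25 and nothing clears FDR 0.05; the
assertable outcome is the argmin, not significance).

## Numerical choices

- Steady-state validation: dense `S·v` with max-norm residual over
  non-boundary metabolites, default tolerance 1e-9 (absolute; flux
  magnitudes in these files are O(1)–O(10)).
- Extreme-yield tolerance: relative 1e-9 (ties at an extreme are real in
  EFM data; exact comparison would split them by rounding noise).
- Hypergeometric tail via `scipy.stats.hypergeom.sf(k−1, N, K, n)`;
  BH via `scipy.stats.false_discovery_control`, clipped to [0, 1].
- GPR tree equality for round-trips uses a normalized form (same-kind
  nodes flattened, children sorted), i.e. equality up to
  associativity/commutativity of `and`/`or`.
- Test and acceptance problem sizes (25-element enumeration sweep, 1000
  random GPR trees, 200 random mode collections, 50 round-trip modes)
  were chosen to make each property check run in seconds while covering
  every contingency shape / tree shape class involved.

## Known limitations

- One statistic per reaction: GPR resolution keeps a single gene record
  per reaction; no averaging over isozymes or complex members.
- Enrichment treats reactions as exchangeable; no correction for the
  dependence between overlapping modes beyond BH across modes.
- SBML identifiers must be valid SIds to survive writing (libsbml
  rejects others); the reader imposes no such restriction.
- Subsystem multi-labels are joined with `"; "` internally, so labels
  containing that separator would be split on round-trip.
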