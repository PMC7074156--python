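# fluxmodes

Selection, analysis and network export of **elementary flux modes (EFMs)**
from genome-scale metabolic models.

An elementary flux mode is a minimal set of reactions that can operate at
steady state: a self-contained route from uptake to release. Enumeration
tools (TreeEFM, efmtool, FluxModeCalculator, ...) emit EFMs as plain-text
files of reaction indices against a model's reaction order — and then the
real work starts: a single model easily yields thousands of modes, far too
many to inspect. `fluxmodes` is the downstream toolkit for that situation.
It is aimed at systems biologists who have a COBRA-style SBML model and an
EFM enumeration in hand and want to decide *which* modes matter and see
*what* they do:

- **Filtering** — keep the modes containing (or excluding) a reaction of
  interest, e.g. all acetate-releasing modes.
- **Yield analysis** — score each mode by
  `Y = |v_out| / |v_in|`, the product-release flux per unit of
  substrate-uptake flux, and select the modes with extreme yield.
- **Omics mapping & enrichment** — map gene-level differential-expression
  statistics onto reactions through GPR rules (`AND` = enzyme complex →
  gene with **minimum** expression; `OR` = isozymes → gene with **maximum**
  expression), then test each mode for over-representation of
  significantly up-/down-regulated reactions with a one-sided
  hypergeometric test, `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`,
  Benjamini–Hochberg-adjusted across modes.
- **Submodel extraction** — write one mode as a standalone SBML (L3V1 +
  FBC v2 + groups) model, optionally with ubiquitous currency metabolites
  (ATP, H⁺, H₂O, ...) removed.
- **Comparison** — per-mode subsystem-occurrence profiles; the *backbone*
  `{r : f_r > τ}` of reactions present in more than a fraction τ of modes,
  with per-reaction occurrence percentages; pairwise overlap.
- **Network export** — typed metabolite/reaction/gene graphs with flux,
  occurrence and expression attributes, written as GraphML, SIF (+
  attribute tables) or JSON for Cytoscape-style visualization tools.

EFM *computation* is out of scope; so are layout and rendering.

## Worked example

Everything below runs on a bundled synthetic study — a 19-reaction
overflow-metabolism network with four planted steady-state modes and a
planted differential-expression table (see `docs/methods.md`):

```console
$ fluxmodes fixtures generate --seed 7 --out bundle
wrote bundle/efms.txt, bundle/fluxes.txt, bundle/gene_stats.tsv, bundle/ground_truth.json, bundle/model.xml

$ fluxmodes filter --model bundle/model.xml --efms bundle/efms.txt \
    --fluxes bundle/fluxes.txt --reaction EX_ac --out filtered
3 of 4 EFMs contains reaction EX_ac

$ fluxmodes yield --model bundle/model.xml --efms filtered/efms_filtered.txt \
    --fluxes filtered/fluxes_filtered.txt \
    --input-reaction EX_glc --output-reaction EX_ac --out yields
yield range 1..2; max attained by EFM(s) [1, 3], min by EFM(s) [2]

$ cat yields/yields.tsv
efm_id  input_flux  output_flux  yield
1       2.0         4.0          2.0
2       1.5         1.5          1.0
3       1.5         3.0          2.0
```

Mode 1 converts each glucose into two acetates (yield 2.0, the maximum);
mode 2 diverts half its pyruvate to overflow and releases only one
(yield 1.0, the minimum). The mode that releases no acetate at all was
removed by the filter. Continuing with enrichment, backbone and export:

```console
$ fluxmodes enrich --model bundle/model.xml --efms bundle/efms.txt \
    --gene-stats bundle/gene_stats.tsv --out enrich
mapped data onto 12 reactions; 0 EFM(s) enriched up, 0 down (adjusted p < 0.05)

$ fluxmodes backbone --efms bundle/efms.txt --n-reactions 19 --tau 0.8 --out backbone
5 reactions present in more than 80% of EFMs

$ fluxmodes extract --model bundle/model.xml --efms bundle/efms.txt \
    --efm-id 1 --remove-ubiquitous --out sub
wrote sub/synthnet_EFM1.xml (12 reactions, 8 metabolites, 11 genes)

$ fluxmodes export --submodel sub/synthnet_EFM1.xml --full-model bundle/model.xml \
    --efms bundle/efms.txt --fluxes bundle/fluxes.txt --efm-id 1 \
    --gene-stats bundle/gene_stats.tsv --out net
wrote net/synthnet_EFM1.graphml (31 nodes, 27 edges)
```

`enrichment_up.tsv` lists each mode's contingency counts (k, n, K, N) with
raw and adjusted p — on this small background the dehydrogenase-route mode
has the smallest p but does not clear 0.05, which the output reports
honestly. The five τ = 0.8 backbone reactions are the shared
glucose-uptake/glycolysis trunk plus the maintenance reaction, each
carrying a 100% occurrence label. The GraphML file carries node types,
compartments, subsystems, per-edge fluxes and per-gene log2 fold changes —
the attributes a Cytoscape style binds to (attribute names are listed in
`fluxmodes/graph_export.py`).

The same steps are available as library calls (`parse_efm_file`,
`compute_yields`, `map_gene_stats_to_reactions`, `enrich_efms`,
`extract_submodel`, `build_graph`, ...); the CLI is a thin wrapper.

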