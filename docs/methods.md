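# Methods

## Problem setting

AP-MS pulldowns of two H3K9me2 writers (EHMT1, EHMT2) and two readers (CBX3,
CBX5) at two cell-cycle synchronization points (G1/S, G2/M) yield total
peptide counts per protein per sample, with one IgG mock pulldown per phase
as the non-specific background. The package turns such count tables into
phase-resolved interactomes and downstream candidate screens. All analysis
operates on counts already summed per protein per sample; peptide-to-protein
inference, FDR modeling of spectra, and search-engine scoring are upstream of
the inputs and out of scope.

## Hit classification

Filters run in a fixed order — low enrichment, then fold change, then
contaminant — and the first failure is the recorded reason, so reason tallies
partition each pulldown and are reproducible.

| parameter | default | meaning |
|---|---|---|
| `min_peptides` | 4 | strict floor: a bait count of exactly 4 passes ("fewer than four" fails) |
| `log2fc_threshold` | 1.0 | minimum log2(bait/IgG); *reaching* the threshold passes |
| `pseudocount` | 1.0 | added to both counts so zero IgG counts stay finite |
| `contaminant_families` | ACT, KRT, TUB, HIST | case-insensitive identifier prefixes |

The fold-change cutoff used in the original wet-lab protocol was never
published; 2-fold is this package's default and should be reported with any
result. Contaminant matching is by family prefix because contaminant
catalogs name families (actins, keratins, tubulins, histones), not
accessions; `ACT` also catches actin-like `ACTL*` symbols, which is the
intended behavior for a conservative contaminant screen.

`qc_enrichment_ratio` reports the summed bait/IgG count ratio before and
after filtering. A per-bait-protein-only reading of the post-filtration
enrichment check would also be defensible; the summed reading is implemented
because it is computable for every bait without knowing which row is the
bait itself.

## Set algebra

Interactome sets are keyed by (bait, phase). Decisions with more than one
defensible reading:

- *shared by ≥ k regulators* counts distinct baits, never phases: a protein
  seen with one bait in both phases counts once.
- *phase switchers* use strict disjointness — the protein is present in both
  phases and its G1/S bait-membership set shares no bait with its G2/M set.
  A looser reading ("gained at least one new partner") would be a superset;
  the strict reading is the most literal interpretation of switching
  regulators.
- Percentages are rounded (one decimal by default) only at the reporting
  layer; internal fractions are exact ratios of set sizes.

## Nuclear and expression validation

Both steps are intersections, hence order-insensitive, idempotent partitions.
Proteins missing from the annotation table are treated as non-nuclear
(inclusion requires positive `GO:0005634` annotation; `keep_unknown=True`
relaxes this), and proteins missing from the expression table are treated as
not expressed and removed. Expression is consumed as boolean presence per
phase; deriving presence calls from raw microarray intensities is out of
scope — the flag table is the contract.

## Network statistics

Graphs are simple and undirected; duplicate edges collapse under canonical
(min, max) ordering and self-loops are dropped. The confidence filter keeps
edges with score strictly greater than `min_confidence` (default 0.7).
Unscored edges are dropped unless `min_confidence == 0`, or always kept with
`unscored="keep"` for reference sets that publish no scores — declare which
class an input belongs to.

Hub coverage ranks one partition's nodes by number of edges crossing to the
other partition, ties broken lexicographically by node id (the original
analysis does not state its hub-selection rule; greedy-by-degree with a
deterministic tie-break makes runs reproducible). Each crossing edge counts
once toward coverage. A graph with no crossing edges has coverage 0 by
convention. Bait-pair edge attribution counts edges with at least one
endpoint in the pair's shared interactome (`mode="any"`, default) or both
endpoints (`mode="both"`).

## Histone-mimicry SLiM screen

The motif is an ordered list of per-position residue classes with the target
lysine fixed (`k_index=3` in both presets). Two published motif versions ship
as presets without reconciliation, since both are in circulation:
`results_final` = `[ACEGKLNS][R][K][AEGKLMNQRSTV]` (the default) and
`methods_scansite` = `[ACGKLNS][R][K][AEGKLMNQRSTV]`. Both accept the
canonical histone ARKS context. Coordinates are 1-based and the reported
anchor is the K position, aligning with site nomenclature such as HDAC1 K432.
All overlapping matches are reported; candidacy needs at least one.
Non-standard letters (X, U, B, Z) never satisfy a class.

Tier 1 uses the **union** of the two writers' nuclear interactomes: the
phrase "interacted with EHMT1 and EHMT2" is ambiguous between union and
intersection, and the union is consistent with comparing against "the
nuclear interactome of EHMT1 and EHMT2" as one dataset;
`writer_mode="intersection"` is available. Tier 2 intersects tier 1 with the
union of the reader interactomes (readers are taken from the cellular,
unvalidated sets in the default pipeline, since reading only requires the
interaction to have been captured). Evidence flags require an exact position
match between a known methyl-lysine site and the predicted K.

## Complex over-representation

`P(X ≥ k)` for `X ~ Hypergeometric(N, K, n)` via `scipy.stats.hypergeom.sf`,
validated in tests against exhaustive subset enumeration and closed-form
combinatorics for universes up to 12. Complex memberships are restricted to
the universe before the ≥ 4-member floor is applied. The significance column
uses the raw p ≤ 0.05 rule by default (matching how complex-level results
are usually quoted), with BH-adjusted values always reported alongside. The
universe defaults to catalog members ∪ query because the original analysis
never states its universe; pass an explicit universe for anything
publication-grade. Because the test statistic is discrete, the attainable
type-I level at α = 0.05 is slightly below 0.05; the calibration test
computes the exact attainable level from the null distribution and checks
the Monte-Carlo rejection fraction against it.

## Synthetic-study generator

What the generator emulates, per artifact:

- **Counts**: true interactors draw bait counts from a negative binomial
  with mean 40 and dispersion 10 (variance = mean + mean²/dispersion) over an
  IgG background with mean 2 — a 20-fold separation, comfortably beyond the
  8-fold regime where the three filters recover the planted sets exactly.
  Designated noise proteins and pulldown background draw Poisson counts
  truncated at 3, i.e. strictly below the four-peptide floor: sub-threshold
  noise is the generator's *definition* of noise, not an emergent property.
  Contaminant-family proteins are comparably abundant in bait and IgG
  pulldowns. Pulldowns are otherwise sparse (zero counts), as AP-MS count
  matrices are.
- **Interactor structure**: each bait has 30 true interactors per phase;
  25% are maintained across phases; 45% of each bait's interactors are
  drawn from a pool where each protein is explicitly assigned to a pair of
  baits, which yields ~28–30% of the union shared by ≥ 2 regulators — the
  regime observed in the real study (30.39%). Per-bait maintained fractions
  land near 15%, inside the observed 5.5–23.2% range.
- **Proteome**: 40% of proteins carry one planted motif occurrence
  (roughly the fraction of the human proteome matching the final SLiM,
  8230 of ~20k). In exact-planting mode (default) flanking sequence is
  rejection-sampled so the planted registry equals the scanner's output — a
  clean oracle; permissive mode skips rejection for speed and only
  guarantees registry ⊆ hits.
- **Annotations**: 58% nuclear, 4% expression-absent per phase, per-protein
  Bernoulli draws (so realized fractions fluctuate binomially).
- **Reference network**: pair-independent edges at density 0.02 among
  nuclear pairs and 0.002 elsewhere, uniform scores in [0, 1]. At n = 500
  this reproduces the qualitative nuclear ≫ non-nuclear degree separation;
  absolute mean degrees depend on node count and score filtering and are not
  calibrated to any published figure.
- **Complexes**: 25 complexes with 4–10 members; two draw all members from a
  designated query set (anticipated tier-2 candidates) as positive controls
  for over-representation.

What it does **not** emulate: spectra, peptides, retention times,
search-engine scoring, correlated contaminant abundances, protein-family
homology (accidental motif sharing between paralogs), degree-heterogeneous
(scale-free) network topology, or annotation incompleteness bias. Passing
parameter-recovery tests therefore demonstrates correctness of the
filtering/screening logic under the stated noise model, not robustness to
real-data pathologies such as mis-identified peptides or batch effects.

Determinism: every generator derives an independent child RNG stream from
`SimulationConfig.seed`, so identical configs give identical artifacts and
artifacts do not perturb one another.

## Numerical and degenerate-input conventions

- `log2_enrichment(0, 0, c) = 0` by symmetry of the pseudocount.
- Empty count tables yield empty hit tables; an absent IgG sample for a
  phase with bait samples is a configuration error naming the filter stage.
- `mean_degree` of an empty graph is an error, not NaN.
- Venn partitions never contain an empty-signature region; 1–8 sets are
  supported.
- `phase_overlap` fractions of an empty union are (0, 0, 0).
- BH adjustment requires p ∈ (0, 1]; p = 0 is rejected as an input error.

## Problem sizes

Default test and acceptance runs use 400-protein universes, 30 interactors
per bait-phase, 500-node reference networks, 1000-sequence scanner-oracle
sweeps, 500-collection set-algebra sweeps, and 2000–2500 null-calibration
replicates — sizes chosen so the full suite completes in seconds while
keeping binomial/Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The published end-to-end hit lists cannot be regenerated from raw counts
  without the unpublished fold-change cutoff; published-scale checks
  therefore recompute the set arithmetic from the published cardinalities
  rather than re-deriving the membership lists.
- The enrichment universe and multiple-testing handling of the original
  analysis are unstated; defaults here may rank borderline complexes
  differently.
- The mimicry screen treats motif presence as binary; no positional weight
  or accessibility scoring is applied.
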