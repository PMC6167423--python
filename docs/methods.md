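# Methods

This note documents the models and procedures `fingernet` implements, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Study design model

A study is a set of samples assigned to treatment groups: one vehicle
control plus dose groups per compound (`StudyDesign`). The packaged default
(`default_design`) mirrors a low-dose exposure study on hepatic cells: a
DMSO control of 17 samples and three dose groups of 12 samples per
compound (BPA at 10⁻⁶/10⁻⁹/10⁻¹² M; 17β-estradiol at 10⁻⁹/10⁻¹²/10⁻¹⁵ M
labels). Group structure enters the statistics only through the dummy
response matrix **Y** (one column per group, column-centered). Note that a
centered g-column dummy matrix always has rank g−1 — its columns sum to
zero — so all projections onto its column space use least squares; "rank
deficiency" errors refer to designs with fewer than two non-empty groups.

## Synthetic spectra

Raw spectra for studies of this kind are rarely deposited, so the generator
is first-class, tested code. Each sample row is

    f · (B + signal + s·vᵀ + ε),    ε ~ N(0, σ²) i.i.d. per bin

- `B = 20σ` is a flat baseline keeping intensities positive (negative
  values, possible only in an extreme tail, are clipped to zero with a
  warning);
- `signal` shifts designated bins by `effect × σ` per group, where each
  `SignatureSpec` places a metabolite's multi-bin signature at fixed
  chemical shifts with signed per-group effects (control effect is always
  zero);
- `s·vᵀ` is a rank-one structured confounder: a fixed random unit loading
  `v` over bins and per-sample scores `s ~ N(0, confounder_sd²)` drawn
  independently of the treatment labels — exactly the kind of variation
  orthogonal signal correction is designed to remove;
- `f ~ lognormal(0, 0.05)` is a per-sample size factor (dilution/cell-count
  variation), the reason total-area normalization exists. It is exposed as
  `size_factor_sd` so calibration tests can isolate the noise component.
- all random variates are drawn unconditionally and scaled afterwards, so
  two runs differing only in `confounder_sd` or `size_factor_sd` share the
  same noise stream — used by tests to measure planted variance shares by
  differencing.

An alternative `intensity_scale="lognormal"` mode builds the same structure
on the log scale and exponentiates (strictly multiplicative intensities).
The additive mode is the default because the generator's contract is stated
on the intensity scale: a planted effect of `e·σ` must appear as a mean
shift of `e·σ` in the returned matrix, which exponentiation would distort.

Default study conditions (chosen once, a priori): 200 bins over 0.5–4.5
ppm, `noise_sd = 1`, `confounder_sd = 2` (a visible but not dominating
structured component), top-dose effect 3σ for the strong-signal demos.

**Dose profiles.** With one identical effect in every exposed group, the
group means of **X** collapse to two points (control vs. exposed), and the
attainable R²Y for the 17+12+12+12 design has a closed-form cap of ≈ 0.39 —
below the usual 50 % robustness threshold no matter how strong the signal.
Real discriminance tables show the opposite: some metabolites respond at
every dose, some grade with dose, some only at the top dose. The demo
generator therefore defaults to a `mixed` profile (one third of signal bins
in each of those three categories), which spans the between-group space and
makes dose groups mutually separable; a `uniform` profile is available.
`signatures_from_shift_table` goes further and plants signatures exactly at
the packaged tables' chemical shifts with the tables' per-dose flags as the
effect pattern.

Toy metabolic networks (`generate_toy_network`) are connected bipartite
graphs with optional hub metabolites and optional compartment replication
(transport reactions linking replicas); `demo_metabolic_network` is a
hand-curated ~45-reaction core-metabolism network (TCA cycle, urea cycle,
transaminations, branched-chain amino-acid degradation, choline branch,
lumped where a pathway adds nothing topologically) whose BiGG-style ids
line up with the packaged metabolite name mapping. It is synthetic and is
not a substitute for a genome-scale reconstruction; `read_sbml` accepts one
when available.

## Preprocessing

Binning sums trace intensities into half-open `[left, right)` buckets of
0.01 ppm by default, dropping bins that intersect exclusion windows
(residual water 4.5–5.0 ppm and the chemical-shift reference ±0.05 ppm by
default — community conventions; binning conserves total signal outside
exclusions exactly). Normalization divides each spectrum by its total area.
Scaling mean-centers and/or Pareto-scales columns (divide by √SD, ddof=1;
zero-SD columns are left unscaled and flagged). The scaling state machine
is one-way (`raw → normalized → scaled`), so double normalization or
double scaling is a hard error rather than a silent distortion.

## Chemometrics

**PCA screening.** SVD scores with Hotelling T² over the retained k
components; a sample is flagged when T² exceeds `k(n−1)/(n−k)·F₁₋α(k,n−k)`.
Flagged samples are reported, not removed, unless the pipeline is
configured to exclude them.

**OSC.** Per removed component: seed the score with the first PC score,
orthogonalize against **Y**, solve the least-squares weight `min‖Xw − t‖`
(unit-norm `w`), recompute `t = Xw`, iterate to a relative score change
below `tol` (default 1e-10, max 1000 iterations — non-convergence is an
error carrying the last relative change); a final orthogonalization
enforces |corr(t, y)| at machine precision before deflation `X ← X − t pᵀ`.
The removed variance fraction is ‖t pᵀ‖²/‖X‖². One OSC component is the
default — the conservative choice when the number actually used upstream
is unknown.

**PLS-DA.** Two-block NIPALS (PLS2) on centered **X** and the centered
dummy **Y**; supports any number of groups. Invariants maintained and
tested: unit-norm weight columns, pairwise-orthogonal scores, non-negative
per-component explained Y sum-of-squares, non-decreasing cumulative R²Y.
Component signs are fixed deterministically (largest-magnitude weight entry
positive).

**Cross-validation.** Stratified k-fold (7 by default; fold assignment via
scikit-learn with a fixed seed — determinism is required for byte-identical
reruns). Per fold, training means re-center both blocks; Q²(a) = 1 −
PRESS(a)/SS with PRESS accumulated over held-out dummy predictions using
the first *a* components. The component count is chosen by "add while
cumulative Q² increases", hard-capped (default 10). This literal rule tends
to keep more components than the classical "stop when the gain is
negligible" convention, driving training R²Y high while Q² remains honest;
the cap and an explicit `n_components` override are the escape hatches.

**Permutation test.** Group labels are permuted uniformly; R²Y and Q² are
recomputed with the same component count and folds. The empirical p-value
`(1 + #{Q²ₚₑᵣₘ ≥ Q²}) / (n_perm + 1)` has attainable minimum 1/(n_perm+1);
200 permutations by default. The Simca-style intercept criterion is
deliberately not implemented — the empirical p is well defined without it.

**Univariate screen.** Kruskal–Wallis across the comparison's groups
(scipy, average ranks, tie correction); the all-identical-values edge case
returns H=0, p=1 instead of raising. No multiple-testing correction by
default, matching the raw α = 0.05 convention of this analysis style; a
Benjamini–Hochberg option exists (`fdr_correction=True`).

**Selection rule.** A bin is discriminant iff VIP > 1.5 **and** p < 0.05.
Both statistics are recorded per selected bin. Per-dose fingerprints reuse
the joint model's VIP with a dose-vs-control Kruskal–Wallis — one
defensible reading of how joint multivariate importance and per-dose flags
combine; per-dose PLS-DA models are possible with a two-group comparison
config instead.

A known statistical property of this conjunction rule (measured by the
acceptance suite's parameter-recovery study): the VIP of a null bin and its
Kruskal–Wallis statistic are strongly dependent — both grow with the bin's
chance between-group separation — so the VIP gate removes only about half
of the α-level false positives. With 190 null bins at α = 0.05, a few false
positives per run are expected whenever the planted effect is moderate
(≈1.5σ); driving the expected false-positive count below ~1 requires either
effects near 3σ, the FDR option, or a smaller bin count. Recovery of truly
planted bins is essentially unaffected (≥ 8/10 recovered in all seeded runs
at 1.5σ).

## Fingerprint annotation and aggregation

Selected bins are annotated to the metabolite owning the nearest tabulated
¹H shift within `tol_ppm` (default 0.02 ppm = two default bins); distances
equal up to float jitter tie-break alphabetically, and bins with no shift
in range are kept as `unassigned`. The packaged tables transcribe a
published HepG2 BPA/estradiol study's discriminant-metabolite tables
(metabolite, shifts with multiplicities, per-dose flags); aggregation
produces the metabolite × comparison flag matrix and its unique-metabolite
count. Effect directions (increase vs. decrease) are not part of those
tables, so the generator assigns directions at random and nothing
downstream asserts a direction.

## Network analysis

SBML models are read via libsbml (parse errors are atomic failures;
species must carry a compartment). Compartment collapse maps each species
to its base id (stripping the `_c`-style or `[c]`-style designation of its
own compartment tag; configurable regex), then (a) removes reactions whose
substrate and product multisets coincide (pure transport), and (b)
deduplicates reactions with identical substrate/product multisets and
reversibility — reversible duplicates also match with sides swapped —
keeping the lexicographically smallest id. The operation is idempotent and
returns the old→new id map plus removal/dedup logs.

The compound graph is bipartite and undirected (reaction reversibility is
ignored for path-finding; substrate–product adjacency is what matters for
connecting a fingerprint — a directed mode would halve reachability under
irreversible annotations of uncertain quality). Side compounds (packaged
editable list: water, protons, ATP/ADP/AMP, NAD(P)(H), CO₂, phosphate,
diphosphate, O₂, CoA) are removed before any degree is computed; reactions
keep remaining edges but are dropped when they lose all substrates or all
products. Metabolite node weights: squared degree (default), degree, or
unit; reaction nodes weigh 1. Squared degree is the established
hub-avoidance criterion for metabolite-connecting paths and is
configurable because the exact topological weight used by any given
upstream tool may differ.

Lightest paths are computed by Dijkstra over `(cost, node-sequence)` keys:
an edge traversal adds the entered node's weight and the source weight
counts once, so the accumulated cost equals the node-weight sum; the
secondary key makes tie-breaking exactly lexicographic and the search
deterministic. An exhaustive simple-path enumeration oracle (networkx)
verifies equivalence on small random graphs. A sub-network is the union of
lightest paths over all unordered seed pairs, with per-pair provenance and
unreachable pairs recorded. Set algebra (`intersect`/`difference`/`union`)
applies the operation independently to metabolite, reaction and seed sets
— the paper-style "common machinery" and "compound-specific machinery"
constructions — and refuses to combine sub-networks from different parent
graphs (content-hash check).

Fingerprint names map to network ids by case-insensitive exact match on a
curated synonym table (packaged for the shipped shift tables; isopropanol
is intentionally absent — it has no counterpart in the human
reconstruction). Unmapped names are reported, never dropped silently. When
a seed metabolite also appears on the side-compound list (AMP is the
canonical example), the seed wins: it is removed from the side list for
that run and the collision is logged.

## Pipeline

One YAML config drives everything; every stage seed derives from the
master seed by stable hashing, so identical config + seed reproduces
byte-identical numerical outputs (wall-clock time is logged, never written
into results). Validation collects *all* config errors before any
computation; a stage failure aborts the run with the stage name and removes
the files written so far. Outputs per comparison: model JSON (A, R²Y, Q²,
permutation p, flagged outliers, fingerprints), scores TSV, score plot,
fingerprint TSVs; study-level: design/spectra TSVs, aggregated fingerprint
table, SIF/GraphML sub-networks, common/specific pair sub-networks, and
`report.json`.

## Problem sizes used by the shipped checks

The acceptance script and tests run at desk scale, chosen to exercise every
code path at full statistical fidelity: 53–89 samples × 200 bins, 7-fold
CV, 200 permutations, 50-run recovery studies, 100 random graphs of ≤ 12
nodes for the path oracle, and the curated ~45-reaction demo network for
end-to-end runs. A genome-scale SBML model drops in via the `network.sbml`
config key without code changes.

## Known limitations

- No peak alignment, baseline correction or phasing — inputs are assumed
  to be well-calibrated binned intensities; no Lorentzian peak shapes or
  J-coupling structure in the generator.
- Chemical-shift annotation is nearest-neighbour within a tolerance;
  overlapping signatures in crowded regions (3.5–4.0 ppm) can be assigned
  to a neighbouring metabolite.
- The component-selection rule is greedy on cumulative Q² and can overfit
  training R²Y (see above).
- Sub-network extraction is purely topological: no stoichiometric balance,
  flux feasibility or atom mapping; results depend on the side-compound
  list and the weight scheme.
- Numerical reproduction of any specific commercial chemometrics package
  (e.g. Simca) is out of scope; algorithms follow the published NIPALS/OSC
  formulations.
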