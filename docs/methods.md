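# Methods

This note documents the models and procedures implemented in `mrprep`, the
parameters that matter, the synthetic data the package validates itself
against, and the numerical choices behind the code.

## Confidence metrics and their detection

Predicted-model files carry one confidence value per residue in the atom
B-factor column. Four conventions are supported (`ConfidenceKind`):

| kind | meaning | range | higher is |
|---|---|---|---|
| `plddt100` | predicted local distance difference test | 0–100 | better |
| `plddt1` | pLDDT as a fraction | 0–1 | better |
| `rmsd_angstrom` | estimated r.m.s.d. from the true structure, Å | ≥ 0 | worse |
| `bfactor_already` | crystallographic B, Å² | ≥ 0 | — |

The representative value per residue is taken from the Cα atom (first atom
as fallback); predictors write a single value per residue, so per-atom
variation is ignored.

Automatic detection is a heuristic over the value distribution: everything
in [0, 1] is a pLDDT fraction; values in [0, 100] with at least 5% above 20
are 0–100 pLDDT; values confined to [0, 20] are r.m.s.d. estimates; anything
else is treated as already-converted B. The 5% guard exists because an
all-low-confidence pLDDT profile is indistinguishable from an r.m.s.d.
profile on range alone; a caller who knows the producer should declare the
kind (CLI `--kind`) rather than rely on detection. Any negative value is an
error.

## Confidence → B-factor conversion

With pLDDT as a fraction *p*, the conversion is

    rmsd(p) = min(rmsd_cap, lddt_scale · exp(lddt_slope · (lddt_midpoint − p)))
    B(rmsd) = (8π²/3) · rmsd²

Parameters (`ConversionParams`), all exposed and positive:

* `lddt_midpoint` = 0.7 — the pLDDT fraction at which rmsd equals
  `lddt_scale`; chosen to coincide with the conventional pLDDT-70 confidence
  boundary, so a residue at the pruning threshold has rmsd exactly 1.5 Å and
  B ≈ 59.22 Å².
* `lddt_scale` = 1.5 Å — error scale at the midpoint.
* `lddt_slope` = 4.0 — steepness of the exponential.
* `rmsd_cap` = 20 Å — ceiling preventing absurd B factors (B would otherwise
  exceed 16 000 Å² at pLDDT 0); must be ≥ `lddt_scale`.

The quadratic B form is the standard isotropic displacement relation; it is
strictly increasing, so the composite map sends higher confidence to lower B
everywhere the cap is not active. `bfactor_to_rmsd` inverts it exactly
(round trip tested to 1e-9 relative). r.m.s.d.-valued profiles skip the
exponential and go straight through the quadratic form, uncapped: the
producer's own error estimate is taken at face value. A `bfactor_already`
profile passes through unchanged.

Conversion and pruning are independent library calls and the caller chooses
the order; the CLI converts first and then prunes, which makes the pruning
decision depend only on the original confidence values, never on the
converted column.

## Pruning and segment cleanup

`prune_low_confidence` keeps exactly the residues with pLDDT ≥ threshold
(default 70, on the 0–100 scale; rescaled internally for fraction-valued
profiles). The comparison is inclusive — a residue at exactly 70 is kept.
The operation is order-preserving and idempotent. r.m.s.d. profiles require
an explicit Å threshold (residues with larger estimated error are removed);
there is no defensible default because the scale depends on the producer.

Pruning leaves isolated fragments behind. `remove_short_segments` groups
residues into contiguous segments — same chain, consecutive author
numbering, successive Cα–Cα distance ≤ `break_distance` (default 4.5 Å,
chosen to exceed the 3.8 Å virtual Cα–Cα bond with margin for distorted
geometry) — and drops segments shorter than `min_len` (default 3). An empty
result is permitted; re-segmenting the output is a fixed point.

`trim_to_target` keeps the union of inclusive (chain, start, end) residue
ranges; `alignment_ranges` produces such ranges by global pairwise alignment
of the model sequence against a target sequence (BLOSUM62, gap open −11 /
extend −1). The alignment scoring scheme is configuration, not contract.

## Domain slicing

### Coordinate clustering

Cα coordinates are clustered into `n_clusters` groups. The default linkage
is Ward agglomerative clustering because it is fully deterministic —
repeated runs are bit-identical — and behaves well on compact, blob-like
domains; seeded k-means is available as an alternative. The cluster count is
user input; the default sweep prepares the 1-, 2- and 3-cluster splits, and
no automatic selection of the cluster number is attempted. Residues lacking
a Cα atom inherit the cluster of the nearest preceding Cα-bearing residue.

### PAE partitioning

The predicted-aligned-error matrix (entry (i, j) = expected positional error
of residue i when aligned on residue j, Å) is parsed into a residue graph:

1. symmetrize: s = (PAE + PAEᵀ)/2 (PAE files are asymmetric; the mean is a
   conservative rigidity estimate);
2. connect i–j when s ≤ `edge_cutoff` (default 10 Å) with weight
   (1/max(s, `pae_floor`))^`pae_power` (defaults: floor 0.25 Å so a zero
   error cannot produce an infinite weight, power 1);
3. partition each connected component independently with greedy modularity
   maximization at `resolution` (default 1.0), nodes in residue order.

Every constant is a parameter of `PAESplitParams`. Greedy modularity is
deterministic on a fixed graph; components whose inter-block error exceeds
the cutoff are separated unconditionally, which is what makes recovery on
clean block matrices exact. A known behaviour of modularity maximization is
that large near-uniform blocks can be oversplit into two or three
sub-communities when edge weights carry noise; the min-domain merge (below)
absorbs small splinters but not balanced oversplits. Raising `edge_cutoff`
or lowering `resolution` coarsens the partition when that matters.

### Minimum domain size

Domains below `min_domain` residues (default 20 — smaller fragments carry
too little scattering matter to be useful search models) are merged,
smallest first, into the domain with the nearest Cα centroid (ties → lower
domain id), repeating until stable or only one domain remains. When a PAE
partition is computed without an accompanying model there are no
coordinates, and undersized groups are instead merged into the group with
the smallest mean symmetrized PAE to them — the same idea with the PAE as
the distance.

Partitions are always validated: domains disjoint, non-empty, exhaustive
over non-removed residues, ids numbered by ascending first residue index.
Domains may be discontiguous in sequence. `extract_search_models` carries
atoms and B values over unchanged, so |input| = |removed| + Σ|domains|
holds for every slice.

## Scoring

`average_plddt` is the arithmetic mean on the 0–100 scale, banded at the
conventional colour-scale cutoffs: < 50 very_low, [50, 70) low, [70, 90)
confident, ≥ 90 very_high. The ≥ 70 boundary (inclusive) marks a
high-confidence prediction.

`coverage_weighted_score` = Σᵢ pLDDTᵢ / target_length = mean pLDDT ×
coverage. It is monotone in both confidence and coverage and equals the
mean at full coverage. It follows the idea of coverage-weighted ranking
scores used for search-model selection (the "H-score" family) but is this
package's own definition; no numerical equality with any published score is
claimed, and no per-residue capping or alternative rescaling is applied.

## Synthetic fixtures

`generate_model` builds a Cα-only single chain: each domain is a
self-avoiding random walk with exact 3.8 Å steps confined to a sphere of
radius 3·size^(1/3) Å, recentred on a line of centroids `separation` apart
(default 50 Å) and oriented first-to-last residue along that line; linkers
are extended equal-step walks solved to land exactly on the next domain's
first residue (the final two steps are placed on the sphere-intersection
circle). A linker that cannot span the gap at the given step length raises
"infeasible linker" — with 50 Å separation and ~12 Å domain radii roughly
14+ linker residues are needed; the generator default is 20.

Per-residue pLDDT is drawn from Gaussians (domains 90 ± 3, linkers 45 ± 5,
clamped to [0, 100]) and written to the B column. `generate_pae` draws entry
(i, j) from the intra distribution (2 ± 0.5 Å) when the planted labels match
and the inter distribution (25 ± 3 Å) otherwise, with independent draws for
(i, j) and (j, i) — deliberately asymmetric to exercise symmetrization — and
a zero diagonal. Each linker carries its own label, so only within-linker
pairs count as intra. All draws come from one seed sequence per spec in a
fixed order (coordinates, then pLDDT, then PAE); identical specs give
bit-identical fixtures within this implementation, and statistical (not
bit-level) reproducibility is what is promised across implementations.

What the fixtures do **not** emulate: secondary structure, side chains,
realistic packing, correlated predictor errors, gradual confidence decay at
domain edges, or multimer PAE layouts. Passing the planted-recovery tests
therefore demonstrates that the geometry and graph machinery is correct
under idealized conditions — compact well-separated domains, clean block
PAE — not that the tool resolves borderline architectures on real
predictions.

Recovery is scored with the adjusted Rand index over residues that carry a
planted domain label; linker residues have no planted domain (any spatial
partition must still assign them somewhere, typically to the nearest
domain) and are excluded from the comparison. Validation problem sizes:
two-domain (60+60, 25-residue linker) and three-domain (3×50/60, 25-residue
linkers) fixtures at 60 Å centroid separation — at least five times the
~11–12 Å domain radius, the regime in which recovery is expected to be
essentially perfect — with 50 seeds in the recovery sweep, and 90–145
residue matrices for the PAE route.

## I/O conventions

PDB and mmCIF parsing/writing are delegated to gemmi. Readers keep polymer
atoms only (no HETATM, no waters), altloc blank/'A' only, first model only;
residue identity is (chain id, author seq id, insertion code), and parsing
never reorders residues; duplicate or non-increasing residue identities are
errors. PDB fixed columns limit round-trip fidelity to 1e-3 Å on
coordinates and 1e-2 on B values (%8.3f / %6.2f); coordinates outside the
fixed-width columns are an error directing the caller to mmCIF. PAE JSON is
accepted in the three dialects in circulation — flat
residue1/residue2/distance pair lists (1-based, full L² coverage required),
nested `predicted_aligned_error` lists, and a bare `pae` key — and a
serializer emits all three, which the tests use to prove dialect
equivalence. PAE row/column i maps to the i-th residue of the model in file
order; a size mismatch with the model is an error, never a silent
truncation. AlphaFold-database URLs are constructed offline from the
documented `AF-<accession>-F1-model_v<n>` naming convention (default
version 4); no network access is performed anywhere.

## Known limitations

* Cluster count is user-chosen; there is no automatic model selection.
* Modularity-based PAE parsing can oversplit large uniform rigid blocks
  under weight noise (see above).
* Multimer PAE layouts (chain interleaving across producers) are not
  handled; multi-chain models are supported for coordinates only.
* The confidence-kind heuristic cannot distinguish an all-low pLDDT profile
  from an r.m.s.d. profile; declare the kind when the producer is known.
* NMR-style multi-model files contribute only their first model.
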