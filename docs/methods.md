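# Methods

## Overview

`netscreen` clusters one compound panel three times — on structural
similarity, on docking-score profiles, and on PPI-degree-weighted
network-effect profiles — and treats *disagreement* between the three trees
as the scientific signal.  This note records the models, the defaults and the
design choices made where the design was genuinely open.

## Structural similarity

**Overlap coefficient.**  For molecules *a*, *b* with heavy-atom counts
*c₁*, *c₂* and a maximum common connected substructure of *n* heavy atoms,
similarity is *n*/min(*c₁*, *c₂*).  Hydrogens are excluded throughout
(standard cheminformatics convention).  The coefficient is 1.0 whenever the
smaller molecule is contained in the larger, so it is sensitive to local
fragment sharing between molecules of very different sizes — and
correspondingly promiscuous between small molecules: profiles (matrix
columns), not raw coefficients, are what get clustered.

**MCS search.**  The search is delegated to RDKit's `rdFMCS`.  Matching
rules are exposed on `McsParams`:

* `atom_compare`: `elements` (default) or `any`;
* `bond_compare`: `exact` (default; aromatic only matches aromatic),
  `order` (aromatic additionally matches the corresponding Kekulé order),
  or `any`;
* `ring_matches_ring` (default off) and `timeout_s` (default 10 s per pair).

The strict defaults make the search exactly reproducible by an exhaustive
common-connected-subgraph enumerator, which the test suite exploits.
Mismatch-tolerant "flexible" MCS variants are emulated by relaxing the
comparison levels rather than by an integer mismatch budget (the backend
does not support counting mismatches); only connected common substructures
are produced — a disconnected-MCS mode is not implemented.  On timeout the
best-so-far substructure is used and flagged on the result, never silently.
Molecule pairs sharing no atom type get coefficient 0.0 (logged) rather than
an error.  A single shared atom type with no shared bond counts as a 1-atom
common substructure (the backend reports such matches as empty).

**Fingerprint alternative.**  `morgan_tanimoto` computes Tanimoto similarity
of hashed Morgan fingerprints (radius 2, 2048 bits by default) — the
standard ECFP4-style comparison — for cross-checking the MCS picture.

## Docking scores and rank normalisation

Scores are validated to the 0–10 pKd/pKi scale; empty/`NA`/`NaN` cells are
missing values.  Each compound row is replaced by descending ranks over its
non-missing proteins with average-rank ties (`scipy.stats.rankdata` on the
negated row), so each row's ranks sum to *p*(*p* + 1)/2 and are invariant
under strictly increasing per-compound score transforms.  Scores are not
rescaled before ranking: the ranking *is* the normalisation.  Rows with
fewer than two scored proteins cannot be ranked and raise.  Matrices may be
supplied in either orientation (`transpose` flag); canonical storage is
compounds × proteins.

## PPI network and network effect

Edge lists are parsed into an undirected simple graph; STRING exports carry
combined scores on the 0–1000 integer scale and are divided by 1000 on read,
so the default `min_confidence = 0.7` corresponds to STRING's
"high confidence" 700.  Self-loops are dropped (node retained), duplicates
collapsed, sub-threshold edges removed; the node set is the endpoints of
surviving edges plus any node-list file entries.  Degree is the count of
incident edges; betweenness centrality is computed for reporting only and
never enters any score.

The network-effect matrix is the elementwise product
effect(*c*, *p*) = rank(*c*, *p*) × degree(*p*).  Proteins absent from the
degree table follow a policy (default `zero`: no PPI evidence ⇒ no network
leverage; alternatives `drop` and `error`), always with a logged report.
Degree-0 columns are identically zero — they carry no information but keep
the matrix aligned with the rank matrix.

## Clustering with multiscale-bootstrap AU support

Items (compounds) are compared by *d*(*i*, *j*) = 1 − Pearson correlation of
their feature profiles; flat (zero-variance) profiles are an error naming
the item.  Agglomerative clustering uses `scipy.cluster.hierarchy.linkage`
(average linkage by default — the convention of the R multiscale-bootstrap
clustering tools; complete, single and Ward are available).  Scipy's
nearest-neighbour-chain algorithm is deterministic for fixed input, which is
the property the pipeline needs; its tie-breaking is reproducible but not
the lexicographic lowest-pair rule, a deliberate trade for using the
standard, well-tested implementation.

**Bootstrap.**  For each scale *r* ∈ {0.5, …, 1.4} (step 0.1),
*B* replicates (default 1000; tests and the acceptance script use 100 for
speed) resample round(*r* · *n_features*) feature columns with replacement,
recluster, and count for each observed internal cluster whether its exact
leaf set reappears: BP*ᵣ* = hits/*B*.  Resampling is over feature columns
with items fixed — the column-bootstrap semantics of the R tooling.  The
choice of what the "features" are per axis: the similarity-matrix columns
(structure), the raw score profiles (docking), and the network-effect
profiles (network); this orientation is echoed in the run report.  In a
replicate, a resampled column set can leave an item with zero variance;
such rows are treated as uncorrelated (correlation 0) rather than aborting
the replicate.

**AU fit.**  Per cluster, BP values are clipped to [1/(2*B*), 1 − 1/(2*B*)]
and probit-transformed, then fitted by weighted least squares as

    Φ⁻¹(1 − BPᵣ) = v·√r + c/√r,

with weights from the delta-method binomial variance
BP(1 − BP)/(B·φ(z)²) — boundary scales get near-zero weight.  Then
AU = 1 − Φ(v − c) and smoothed BP = 1 − Φ(v + c); standard errors come from
the weighted normal equations.  Anchors: BP ≡ 0.5 at every scale gives
v = c = 0 and AU = 0.5 exactly; a cluster whose BP rises toward 1 with *r*
has v < 0 and AU → 1.  Degenerate cases: if every BP*ᵣ* is exactly 0 or 1
no fit is attempted and AU is the boundary value at the scale nearest 1,
flagged as degenerate; with a single scale the machinery reduces to the
classical bootstrap (AU = BP = BP₁, flagged).  The root cluster reappears in
every replicate and therefore carries support 1.  No claim of numeric parity
with the R implementation is made (RNG streams differ); parity is
algorithmic.

**Reproducibility.**  One root seed spawns per-scale and per-replicate
`numpy` SeedSequence streams, so results are bit-identical for a fixed seed
and independent of any execution-order considerations.

**Tree comparison.**  Two trees over the same leaves are compared at flat
*k*-cuts (`fcluster`, maxclust criterion) by adjusted Rand and
Fowlkes–Mallows, plus the Pearson correlation of their cophenetic distance
vectors (label-aligned).  Newick export places each internal node at half
its merge height (ultrametric halving: two leaves merged at 0.4 serialise as
`(A:0.2,B:0.2);`), with AU values as internal node labels; negative branch
lengths from non-monotone linkages are clamped to 0.

## Pipeline

`run_pipeline` composes the stages in order and writes every intermediate
(similarity, rank, degree, betweenness, network-effect CSVs; three Newick
trees with support tables; comparison table; JSON report echoing the full
config).  Compound ids must match exactly between the structure file and the
docking matrix (an `id_map` TSV supports aliasing); a mismatch reports the
symmetric difference before any computation.  Axis-specific bootstrap seeds
are derived from the single config seed.  Clustering requires complete
feature matrices: a docking matrix with missing cells is rankable but not
clusterable, and the pipeline says so rather than imputing.

## Synthetic fixtures: what they emulate and what they don't

`generate_fixtures` builds a screen whose ground truth is known on all three
axes:

* **Compounds** come from four embedded scaffold families (sugar polyols,
  salicylates, alkyl diamines, alkyl pyridines), three members each at the
  default *n* = 12.  Within a family, members are chain homologues, so
  within-family overlap coefficients are ≈ 1 and family identity is the
  structural ground truth.  Families were chosen with distinct heteroatom
  and bond-order patterns so that, under the strict MCS defaults,
  profile-correlation clustering separates them cleanly.
* **The PPI graph** is a Barabási–Albert preferential-attachment graph
  (*m* = 2) over 45 proteins — matching the heavy-tailed degree
  distributions of real interactomes — with STRING-style combined scores
  drawn uniformly from [700, 1000) so every edge survives the 0.7 threshold.
  The 5 top-degree nodes are the planted hubs.
* **Docking scores** define two groups: group X scores high (uniform 8–10)
  on hub proteins and low (uniform 1–3) elsewhere; group Y is the mirror
  image.  Gaussian noise (sd 0.5) is added and scores clipped to [0, 10].
  Group membership deliberately cuts across the scaffold families: one
  structurally similar pair (same family) is split across X/Y, and one
  structurally dissimilar pair (different families) shares a group, so the
  network axis must disagree with the structure axis at exactly those
  planted pairs.

Defaults (12 compounds, 45 proteins, 5 hubs, noise sd 0.5, scores 8–10 vs
1–3, confidence ≥ 0.7) are the study conditions of the packaged benchmark
scenario.  The planted separation is strong by design — the fixture
validates the machinery, not the difficulty of real screens.  Real data
differ in ways the generator does not emulate: docking scores correlate with
compound size and binding-site chemistry rather than with a clean two-group
design; PPI confidence correlates with degree; structural families are not
pure containment homologues; and group structure is rarely binary.  Passing
the planted tests therefore demonstrates correctness of the computation and
the discordance logic, not expected effect sizes on real panels.

The packaged static benchmark (12 named anti-ageing-related compounds with
well-known structures; 45 docked protein targets with PDB ids) provides
realistic molecule sizes — from salicylic acid (10 heavy atoms) to rapamycin
(65) — for similarity computations.  PPI degrees in the target table are
transcribed from a published network snapshot; entries whose printed digit
grouping was ambiguous are left missing rather than guessed.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] and dissimilarities to [0, 2];
  rounding-level negatives clamp to 0; matrices are symmetrised before
  linkage.
* Rank ties use average ranks; MCS coefficient for atom-type-disjoint pairs
  is 0.0; empty bootstrap-scale resamples (< 3 columns) are rejected up
  front.
* All CSV writers emit `NA` for missing values and round-trip bit-exactly
  through the package's own readers at full float precision.

## Problem sizes used by the tests and acceptance script

Unit and property tests run at small sizes (≤ 12 items, ≤ 50 features,
B ≤ 400).  The acceptance script uses 10 fixture seeds × the full pipeline
at B = 100 per scale, plus 5 two-block AU runs — sizes chosen so a complete
validation runs in well under a minute on one core while every measured
quantity is still computed from scratch.

## Known limitations

* Disconnected maximum common substructures are not supported.
* No identifier mapping between gene symbols and database-specific protein
  ids: inputs must already use consistent symbols.
* AU p-values are not adjusted for testing multiple clusters.
* Clustering features must be complete (no missing-cell imputation).
* MACCS keys and 3D/conformer similarity are deliberately out of scope.
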