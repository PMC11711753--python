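# Methods

This note documents the models, conventions and numerical choices behind
`ptmnav`, in the order data flows through the package.

## Pathway skeletons

Both KEGG (KGML) and WikiPathways (GPML) define a pathway as a mixed graph:
typed nodes with 2-D cartesian drawing coordinates (origin top-left, y
growing downward), directed/undirected typed edges, and *group* nodes
defined only by their member nodes. The skeleton model unifies both
dialects with four regular node types (`gene_protein`, `compound`,
`pathway`, `misc`) plus `group`, and edges whose endpoints may be **other
edges** (needed to represent GPML anchors). Pathways without a single
gene/protein node are deliberately not imported — they carry no signaling
information a PTM dataset could attach to — and are reported as "skipped"
rather than raising.

The JSON serialization (`formatVersion: 1`, top-level keys `pathwayId`,
`name`, `organism`, `sourceDb`, `nodes`, `edges`) is defined by this
package; upstream sources publish no schema for such a format, so the
field names here are artifact-defined. Coordinates serialize at 2-decimal
precision, which makes a double round-trip byte-stable.

### KGML normalization

* Node types: `gene` and `ortholog` collapse into `gene_protein`; `map`
  becomes `pathway`; `compound` is unchanged.
* Relations keep their subtype vocabulary except for two merges:
  indirect / "indirect effect" → `indirect`, and inhibition / repression →
  `inhibition`. The shipped table has 19 raw subtypes mapping onto 17
  unified ones. The 16 subtypes documented in the KGML specification are
  extended by the legacy `indirect` form (required for the merge) and by
  `sumoylation` / `demethylation`; the exact historical list is not
  published with the KGML schema, so this completion is artifact-defined.
* Reactions (many-to-many, substrate list × product list) are replaced by
  one directed relation per substrate–product pair — |S|·|P| edges. A
  reversible reaction keeps one edge per pair with a `reversible` marker
  instead of a duplicate back-edge; consumers that need both directions
  can expand the marker.
* Identifier mapping is a two-stage offline table (source id → UniProt
  accession(s) → gene name), loaded from 2-column TSVs. Lookups are total:
  a missing key leaves the node with empty accessions and a label that
  falls back to the diagram label, then the raw KEGG id. No network access
  occurs anywhere in the package.
* Multi-gene entries become one node carrying all mapped accessions and
  gene names, labeled by the first mapped gene name — this maximizes the
  number of nodes with a human-readable label.

The XML dialect itself is parsed with Biopython's KGML parser; all
normalization above is this package's.

### GPML normalization

* 13 node kinds map onto the four unified types: GeneProduct, Protein and
  Rna → `gene_protein`; Metabolite → `compound`; Pathway → `pathway`;
  Complex, Unknown, CellularComponent, Event, Organelle, Cell, Label and
  Shape → `misc`.
* 24 edge (arrowhead) types: 10 convert into KEGG-derived subtypes
  (e.g. Arrow → activation, TBar → inhibition, mim-binding →
  binding/association) and 14 are retained verbatim (e.g. Line, Receptor,
  mim-catalysis). The mapped/retained partition follows the GPML 2013a
  vocabulary; its exact membership is a design choice of this package,
  validated only by the 13/24/10/14 conformance counts.
* Anchors — interactions terminating on other interactions — are resolved
  into edges whose endpoint reference is an edge id; chains resolve
  acyclically and no anchor construct survives import.
* GPML `State` decorations (PTMs drawn on the diagram) are ignored:
  projected PTMs come from experimental data, not from the diagram.
  Documented limitation.
* Xref unification prefers a direct UniProt xref, otherwise the offline
  table resolves Entrez/Ensembl/HGNC identifiers.

## Projection

A PTM record matches a skeleton node if they share a UniProt accession
(isoform suffixes stripped: `P42345-2` ≡ `P42345`) **or** a gene name
(case-insensitive) — union semantics, so accession-only and gene-only
records both project. A record matching several nodes yields one PTM node
per match; canonical diagrams often draw one protein in several cascade
branches. Unmatched records are returned on the graph, never silently
dropped.

With `collapse=True`, per-record satellites are replaced by one summary
node per (protein node, regulation category) carrying the peptide count;
the counts always sum to the number of (record, node) matches.

Three color schemes: categorical regulation (up `#d62728`, down
`#1f77b4`, not `#999999`, configurable), continuous by log2 fold change,
and continuous by potency (pEC50) for dose-resolved data. Continuous
domains are fitted over **matched** records only, after projection; domain
endpoints map exactly onto the endpoint colors; a zero-width domain yields
the midpoint color; records missing the value render in a designated
no-value gray.

Kinase–substrate annotation rows overlay as kinase-node → PTM-node edges
when the kinase is present in the skeleton and the substrate site
(accession-or-gene, residue, 1-based position) matches any site of a
projected peptide. Kinase-activity results flag nodes when
|score| ≥ 0.5 (inclusive) and FDR < 0.1 (exclusive) by default, colored
red/blue/purple for up/down/unknown direction.

## Layout and SVG export

PTM satellites have no diagram coordinates; they are placed by minimizing,
per reference node, a potential of spring terms (rest length 28 px toward
the reference) plus pairwise inverse-distance repulsion among satellites
of the same reference. The integrator is gradient descent with
backtracking line search (default 300 iterations), so the energy is
monotonically non-increasing by construction and the trajectory is exactly
reproducible — the seed only rotates the initial angular placement. The
determinism contract is deliberately favored over visually replicating any
particular interactive force engine; the force constants are this
package's defaults. If the iteration budget leaves residual overlaps,
satellites are projected onto a circle around the reference wide enough
that adjacent chords respect the collision radius (14 px default,
guaranteed to 1e-6).

SVG output is plain SVG 1.1 text with one element per visible entity and
stable, id-derived element ids. Group nodes render as the convex hull
polygon over their member rectangles' corners (computed with Qhull). The
four visual edge classes are distinguished by dash pattern and marker:
activation solid+arrow, inhibition solid+T-bar, binding/association
dashed, indirect long-dashed+arrow; all remaining subtypes share one
generic style. PTM→skeleton anchor edges exist only for the force model
and are never drawn. Edges that end on other edges are drawn to the
midpoint of the target edge.

## Enrichment battery

**ECDF-difference score.** Items sort descending by value (stable; ties
keep input order). The score is the mean over rank positions of
ECDF_signature − ECDF_rest. The integrated (area) form is the default;
this is the conventional default for single-sample rank enrichment. The
maximum-deviation (Kolmogorov–Smirnov) form was considered and not
implemented as no consumer in this package needs it. Zero overlap, or a
signature swallowing the entire profile, produce an NaN score — a
reportable outcome, not an exception. Signed signature members (direction
−1) have their profile values negated before ranking, so a site that goes
*down* under a signature that expects down-regulation contributes
positively.

Duplicate handling is the profile's policy: `collapse_max_abs` keeps the
entry of maximum absolute value per key (gene-centric, and the site-level
convention for PTM signatures), `keep_all` keeps every occurrence so a
gene is counted once per regulated peptide (gene-centric redundant).
The two coincide exactly on duplicate-free profiles.

**Permutation p-values.** The member *set* is permuted: random equal-size
sets of profile positions, p = (1 + #{|score_perm| ≥ |score_obs|}) /
(1 + n_perm), with n_perm = 1000 by default and a seeded generator. This
estimator is conservative by at most 1/(1+n_perm) and calibrates to the
nominal type-I error under the null (verified in the acceptance suite).
The permutation scheme is this package's; scores are comparable across
implementations of the same statistic in sign and ordering, not guaranteed
numerically identical to weighted variants. BH adjustment runs per
experiment across signatures; NaN-scored signatures are excluded from the
family. Pathway ranking for display sorts by |GCR score| descending,
NaN-scored last, stable among ties.

**KSEA.** z = (mean_substrates − mean_all)·√m / sd_all over log2 fold
changes deduplicated by maximum absolute value; sd uses ddof = 1 (the
statistic's source does not pin the denominator; both choices differ by
< 1% at realistic dataset sizes). Two-sided normal p, BH across the
kinases reported, minimum substrate count 3. A zero-variance background
makes every z undefined and raises a diagnostic error. Taking the entire
background as the substrate set gives z = 0 identically.

**Motif enrichment.** PSSM weights are positive preferences per position
(−5..+4 around the phospho-acceptor by default; width configurable) and
peptides score as the sum of log2 weights over their flanking window;
padding characters and residues absent from the matrix are skipped.
Scores become percentiles of a per-kinase background distribution
(fraction of background ≤ score). Each site keeps its top-15 kinases by
percentile (ties broken by kinase name for determinism). Per regulation
direction and kinase, a 2×2 Fisher exact test (two-sided) contrasts
(regulated in that direction vs all other sites) × (kinase in top-k vs
not), BH across kinases within the direction.

**BH adjustment** is the standard step-up procedure (via statsmodels).
Note that BH is *not* idempotent on already-adjusted vectors in general
([0.25, 1] → [0.5, 1] → [1, 1]); the guaranteed properties are
elementwise never-decreasing output, permutation equivariance, and
constant vectors as fixed points.

## Data ingestion

The regulation CSV reader sniffs the delimiter among comma/tab/semicolon,
normalizes regulation labels case-insensitively to {up, down, not},
splits site strings (`S1134`; multi-site `S236&S240`) into residue +
1-based position (positions refer to the UniProt canonical sequence), and
collects malformed rows into an error report with line numbers rather than
aborting; only a missing required column is a hard error. Column names
have documented defaults and are fully overridable, since upstream tools
do not share a single header convention. The decimal separator is fixed
to ".".

Dose-response ingestion reads a fitted-curves TSV plus a TOML parameter
file giving the drug name and dose series (nanomolar or molar). Regulated
curves become up/down records carrying pEC50 and curve fold change;
others become "not" records without potency. The dosed concentration
range maps to a pEC50 window (1 nM..10 µM → [9.0, 5.0]); potencies outside
it are extrapolations of the curve fit and are flagged in the record
details. A drug-name mismatch between the curves table and the TOML is a
hard error. Curve fitting itself is out of scope — curves are read, never
computed.

Low/high-dose pairs deduplicate to one entry per peptide: duplicates
within one experiment (multiply phosphorylated peptides) resolve to the
lowest adjusted p-value first; then a significant high-dose entry always
wins; a significant low-dose entry wins over a non-significant high dose;
otherwise the high-dose entry is kept. The three outcome rules are
mutually exclusive and exhaustive, and the firing rule is recorded.

## Synthetic data

The fixtures module generates every input the package consumes. Pathway
fixtures emit real KGML/GPML XML alongside the ground-truth skeleton and a
matching offline id-mapping table, so the readers are tested for
structural equality (an id-independent fingerprint that survives
edge-on-edge references), not byte layout. Fixtures are byte-deterministic
under their seed.

The dataset generator emulates a kinase-inhibitor perturbation screen: the
planted kinase's substrates receive a common log2 fold-change shift
(default −1.5) over Gaussian noise (default sd 0.3), all other peptides
are null, and regulation labels derive from the global fold-change
quantiles (default 10% up, 10% down). The default scale is 500 peptides
with 10 planted substrates. Potency mode assigns pEC50 values evenly
spaced across a narrow band (e.g. 6.4–7.4, the window of a selective
inhibitor acting through a single upstream target), endpoints included
exactly.

What the generator does **not** emulate: missing values, peptide-level
intensity structure, multiply-regulated proteins with conflicting
directions, correlated substrate sets between kinases, or realistic
phosphoproteome depth (tens of thousands of sites). Passing tests
demonstrate correctness of the algorithms and calibration of their null
distributions under these controlled conditions, not end-to-end
performance on real instrument output.

## Problem sizes and determinism

The test and acceptance suites run on deliberately small problems:
profiles of ≤ 200 items, 500-peptide datasets, 100-run recovery
experiments, 500-signature permutation calibrations at n_perm = 1000, and
2×2 tables with margins ≤ 30 for the exhaustive Fisher check. All
randomness flows through explicit seeds; two runs with the same seed are
bit-identical, including layout coordinates and generated XML.

## Known limitations

* The GPML mapped/retained edge partition and the three KGML subtype
  completions are artifact-defined (see above); diagrams using vocabulary
  outside the shipped tables degrade gracefully (misc nodes, verbatim
  retained subtypes with the generic edge style, logged warnings).
* Set-enrichment scores are rank-based and unweighted; weighted-ECDF
  variants will order signatures similarly but produce different
  magnitudes.
* Overlay matching requires exact site coordinates; no tolerance for
  off-by-one site localization is applied.
* The renderer draws straight-line edges only and does not reproduce
  waypointed (elbow) connectors from the source diagrams.
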