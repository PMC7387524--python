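# Methods

This note documents the models, conventions and numerical choices behind
`aarsfp`, and what the synthetic study conditions do and do not establish
about real structural data.

## Scaffold model and specificity assignment

The ligand of an aaRS complex is either the free amino acid
(pre-activation) or an aminoacyl-adenylate / non-hydrolysable analog
(post-activation). Only contacts with the amino-acid substructure confer
specificity; contacts with the adenosine/phosphate moiety probe the shared
ATP site. Each of the 22 amino acids is therefore represented by a
heavy-atom *scaffold* graph: the residue's chemical-component connectivity
(bundled with biotite) with hydrogens stripped and the carboxyl hydroxyl
oxygen (OXT) removed, because that hydroxyl is cleaved during activation;
the carbonyl oxygen is retained and backbone atoms (N, CA, C, O) are
flagged. In post-activation ligands the position corresponding to the
hydroxyl is the ester bridge oxygen and is not part of the scaffold.

Scaffolds are matched into full ligand graphs by subgraph
*monomorphism* — injective, element-preserving maps under which every
scaffold bond lands on a ligand bond. Monomorphism (not induced
isomorphism) is required so that the scaffold, whose atoms gain extra
bonds inside a larger ligand, still matches. Matching deliberately
ignores bond orders and aromaticity flags: ligand dictionaries disagree on
the orders of sulfamoyl analogs and AMP esters, and order-free matching
lets all of them hit the same scaffold. Enumeration is exhaustive
(networkx VF2), exactly deduplicated, and sorted lexicographically so
results are order-independent.

A contact record is then assigned the **union** of scaffold atoms its
ligand atoms receive over *all* isomorphisms. Symmetric groups —
the valine methyls, aromatic rings, carboxylate oxygens — are thus
assigned to every automorphic position rather than to an arbitrary one.
Records whose ligand atoms receive no scaffold atom (adenosine, phosphate,
ribose) are dropped. Two consequences are worth noting:

* the union is idempotent and independent of enumeration order;
* element-only matching admits rare chemically spurious embeddings — the
  four-atom glycine scaffold also matches the ribose N9–C1′–C2′–O2′
  fragment of an adenylate. The union convention absorbs this: a true
  glycine contact is still assigned correctly, and a ribose contact in a
  glycine complex would be (conservatively) retained. This is an inherent
  ambiguity of order-free matching of very small patterns, not a defect of
  larger scaffolds.

Matching failure (zero embeddings) raises an error naming the complex: it
signals a wrong ligand or a corrupt graph, never a silent empty result.

## Occupancy and frequency statistics

*Occupancy* of a (scaffold atom, interaction type) pair for one enzyme is
the fraction of its structures showing that contact at least once
(duplicate records within a structure do not inflate it). Entries with
occupancy strictly below a cutoff (default **0.1**) are treated as
crystallographic noise and neglected; an entry exactly at the cutoff is
kept. Class-level frequency tables instead count every record, because
they describe interaction abundance rather than conservation. Water
bridges are excluded from both by default: structures solved without
ordered waters cannot show them, so counting them would import an
experimental bias.

Percentages are rounded **half-up to two decimals**. Published tables of
this kind mix rounding conventions; standardizing on half-up makes the
arithmetic reproducible and is documented wherever a comparison is made.

Group comparisons use the two-sided Mann–Whitney U test. For pooled sizes
n+m ≤ 16 the null distribution is enumerated exactly over all label
assignments of the pooled values, which handles ties exactly (identical
samples give p = 1); larger samples use scipy's tie-corrected normal
approximation with continuity correction. Pearson and Spearman
correlations delegate to scipy (average ranks for ties).

The bundled physicochemical reference table contains side-chain analog
transfer free energies from water to cyclohexane (Radzicka & Wolfenden
1988, kcal/mol); glycine and proline have no measured analog and are
omitted, and analyses using the table must restrict to the tabulated
amino acids.

## Fingerprints

Segments, in fixed concatenation order:

| segment | width | content |
|---|---|---|
| seq | 20 | one bit per standard residue type among interacting residues (multiplicity ignored; metals/unknowns set no bit) |
| int | 500 | hashed features *(interaction type \| ligand group \| residue type)* |
| editing | 22 | one bit per ligand the enzyme proofreads against (fixed alphabetical ligand order) |
| volume | 12 | one-hot cavity-volume bin |

The *ligand group* of a feature is the element symbol of each assigned
scaffold atom (one feature per atom), the pseudo-group `ring` for π
interactions, and the coordinating atom's element for metal complexes.
Features are lower-cased canonically and hashed with **FNV-1a 64-bit**,
`bit = hash mod 500 + 1`. The hash is a package convention: absolute bit
indices are implementation-specific, Jaccard distances are not. A
diagnostic enumerates the realizable feature vocabulary (~190 strings
after restricting each interaction type to its chemically possible
groups) and reports the fraction of feature pairs sharing a bit
(≈0.2 % at 500 bits).

Volume bins are half-open, `[30+20(k−1), 30+20k)` ų for k = 1…12, with
clamping below 30 and at/above 270, so exactly one bit is always active.

The `Seq+Int*` design family uses the hashed 500-bit segment only —
residue identity is already part of every hashed feature, and the segment
arithmetic (500 + 22 + 12 = 534) shows the 20-bit composition vector is
not appended. `Seq_sim` is the standalone 20-bit baseline.

Jaccard distance follows the standard active-bit formula; two all-zero
fingerprints are defined to be at distance 0 (indistinguishable
observations). The distance is a metric on binary vectors up to that
convention.

## Recognition space and silhouette

The pairwise Jaccard matrix is embedded into 2-D by a pluggable backend:
distance matrix in, coordinates out, seedable. The default is UMAP with
`n_neighbors=60, min_dist=0.1, n_components=2` (clamped with a warning
when the dataset is smaller than the neighborhood); a deterministic
classical-scaling (PCoA) backend is provided for fast exact tests and
degenerate inputs.

The mean silhouette coefficient, with enzyme identity as the cluster
label, scores how well a fingerprint design separates recognition:
s(i) = (b(i) − a(i)) / max(a(i), b(i)), singleton clusters and
zero-distance ties score 0. Silhouettes are computed on the embedded
coordinates with Euclidean distance — the score then measures the quality
of the embedding a reader actually looks at — but a precomputed-distance
mode is available to score the Jaccard space directly. Because embeddings
are stochastic, design comparisons run over a list of seeds and report
per-seed values with mean and dispersion; tests assert ordering
properties across seeds, never absolute coordinates.

## Geometry

Signed dihedrals use the IUPAC convention, range (−180°, 180°], computed
with the atan2 cross-product formula; coincident or collinear defining
points raise. The default ligand torsion quadruple is ribose O5′ →
phosphorus → bridging ester oxygen → carbonyl carbon, i.e. the rotation
about the phosphoester bridge that flips the amino-acid moiety from one
side of the adenosine plane to the other. The published analyses of this
angle do not name their exact quadruple, so the choice here is a package
convention, recorded in output metadata and fully configurable; absolute
angles from real structures are therefore comparable only in sign and
separation, not digit-for-digit.

## Curation

Sequence identity = identical aligned positions / full alignment length
(gap columns included; configurable to shorter-sequence length), from a
global Needleman–Wunsch alignment with BLOSUM62. Gap penalties are
open 10 / extend 0.5 (the first gapped position costs the opening
penalty), a common pairing for BLOSUM62; the analyses this reproduces did
not state theirs. Single-linkage clustering at ≥95 % identity is computed
as connected components of the similarity graph. Representative selection
is deterministic with ordered criteria — wild type first, then best
resolution, then lexicographic id — a documented refinement of
"preferring wild type and high quality". MSA renumbering maps the k-th
residue of a structure to the alignment column of its k-th non-gap
character; the exported table layout has unified positions as rows and
structures as columns.

## Synthetic data generator

The generator is the package's study condition: it emulates the
statistical structure reported for the real corpus, not any individual
structure.

* **Backbone conservation**: hydrogen bonds to the ligand amine with
  probability 0.83 (Class I) / 0.92 (Class II); carboxyl hydrogen bonds
  0.33 / 0.66 and salt bridges 0.29 / 0.39 — the reported per-class
  structure fractions.
* **Side-chain chemistry**: hydrophobic contacts on side-chain carbons
  (p 0.75 Class I / 0.50 Class II), hydrogen bonds on polar side-chain
  atoms (0.55 / 0.75), salt bridges on charged termini (0.45 / 0.65),
  π-stacking on full rings only for the Phe/Tyr/Trp handlers (0.70), and
  zinc coordination for the Cys/Ser/Thr handlers (0.60). The class skews
  mirror the reported dominance of hydrophobic contacts in Class I and
  hydrogen bonds in Class II.
* **Partner residues**: each contact has a concentrated residue
  distribution — a per-enzyme dominant partner (0.65–0.75) plus
  class-shared minors — emulating the conserved key residues seen in
  recognition summaries while keeping 20-bit composition overlapping
  between enzymes.
* **Volumes**: Normal(143.40, 39.62²) ų for Class I, Normal(90.36,
  32.09²) ų for Class II, rejection-sampled above a 10 ų physical floor.
* **States and noise**: pre/post-activation drawn at the observed
  240:184 mix (post ligands carry a full adenylate graph); each complex
  has a 0.05 chance of one spurious uniform (atom, type, residue) contact,
  which exercises the occupancy cutoff. Noise types are restricted to
  hydrogen bond / hydrophobic / salt bridge so spurious records remain
  structurally valid (a one-atom π record would violate the ring rule).

`expected_occupancies` converts a template into per-(atom, type)
expectations, combining entries across scaffold automorphism orbits as
p = 1 − Π(1 − p_e) — the quantity the union-assignment convention actually
estimates (e.g. a 0.75 methyl contact on valine yields 0.9375 per methyl).
Templates are plain data and serialise to YAML for re-parameterisation.

**What passing on synthetic data shows** — that every pipeline stage
implements its contract: assignment, counting, hashing, distances,
embedding and scoring behave correctly on data with known ground truth,
and occupancy estimates recover their generating probabilities within
binomial error. **What it does not show** — anything about contact
detection (records are consumed, not detected), about the adequacy of
the emulation to any particular real enzyme, or about published
dataset-specific values (absolute silhouettes, real torsion angles,
per-atom occupancies), which depend on the real corpus.

## Problem sizes and defaults

Parameter-recovery checks use 200 structures per enzyme (binomial SE
≈0.035 at p = 0.5); design comparisons use 20 per enzyme (440 points)
with 60-neighbor UMAP, several embedding seeds; subgraph-matcher
equivalence is verified against a brute-force enumeration oracle on
hundreds of random graphs of up to 12 atoms. These sizes give stable
statistics while keeping a full run in the minutes range on one core.

## Known limitations

* Scaffold matching cannot distinguish stereoisomers or bond orders by
  design; very small scaffolds (glycine) admit spurious embeddings into
  the adenylate moiety (see above).
* The editing table bundled as default is approximate: proofreading
  targets outside the 22-ligand vocabulary (norvaline, homocysteine)
  cannot be encoded, so those entries are reduced or empty. Supply a
  curated file for real analyses.
* PLIP reports are consumed at the level of the standard interaction
  elements; exotic report variants may need the tabular input path.
* The generator produces no 3-D coordinates beyond the toy adenylate
  quadruple used for torsion tests, and does not emulate crystallographic
  artifacts (alternate conformations, missing atoms, occupancy < 1).
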