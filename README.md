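# aarsfp

Interaction-fingerprint analysis of amino acid recognition by
aminoacyl-tRNA synthetases (aaRSs).

## The problem

aaRSs implement the readout of the genetic code: each of the 22 enzymes
(20 canonical, plus pyrrolysyl- and phosphoseryl-tRNA synthetase) must
pick its own amino acid out of a pool of chemically similar competitors
before attaching it to the cognate tRNA. Crystal structures of
aaRS·amino-acid and aaRS·aminoacyl-adenylate complexes record the
non-covalent contacts that accomplish this discrimination. `aarsfp`
turns such per-complex contact annotations (e.g. PLIP reports) into
quantitative, comparable descriptions of recognition:

1. **Scaffold mapping** — each amino-acid ligand is reduced to its
   heavy-atom scaffold (the amino acid minus the carboxyl hydroxyl that
   is cleaved during activation). Contacts are mapped onto scaffold
   atoms by subgraph-isomorphism matching of the scaffold into the full
   ligand graph, so only specificity-conferring contacts survive and
   contacts on symmetric groups (the two valine methyls, aromatic
   rings) are assigned to every equivalent atom.
2. **Occupancy statistics** — per (scaffold atom, interaction type)
   occupancy across an enzyme's structures, class-level frequency
   tables, side-chain recognition summaries in unified MSA numbering,
   and the associated correlation / rank statistics
   (Pearson, Spearman, Mann–Whitney U).
3. **Fingerprints** — every complex becomes a segmented binary vector:
   a hashed 500-bit contact segment (features of the form *interaction
   type | ligand group | residue*, FNV-1a hashed to bits 1–500), a
   22-bit editing (proofreading) segment, and a 12-bit one-hot
   binding-cavity-volume segment (30–270 Å³ in 20 Å³ bins) — 534 bits in
   total — plus a 20-bit binding-site-composition baseline. Pairwise
   dissimilarity is the Jaccard distance
   *d(a,b) = 1 − n<sub>a∧b</sub> / (n<sub>a</sub> + n<sub>b</sub> − n<sub>a∧b</sub>)*.
4. **Recognition space** — the Jaccard matrix is embedded into 2-D
   (UMAP by default, `n_neighbors=60, min_dist=0.1`; any seedable
   backend that consumes a precomputed distance matrix can be plugged
   in) and fingerprint designs are scored by the mean silhouette
   coefficient with enzyme identity as the cluster label.
5. **Curation & geometry** — Needleman–Wunsch (BLOSUM62) identity with
   single-linkage clustering at 95 % for representative selection,
   MSA-based residue renumbering, phosphoester torsion angles, and
   cavity-volume group comparisons.

A first-class synthetic-data generator (`aarsfp.synthetic`) produces
complete `StructureComplex` datasets whose statistical structure mirrors
the published corpus — conserved backbone hydrogen bonding (≈83 % of
Class I and ≈92 % of Class II structures bond the ligand amine),
class-skewed contact chemistry, class-dependent cavity volumes
(Normal(143.40, 39.62²) vs Normal(90.36, 32.09²) Å³) — so the entire
pipeline is testable without downloading structures.

## Worked example

```python
from aarsfp import (build_fingerprint, compare_designs, compute_occupancy,
                    generate_complexes, jaccard_distance)
from aarsfp.synthetic import default_spec

spec = default_spec()
complexes = generate_complexes(spec, n_per_aars=20, seed=42)

alars = [c for c in complexes if c.aars == "AlaRS"]
profile = compute_occupancy(alars, cutoff=0.1)
for (atom, itype), freq in sorted(profile.entries.items()):
    print(f"  AlaRS {atom:>3s}  {itype.value:<13s} occupancy {freq:.2f}")

fp_a = build_fingerprint(alars[0], "Seq+Int+Ed+Vol")
fp_b = build_fingerprint(alars[1], "Seq+Int+Ed+Vol")
print(f"Jaccard distance: {jaccard_distance(fp_a, fp_b):.3f}")

result = compare_designs(
    complexes, designs=["Seq_sim", "Seq+Int", "Seq+Int+Ed"], seeds=[0, 1],
)
for design in result.designs:
    print(f"  {design:<12s} mean silhouette {result.mean[design]:+.4f}")
```

prints

```
  AlaRS  CB  hydrophobic   occupancy 0.50
  AlaRS   N  hydrogen_bond occupancy 0.95
  AlaRS   O  hydrogen_bond occupancy 0.65
  AlaRS   O  salt_bridge   occupancy 0.40
Jaccard distance: 0.778
  Seq_sim      mean silhouette -0.1165
  Seq+Int      mean silhouette +0.2200
  Seq+Int+Ed   mean silhouette +0.4907
```

Reading: 19 of 20 synthetic AlaRS structures hydrogen-bond the ligand's
primary amine (N) and half contact the alanine Cβ hydrophobically —
below 0.1 a contact would be treated as noise and dropped. Two AlaRS
structures still differ in ~78 % of their active fingerprint bits.
Across designs, binding-site composition alone barely separates
enzymes (negative silhouette: foreign enzymes often look closer than
one's own), adding typed contacts lifts the mean silhouette to +0.22,
and encoding proofreading capability lifts it further — the monotone
improvement expected when each added information layer is
recognition-relevant.

There is also a small CLI: `aarsfp simulate --n 20 --seed 1 --out DIR
[--plip-xml]` writes a synthetic dataset (optionally as PLIP-style XML
reports), and `aarsfp compare-designs --complexes DIR/complexes.json`
runs the silhouette comparison.

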