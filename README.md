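# bcrclone

B-cell receptor (BCR) clonality analysis for single-cell V(D)J data, aimed at
studies of B-cell–rich infiltrates (e.g. primary cutaneous B-cell lymphomas
versus reactive lymphoid proliferations) where the scientific questions are:
*is there a dominant clone, how large is it, what phenotypes does it span, and
how hypermutated is it compared to the polyclonal background?*

The package takes 10x Genomics-style `filtered_contig_annotations.csv` tables
or AIRR Rearrangement TSVs (one row per assembled BCR contig per cell barcode)
plus optional per-cell phenotype metadata and a germline V-segment FASTA, and
produces per-sample clonality summaries. A fully seeded synthetic-repertoire
generator with planted ground truth makes every stage testable without
patient data.

## What it computes

1. **Cell QC.** Cells with more than two contigs, or multiple contigs of the
   same chain class (heavy = IGH; light = IGK ∪ IGL, so a κ+λ cell counts as
   duplicate light), are removed. Single-chain and one-heavy+one-light cells
   pass.
2. **Clonotypes.** Cells are grouped by exact chain signature
   (locus, V/J/C gene calls, CDR3 amino-acid sequence, per chain).
3. **Partial-clone merging.** Chain dropout splits a dominant clone into a
   paired clonotype plus single-chain fragments. For each of the two most
   frequent clonotypes that carries only one chain, fully paired clonotypes
   are merged with it iff they share the same V, C and J genes on that chain
   and the CDR3s reach ≥ 85% identity under global pairwise alignment
   (Needleman–Wunsch with affine gaps; BLOSUM100, gap open 10, gap extend 4).
   Clones that end up with more than two distinct CDR3 chains are removed.
4. **Somatic hypermutation.** Per contig, SHM = 1 − identity of the V region
   to its germline V segment (nucleotide global alignment; identity =
   identical bases / germline positions), summarised per sample for the top
   clone versus polyclonal B cells.
5. **Expansion and diversity.** Per sample: the top-clone expansion fraction
   `size(top clone) / n(B cells)`, the phenotype composition of the top clone,
   and the Shannon entropy `H = −Σ p ln p` of the composition. Disease groups
   are compared with two-sided Wilcoxon rank-sum tests with
   Benjamini–Hochberg FDR correction.

## Worked example

Simulate a follicle-centre-lymphoma-like sample (2000 B cells, planted top
clone at 52% of cells, 10% chain dropout, 2% doublets, SHM 5% per base in the
top clone vs 2% in the background) and analyse it:

```bash
bcrclone simulate --scenario pcFCL_like -o demo/sim
bcrclone run-all \
    --contigs demo/sim/filtered_contig_annotations.csv \
    --meta demo/sim/cell_meta.tsv \
    --germline demo/sim/germline_v.fasta \
    -o demo/out
```

prints

```
pcFCL_like: top clone pcFCL_like_clonotype3 (1010/2000 B cells, expansion 0.505, entropy 0.688)
```

The recovered expansion fraction 0.505 is the planted 0.52 minus the doublet
cells QC removed; the merging step has re-attached the dropout fragments of
the clone (see `merged_from` in `demo/out/clonotypes.tsv`). The SHM summary
separates compartments:

```
sample_id   compartment  n     median   q1      q3      min    max
pcFCL_like  polyclonal   1765  0.0203   0.0138  0.0244  0.0    0.0473
pcFCL_like  top_clone    1917  0.0488   0.0418  0.0574  0.0135 0.1045
```

— the top clone's median per-base mutation load (0.049) recovers the planted
rate (0.05) and clearly exceeds the polyclonal background (0.020), the
qualitative signature of a germinal-centre-derived expanded clone. Other
outputs in `demo/out/`: `qc_report.tsv` (QC partition counts),
`cell_clonotypes.tsv` (barcode → clonotype), `sample_summary.tsv`,
`manifest.json` (every tunable, including the substitution-matrix checksum).

The same operations are importable:

```python
from bcrclone import (filter_cells, build_clonotypes, merge_partial_clones,
                      top_clone, cdr3_identity)
cdr3_identity("CARDYWGQGTLVTVSSASTW", "CSKDYWGQGTLVTVSSASTW")  # 0.9
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates the four built-in disease-like scenarios (top-clone fractions 0.02,
0.04, 0.52 and 0.97, spanning reactive to aggressive entities), runs the full
pipeline on each, and prints the planted versus recovered expansion fraction
and phenotype entropy per scenario; the JSON result object is written to
`--out`.
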