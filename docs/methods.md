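# Methods

## Data model and QC

A contig is one assembled BCR chain for one cell barcode, carrying locus
(IGH/IGK/IGL), V/D/J/C gene calls, the CDR3 in nucleotide and amino-acid
space, the full contig nucleotide sequence, a UMI count and a productive
flag. Both supported table dialects (10x CSV, AIRR TSV) are normalised to
this model; rows with non-immunoglobulin loci go to a reject report so that
`records + rejects` always equals the input row count.

Non-productive contigs are read and flagged, not dropped at parse time;
whether they enter clonotyping is a QC flag (`require_productive`, default
on). Cell QC removes cells with more than two contigs
(`removed_gt2_contigs`; this rule is evaluated first, so a three-contig cell
with duplicate chains gets this label) and cells with two contigs of the
same chain class (`removed_dup_chain`). The chain classes are heavy (IGH)
and light (IGK ∪ IGL): a κ+λ co-expressing cell is treated as a
duplicate-light cell by default, overridable with
`kappa_lambda_duplicate=False` for locus-level counting. Single-chain cells
pass — the merging step depends on them surviving.

## Alignment and identity

Global pairwise alignment uses the three-state affine-gap recursion
(Needleman–Wunsch/Gotoh). A gap run of length ℓ costs
`gap_open + gap_extend·(ℓ−1)`; terminal gaps are penalised. Note that the R
aligner whose parameterisation the defaults mirror charges
`gap_open + gap_extend·ℓ` per run; the convention used here is the common
one in which `gap_open` is the full cost of a length-1 gap. With the default
open 10 / extend 4 the two conventions differ by one extension unit per gap
run, which does not move any CDR3 pair across the 85% identity boundary in
the substitution-dominated regime the merge rule operates in (gaps between
within-lineage CDR3s are rare; a single mismatch is always cheaper than two
single-residue gap runs under BLOSUM100).

The left-gap state has an in-row dependence that is vectorised as a running
maximum (`Y[i,j] = max_{k<j}(Z[k] + e·k) − e·(j−1)` with
`Z = max(M, X) − gap_open`), which is algebraically identical to the scalar
recurrence; the DP is verified against an exhaustive enumeration oracle over
all global alignments of short pairs. Traceback tie-breaking is fixed
(diagonal > up > left) so aligned strings are deterministic; the score is
unique regardless.

Identity is `n_match / n_columns` with the full alignment length (including
gap columns) as denominator — the "PID1" convention. The denominator is
configurable (`shorter`, `reference`) because published pipelines differ and
the choice is not dictated by the analysis definition. CDR3 comparison is at
the amino-acid level (a BLOSUM matrix presupposes amino acids); there is no
nucleotide CDR3 mode.

The BLOSUM100 matrix (1/3-bit units) is vendored as an NCBI-format text file
with an SHA-256 checksum verified at load time, for bit-exact
reproducibility; other matrices resolve through Biopython.

## Clonotyping and partial-clone merging

Clonotypes are exact-signature groups: equality of locus, V call, J call,
allele-stripped C call (`IGHG1*01` → `IGHG1`; a class switch therefore
breaks equality) and CDR3 amino-acid sequence, on each recovered chain.
The D gene is not part of any equality clause. Ranking is by size, with ties
broken by total member UMIs, then lexicographic clonotype id.

The merging rule rescues dominant clones split by chain dropout. Evaluated
clonotypes are those among the two most frequent that carry a single chain
signature; merge partners are fully paired clonotypes that, on the shared
chain, match the evaluated clone's V, C and J genes and reach
`identity_min = 0.85` CDR3 identity (boundary inclusive). Because members of
a clonotype share an exact signature, the all-member quantifier reduces to
one signature-level comparison. After each evaluation the ranking is
recomputed, so a light-only fragment can enter the top two once the
heavy-only fragment has been absorbed; at most two clonotypes are evaluated.
Merging moves cells (conservation holds by construction), records
provenance transitively in `merged_from`, adopts the missing chain signature
from the largest absorbed partner, and never crosses samples.

The clone-level filter then removes clones with more than two distinct CDR3
chains. "Distinct" is evaluated per chain class with the same ≥ 85% identity
criterion the merge rule uses: CDR3 variants above the threshold are
hypermutated forms of one chain and count once; variants below it are
genuinely different chains. Counting raw distinct CDR3 strings instead would
delete every merge product whose CDR3s are similar-but-not-identical,
making the merge rule vacuous — the collapsed count keeps the two rules
coherent while still removing chimeric merges (e.g. a heavy-only clone
absorbed partners with inconsistent light chains).

## Somatic hypermutation

SHM per contig is `1 − v_identity`. The contig's full nucleotide sequence is
globally aligned to the germline segment named by its V call (match +1,
mismatch −1, gap open 5, gap extend 2 — a documented stand-in for an
external V(D)J annotator's scoring); `v_identity` is identical aligned bases
divided by germline length. Columns where the germline is gapped (the
junction, J and constant-region bases 3' of the V) fall outside the
denominator, so the statistic covers the V gene only, matching the
convention of IgBLAST-style "V identity". Reference positions deleted in the
read reduce the match count and hence count against identity. Contigs whose
V call does not resolve in the reference (after allele stripping on either
side) are skipped and counted, not raised.

## Expansion, diversity and comparisons

The expansion-fraction denominator is all B-lineage cells in the metadata
(naive/GC/memory/plasma/aberrant labels, or any cell with no phenotype
label), so B cells without a recovered BCR still count; without metadata it
falls back to QC-passed cells with a productive BCR. Shannon entropy is in
natural-log units (nats) by default, with an optional log base. Group
comparisons use two-sided Wilcoxon rank-sum tests (exact null distribution
for small tie-free samples, continuity-corrected normal approximation
otherwise) and Benjamini–Hochberg adjustment; all comparisons produced by
one call are one FDR family. Groups with fewer than two samples are skipped
with a warning.

## Synthetic repertoires

The generator plants one top clone at a configurable fraction of `n_cells`
over `n_background_clones` background clones with geometric size weights
(p = 0.3, so the top clone is unambiguous at the fractions of interest).
Each clone has fixed heavy and light signatures (germline V/J draws, random
CDR3 with canonical Cys/Trp-or-Phe anchors, 15–21 aa); each cell's contig V
region carries i.i.d. per-base substitutions at the clone's SHM rate
(defaults 0.05 top / 0.02 background — germinal-centre-level vs background
mutational load). Cell anomalies are mutually exclusive per cell — doublet
(third contig from another clone), duplicate-chain (two different-locus
light contigs, no heavy), or dropout (one chain removed uniformly) — which
makes planted anomaly counts exactly recoverable from the QC report.
Phenotypes are labels drawn from clone-specific mixtures; no transcriptome
is simulated.

The germline pool is a small synthetic V/J reference (fixed internal seed,
realistic lengths ~290–300 nt V) rather than IMGT downloads; gene names
follow IMGT-style nomenclature so allele-stripping paths are exercised. The
SHM model has no indels by default and no AID hotspot structure, so green
recovery tests establish that the identity statistic and compartment
ordering are computed correctly — not that the generator reproduces real
mutational spectra. Dropout is uniform per cell, whereas in real data light
chains drop out more often than heavy.

Four named scenarios span the observed spectrum of clonal expansion
(top-clone fractions 0.02, 0.04, 0.52, 0.97 with matching phenotype
mixtures: reactive/marginal-zone-like mixed phenotypes through
GC-restricted to aberrant-dominated). All generation is deterministic given
the config, byte-for-byte.

## Numerical choices and limitations

* Floating-point ties in traceback use a 1e-9 tolerance; scores are integer
  sums in practice, so this is conservative.
* `identity_min` is validated to (0, 1]; the 0.85 default is inclusive
  ("at least 85%").
* Merging candidates must be fully paired; single-chain fragments are never
  merged into each other (a heavy-only and a light-only fragment can only be
  joined through a paired intermediary).
* The pipeline is per-sample throughout; no cross-sample clone tracking, no
  lineage trees, no isotype phylogeny.
* Statistical comparisons require ≥ 2 groups with ≥ 2 samples each and are
  skipped otherwise; with the single-sample scenario runs the comparison
  stage does not execute.
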