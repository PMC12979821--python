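"""Core domain types for single-cell BCR repertoire analysis.

The data model mirrors what a 10x Genomics V(D)J experiment produces after
contig assembly and annotation: per-cell-barcode contigs carrying gene calls
and CDR3 sequences, optional per-cell phenotype metadata, and a germline
V-segment reference used for somatic-hypermutation quantification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Chain(str, enum.Enum):
    """BCR chain locus. IGH is the heavy chain; IGK and IGL are light chains."""

    IGH = "IGH"
    IGK = "IGK"
    IGL = "IGL"

    @property
    def is_heavy(self) -> bool:
        return self is Chain.IGH

    @property
    def is_light(self) -> bool:
        return not self.is_heavy


AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ContigRecord:
    """One assembled BCR contig for one cell barcode."""

    contig_id: str
    barcode: str
    sample_id: str
    chain: Chain
    v_call: str
    j_call: str
    cdr3_aa: str
    d_call: str = ""
    c_call: str = ""
    cdr3_nt: str = ""
    sequence_nt: str = ""
    umis: int = 0
    productive: bool = True

    def __post_init__(self) -> None:
        if self.umis < 0:
            raise ValueError(f"umis must be non-negative, got {self.umis}")
        if self.cdr3_aa:
            allowed = AA_ALPHABET | ({"*"} if not self.productive else set())
            bad = set(self.cdr3_aa) - allowed
            if bad:
                raise ValueError(
                    f"contig {self.contig_id}: invalid CDR3 residues {sorted(bad)}"
                )


@dataclass(frozen=True)
class CellMeta:
    """Per-cell phenotype/sample metadata consumed (not derived) by the pipeline."""

    barcode: str
    sample_id: str
    disease: str = ""
    phenotype: str = ""


@dataclass(frozen=True)
class GermlineSegment:
    """A germline V-gene reference sequence (nucleotide)."""

    gene: str
    sequence_nt: str


class QcStatus(str, enum.Enum):
    PASS = "pass"
    REMOVED_GT2_CONTIGS = "removed_gt2_contigs"
    REMOVED_DUP_CHAIN = "removed_dup_chain"


@dataclass
class CellBcr:
    """QC-resolved paired-chain view of one cell.

    A pass cell has at most one heavy and one light contig and at least one of
    the two; removed cells keep their raw contigs for reporting.
    """

    barcode: str
    sample_id: str
    qc_status: QcStatus
    heavy: ContigRecord | None = None
    light: ContigRecord | None = None
    raw_contigs: tuple[ContigRecord, ...] = ()

    @property
    def umis(self) -> int:
        return sum(c.umis for c in (self.heavy, self.light) if c is not None)


def strip_allele(gene: str) -> str:
    """Drop the IMGT allele suffix: ``IGHG1*01`` -> ``IGHG1``."""
    return gene.split("*", 1)[0] if gene else gene


@dataclass(frozen=True)
class ChainSignature:
    """The clone-defining identity of one chain: locus, V/J/C calls and CDR3.

    The C gene is compared allele-stripped; a class switch (different C gene)
    breaks signature equality.
    """

    chain: Chain
    v_call: str
    j_call: str
    c_call: str
    cdr3_aa: str

    @classmethod
    def from_contig(cls, contig: ContigRecord) -> "ChainSignature":
        return cls(
            chain=contig.chain,
            v_call=contig.v_call,
            j_call=contig.j_call,
            c_call=strip_allele(contig.c_call),
            cdr3_aa=contig.cdr3_aa,
        )


@dataclass
class Clonotype:
    """A set of cells sharing a chain signature, with merge provenance."""

    clonotype_id: str
    sample_id: str
    heavy_sig: ChainSignature | None
    light_sig: ChainSignature | None
    members: list[CellBcr] = field(default_factory=list)
    merged_from: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_barcodes(self) -> set[str]:
        return {c.barcode for c in self.members}

    @property
    def total_umis(self) -> int:
        return sum(c.umis for c in self.members)

    @property
    def is_paired(self) -> bool:
        return self.heavy_sig is not None and self.light_sig is not None

    @property
    def is_single_chain(self) -> bool:
        return not self.is_paired

    def distinct_cdr3s(self) -> set[tuple[str, str]]:
        """Distinct (chain-class, CDR3) pairs across all member contigs.

        This counts the CDR3 chains a clone jointly defines; clones with more
        than two are removed by the clone-level chain-count filter.
        """
        out: set[tuple[str, str]] = set()
        for cell in self.members:
            if cell.heavy is not None:
                out.add(("heavy", cell.heavy.cdr3_aa))
            if cell.light is not None:
                out.add(("light", cell.light.cdr3_aa))
        return out


@dataclass(frozen=True)
class ShmEstimate:
    """Somatic hypermutation for one contig: 1 - identity to the germline V."""

    contig_id: str
    barcode: str
    sample_id: str
    v_call: str
    v_identity: float
    clonotype_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.v_identity <= 1.0:
            raise ValueError(f"v_identity out of [0,1]: {self.v_identity}")

    @property
    def shm(self) -> float:
        return 1.0 - self.v_identity


@dataclass
class SampleSummary:
    """Per-sample clonality summary: top-clone expansion, phenotype mix, entropy."""

    sample_id: str
    disease: str
    n_b_cells: int
    top_clone_id: str
    top_clone_size: int
    expansion_fraction: float
    phenotype_composition: dict[str, float]
    shannon_entropy: float


@dataclass(frozen=True)
class GroupComparison:
    """One two-sided rank-sum comparison between two disease groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    p_adjusted: float
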