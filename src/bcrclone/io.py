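"""Readers and writers for contig tables, cell metadata and germline FASTA.

Two contig-table dialects are supported and normalized to one internal model:

* ``tenx_csv`` — the 10x Genomics ``filtered_contig_annotations.csv`` column
  names (``barcode``, ``chain``, ``v_gene``, ``cdr3``, ``umis`` ...);
* ``airr_tsv`` — AIRR Rearrangement TSV with MiAIRR field names (``cell_id``,
  ``locus``, ``v_call``, ``junction_aa``, ``duplicate_count`` ...).

Rows whose chain/locus value is not an immunoglobulin locus (e.g. TR loci from
a mixed enrichment) are not a crash: they are collected into a reject report so
that ``records + rejects`` always accounts for every input row. Non-productive
contigs are read and flagged; dropping them is a downstream QC decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import CellMeta, Chain, ContigRecord, GermlineSegment

logger = logging.getLogger(__name__)

TENX_REQUIRED = ["barcode", "chain", "v_gene", "j_gene", "cdr3", "umis", "productive"]
AIRR_REQUIRED = [
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "junction_aa",
    "duplicate_count",
    "productive",
]


class FormatError(ValueError):
    """A table is missing mandatory columns or is otherwise malformed."""


@dataclass(frozen=True)
class RejectedRow:
    row: int
    reason: str


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "t", "yes", "1"}:
        return True
    if s in {"false", "f", "no", "0", "none", "nan", ""}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def _opt(row: pd.Series, *names: str) -> str:
    for name in names:
        if name in row.index and pd.notna(row[name]):
            s = str(row[name]).strip()
            if s and s.lower() not in {"none", "nan"}:
                return s
    return ""


def read_contigs(
    path: str | Path,
    dialect: str = "tenx_csv",
    sample_id: str = "",
) -> tuple[list[ContigRecord], list[RejectedRow]]:
    """Read a contig annotation table into ContigRecords plus a reject report.

    ``sample_id`` is a default used when the table has no ``sample_id`` column
    (10x tables usually do not); it falls back to the file stem.
    """
    path = Path(path)
    if dialect == "tenx_csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
        required = list(TENX_REQUIRED)
        # accept AIRR-style call columns in a CSV too
        colmap = {"v_gene": "v_call", "d_gene": "d_call", "j_gene": "j_call",
                  "c_gene": "c_call", "cdr3": "junction_aa", "cdr3_nt": "junction",
                  "umis": "duplicate_count", "barcode": "cell_id", "chain": "locus"}
        for tenx, airr in colmap.items():
            if tenx not in df.columns and airr in df.columns:
                df = df.rename(columns={airr: tenx})
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        get = dict(
            contig_id=("contig_id",),
            barcode=("barcode",),
            chain=("chain",),
            v_call=("v_gene",),
            d_call=("d_gene",),
            j_call=("j_gene",),
            c_call=("c_gene",),
            cdr3_aa=("cdr3",),
            cdr3_nt=("cdr3_nt",),
            sequence_nt=("sequence",),
            umis=("umis",),
            productive=("productive",),
            sample_id=("sample_id",),
        )
    elif dialect == "airr_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=[""])
        missing = [c for c in AIRR_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        get = dict(
            contig_id=("sequence_id",),
            barcode=("cell_id",),
            chain=("locus",),
            v_call=("v_call",),
            d_call=("d_call",),
            j_call=("j_call",),
            c_call=("c_call",),
            cdr3_aa=("junction_aa",),
            cdr3_nt=("junction",),
            sequence_nt=("sequence",),
            umis=("duplicate_count",),
            productive=("productive",),
            sample_id=("sample_id",),
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    default_sample = sample_id or path.stem
    records: list[ContigRecord] = []
    rejects: list[RejectedRow] = []
    for idx, row in df.iterrows():
        raw_chain = _opt(row, *get["chain"]).upper()
        try:
            chain = Chain(raw_chain)
        except ValueError:
            rejects.append(RejectedRow(int(idx), f"unknown chain {raw_chain!r}"))
            continue
        try:
            umis_s = _opt(row, *get["umis"])
            if umis_s and "." in umis_s:
                raise ValueError(f"UMI count must be an integer, got {umis_s!r}")
            rec = ContigRecord(
                contig_id=_opt(row, *get["contig_id"]) or f"{path.stem}_row{idx}",
                barcode=_opt(row, *get["barcode"]),
                sample_id=_opt(row, *get["sample_id"]) or default_sample,
                chain=chain,
                v_call=_opt(row, *get["v_call"]),
                d_call=_opt(row, *get["d_call"]),
                j_call=_opt(row, *get["j_call"]),
                c_call=_opt(row, *get["c_call"]),
                cdr3_aa=_opt(row, *get["cdr3_aa"]),
                cdr3_nt=_opt(row, *get["cdr3_nt"]),
                sequence_nt=_opt(row, *get["sequence_nt"]),
                umis=int(umis_s) if umis_s else 0,
                productive=_as_bool(row[get["productive"][0]]),
            )
        except ValueError as exc:
            rejects.append(RejectedRow(int(idx), str(exc)))
            continue
        records.append(rec)
    if rejects:
        logger.warning("%s: rejected %d of %d rows", path, len(rejects), len(df))
    return records, rejects


def write_contigs(
    records: list[ContigRecord], path: str | Path, dialect: str = "airr_tsv"
) -> None:
    """Write ContigRecords as a 10x-style CSV or an AIRR Rearrangement TSV."""
    path = Path(path)
    rows = []
    for r in records:
        if dialect == "tenx_csv":
            rows.append(dict(
                barcode=r.barcode, contig_id=r.contig_id, chain=r.chain.value,
                v_gene=r.v_call, d_gene=r.d_call, j_gene=r.j_call, c_gene=r.c_call,
                cdr3=r.cdr3_aa, cdr3_nt=r.cdr3_nt, sequence=r.sequence_nt,
                umis=r.umis, productive=str(r.productive),
                sample_id=r.sample_id,
            ))
        elif dialect == "airr_tsv":
            rows.append(dict(
                sequence_id=r.contig_id, cell_id=r.barcode, locus=r.chain.value,
                v_call=r.v_call, d_call=r.d_call, j_call=r.j_call, c_call=r.c_call,
                junction_aa=r.cdr3_aa, junction=r.cdr3_nt, sequence=r.sequence_nt,
                duplicate_count=r.umis, productive=str(r.productive),
                sample_id=r.sample_id,
            ))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame(rows)
    if dialect == "tenx_csv":
        df.to_csv(path, index=False)
    else:
        df.to_csv(path, sep="\t", index=False)


def write_rejects(rejects: list[RejectedRow], path: str | Path) -> None:
    pd.DataFrame([{"row": r.row, "reason": r.reason} for r in rejects]).to_csv(
        path, sep="\t", index=False
    )


def read_cell_meta(path: str | Path) -> list[CellMeta]:
    """Read a per-cell metadata table (TSV or CSV; barcode + sample_id required)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in ("barcode", "sample_id") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    dup = df.duplicated(subset=["barcode", "sample_id"], keep=False)
    if dup.any():
        offenders = sorted(df.loc[dup, "barcode"].unique())
        raise FormatError(
            f"{path}: duplicate (barcode, sample_id) keys for barcodes {offenders}"
        )
    return [
        CellMeta(
            barcode=row["barcode"],
            sample_id=row["sample_id"],
            disease=str(row.get("disease", "") or ""),
            phenotype=str(row.get("phenotype", "") or ""),
        )
        for _, row in df.iterrows()
    ]


def write_cell_meta(meta: list[CellMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"barcode": m.barcode, "sample_id": m.sample_id,
             "disease": m.disease, "phenotype": m.phenotype}
            for m in meta
        ]
    ).to_csv(path, sep="\t", index=False)


def read_germline_fasta(path: str | Path) -> list[GermlineSegment]:
    """Read a germline V-segment FASTA; the first header token is the gene name."""
    segments: list[GermlineSegment] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        if gene in seen:
            raise FormatError(f"{path}: duplicate gene name {gene!r}")
        seen.add(gene)
        segments.append(GermlineSegment(gene=gene, sequence_nt=str(rec.seq).upper()))
    if not segments:
        logger.warning("%s: empty germline FASTA", path)
    return segments


def write_germline_fasta(segments: list[GermlineSegment], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s.sequence_nt), id=s.gene, description="") for s in segments],
        str(path),
        "fasta",
    )
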