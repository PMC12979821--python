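"""Somatic hypermutation quantification against a germline V reference.

SHM is reported per contig as ``1 - identity in the variable region``: the
contig's nucleotide sequence is globally aligned to the germline V segment its
``v_call`` names (match +1, mismatch -1, gap open 5, gap extend 2) and identity
is the number of identical aligned bases divided by the number of germline
(non-gap reference) positions. Sequence 3' of the V segment — junction, J and
constant-region bases — aligns against reference gaps and does not enter the
denominator, so the statistic covers the V gene only, matching how V identity
is conventionally reported by V(D)J annotation tools. When an upstream
annotator has already computed ``v_identity`` (AIRR column), that value can be
ingested directly instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentParams, global_align, nucleotide_matrix
from .types import ContigRecord, GermlineSegment, ShmEstimate, strip_allele

logger = logging.getLogger(__name__)

NT_PARAMS = AlignmentParams(matrix="NT", gap_open=5.0, gap_extend=2.0)
_NT_MATRIX = nucleotide_matrix(match=1, mismatch=-1)


def v_region_identity(contig: ContigRecord, germline: GermlineSegment) -> float:
    """Identity of the contig's V region to the germline V segment, in [0, 1].

    Identity = identical aligned bases / germline length (reference positions
    deleted in the read count against identity via the denominator).
    """
    if not contig.sequence_nt or not germline.sequence_nt:
        raise ValueError(
            f"contig {contig.contig_id}: empty sequence for V-identity computation"
        )
    res = global_align(
        germline.sequence_nt, contig.sequence_nt, NT_PARAMS, matrix=_NT_MATRIX
    )
    n_ref = len(germline.sequence_nt)
    return res.n_match / n_ref


@dataclass
class ShmResult:
    estimates: list[ShmEstimate]
    n_skipped: int = 0
    skipped_v_calls: list[str] = field(default_factory=list)


def estimate_shm(
    contigs: list[ContigRecord],
    germline: list[GermlineSegment],
    assignment: dict[str, str] | None = None,
) -> ShmResult:
    """Per-contig SHM estimates for every contig whose v_call resolves.

    ``assignment`` maps barcode -> clonotype_id (used downstream to split the
    top clone from polyclonal cells). Contigs with an unresolvable v_call are
    skipped with a warning and counted, not raised.
    """
    by_gene = {g.gene: g for g in germline}
    # tolerate allele-suffixed calls against an allele-less reference
    by_gene_stripped = {strip_allele(g.gene): g for g in germline}
    out = ShmResult(estimates=[])
    for contig in contigs:
        seg = by_gene.get(contig.v_call) or by_gene_stripped.get(
            strip_allele(contig.v_call)
        )
        if seg is None or not contig.sequence_nt:
            out.n_skipped += 1
            out.skipped_v_calls.append(contig.v_call)
            continue
        ident = v_region_identity(contig, seg)
        out.estimates.append(
            ShmEstimate(
                contig_id=contig.contig_id,
                barcode=contig.barcode,
                sample_id=contig.sample_id,
                v_call=contig.v_call,
                v_identity=ident,
                clonotype_id=(assignment or {}).get(contig.barcode, ""),
            )
        )
    if out.n_skipped:
        logger.warning(
            "SHM: skipped %d contig(s) with unresolvable v_call (e.g. %s)",
            out.n_skipped, sorted(set(out.skipped_v_calls))[:5],
        )
    return out


def shm_table(result: ShmResult, top_clone_ids: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-contig SHM table with a top-clone/polyclonal compartment label."""
    top_clone_ids = top_clone_ids or {}
    rows = []
    for e in result.estimates:
        comp = (
            "top_clone"
            if e.clonotype_id and e.clonotype_id == top_clone_ids.get(e.sample_id)
            else "polyclonal"
        )
        rows.append(dict(
            contig_id=e.contig_id, barcode=e.barcode, sample_id=e.sample_id,
            v_call=e.v_call, v_identity=e.v_identity, shm=e.shm,
            clonotype_id=e.clonotype_id, compartment=comp,
        ))
    return pd.DataFrame(rows)


def shm_by_group(
    result: ShmResult, top_clone_ids: dict[str, str]
) -> pd.DataFrame:
    """Per-sample, per-compartment SHM summary (top clone vs polyclonal).

    Returns one row per (sample_id, compartment) with n, median, quartiles,
    min and max of the per-contig SHM values.
    """
    table = shm_table(result, top_clone_ids)
    if table.empty:
        return pd.DataFrame(
            columns=["sample_id", "compartment", "n", "median", "q1", "q3",
                     "min", "max"]
        )
    rows = []
    for (sample_id, comp), grp in table.groupby(["sample_id", "compartment"]):
        v = grp["shm"].to_numpy()
        rows.append(dict(
            sample_id=sample_id, compartment=comp, n=len(v),
            median=float(np.median(v)),
            q1=float(np.quantile(v, 0.25)), q3=float(np.quantile(v, 0.75)),
            min=float(v.min()), max=float(v.max()),
        ))
    return pd.DataFrame(rows)
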