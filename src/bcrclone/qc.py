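"""Cell- and clone-level BCR quality filters.

Cells with more than two contigs, or with multiple contigs of the same chain
class (heavy = IGH; light = IGK or IGL, so a kappa+lambda cell counts as a
duplicate light chain), are removed. The >2-contigs rule is checked first, so
a 3-contig cell is always labelled ``removed_gt2_contigs``. Exactly-two-contig
cells with one heavy and one light chain pass, as do single-chain cells (the
clonotype merging step depends on them surviving).

Clone-level: clonotypes whose member cells jointly define more than two
distinct CDR3 sequences are removed after merging.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .types import CellBcr, Clonotype, ContigRecord, QcStatus

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Per-sample QC partition counts; every input cell is in exactly one class."""

    counts: dict[str, dict[QcStatus, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sample, by_status in sorted(self.counts.items()):
            n_pass = by_status.get(QcStatus.PASS, 0)
            n_gt2 = by_status.get(QcStatus.REMOVED_GT2_CONTIGS, 0)
            n_dup = by_status.get(QcStatus.REMOVED_DUP_CHAIN, 0)
            rows.append(
                dict(sample_id=sample, n_input_cells=n_pass + n_gt2 + n_dup,
                     n_pass=n_pass, n_removed_gt2=n_gt2, n_removed_dup_chain=n_dup)
            )
        return pd.DataFrame(rows)


def filter_cells(
    contigs: list[ContigRecord],
    require_productive: bool = True,
    kappa_lambda_duplicate: bool = True,
) -> tuple[list[CellBcr], QcReport]:
    """Group contigs by cell and apply the per-cell contig-count/chain filters.

    ``require_productive`` drops non-productive contigs before grouping (the
    default for clonotyping). With ``kappa_lambda_duplicate`` (default), IGK and
    IGL contigs in one cell count as duplicate light chains; if disabled, only
    two contigs of the same locus are duplicates.
    """
    if require_productive:
        contigs = [c for c in contigs if c.productive]
    by_cell: dict[tuple[str, str], list[ContigRecord]] = defaultdict(list)
    for c in contigs:
        by_cell[(c.sample_id, c.barcode)].append(c)

    cells: list[CellBcr] = []
    report = QcReport()
    for (sample_id, barcode), cell_contigs in sorted(by_cell.items()):
        status = _classify(cell_contigs, kappa_lambda_duplicate)
        heavy = light = None
        if status is QcStatus.PASS:
            for c in cell_contigs:
                if c.chain.is_heavy:
                    heavy = c
                else:
                    light = c
        cells.append(
            CellBcr(
                barcode=barcode, sample_id=sample_id, qc_status=status,
                heavy=heavy, light=light, raw_contigs=tuple(cell_contigs),
            )
        )
        report.counts.setdefault(sample_id, defaultdict(int))[status] += 1
    return cells, report


def _classify(cell_contigs: list[ContigRecord], kappa_lambda_duplicate: bool) -> QcStatus:
    if len(cell_contigs) > 2:
        return QcStatus.REMOVED_GT2_CONTIGS
    if kappa_lambda_duplicate:
        keys = ["heavy" if c.chain.is_heavy else "light" for c in cell_contigs]
    else:
        keys = [c.chain.value for c in cell_contigs]
    if len(keys) != len(set(keys)):
        return QcStatus.REMOVED_DUP_CHAIN
    return QcStatus.PASS


def passing_cells(cells: list[CellBcr]) -> list[CellBcr]:
    return [c for c in cells if c.qc_status is QcStatus.PASS]


def clone_cdr3_chain_count(
    clonotype: Clonotype, identity_min: float = 0.85, params=None
) -> int:
    """Number of distinct CDR3 chains a clonotype's members jointly define.

    Within a chain class, CDR3s reaching ``identity_min`` pairwise identity are
    hypermutated variants of one chain and count once (the same criterion the
    merging rule uses); CDR3s below it are genuinely different chains. Greedy
    single-linkage against sorted representatives keeps this deterministic.
    """
    from .align import AlignmentParams, cdr3_identity

    if params is None:
        params = AlignmentParams()
    n_chains = 0
    by_class: dict[str, set[str]] = defaultdict(set)
    for chain_class, cdr3 in clonotype.distinct_cdr3s():
        by_class[chain_class].add(cdr3)
    for cdr3s in by_class.values():
        reps: list[str] = []
        for cdr3 in sorted(cdr3s):
            if not any(cdr3_identity(cdr3, r, params) >= identity_min for r in reps):
                reps.append(cdr3)
        n_chains += len(reps)
    return n_chains


def filter_clone_chain_count(
    clonotypes: list[Clonotype],
    max_cdr3_chains: int = 2,
    identity_min: float = 0.85,
    params=None,
) -> tuple[list[Clonotype], list[Clonotype]]:
    """Remove clonotypes that jointly define more than ``max_cdr3_chains``
    distinct CDR3 chains (see :func:`clone_cdr3_chain_count`).

    Returns (retained, removed). A well-formed clone defines at most two
    chains (one heavy, one light); more indicates a chimeric merge or doublet
    leakage.
    """
    retained, removed = [], []
    for ct in clonotypes:
        if clone_cdr3_chain_count(ct, identity_min, params) > max_cdr3_chains:
            removed.append(ct)
        else:
            retained.append(ct)
    if removed:
        logger.info(
            "clone chain-count filter removed %d clonotype(s): %s",
            len(removed), [ct.clonotype_id for ct in removed],
        )
    return retained, removed
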