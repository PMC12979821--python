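"""Clonotype construction and identity-based rescue of partial clonotypes.

Cells are first grouped into clonotypes by exact chain-signature equality
(locus, V/J/C calls and CDR3 amino-acid sequence, for each recovered chain).
Chain dropout in single-cell V(D)J data then leaves fragments of one biological
clone split across a paired clonotype and single-chain clonotypes.

The merging rule repairs this for the dominant clones only: for each of the two
most frequent clonotypes that carries a single chain signature (the "evaluated
clonotype"), fully-paired clonotypes are merged with it when, on the chain they
share, all cells carry the same V, C and J genes and their CDR3 shows at least
85% identity to the evaluated clonotype's reference CDR3 under global alignment
(BLOSUM100, gap open 10, gap extend 4). Ranking is recomputed after each merge
so that, e.g., a light-only fragment can be evaluated once the heavy-only
fragment has been absorbed. Merging never crosses samples.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import pandas as pd

from .align import AlignmentParams, cdr3_identity
from .qc import filter_clone_chain_count
from .types import CellBcr, ChainSignature, Clonotype

logger = logging.getLogger(__name__)

# how many of the most frequent clonotypes are evaluated for rescue
N_TOP_EVALUATED = 2


def build_clonotypes(cells: list[CellBcr], sample_id: str | None = None) -> list[Clonotype]:
    """Group QC-passed cells by exact (heavy, light) chain-signature pair.

    Single-chain cells group by their single signature. Returned clonotypes are
    ranked by size descending (ties by total UMIs, then id).
    """
    if sample_id is not None:
        cells = [c for c in cells if c.sample_id == sample_id]
    groups: dict[tuple, list[CellBcr]] = defaultdict(list)
    for cell in cells:
        hsig = ChainSignature.from_contig(cell.heavy) if cell.heavy else None
        lsig = ChainSignature.from_contig(cell.light) if cell.light else None
        if hsig is None and lsig is None:
            continue
        groups[(cell.sample_id, hsig, lsig)].append(cell)

    clonotypes = []
    for n, ((sid, hsig, lsig), members) in enumerate(sorted(
        groups.items(),
        key=lambda kv: (-len(kv[1]), -sum(c.umis for c in kv[1]), str(kv[0])),
    )):
        clonotypes.append(
            Clonotype(
                clonotype_id=f"{sid}_clonotype{n + 1}",
                sample_id=sid, heavy_sig=hsig, light_sig=lsig, members=list(members),
            )
        )
    return rank_clonotypes(clonotypes)


def rank_clonotypes(clonotypes: list[Clonotype]) -> list[Clonotype]:
    """Sort by size descending; ties by total member UMIs, then lexicographic id."""
    return sorted(
        clonotypes, key=lambda ct: (-ct.size, -ct.total_umis, ct.clonotype_id)
    )


def top_clone(clonotypes: list[Clonotype]) -> Clonotype:
    """The largest clonotype (documented tie-break: UMIs, then id)."""
    if not clonotypes:
        raise ValueError("top_clone requires a non-empty clonotype collection")
    return rank_clonotypes(clonotypes)[0]


def _genes_match(a: ChainSignature, b: ChainSignature) -> bool:
    # V, C and J genes; D is deliberately not part of the clause
    return (
        a.chain.is_heavy == b.chain.is_heavy
        and a.v_call == b.v_call
        and a.j_call == b.j_call
        and a.c_call == b.c_call
    )


def _mergeable(
    evaluated: Clonotype,
    candidate: Clonotype,
    params: AlignmentParams,
    identity_min: float,
) -> bool:
    """Does ``candidate`` (fully paired) belong to the evaluated single-chain clone?

    Gene equality and CDR3 identity are tested on every chain present on both
    sides; for a single-chain evaluated clone that is exactly its one chain.
    Because members of a clonotype share an exact signature, the all-cells
    quantifier reduces to a single signature-level comparison.
    """
    pairs = []
    if evaluated.heavy_sig is not None and candidate.heavy_sig is not None:
        pairs.append((evaluated.heavy_sig, candidate.heavy_sig))
    if evaluated.light_sig is not None and candidate.light_sig is not None:
        pairs.append((evaluated.light_sig, candidate.light_sig))
    if not pairs:
        return False
    for ref, cand in pairs:
        if not _genes_match(ref, cand):
            return False
        if cdr3_identity(ref.cdr3_aa, cand.cdr3_aa, params) < identity_min:
            return False
    return True


def merge_partial_clones(
    clonotypes: list[Clonotype],
    params: AlignmentParams | None = None,
    identity_min: float = 0.85,
    apply_chain_count_filter: bool = True,
) -> list[Clonotype]:
    """Rescue single-chain clonotypes among the two most frequent clones.

    For each sample independently: while one of the two most frequent
    clonotypes has only a single chain signature (and has not been evaluated
    yet), absorb every fully-paired clonotype that matches it on V/C/J genes
    and reaches ``identity_min`` CDR3 identity on the shared chain; re-rank and
    repeat, evaluating at most two clonotypes. The merged clonotype adopts the
    missing chain signature from its largest absorbed partner and records
    provenance in ``merged_from``. The clone-level chain-count filter runs
    afterwards unless disabled.
    """
    if params is None:
        params = AlignmentParams()
    if not (0.0 < identity_min <= 1.0):
        raise ValueError(f"identity_min must be in (0, 1], got {identity_min}")

    by_sample: dict[str, list[Clonotype]] = defaultdict(list)
    for ct in clonotypes:
        by_sample[ct.sample_id].append(ct)

    merged_all: list[Clonotype] = []
    for sample_id in sorted(by_sample):
        merged_all.extend(
            _merge_sample(by_sample[sample_id], params, identity_min)
        )
    if apply_chain_count_filter:
        merged_all, _removed = filter_clone_chain_count(
            merged_all, identity_min=identity_min, params=params
        )
    return rank_clonotypes(merged_all)


def _merge_sample(
    clonotypes: list[Clonotype], params: AlignmentParams, identity_min: float
) -> list[Clonotype]:
    pool = list(clonotypes)
    evaluated_budget = N_TOP_EVALUATED
    evaluated_ids: set[str] = set()
    while evaluated_budget > 0:
        pool = rank_clonotypes(pool)
        target = next(
            (
                ct for ct in pool[:N_TOP_EVALUATED]
                if ct.is_single_chain and ct.clonotype_id not in evaluated_ids
            ),
            None,
        )
        if target is None:
            break
        evaluated_ids.add(target.clonotype_id)
        evaluated_budget -= 1
        partners = [
            ct for ct in pool
            if ct is not target and ct.is_paired
            and _mergeable(target, ct, params, identity_min)
        ]
        if not partners:
            continue
        partners.sort(key=lambda ct: (-ct.size, ct.clonotype_id))
        for partner in partners:
            target.members.extend(partner.members)
            target.merged_from.append(partner.clonotype_id)
            target.merged_from.extend(partner.merged_from)
            if target.heavy_sig is None and partner.heavy_sig is not None:
                target.heavy_sig = partner.heavy_sig
            if target.light_sig is None and partner.light_sig is not None:
                target.light_sig = partner.light_sig
            pool.remove(partner)
        logger.info(
            "sample %s: merged %d clonotype(s) into %s (size now %d)",
            target.sample_id, len(partners), target.clonotype_id, target.size,
        )
    return pool


def clonotype_table(clonotypes: list[Clonotype]) -> pd.DataFrame:
    """Flat per-clonotype summary table."""
    rows = []
    for ct in rank_clonotypes(clonotypes):
        rows.append(dict(
            clonotype_id=ct.clonotype_id,
            sample_id=ct.sample_id,
            size=ct.size,
            heavy_v=ct.heavy_sig.v_call if ct.heavy_sig else "",
            heavy_j=ct.heavy_sig.j_call if ct.heavy_sig else "",
            heavy_c=ct.heavy_sig.c_call if ct.heavy_sig else "",
            heavy_cdr3=ct.heavy_sig.cdr3_aa if ct.heavy_sig else "",
            light_v=ct.light_sig.v_call if ct.light_sig else "",
            light_j=ct.light_sig.j_call if ct.light_sig else "",
            light_c=ct.light_sig.c_call if ct.light_sig else "",
            light_cdr3=ct.light_sig.cdr3_aa if ct.light_sig else "",
            merged_from=";".join(ct.merged_from),
        ))
    return pd.DataFrame(rows)


def cell_assignment(clonotypes: list[Clonotype]) -> pd.DataFrame:
    """Per-cell clone assignment table (barcode -> clonotype_id)."""
    rows = []
    for ct in clonotypes:
        for cell in ct.members:
            rows.append(dict(
                barcode=cell.barcode, sample_id=cell.sample_id,
                clonotype_id=ct.clonotype_id,
            ))
    return pd.DataFrame(rows)
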