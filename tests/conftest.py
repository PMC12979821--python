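from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bcrclone.types import CellMeta, Chain, ContigRecord


def make_contig(
    barcode: str,
    chain: Chain = Chain.IGH,
    sample_id: str = "s1",
    cdr3_aa: str = "CARDYW",
    v_call: str = "IGHV1-1",
    j_call: str = "IGHJ1",
    c_call: str = "IGHM",
    umis: int = 5,
    suffix: int = 1,
    **kwargs,
) -> ContigRecord:
    return ContigRecord(
        contig_id=f"{barcode}_contig_{suffix}",
        barcode=barcode,
        sample_id=sample_id,
        chain=chain,
        v_call=v_call,
        j_call=j_call,
        c_call=c_call,
        cdr3_aa=cdr3_aa,
        umis=umis,
        **kwargs,
    )


def light_contig(barcode: str, chain: Chain = Chain.IGK, cdr3_aa: str = "CQQSYF",
                 **kwargs) -> ContigRecord:
    kwargs.setdefault("v_call", "IGKV1-1")
    kwargs.setdefault("j_call", "IGKJ1")
    kwargs.setdefault("c_call", "IGKC")
    kwargs.setdefault("suffix", 2)
    return make_contig(barcode, chain=chain, cdr3_aa=cdr3_aa, **kwargs)


@pytest.fixture
def paired_cell_contigs():
    """One canonical IGH+IGK cell."""
    return [make_contig("AAAC-1"), light_contig("AAAC-1")]


def brute_force_score(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Independent alignment oracle: exhaustive enumeration of all global
    alignments with affine gap runs (run of length l costs open + ext*(l-1)).

    Exponential; only usable for short sequences.
    """
    best = [float("-inf")]

    def rec(i: int, j: int, score: float, prev_gap: str | None) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + score_fn(a[i], b[j]), None)
        if i < len(a):
            cost = gap_extend if prev_gap == "b" else gap_open
            rec(i + 1, j, score - cost, "b")
        if j < len(b):
            cost = gap_extend if prev_gap == "a" else gap_open
            rec(i, j + 1, score - cost, "a")

    rec(0, 0, 0.0, None)
    return best[0]


def all_seq_pairs(alphabet: str, max_len: int):
    """All ordered sequence pairs with lengths 1..max_len over alphabet."""
    seqs = [
        "".join(t)
        for n in range(1, max_len + 1)
        for t in itertools.product(alphabet, repeat=n)
    ]
    return itertools.product(seqs, seqs)


@pytest.fixture
def meta_two_samples():
    return [
        CellMeta("AAAC-1", "s1", disease="pcFCL", phenotype="GC LZ"),
        CellMeta("AAAG-1", "s1", disease="pcFCL", phenotype="GC DZ"),
        CellMeta("AAAT-1", "s2", disease="pcMZL", phenotype="plasma cell"),
    ]
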