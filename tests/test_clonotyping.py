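"""Clonotype construction, top-clone selection, and partial-clone merging."""

from __future__ import annotations

import pytest

from bcrclone.clonotyping import (
    build_clonotypes,
    cell_assignment,
    merge_partial_clones,
    top_clone,
)
from bcrclone.qc import filter_cells, passing_cells
from bcrclone.simulate import SimulationConfig, simulate_sample
from bcrclone.types import Chain

from conftest import light_contig, make_contig


def cells_from(contigs):
    cells, _ = filter_cells(contigs)
    return passing_cells(cells)


def paired_cells(n, cdr3_h="CARDYWGQGTLVTVSSASTW", cdr3_l="CQQSYF", prefix="P",
                 umis=5, **kw):
    contigs = []
    for i in range(n):
        bc = f"{prefix}{i}-1"
        contigs.append(make_contig(bc, cdr3_aa=cdr3_h, umis=umis, **kw))
        contigs.append(light_contig(bc, cdr3_aa=cdr3_l, umis=umis))
    return contigs


class TestBuildClonotypes:
    def test_identical_cells_one_clonotype(self):
        cts = build_clonotypes(cells_from(paired_cells(5)))
        assert len(cts) == 1 and cts[0].size == 5

    def test_one_residue_difference_two_clonotypes(self):
        contigs = paired_cells(1, prefix="A") + paired_cells(
            1, cdr3_h="CARDYWGQGTLVTVSSASTF", prefix="B"
        )
        cts = build_clonotypes(cells_from(contigs))
        assert len(cts) == 2

    def test_class_switch_splits_clonotype(self):
        contigs = paired_cells(2, prefix="A", c_call="IGHM") + paired_cells(
            2, prefix="B", c_call="IGHG1"
        )
        assert len(build_clonotypes(cells_from(contigs))) == 2

    def test_allele_stripping_in_signature(self):
        contigs = paired_cells(1, prefix="A", c_call="IGHG1*01") + paired_cells(
            1, prefix="B", c_call="IGHG1*02"
        )
        assert len(build_clonotypes(cells_from(contigs))) == 1

    def test_planted_partition_recovered_without_dropout(self):
        sample = simulate_sample(SimulationConfig(
            seed=11, n_cells=300, top_clone_fraction=0.3,
            chain_dropout_rate=0.0, doublet_rate=0.0,
        ))
        cts = build_clonotypes(cells_from(sample.contigs))
        got = {
            frozenset(ct.member_barcodes) for ct in cts
        }
        truth_groups: dict[str, set[str]] = {}
        for bc, cid in sample.truth.partition.items():
            truth_groups.setdefault(cid, set()).add(bc)
        assert got == {frozenset(v) for v in truth_groups.values()}


class TestTopClone:
    def test_largest_wins(self):
        contigs = paired_cells(10, prefix="A") + paired_cells(
            3, cdr3_h="CQRDYWGQGTLVTVSSASTW", prefix="B"
        )
        cts = build_clonotypes(cells_from(contigs))
        assert top_clone(cts).size == 10

    def test_umi_tie_break(self):
        contigs = paired_cells(5, prefix="A", umis=4) + paired_cells(
            5, cdr3_h="CQRDYWGQGTLVTVSSASTW", prefix="B", umis=6
        )
        cts = build_clonotypes(cells_from(contigs))
        winner = top_clone(cts)
        assert winner.heavy_sig.cdr3_aa == "CQRDYWGQGTLVTVSSASTW"

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            top_clone([])


def mutate(cdr3: str, k: int) -> str:
    """Substitute the first k positions after the anchor with a fixed partner."""
    sub = {"A": "S", "R": "K", "D": "E", "Y": "F", "W": "F", "G": "A",
           "Q": "E", "T": "S", "L": "I", "V": "I", "S": "T", "C": "S"}
    out = list(cdr3)
    for i in range(1, k + 1):
        out[i] = sub[cdr3[i]]
    return "".join(out)


def merge_fixture(identity_k: int, n_single=8, n_paired=20):
    """A heavy-only clone in the top-2 plus a paired clone whose heavy CDR3
    differs by identity_k substitutions (identity (20-k)/20)."""
    cdr3_h = "CARDYWGQGTLVTVSSASTW"
    single = [make_contig(f"S{i}-1", cdr3_aa=cdr3_h) for i in range(n_single)]
    paired = paired_cells(n_paired, cdr3_h=mutate(cdr3_h, identity_k), prefix="Q")
    return cells_from(single + paired)


class TestMergePartialClones:
    def test_merge_at_identity_090(self):
        cts = merge_partial_clones(build_clonotypes(merge_fixture(2)))
        assert len(cts) == 1
        assert cts[0].size == 28
        assert cts[0].merged_from

    def test_no_merge_at_identity_080(self):
        cts = merge_partial_clones(build_clonotypes(merge_fixture(4)))
        assert sorted(ct.size for ct in cts) == [8, 20]

    def test_boundary_085_inclusive(self):
        cts = merge_partial_clones(build_clonotypes(merge_fixture(3)))
        assert len(cts) == 1 and cts[0].size == 28

    def test_class_switched_candidate_not_merged(self):
        cdr3_h = "CARDYWGQGTLVTVSSASTW"
        single = [make_contig(f"S{i}-1", cdr3_aa=cdr3_h, c_call="IGHM")
                  for i in range(8)]
        paired = paired_cells(20, cdr3_h=mutate(cdr3_h, 2), prefix="Q",
                              c_call="IGHG1")
        cts = merge_partial_clones(build_clonotypes(cells_from(single + paired)))
        assert sorted(ct.size for ct in cts) == [8, 20]

    def test_conservation_and_monotonicity(self):
        before = build_clonotypes(merge_fixture(2))
        top_before = top_clone(before).size
        n_before = sum(ct.size for ct in before)
        after = merge_partial_clones(before)
        assert sum(ct.size for ct in after) == n_before
        assert top_clone(after).size >= top_before

    def test_rank3_single_chain_not_evaluated(self):
        # the single-chain clone must be among the two most frequent
        cdr3_h = "CARDYWGQGTLVTVSSASTW"
        single = [make_contig(f"S{i}-1", cdr3_aa=cdr3_h) for i in range(2)]
        big_a = paired_cells(20, cdr3_h=mutate(cdr3_h, 2), prefix="Q")
        big_b = paired_cells(10, cdr3_h="CWWDYWGQGTLVTVSSASTW", prefix="R",
                             v_call="IGHV9-9")
        cts = merge_partial_clones(build_clonotypes(cells_from(
            single + big_a + big_b
        )))
        assert sorted(ct.size for ct in cts) == [2, 10, 20]

    def test_merging_never_crosses_samples(self):
        cdr3_h = "CARDYWGQGTLVTVSSASTW"
        single = [make_contig(f"S{i}-1", cdr3_aa=cdr3_h, sample_id="s1")
                  for i in range(5)]
        paired = []
        for i in range(9):
            bc = f"Q{i}-1"
            paired.append(make_contig(bc, cdr3_aa=cdr3_h, sample_id="s2"))
            paired.append(light_contig(bc, sample_id="s2"))
        cts = merge_partial_clones(build_clonotypes(cells_from(single + paired)))
        assert sorted(ct.size for ct in cts) == [5, 9]

    def test_invalid_identity_min(self):
        with pytest.raises(ValueError, match="identity_min"):
            merge_partial_clones([], identity_min=1.5)

    def test_dropout_lineage_rescued(self):
        """With 20% dropout the merged top clone recovers >=95% of the
        planted lineage."""
        sample = simulate_sample(SimulationConfig(
            seed=17, n_cells=800, top_clone_fraction=0.4,
            chain_dropout_rate=0.2, doublet_rate=0.0,
        ))
        cts = merge_partial_clones(build_clonotypes(cells_from(sample.contigs)))
        top = top_clone(cts)
        lineage = {bc for bc, cid in sample.truth.partition.items()
                   if cid == "clone_top"}
        assert len(top.member_barcodes & lineage) >= 0.95 * len(lineage)

    def test_assignment_table_covers_all_members(self):
        cts = merge_partial_clones(build_clonotypes(merge_fixture(2)))
        table = cell_assignment(cts)
        assert len(table) == sum(ct.size for ct in cts)
        assert table["clonotype_id"].nunique() == len(cts)
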