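"""Expansion fractions, phenotype composition, Shannon entropy, group tests."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrclone.clonotyping import build_clonotypes, top_clone
from bcrclone.qc import filter_cells, passing_cells
from bcrclone.simulate import SimulationConfig, simulate_sample
from bcrclone.stats import (
    benjamini_hochberg,
    compare_groups,
    expansion_fraction,
    phenotype_composition,
    shannon_entropy,
)
from bcrclone.types import CellMeta

from conftest import light_contig, make_contig


def clone_of(n, prefix="A", sample_id="s1"):
    contigs = []
    for i in range(n):
        bc = f"{prefix}{i}-1"
        contigs.append(make_contig(bc, sample_id=sample_id))
        contigs.append(light_contig(bc, sample_id=sample_id))
    cells, _ = filter_cells(contigs)
    return top_clone(build_clonotypes(passing_cells(cells)))


class TestExpansionFraction:
    def test_forty_of_thousand(self):
        assert expansion_fraction(clone_of(40), 1000) == pytest.approx(0.04)

    def test_all_cells_one_clone(self):
        assert expansion_fraction(clone_of(12), 12) == 1.0

    def test_inconsistent_denominator(self):
        with pytest.raises(ValueError, match="inconsistent"):
            expansion_fraction(clone_of(10), 5)

    def test_planted_fraction_exact_without_dropout(self):
        sample = simulate_sample(SimulationConfig(
            seed=31, n_cells=2000, top_clone_fraction=0.52,
            chain_dropout_rate=0.0, doublet_rate=0.0,
        ))
        cells, _ = filter_cells(sample.contigs)
        top = top_clone(build_clonotypes(passing_cells(cells)))
        assert expansion_fraction(top, len(sample.meta)) == pytest.approx(0.52)


class TestPhenotypeComposition:
    def test_single_phenotype(self):
        top = clone_of(10)
        meta = {f"A{i}-1": "GC LZ" for i in range(10)}
        assert phenotype_composition(top, meta) == {"GC LZ": 1.0}

    def test_mixture(self):
        top = clone_of(10)
        meta = {f"A{i}-1": ("plasma cell" if i < 6 else "memory B")
                for i in range(10)}
        comp = phenotype_composition(top, meta)
        assert comp == {"memory B": 0.4, "plasma cell": 0.6}

    def test_unresolvable_barcode_unlabelled(self):
        top = clone_of(4)
        comp = phenotype_composition(top, {"A0-1": "naive B"})
        assert comp == {"naive B": 0.25, "unlabelled": 0.75}

    def test_meta_list_filtered_by_sample(self):
        top = clone_of(2)
        meta = [
            CellMeta("A0-1", "s1", phenotype="GC LZ"),
            CellMeta("A1-1", "s1", phenotype="GC LZ"),
            CellMeta("A0-1", "s2", phenotype="plasma cell"),
        ]
        assert phenotype_composition(top, meta) == {"GC LZ": 1.0}


class TestShannonEntropy:
    def test_single_category_zero(self):
        assert shannon_entropy({"a": 1.0}) == 0.0

    def test_uniform_is_ln_k(self):
        comp = {c: 0.25 for c in "abcd"}
        assert shannon_entropy(comp) == pytest.approx(math.log(4))

    def test_half_quarter_quarter(self):
        assert shannon_entropy({"a": 0.5, "b": 0.25, "c": 0.25}) == pytest.approx(
            1.5 * math.log(2)
        )

    def test_base2(self):
        comp = {c: 0.25 for c in "abcd"}
        assert shannon_entropy(comp, base=2) == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            shannon_entropy({"a": -0.1, "b": 1.1})

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    def test_permutation_invariance_and_uniform_maximum(self, weights):
        p = np.array(weights) / sum(weights)
        comp = {str(i): float(x) for i, x in enumerate(p)}
        h = shannon_entropy(comp)
        shuffled = dict(reversed(list(comp.items())))
        assert shannon_entropy(shuffled) == pytest.approx(h)
        assert h <= math.log(len(p)) + 1e-12


class TestCompareGroups:
    def frame(self, groups: dict[str, list[float]]) -> pd.DataFrame:
        rows = [
            {"disease": g, "value": v} for g, vs in groups.items() for v in vs
        ]
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        res = compare_groups(self.frame({
            "a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0],
        }))
        assert len(res) == 1
        assert res[0].p_value == pytest.approx(1.0, abs=0.05)
        assert res[0].p_adjusted >= res[0].p_value

    def test_separated_groups_exact_p(self):
        """Fully separated groups of sizes 4 and 5: the exact two-sided
        rank-sum p is 2 / C(9,4), by enumeration of rank assignments."""
        res = compare_groups(self.frame({
            "low": [1.0, 2.0, 3.0, 4.0],
            "high": [10.0, 11.0, 12.0, 13.0, 14.0],
        }))
        assert res[0].p_value == pytest.approx(2 / math.comb(9, 4))

    def test_small_group_skipped(self, caplog):
        res = compare_groups(self.frame({
            "a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "tiny": [9.0],
        }))
        assert {(c.group_a, c.group_b) for c in res} == {("a", "b")}

    def test_reference_mode(self):
        res = compare_groups(
            self.frame({
                "ref": [1.0, 2.0, 3.0], "a": [4.0, 5.0, 6.0],
                "b": [1.5, 2.5, 3.5],
            }),
            reference="ref",
        )
        assert {(c.group_a, c.group_b) for c in res} == {("a", "ref"), ("b", "ref")}


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        # step-up: p_(i) * m / i, cumulative min from the largest
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )
        assert benjamini_hochberg([0.01, 0.04, 0.03, 0.02]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )
        assert benjamini_hochberg([0.001, 0.1, 0.9]) == pytest.approx(
            [0.003, 0.15, 0.9]
        )

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10))
    def test_monotone_and_bounded(self, ps):
        adj = benjamini_hochberg(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        assert all(a <= 1.0 + 1e-12 for a in adj)
        order = np.argsort(ps)
        sorted_adj = np.array(adj)[order]
        assert (np.diff(sorted_adj) >= -1e-12).all()
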