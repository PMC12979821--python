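"""Clonal-expansion fractions, infiltrate diversity, and group comparisons.

The expansion fraction of a sample is the size of its most frequent clonotype
divided by the total number of B cells (all B-lineage cells from metadata when
available, otherwise all QC-passed cells with a productive BCR). Composition
diversity is Shannon entropy in natural-log units. Disease groups are compared
with two-sided Wilcoxon rank-sum tests (exact for small samples without ties),
Benjamini-Hochberg adjusted across the family of comparisons.
"""

from __future__ import annotations

import logging
import math
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import CellMeta, Clonotype, GroupComparison

logger = logging.getLogger(__name__)


def expansion_fraction(top: Clonotype, n_b_cells: int) -> float:
    """Size of the top clone over the total number of B cells in the sample."""
    if top.size <= 0:
        raise ValueError("top clonotype is empty")
    if n_b_cells < top.size:
        raise ValueError(
            f"inconsistent denominator: n_b_cells={n_b_cells} < top clone "
            f"size {top.size}"
        )
    return top.size / n_b_cells


def phenotype_composition(
    top: Clonotype, meta: list[CellMeta] | dict[str, str]
) -> dict[str, float]:
    """Phenotype frequency vector over the member cells of a clonotype.

    Cells whose barcode is not in the metadata are counted as ``unlabelled``.
    """
    if isinstance(meta, dict):
        lookup = meta
    else:
        lookup = {m.barcode: m.phenotype for m in meta if m.sample_id == top.sample_id}
    counts = Counter(
        lookup.get(cell.barcode) or "unlabelled" for cell in top.members
    )
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}


def shannon_entropy(composition: dict[str, float], base: float | None = None) -> float:
    """Shannon entropy H = -sum p ln p of a composition (natural log by default).

    Zero-probability categories contribute nothing; H is 0 for a single
    category and ln(k) for a uniform composition over k categories.
    """
    p = np.asarray(list(composition.values()), dtype=float)
    if (p < 0).any():
        raise ValueError("composition fractions must be non-negative")
    total = p.sum()
    if total <= 0:
        return 0.0
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        logger.warning("composition sums to %.6f; renormalising", total)
    h = float(sps.entropy(p))  # scipy normalises and uses natural log
    if base is not None:
        h /= math.log(base)
    return h


def compare_groups(
    values: pd.DataFrame,
    reference: str | None = None,
    value_col: str = "value",
    group_col: str = "disease",
    min_group_size: int = 2,
) -> list[GroupComparison]:
    """Two-sided Wilcoxon rank-sum tests between disease groups, BH-adjusted.

    With ``reference`` set, every other group is tested against it; otherwise
    all pairwise comparisons are run. All p-values produced by one call form a
    single Benjamini-Hochberg family. Groups smaller than ``min_group_size``
    are skipped with a warning. SciPy's ``mannwhitneyu`` picks the exact
    distribution for small tie-free samples and the continuity-corrected
    normal approximation otherwise.
    """
    groups = {
        g: sub[value_col].to_numpy(dtype=float)
        for g, sub in values.groupby(group_col)
    }
    usable = {}
    for g, v in groups.items():
        if len(v) < min_group_size:
            logger.warning("group %r has %d sample(s) (<%d); skipped",
                           g, len(v), min_group_size)
        else:
            usable[g] = v

    if reference is not None:
        if reference not in usable:
            raise ValueError(f"reference group {reference!r} missing or too small")
        pairs = [(g, reference) for g in sorted(usable) if g != reference]
    else:
        names = sorted(usable)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]

    raw = []
    for a, b in pairs:
        res = sps.mannwhitneyu(usable[a], usable[b], alternative="two-sided",
                               method="auto")
        raw.append((a, b, float(res.statistic), float(res.pvalue)))
    if not raw:
        return []
    adjusted = benjamini_hochberg([r[3] for r in raw])
    return [
        GroupComparison(
            group_a=a, group_b=b, n_a=len(usable[a]), n_b=len(usable[b]),
            statistic=stat, p_value=p, p_adjusted=p_adj,
        )
        for (a, b, stat, p), p_adj in zip(raw, adjusted)
    ]


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    if not p_values:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


def comparison_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(group_a=c.group_a, group_b=c.group_b, n_a=c.n_a, n_b=c.n_b,
                 statistic=c.statistic, p_value=c.p_value, p_adjusted=c.p_adjusted)
            for c in comparisons
        ]
    )
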