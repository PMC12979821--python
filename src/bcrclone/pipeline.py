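"""End-to-end orchestration: read -> QC -> clonotype -> merge -> SHM -> summaries.

Each stage writes its tabular output so stages are independently inspectable;
a manifest records every tunable that affects results. The pipeline is
deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import AlignmentParams, load_matrix
from .clonotyping import (
    build_clonotypes,
    cell_assignment,
    clonotype_table,
    merge_partial_clones,
    top_clone,
)
from .io import read_cell_meta, read_contigs, read_germline_fasta, write_rejects
from .qc import filter_cells, passing_cells
from .shm import estimate_shm, shm_by_group, shm_table
from .stats import (
    comparison_table,
    compare_groups,
    expansion_fraction,
    phenotype_composition,
    shannon_entropy,
)
from .types import CellMeta, Clonotype, SampleSummary

logger = logging.getLogger(__name__)

B_LINEAGE_PHENOTYPES = {
    "naive B", "GC LZ", "GC DZ", "memory B", "plasma cell", "aberrant",
}


@dataclass
class PipelineConfig:
    contigs: str
    dialect: str = "tenx_csv"
    meta: str | None = None
    germline: str | None = None
    outdir: str = "bcrclone_out"
    sample_id: str = ""
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    identity_min: float = 0.85
    require_productive: bool = True
    kappa_lambda_duplicate: bool = True
    entropy_base: float | None = None
    reference_group: str | None = None
    seed: int = 0


@dataclass
class PipelineResult:
    summaries: list[SampleSummary]
    clonotypes: list[Clonotype]
    outdir: Path


def _n_b_cells(sample_id: str, meta: list[CellMeta], fallback: int) -> int:
    """Denominator for the expansion fraction: all B-lineage cells in metadata
    (so cells without a recovered BCR still count), else all QC-pass cells."""
    if meta:
        n = sum(
            1 for m in meta
            if m.sample_id == sample_id
            and (not m.phenotype or m.phenotype in B_LINEAGE_PHENOTYPES)
        )
        if n:
            return n
    return fallback


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    contigs, rejects = read_contigs(
        config.contigs, dialect=config.dialect, sample_id=config.sample_id
    )
    write_rejects(rejects, outdir / "rejects.tsv")
    meta = read_cell_meta(config.meta) if config.meta else []
    germline = read_germline_fasta(config.germline) if config.germline else []

    cells, qc_report = filter_cells(
        contigs,
        require_productive=config.require_productive,
        kappa_lambda_duplicate=config.kappa_lambda_duplicate,
    )
    qc_report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    passed = passing_cells(cells)
    logger.info("QC: %d/%d cells pass", len(passed), len(cells))

    clonotypes = build_clonotypes(passed)
    clonotypes = merge_partial_clones(
        clonotypes, params=config.alignment, identity_min=config.identity_min
    )
    clonotype_table(clonotypes).to_csv(
        outdir / "clonotypes.tsv", sep="\t", index=False
    )
    assign = cell_assignment(clonotypes)
    assign.to_csv(outdir / "cell_clonotypes.tsv", sep="\t", index=False)

    sample_ids = sorted({ct.sample_id for ct in clonotypes})
    top_ids: dict[str, str] = {}
    summaries: list[SampleSummary] = []
    meta_by_sample = {
        sid: [m for m in meta if m.sample_id == sid] for sid in sample_ids
    }
    pheno_lookup = {(m.sample_id, m.barcode): m.phenotype for m in meta}
    disease_lookup = {m.sample_id: m.disease for m in meta}
    for sid in sample_ids:
        sample_cts = [ct for ct in clonotypes if ct.sample_id == sid]
        top = top_clone(sample_cts)
        top_ids[sid] = top.clonotype_id
        n_pass = sum(1 for c in passed if c.sample_id == sid)
        denom = _n_b_cells(sid, meta_by_sample.get(sid, []), n_pass)
        comp = phenotype_composition(
            top, {b: p for (s, b), p in pheno_lookup.items() if s == sid}
        )
        summaries.append(SampleSummary(
            sample_id=sid,
            disease=disease_lookup.get(sid, ""),
            n_b_cells=denom,
            top_clone_id=top.clonotype_id,
            top_clone_size=top.size,
            expansion_fraction=expansion_fraction(top, denom),
            phenotype_composition=comp,
            shannon_entropy=shannon_entropy(comp, base=config.entropy_base),
        ))

    summary_df = pd.DataFrame([
        dict(sample_id=s.sample_id, disease=s.disease, n_b_cells=s.n_b_cells,
             top_clone_id=s.top_clone_id, top_clone_size=s.top_clone_size,
             expansion_fraction=s.expansion_fraction,
             shannon_entropy=s.shannon_entropy,
             phenotype_composition=json.dumps(s.phenotype_composition))
        for s in summaries
    ])
    summary_df.to_csv(outdir / "sample_summary.tsv", sep="\t", index=False)

    if germline:
        assignment = dict(zip(assign["barcode"], assign["clonotype_id"]))
        shm_res = estimate_shm(
            [c for cell in passed for c in (cell.heavy, cell.light) if c],
            germline, assignment,
        )
        shm_table(shm_res, top_ids).to_csv(
            outdir / "shm_contigs.tsv", sep="\t", index=False
        )
        shm_by_group(shm_res, top_ids).to_csv(
            outdir / "shm_summary.tsv", sep="\t", index=False
        )
    else:
        logger.warning("no germline reference supplied; SHM stage skipped")

    diseases = summary_df["disease"].replace("", pd.NA).dropna()
    if diseases.nunique() >= 2 and (diseases.value_counts() >= 2).sum() >= 2:
        comparisons = compare_groups(
            summary_df.rename(columns={"expansion_fraction": "value"}),
            reference=config.reference_group,
        )
        comparison_table(comparisons).to_csv(
            outdir / "group_comparisons.tsv", sep="\t", index=False
        )

    manifest = dict(
        bcrclone_version=__version__,
        seed=config.seed,
        dialect=config.dialect,
        identity_min=config.identity_min,
        alignment=asdict(config.alignment),
        matrix_sha256=hashlib.sha256(
            load_matrix(config.alignment.matrix).scores.tobytes()
        ).hexdigest(),
        require_productive=config.require_productive,
        kappa_lambda_duplicate=config.kappa_lambda_duplicate,
        entropy_base=config.entropy_base,
        n_input_rows=len(contigs) + len(rejects),
        n_rejected_rows=len(rejects),
        n_cells=len(cells),
        n_pass_cells=len(passed),
        n_clonotypes=len(clonotypes),
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(summaries=summaries, clonotypes=clonotypes, outdir=outdir)
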