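"""Synthetic paired-chain BCR repertoires with known ground truth.

The generator emulates the statistical structure the clonality analysis
assumes: one planted top-expanded clone at a configurable fraction of cells,
a polyclonal background of geometrically sized clones, per-contig somatic
point mutations in the V segment at configurable rates (higher in the top
clone, as in germinal-centre-derived lymphomas), chain-dropout cells that
exercise the partial-clone merging step, duplicate-chain cells and 3-contig
doublets that exercise the cell QC, and per-cell phenotype labels drawn from
clone-specific mixtures.

Everything is deterministic given the seed. The germline V/J pool is a small
fixed synthetic reference (realistic lengths, not IMGT sequences); phenotypes
are labels only — no transcriptome is simulated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .types import CellMeta, Chain, ContigRecord, GermlineSegment

NT = np.array(list("ACGT"))
AA20 = list("ACDEFGHIKLMNPQRSTVWY")
PHENOTYPES = ["naive B", "GC LZ", "GC DZ", "memory B", "plasma cell", "aberrant"]
HEAVY_ISOTYPES = ["IGHM", "IGHD", "IGHG1", "IGHG2", "IGHG3", "IGHA1"]

# one codon per amino acid, for deterministic reverse translation of CDR3s
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_GERMLINE_POOL_SEED = 7_654_321  # fixed: the pool is a versioned reference


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NT, size=length))


def germline_pool() -> list[GermlineSegment]:
    """The bundled synthetic germline reference: V and J segments per locus.

    Sequences are random but fixed (internal seed); lengths are realistic
    (~300 nt V segments, short J segments). Gene names follow IMGT-style
    nomenclature so that real tooling conventions (allele stripping etc.)
    are exercised.
    """
    rng = np.random.default_rng(_GERMLINE_POOL_SEED)
    segments: list[GermlineSegment] = []
    for i in range(8):
        segments.append(GermlineSegment(f"IGHV1-{i + 1}", _random_nt(rng, 296)))
    for i in range(6):
        segments.append(GermlineSegment(f"IGKV1-{i + 1}", _random_nt(rng, 287)))
    for i in range(6):
        segments.append(GermlineSegment(f"IGLV1-{i + 1}", _random_nt(rng, 289)))
    for i in range(6):
        segments.append(GermlineSegment(f"IGHJ{i + 1}", _random_nt(rng, 53)))
    for i in range(5):
        segments.append(GermlineSegment(f"IGKJ{i + 1}", _random_nt(rng, 38)))
    for i in range(5):
        segments.append(GermlineSegment(f"IGLJ{i + 1}", _random_nt(rng, 38)))
    return segments


def v_segments(pool: list[GermlineSegment] | None = None) -> list[GermlineSegment]:
    pool = pool if pool is not None else germline_pool()
    return [g for g in pool if "V" in g.gene]


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for one simulated sample.

    Defaults describe a moderately expanded cutaneous B-cell infiltrate: a top
    clone carrying 20% of cells with germinal-centre-level hypermutation
    (5% per base) over a polyclonal background (2% per base), 10% chain
    dropout and 2% doublets.
    """

    seed: int = 0
    sample_id: str = "sim_sample"
    disease: str = "simulated"
    n_cells: int = 1000
    top_clone_fraction: float = 0.2
    n_background_clones: int = 150
    shm_rate_top: float = 0.05
    shm_rate_background: float = 0.02
    chain_dropout_rate: float = 0.1
    doublet_rate: float = 0.02
    dup_chain_rate: float = 0.0
    class_switch_prob: float = 0.0
    cdr3_length_range: tuple[int, int] = (15, 21)
    background_clone_geom_p: float = 0.3
    phenotype_mixture_top: dict[str, float] = field(
        default_factory=lambda: {"GC LZ": 0.4, "GC DZ": 0.3, "memory B": 0.3}
    )
    phenotype_mixture_background: dict[str, float] = field(
        default_factory=lambda: {
            "naive B": 0.4, "memory B": 0.3, "GC LZ": 0.1, "GC DZ": 0.1,
            "plasma cell": 0.1,
        }
    )

    def __post_init__(self) -> None:
        for name in ("top_clone_fraction", "shm_rate_top", "shm_rate_background",
                     "chain_dropout_rate", "doublet_rate", "dup_chain_rate",
                     "class_switch_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.top_clone_fraction * self.n_cells < 1:
            raise ValueError(
                "infeasible config: top_clone_fraction * n_cells < 1 "
                f"({self.top_clone_fraction} * {self.n_cells})"
            )
        for mix_name in ("phenotype_mixture_top", "phenotype_mixture_background"):
            mix = getattr(self, mix_name)
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{mix_name} must sum to 1")
        rates = self.chain_dropout_rate + self.doublet_rate + self.dup_chain_rate
        if rates > 1.0:
            raise ValueError("anomaly rates sum to more than 1")


@dataclass
class GroundTruth:
    """What was planted: per-cell clone/phenotype/anomaly and mutation counts."""

    sample_id: str
    true_top_fraction: float
    n_cells: int
    n_doublets: int
    n_dup_chain: int
    n_dropout: int
    cells: list[dict] = field(default_factory=list)

    @property
    def partition(self) -> dict[str, str]:
        """barcode -> true clone id."""
        return {c["barcode"]: c["clone_id"] for c in self.cells}

    def to_json(self) -> str:
        return json.dumps(
            dict(
                sample_id=self.sample_id,
                true_top_fraction=self.true_top_fraction,
                n_cells=self.n_cells, n_doublets=self.n_doublets,
                n_dup_chain=self.n_dup_chain, n_dropout=self.n_dropout,
                cells=self.cells,
            ),
            indent=1,
        )


@dataclass
class SimulatedSample:
    config: SimulationConfig
    contigs: list[ContigRecord]
    meta: list[CellMeta]
    germline: list[GermlineSegment]
    truth: GroundTruth


@dataclass(frozen=True)
class _CloneSpec:
    clone_id: str
    heavy_v: str
    heavy_j: str
    heavy_c: str
    heavy_cdr3_aa: str
    light_chain: Chain
    light_v: str
    light_j: str
    light_c: str
    light_cdr3_aa: str
    shm_rate: float


def _make_cdr3(rng: np.random.Generator, lo: int, hi: int, chain: Chain) -> str:
    length = int(rng.integers(lo, hi + 1))
    middle = "".join(rng.choice(AA20, size=length - 2))
    # canonical anchors: Cys104 start; Trp (heavy) / Phe (light) end
    return "C" + middle + ("W" if chain.is_heavy else "F")


def _reverse_translate(aa: str) -> str:
    return "".join(_CODON[c] for c in aa)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """I.i.d. per-base substitutions; returns (mutated sequence, #changes)."""
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        others = [b for b in "ACGT" if b != arr[i]]
        arr[i] = others[int(rng.integers(3))]
    return "".join(arr), len(hits)


def _draw_clone(
    rng: np.random.Generator, clone_id: str, pool: dict[str, GermlineSegment],
    cfg: SimulationConfig, shm_rate: float,
) -> _CloneSpec:
    lo, hi = cfg.cdr3_length_range
    light_chain = Chain.IGK if rng.random() < 0.6 else Chain.IGL
    lp = light_chain.value  # IGK or IGL
    return _CloneSpec(
        clone_id=clone_id,
        heavy_v=f"IGHV1-{int(rng.integers(1, 9))}",
        heavy_j=f"IGHJ{int(rng.integers(1, 7))}",
        heavy_c=str(rng.choice(HEAVY_ISOTYPES)),
        heavy_cdr3_aa=_make_cdr3(rng, lo, hi, Chain.IGH),
        light_chain=light_chain,
        light_v=f"{lp}V1-{int(rng.integers(1, 7))}",
        light_j=f"{lp}J{int(rng.integers(1, 6))}",
        light_c="IGKC" if light_chain is Chain.IGK else "IGLC1",
        light_cdr3_aa=_make_cdr3(rng, lo, hi, light_chain),
        shm_rate=shm_rate,
    )


def _make_contig(
    rng: np.random.Generator, pool: dict[str, GermlineSegment], cfg: SimulationConfig,
    barcode: str, suffix: int, clone: _CloneSpec, heavy: bool,
) -> tuple[ContigRecord, int]:
    if heavy:
        chain, v, j, c = Chain.IGH, clone.heavy_v, clone.heavy_j, clone.heavy_c
        cdr3 = clone.heavy_cdr3_aa
    else:
        chain, v, j, c = clone.light_chain, clone.light_v, clone.light_j, clone.light_c
        cdr3 = clone.light_cdr3_aa
    v_mut, n_mut = _mutate(rng, pool[v].sequence_nt, clone.shm_rate)
    cdr3_nt = _reverse_translate(cdr3)
    seq = v_mut + cdr3_nt + pool[j].sequence_nt
    rec = ContigRecord(
        contig_id=f"{barcode}_contig_{suffix}",
        barcode=barcode, sample_id=cfg.sample_id, chain=chain,
        v_call=v, d_call="IGHD3-10" if heavy else "", j_call=j, c_call=c,
        cdr3_aa=cdr3, cdr3_nt=cdr3_nt, sequence_nt=seq,
        umis=int(rng.poisson(4)) + 1, productive=True,
    )
    return rec, n_mut


def simulate_sample(config: SimulationConfig) -> SimulatedSample:
    """Generate one sample: contigs, metadata, germline reference, ground truth.

    Cell anomalies are mutually exclusive: each cell is a doublet (gains a
    third contig from a random other clone), a duplicate-chain cell (its heavy
    chain replaced by a second, different-locus light chain), a dropout cell
    (loses one chain uniformly at random) or a normal paired cell. This makes
    planted anomaly counts exactly recoverable from the QC report.
    """
    rng = np.random.default_rng(config.seed)
    pool_list = germline_pool()
    pool = {g.gene: g for g in pool_list}

    n_top = int(round(config.top_clone_fraction * config.n_cells))
    n_bg = config.n_cells - n_top

    top_clone = _draw_clone(rng, "clone_top", pool, config, config.shm_rate_top)
    bg_clones = [
        _draw_clone(rng, f"clone_bg{i + 1:04d}", pool, config,
                    config.shm_rate_background)
        for i in range(config.n_background_clones)
    ]
    # geometric clone-size weights: many small clones, an unambiguous top clone
    weights = rng.geometric(config.background_clone_geom_p,
                            size=config.n_background_clones).astype(float)
    weights /= weights.sum()
    bg_assignment = rng.choice(config.n_background_clones, size=n_bg, p=weights)

    clone_of_cell: list[_CloneSpec] = [top_clone] * n_top + [
        bg_clones[i] for i in bg_assignment
    ]

    contigs: list[ContigRecord] = []
    meta: list[CellMeta] = []
    truth = GroundTruth(
        sample_id=config.sample_id,
        true_top_fraction=n_top / config.n_cells,
        n_cells=config.n_cells, n_doublets=0, n_dup_chain=0, n_dropout=0,
    )

    p_doub, p_dup, p_drop = (config.doublet_rate, config.dup_chain_rate,
                             config.chain_dropout_rate)
    for idx, clone in enumerate(clone_of_cell):
        barcode = f"CELL{idx + 1:06d}-1"
        is_top = clone is top_clone
        mix = (config.phenotype_mixture_top if is_top
               else config.phenotype_mixture_background)
        phenotype = str(rng.choice(list(mix.keys()), p=list(mix.values())))

        working_clone = clone
        if is_top and config.class_switch_prob > 0 and rng.random() < config.class_switch_prob:
            switched = str(rng.choice([c for c in HEAVY_ISOTYPES
                                       if c != clone.heavy_c]))
            working_clone = replace(clone, heavy_c=switched)

        u = rng.random()
        if u < p_doub:
            anomaly = "doublet"
        elif u < p_doub + p_dup:
            anomaly = "dup_chain"
        elif u < p_doub + p_dup + p_drop:
            anomaly = "dropout"
        else:
            anomaly = "none"

        heavy_rec, n_mut_h = _make_contig(rng, pool, config, barcode, 1,
                                          working_clone, heavy=True)
        light_rec, n_mut_l = _make_contig(rng, pool, config, barcode, 2,
                                          working_clone, heavy=False)
        cell_contigs = [heavy_rec, light_rec]

        if anomaly == "doublet":
            truth.n_doublets += 1
            other = bg_clones[int(rng.integers(len(bg_clones)))]
            extra, _ = _make_contig(rng, pool, config, barcode, 3, other,
                                    heavy=bool(rng.integers(2)))
            cell_contigs.append(extra)
        elif anomaly == "dup_chain":
            truth.n_dup_chain += 1
            # two light-class contigs from different loci, no heavy chain
            other_locus = (Chain.IGL if working_clone.light_chain is Chain.IGK
                           else Chain.IGK)
            lp = other_locus.value
            alt = replace(
                working_clone,
                light_chain=other_locus,
                light_v=f"{lp}V1-{int(rng.integers(1, 7))}",
                light_j=f"{lp}J{int(rng.integers(1, 6))}",
                light_c="IGKC" if other_locus is Chain.IGK else "IGLC1",
                light_cdr3_aa=_make_cdr3(rng, *config.cdr3_length_range,
                                         other_locus),
            )
            extra, _ = _make_contig(rng, pool, config, barcode, 3, alt, heavy=False)
            cell_contigs = [light_rec, extra]
        elif anomaly == "dropout":
            truth.n_dropout += 1
            dropped = int(rng.integers(2))  # 0: drop heavy, 1: drop light
            cell_contigs = [light_rec] if dropped == 0 else [heavy_rec]

        contigs.extend(cell_contigs)
        meta.append(CellMeta(barcode=barcode, sample_id=config.sample_id,
                             disease=config.disease, phenotype=phenotype))
        truth.cells.append(dict(
            barcode=barcode, clone_id=clone.clone_id, phenotype=phenotype,
            anomaly=anomaly, n_mut_heavy=n_mut_h, n_mut_light=n_mut_l,
        ))

    return SimulatedSample(config=config, contigs=contigs, meta=meta,
                           germline=pool_list, truth=truth)


def write_sample(sample: SimulatedSample, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated sample as text files (both contig dialects + truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tenx_csv": outdir / "filtered_contig_annotations.csv",
        "airr_tsv": outdir / "rearrangements.tsv",
        "meta": outdir / "cell_meta.tsv",
        "germline": outdir / "germline_v.fasta",
        "truth": outdir / "ground_truth.json",
        "config": outdir / "config.yaml",
    }
    rio.write_contigs(sample.contigs, paths["tenx_csv"], dialect="tenx_csv")
    rio.write_contigs(sample.contigs, paths["airr_tsv"], dialect="airr_tsv")
    rio.write_cell_meta(sample.meta, paths["meta"])
    rio.write_germline_fasta(v_segments(sample.germline), paths["germline"])
    paths["truth"].write_text(sample.truth.to_json())
    cfg = asdict(sample.config)
    cfg["cdr3_length_range"] = list(cfg["cdr3_length_range"])
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths


def scenario_suite() -> dict[str, SimulationConfig]:
    """Named scenarios spanning the spectrum of clonal expansion.

    The four entities range from barely expanded reactive infiltrates (~2% of
    B cells in the top clone) through marginal-zone-like (~4%, top clone
    spanning all peripheral B-cell phenotypes up to plasma cells), to
    follicle-centre-like (~52%, germinal-centre-restricted) and aggressive
    large-cell-like (~97%, aberrant-phenotype) samples.
    """
    return {
        "rBLP_like": SimulationConfig(
            seed=101, sample_id="rBLP_like", disease="rB-LP",
            n_cells=2000, top_clone_fraction=0.02, n_background_clones=400,
            shm_rate_top=0.06, shm_rate_background=0.02,
            phenotype_mixture_top={"GC LZ": 0.5, "GC DZ": 0.3, "memory B": 0.2},
        ),
        "pcMZL_like": SimulationConfig(
            seed=102, sample_id="pcMZL_like", disease="pcMZL",
            n_cells=2000, top_clone_fraction=0.04, n_background_clones=400,
            shm_rate_top=0.06, shm_rate_background=0.02,
            phenotype_mixture_top={
                "naive B": 0.1, "GC LZ": 0.2, "GC DZ": 0.1, "memory B": 0.2,
                "plasma cell": 0.4,
            },
        ),
        "pcFCL_like": SimulationConfig(
            seed=103, sample_id="pcFCL_like", disease="pcFCL",
            n_cells=2000, top_clone_fraction=0.52, n_background_clones=300,
            shm_rate_top=0.05, shm_rate_background=0.02,
            phenotype_mixture_top={"GC LZ": 0.55, "GC DZ": 0.45},
        ),
        "pcDLBCL_like": SimulationConfig(
            seed=104, sample_id="pcDLBCL_like", disease="pcDLBCL-LT",
            n_cells=2000, top_clone_fraction=0.97, n_background_clones=60,
            shm_rate_top=0.08, shm_rate_background=0.02,
            phenotype_mixture_top={"aberrant": 0.9, "GC DZ": 0.1},
        ),
    }
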