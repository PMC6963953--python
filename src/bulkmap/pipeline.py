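"""End-to-end orchestration: simulate -> scan -> annotate -> intersect -> DEG.

A run is driven by a single :class:`RunConfig` (usually loaded from
YAML) and is deterministic given its seed: every stage's RNG stream is
derived from the master seed with a fixed offset.  The manifest written
at the end records the config hash, package version, seed and per-stage
row counts, so any output can be regenerated from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import bulkmap
from bulkmap import io_formats, simdata
from bulkmap.bsa_scan import (
    FilterConfig,
    ScanConfig,
    ThresholdConfig,
    run_scan,
)
from bulkmap.expression import DEGConfig, call_degs, ddct, deg_summary
from bulkmap.region_annotate import conjunctive_intersect, genes_in_regions

log = logging.getLogger(__name__)

# fixed offsets decoupling the per-stage RNG streams from one master seed
_SEED_GENO = 11
_SEED_BULK = 23
_SEED_DNA = 37
_SEED_RNA = 41
_SEED_EXPR = 53
_SEED_NULL = 67


@dataclass
class SimSection:
    chrom_lengths: dict = field(default_factory=lambda: {"A01": 10_000_000})
    marker_spacing: int = 50_000
    cm_per_mb: float = 4.0
    indel_fraction: float = 0.2
    n_individuals: int = 323
    causal_chrom: str | None = "A01"
    causal_pos: int | None = 5_000_000
    mode: str = "recessive"
    penetrance: float = 1.0
    n_per_bulk: int = 50
    dna_depth: float = 30.0
    rna_depth: float = 30.0
    base_error: float = 0.001
    n_genes_de_region_bp: int = 1_000_000
    expr: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    out_dir: str = "bulkmap_out"
    seed: int = 0
    sim: SimSection | None = None
    bsa_vcf: str | None = None
    bsr_vcf: str | None = None
    gff3: str | None = None
    counts: str | None = None
    qpcr: str | None = None
    qpcr_reference_gene: str | None = None
    qpcr_calibrator: tuple[str, str] | None = None
    sample_roles: dict = field(default_factory=dict)
    filter: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    deg: DEGConfig = field(default_factory=DEGConfig)

    def __post_init__(self):
        # accept plain dicts (YAML) for every nested config section
        if isinstance(self.sim, dict):
            self.sim = SimSection(**self.sim)
        for key, klass in (
            ("filter", FilterConfig),
            ("scan", ScanConfig),
            ("threshold", ThresholdConfig),
            ("deg", DEGConfig),
        ):
            value = getattr(self, key)
            if isinstance(value, dict):
                setattr(self, key, klass(**value))
        if self.qpcr_calibrator is not None:
            self.qpcr_calibrator = tuple(self.qpcr_calibrator)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate_paths(self) -> None:
        """Fail before any compute if a referenced input is missing."""
        for name in ("bsa_vcf", "bsr_vcf", "gff3", "counts", "qpcr"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: no such file {path!r}")


def simulate_experiment(cfg: RunConfig, out: Path) -> dict:
    """Generate the synthetic experiment and write its standard-format files."""
    sim = cfg.sim
    assert sim is not None
    gmap = simdata.GenomeMap.uniform(
        sim.chrom_lengths,
        spacing=sim.marker_spacing,
        cm_per_mb=sim.cm_per_mb,
        indel_fraction=sim.indel_fraction,
        seed=cfg.seed,
    )
    trait = None
    if sim.causal_chrom is not None:
        trait = simdata.TraitModel(
            causal_chrom=sim.causal_chrom,
            causal_pos=sim.causal_pos,
            mode=sim.mode,
            penetrance=sim.penetrance,
        )
    genotypes = simdata.simulate_f2_genotypes(
        gmap, trait, sim.n_individuals, seed=cfg.seed + _SEED_GENO
    )
    bulk_design = simdata.BulkDesign(
        n_per_bulk=sim.n_per_bulk,
        mean_depth=sim.dna_depth,
        base_error=sim.base_error,
        seed=cfg.seed + _SEED_BULK,
    )
    bulks = simdata.assign_bulks(genotypes, gmap, trait, bulk_design)

    dna_design = simdata.BulkDesign(
        sim.n_per_bulk, sim.dna_depth, sim.base_error, cfg.seed + _SEED_DNA
    )
    rna_design = simdata.BulkDesign(
        sim.n_per_bulk, sim.rna_depth, sim.base_error, cfg.seed + _SEED_RNA
    )
    dna_table = simdata.simulate_bulk_depths(genotypes, bulks, gmap, dna_design)
    rna_table = simdata.simulate_bulk_depths(genotypes, bulks, gmap, rna_design)

    genes = simdata.make_gene_models(gmap)
    de_regions = None
    if trait is not None:
        half = sim.n_genes_de_region_bp // 2
        de_regions = [
            (trait.causal_chrom, max(trait.causal_pos - half, 1), trait.causal_pos + half)
        ]
    expr_design = simdata.ExprDesign(seed=cfg.seed + _SEED_EXPR, **sim.expr)
    counts, truth = simdata.simulate_counts(expr_design, genes=genes, de_regions=de_regions)

    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_vcf(dna_table, out / "bsa.vcf", contig_lengths=sim.chrom_lengths)
    io_formats.write_vcf(
        rna_table, out / "bsr.vcf", samples=("T01", "T02", "T03", "T04"),
        contig_lengths=sim.chrom_lengths,
    )
    io_formats.write_gff3(genes, out / "genes.gff3")
    io_formats.write_counts_tsv(counts, out / "counts.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t")
    return {
        "gmap": gmap,
        "trait": trait,
        "dna_table": dna_table,
        "rna_table": rna_table,
        "genes": genes,
        "counts": counts,
        "truth": truth,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every configured stage; returns the manifest dict."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": bulkmap.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "stages": {},
    }

    chrom_lengths = None
    if cfg.sim is not None:
        sim_out = simulate_experiment(cfg, out / "sim")
        dna_table, rna_table = sim_out["dna_table"], sim_out["rna_table"]
        genes = sim_out["genes"]
        counts = sim_out["counts"]
        chrom_lengths = cfg.sim.chrom_lengths
        manifest["stages"]["simulate"] = {
            "n_dna_variants": len(dna_table),
            "n_rna_variants": len(rna_table),
            "n_genes": len(genes),
        }
    else:
        dna_table = (
            io_formats.read_vcf(cfg.bsa_vcf, cfg.sample_roles) if cfg.bsa_vcf else None
        )
        rna_table = (
            io_formats.read_vcf(cfg.bsr_vcf, cfg.sample_roles) if cfg.bsr_vcf else None
        )
        genes = io_formats.read_gff3(cfg.gff3) if cfg.gff3 else None
        counts = io_formats.read_counts_tsv(cfg.counts) if cfg.counts else None

    thr = ThresholdConfig(
        confidence=cfg.threshold.confidence,
        null_reps=cfg.threshold.null_reps,
        seed=cfg.seed + _SEED_NULL,
    )
    gene_sets = {}
    for label, table in (("BSA", dna_table), ("BSR", rna_table)):
        if table is None:
            continue
        result = run_scan(table, cfg.filter, cfg.scan, thr, chrom_lengths)
        regions = result.regions
        if genes is not None:
            gene_set = genes_in_regions(regions, genes, source=label)
            regions = gene_set.regions  # carries n_genes
            gene_sets[label] = gene_set
            gene_set.assignments.to_csv(
                out / f"{label.lower()}_genes.tsv", sep="\t", index=False
            )
        regions.to_csv(out / f"{label.lower()}_regions.tsv", sep="\t", index=False)
        _write_profiles(result, out / f"{label.lower()}_windows.tsv")
        manifest["stages"][f"scan_{label}"] = {
            "n_input_variants": len(table),
            "n_retained_variants": len(result.track),
            "n_regions": len(regions),
        }

    if len(gene_sets) == 2:
        shared = conjunctive_intersect(gene_sets["BSA"], gene_sets["BSR"])
        shared.to_csv(out / "conjunctive_genes.tsv", sep="\t", index=False)
        manifest["stages"]["conjunctive"] = {"n_shared_genes": len(shared)}

    if counts is not None:
        deg = call_degs(counts, cfg.deg)
        deg.to_csv(out / "deg.tsv", sep="\t")
        manifest["stages"]["deg"] = deg_summary(deg)

    if cfg.qpcr is not None:
        panel = io_formats.read_qpcr_tsv(cfg.qpcr)
        rel = ddct(panel, cfg.qpcr_reference_gene, cfg.qpcr_calibrator)
        rel.to_csv(out / "qpcr_relative.tsv", sep="\t", index=False)
        manifest["stages"]["qpcr"] = {"n_measurements": len(rel)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _write_profiles(result, path: Path) -> None:
    frames = []
    for method, profile in result.profiles.items():
        thr = result.thresholds[method]
        for chrom, frame in profile.frames.items():
            merged = frame.merge(thr[chrom], on="center")
            merged.insert(0, "chrom", chrom)
            merged.insert(0, "method", method)
            frames.append(merged)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
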