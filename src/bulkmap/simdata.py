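"""Synthetic F2 bulked-segregant experiments with known ground truth.

Simulates an F2 population from two fully inbred parents segregating for
a single causal locus, phenotype-based bulk composition, pooled
sequencing depths at parent-informative markers, and negative-binomial
expression counts — everything the downstream scan and DEG stages
consume, with the truth retained for recovery tests.

Conventions: allele ``1`` (the VCF ALT allele) is the head-parent
allele; genotype values 0/1/2 count copies of it.  All randomness flows
from a single integer seed per operation, so identical calls are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from bulkmap.io_formats import VARIANT_COLUMNS, validate_variant_table

TRAIT_MODES = ("recessive", "dominant", "additive-threshold")


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a genetic distance in cM: (1 - e^(-2d/100))/2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass
class GenomeMap:
    """Chromosome sizes plus parent-informative marker positions.

    Markers stand in for biallelic sites fixed for opposite alleles in
    the two parents.  ``marker_types`` optionally tags each marker as
    ``"SNP"`` or ``"indel"``; untagged markers default to SNP.
    """

    chromosomes: list[tuple[str, int]]
    markers: dict[str, np.ndarray]
    cm_per_mb: float = 4.0
    marker_types: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        lengths = dict(self.chromosomes)
        for chrom, pos in self.markers.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.markers[chrom] = pos
            if chrom not in lengths:
                raise ValueError(f"markers on unknown chromosome {chrom!r}")
            if len(pos) and (np.diff(pos) <= 0).any():
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
            if len(pos) and (pos[0] < 1 or pos[-1] > lengths[chrom]):
                raise ValueError(f"marker position outside chromosome {chrom}")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")

    @classmethod
    def uniform(
        cls,
        chrom_lengths: Mapping[str, int],
        spacing: int,
        cm_per_mb: float = 4.0,
        indel_fraction: float = 0.0,
        seed: int = 0,
    ) -> "GenomeMap":
        """Evenly spaced markers every *spacing* bp starting at *spacing*."""
        rng = np.random.default_rng(seed)
        markers, types = {}, {}
        for chrom, length in chrom_lengths.items():
            pos = np.arange(spacing, length + 1, spacing, dtype=np.int64)
            markers[chrom] = pos
            is_indel = rng.random(len(pos)) < indel_fraction
            types[chrom] = np.where(is_indel, "indel", "SNP")
        return cls(
            chromosomes=list(chrom_lengths.items()),
            markers=markers,
            cm_per_mb=cm_per_mb,
            marker_types=types,
        )

    def marker_index(self, chrom: str, pos: int) -> int:
        idx = np.searchsorted(self.markers[chrom], pos)
        if idx >= len(self.markers[chrom]) or self.markers[chrom][idx] != pos:
            raise ValueError(f"{chrom}:{pos} is not a marker position")
        return int(idx)


@dataclass
class TraitModel:
    """Monogenic stand-in trait controlled by one causal marker."""

    causal_chrom: str
    causal_pos: int
    mode: str = "recessive"
    penetrance: float = 1.0

    def __post_init__(self):
        if self.mode not in TRAIT_MODES:
            raise ValueError(f"mode must be one of {TRAIT_MODES}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")


@dataclass
class BulkDesign:
    n_per_bulk: int = 50
    mean_depth: float = 30.0
    base_error: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.n_per_bulk < 1:
            raise ValueError("n_per_bulk must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.base_error < 0.5:
            raise ValueError("base_error must lie in [0, 0.5)")


@dataclass
class ExprDesign:
    n_genes: int = 2000
    dispersion: float = 0.1
    de_fraction: float = 0.1
    log2fc_effect: float = 2.0
    library_sizes: tuple[float, float] = (1e6, 1e6)
    baseline_mean_log: float = 4.5
    baseline_sd_log: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")


def simulate_f2_genotypes(
    gmap: GenomeMap,
    trait: TraitModel | None,
    n: int,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Simulate F2 genotypes at every marker.

    Each individual inherits two independent gametes per chromosome;
    within a gamete, the allele switches between adjacent markers with
    the Haldane recombination fraction for their map distance
    (``cm_per_mb`` x physical distance).  Returns a dict of
    ``(n, n_markers)`` int8 arrays of head-parent allele counts (0/1/2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if trait is not None:
        gmap.marker_index(trait.causal_chrom, trait.causal_pos)

    rng = np.random.default_rng(seed)
    genotypes: dict[str, np.ndarray] = {}
    for chrom, _length in gmap.chromosomes:
        pos = gmap.markers.get(chrom)
        if pos is None or len(pos) == 0:
            genotypes[chrom] = np.zeros((n, 0), dtype=np.int8)
            continue
        m = len(pos)
        d_cm = np.diff(pos) / 1e6 * gmap.cm_per_mb
        r = haldane_r(d_cm)
        # two gametes per individual, interleaved rows
        first = rng.integers(0, 2, size=(2 * n, 1), dtype=np.int8)
        if m > 1:
            crossover = (rng.random((2 * n, m - 1)) < r).astype(np.int8)
            switched = np.cumsum(crossover, axis=1, dtype=np.int32) % 2
            alleles = np.concatenate([first, first ^ switched.astype(np.int8)], axis=1)
        else:
            alleles = first
        genotypes[chrom] = (alleles[0::2] + alleles[1::2]).astype(np.int8)
    return genotypes


def _genetic_phenotype(causal_genotype: np.ndarray, mode: str, rng) -> np.ndarray:
    if mode == "recessive":
        return causal_genotype == 2
    if mode == "dominant":
        return causal_genotype >= 1
    # additive-threshold: head with probability proportional to dosage
    return rng.random(len(causal_genotype)) < causal_genotype / 2.0


def phenotype_individuals(
    genotypes: Mapping[str, np.ndarray],
    gmap: GenomeMap,
    trait: TraitModel,
    seed: int = 0,
) -> np.ndarray:
    """Boolean head/non-head phenotype per individual.

    Penetrance is the probability the phenotype matches the genetic
    expectation; with probability ``1 - penetrance`` it flips, so at
    penetrance 0.5 both bulks are uninformative coin flips.
    """
    rng = np.random.default_rng(seed)
    idx = gmap.marker_index(trait.causal_chrom, trait.causal_pos)
    causal = genotypes[trait.causal_chrom][:, idx]
    genetic = _genetic_phenotype(causal, trait.mode, rng)
    express = rng.random(len(genetic)) < trait.penetrance
    return np.where(express, genetic, ~genetic)


def assign_bulks(
    genotypes: Mapping[str, np.ndarray],
    gmap: GenomeMap,
    trait: TraitModel | None,
    design: BulkDesign,
) -> tuple[np.ndarray, np.ndarray]:
    """Select (head_bulk, nonhead_bulk) individual indices by phenotype.

    With ``trait=None`` (no causal locus) phenotypes are random coin
    flips — the null experiment for type-I checks.
    """
    rng = np.random.default_rng(design.seed)
    n = next(iter(genotypes.values())).shape[0]
    if trait is None:
        pheno = rng.random(n) < 0.5
    else:
        pheno = phenotype_individuals(genotypes, gmap, trait, seed=design.seed)
    head = np.flatnonzero(pheno)
    nonhead = np.flatnonzero(~pheno)
    if len(head) < design.n_per_bulk or len(nonhead) < design.n_per_bulk:
        raise ValueError(
            f"insufficient individuals for bulks of {design.n_per_bulk}: "
            f"{len(head)} head, {len(nonhead)} non-head"
        )
    head_bulk = np.sort(rng.choice(head, size=design.n_per_bulk, replace=False))
    nonhead_bulk = np.sort(rng.choice(nonhead, size=design.n_per_bulk, replace=False))
    return head_bulk, nonhead_bulk


def simulate_bulk_depths(
    genotypes: Mapping[str, np.ndarray],
    bulks: tuple[np.ndarray, np.ndarray],
    gmap: GenomeMap,
    design: BulkDesign,
) -> pd.DataFrame:
    """Pooled sequencing of the two bulks -> VariantTable.

    Per site and bulk: total depth ~ Poisson(mean_depth); ALT
    (head-parent allele) count ~ Binomial(depth, f(1-e) + (1-f)e) with f
    the bulk's true allele frequency and e the base error.  Parents are
    emitted as fixed opposite homozygotes (parent1 = head parent = 1/1).
    """
    head_bulk, nonhead_bulk = bulks
    if np.intersect1d(head_bulk, nonhead_bulk).size:
        raise ValueError("bulks must be disjoint")
    rng = np.random.default_rng(design.seed + 1)  # decouple from bulk sampling
    e = design.base_error
    frames = []
    for chrom, _length in gmap.chromosomes:
        geno = genotypes[chrom]
        if geno.shape[1] == 0:
            continue
        pos = gmap.markers[chrom]
        if gmap.marker_types is not None and chrom in gmap.marker_types:
            vtype = np.asarray(gmap.marker_types[chrom])
        else:
            vtype = np.full(len(pos), "SNP")
        rows = {"chrom": chrom, "pos": pos, "variant_type": vtype}
        for label, bulk in (("bulkA", head_bulk), ("bulkB", nonhead_bulk)):
            f = geno[bulk].sum(axis=0) / (2.0 * len(bulk))
            depth = rng.poisson(design.mean_depth, size=len(pos))
            alt = rng.binomial(depth, f * (1 - e) + (1 - f) * e)
            rows[f"{label}_ref_depth"] = depth - alt
            rows[f"{label}_alt_depth"] = alt
        frames.append(pd.DataFrame(rows))
    table = pd.concat(frames, ignore_index=True)
    table["parent1_gt"] = "1/1"
    table["parent2_gt"] = "0/0"
    return validate_variant_table(table[VARIANT_COLUMNS])


def make_gene_models(
    gmap: GenomeMap,
    gene_length: int = 2000,
    gene_spacing: int = 5000,
    prefix: str = "G",
) -> pd.DataFrame:
    """Tile non-overlapping gene models over the simulated genome."""
    rows = []
    i = 0
    for chrom, length in gmap.chromosomes:
        start = 1
        while start + gene_length - 1 <= length:
            i += 1
            rows.append(
                (
                    f"{prefix}{i:06d}",
                    chrom,
                    start,
                    start + gene_length - 1,
                    "+" if i % 2 else "-",
                )
            )
            start += gene_spacing
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def simulate_counts(
    design: ExprDesign,
    genes: pd.DataFrame | None = None,
    de_regions: Sequence[tuple[str, int, int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for two bulks plus a ground-truth table.

    Counts ~ NB(mean = baseline * 2^(+-log2fc/2) * library-size factor,
    dispersion) via the gamma–Poisson mixture.  When *genes* and
    *de_regions* are given, DE genes are drawn preferentially from genes
    overlapping those regions (spilling outside once exhausted), so the
    conjunctive intersection has signal where the scan does.

    Returns ``(counts, truth)``: counts indexed by gene_id with columns
    ``bulkA, bulkB`` plus ``length`` when gene models are supplied;
    truth has ``is_de`` and ``true_log2fc`` (bulkA over bulkB).
    """
    rng = np.random.default_rng(design.seed)
    if genes is not None:
        gene_ids = genes["gene_id"].to_numpy()
        n_genes = len(gene_ids)
    else:
        n_genes = design.n_genes
        gene_ids = np.array([f"G{i + 1:06d}" for i in range(n_genes)])

    n_de = int(round(design.de_fraction * n_genes))
    is_de = np.zeros(n_genes, dtype=bool)
    if n_de > 0:
        if genes is not None and de_regions:
            in_region = np.zeros(n_genes, dtype=bool)
            for chrom, start, end in de_regions:
                in_region |= (
                    (genes["chrom"] == chrom)
                    & (genes["end"] >= start)
                    & (genes["start"] <= end)
                ).to_numpy()
            preferred = np.flatnonzero(in_region)
            chosen = preferred[: n_de]
            if len(chosen) < n_de:
                rest = rng.choice(
                    np.flatnonzero(~in_region), size=n_de - len(chosen), replace=False
                )
                chosen = np.concatenate([chosen, rest])
        else:
            chosen = rng.choice(n_genes, size=n_de, replace=False)
        is_de[chosen] = True

    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    true_log2fc = np.where(is_de, sign * design.log2fc_effect, 0.0)

    baseline = rng.lognormal(design.baseline_mean_log, design.baseline_sd_log, n_genes)
    lib = np.asarray(design.library_sizes, dtype=float)
    size_factors = lib / lib.mean()
    shape = 1.0 / design.dispersion
    counts = {}
    for j, bulk in enumerate(("bulkA", "bulkB")):
        mu = baseline * 2.0 ** (true_log2fc / 2.0 * (1 if j == 0 else -1))
        mu = mu * size_factors[j]
        lam = rng.gamma(shape, mu / shape)
        counts[bulk] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    if genes is not None:
        counts_df["length"] = (genes["end"] - genes["start"] + 1).to_numpy()
    truth = pd.DataFrame(
        {"is_de": is_de, "true_log2fc": true_log2fc},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return counts_df, truth
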