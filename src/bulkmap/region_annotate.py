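"""Candidate-region gene annotation and the conjunctive intersection."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class CandidateGeneSet:
    """Genes overlapping the candidate regions of one analysis.

    ``assignments`` holds one row per (gene, region) pair with columns
    ``gene_id, chrom, gene_start, gene_end, region_id, source``; a gene
    overlapping two regions appears twice there but once in
    :attr:`gene_ids`.
    """

    source: str
    assignments: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.assignments["gene_id"].unique())

    def per_region_counts(self) -> pd.Series:
        return self.assignments.groupby("region_id")["gene_id"].nunique()


def genes_in_regions(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    source: str = "BSA",
) -> CandidateGeneSet:
    """Assign genes to candidate regions by any-overlap (>= 1 bp).

    A gene [start, end] is included in a region [rstart, rend] iff the
    closed intervals intersect.  Regions on chromosomes absent from the
    gene set are skipped with a warning.  The input *regions* table
    gains an ``n_genes`` column (regions is not modified in place; the
    augmented copy is returned on the set as ``.regions``).
    """
    known_chroms = set(genes["chrom"].unique())
    rows = []
    n_per_region = []
    for i, region in enumerate(regions.itertuples(index=False)):
        region_id = f"{region.chrom}:{int(region.start)}-{int(region.end)}"
        if region.chrom not in known_chroms:
            log.warning("genes_in_regions: unknown chromosome %r, region %s skipped",
                        region.chrom, region_id)
            n_per_region.append(0)
            continue
        hit = genes[
            (genes["chrom"] == region.chrom)
            & (genes["end"] >= region.start)
            & (genes["start"] <= region.end)
        ]
        n_per_region.append(len(hit))
        for g in hit.itertuples(index=False):
            rows.append((g.gene_id, g.chrom, g.start, g.end, region_id, source))
    assignments = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "gene_start", "gene_end", "region_id", "source"],
    )
    gene_set = CandidateGeneSet(source=source, assignments=assignments)
    augmented = regions.copy()
    augmented["n_genes"] = n_per_region
    gene_set.regions = augmented  # type: ignore[attr-defined]
    return gene_set


def conjunctive_intersect(
    set_a: CandidateGeneSet, set_b: CandidateGeneSet
) -> pd.DataFrame:
    """Genes present in both candidate sets, with region provenance.

    Returns a table sorted by gene_id with columns ``gene_id,
    regions_<sourceA>, regions_<sourceB>`` (comma-joined region ids).
    """
    shared = sorted(set(set_a.gene_ids) & set(set_b.gene_ids))

    def provenance(s: CandidateGeneSet, gene: str) -> str:
        regs = s.assignments.loc[s.assignments["gene_id"] == gene, "region_id"]
        return ",".join(sorted(regs.unique()))

    return pd.DataFrame(
        {
            "gene_id": shared,
            f"regions_{set_a.source}": [provenance(set_a, g) for g in shared],
            f"regions_{set_b.source}": [provenance(set_b, g) for g in shared],
        }
    )
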