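"""Readers and writers for the standard formats the pipeline touches.

Internal data model
-------------------
VariantTable : :class:`pandas.DataFrame` with columns
    ``chrom, pos, variant_type, parent1_gt, parent2_gt,
    bulkA_ref_depth, bulkA_alt_depth, bulkB_ref_depth, bulkB_alt_depth``
    sorted by (chrom natural order, pos); ``pos`` is 1-based;
    ``variant_type`` is ``"SNP"`` or ``"indel"``; genotypes are unphased
    strings such as ``"0/0"``.  Bulk A is the trait-positive (head) bulk.
GeneModel table : :class:`pandas.DataFrame` with columns
    ``gene_id, chrom, start, end, strand`` (1-based inclusive).

All coordinates are 1-based throughout; VCF and GFF3 both use that
convention natively so no shifting happens on either side.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
import pysam

from bulkmap._util import sort_by_position

log = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "variant_type",
    "parent1_gt",
    "parent2_gt",
    "bulkA_ref_depth",
    "bulkA_alt_depth",
    "bulkB_ref_depth",
    "bulkB_alt_depth",
]

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]

ROLES = ("parent1", "parent2", "bulkA", "bulkB")

#: default sample naming for simulated VCFs (parent1, parent2, bulkA, bulkB)
DEFAULT_SAMPLES = ("R01", "R02", "R03", "R04")


def validate_variant_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check invariants and return the table sorted canonically."""
    missing = [c for c in VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    depth_cols = [c for c in VARIANT_COLUMNS if c.endswith("_depth")]
    if (table[depth_cols] < 0).any().any():
        raise ValueError("negative depth in variant table")
    if (table["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    bad_type = ~table["variant_type"].isin(["SNP", "indel"])
    if bad_type.any():
        raise ValueError(
            f"unknown variant_type values: {table.loc[bad_type, 'variant_type'].unique()}"
        )
    return sort_by_position(table)


def _gt_string(gt_tuple) -> str | None:
    if gt_tuple is None or any(a is None for a in gt_tuple):
        return None
    return "/".join(str(a) for a in gt_tuple)


def classify_variant(ref: str, alt: str) -> str:
    """SNP when REF and ALT are both single bases, otherwise indel."""
    return "SNP" if len(ref) == 1 and len(alt) == 1 else "indel"


def read_vcf(path: str | Path, sample_roles: Mapping[str, str]) -> pd.DataFrame:
    """Read a VCF into a VariantTable.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped; 4.2 expected).
    sample_roles
        Mapping of VCF sample name to one of ``parent1, parent2, bulkA,
        bulkB``.  All four roles must be assigned.

    Only biallelic records with called genotypes for all four roles and
    an AD field on both bulks are consumed; everything else is dropped
    and counted in the log.
    """
    by_role = {role: sample for sample, role in sample_roles.items()}
    missing_roles = [r for r in ROLES if r not in by_role]
    if missing_roles:
        raise ValueError(f"sample_roles does not assign roles: {missing_roles}")

    rows = []
    n_multi = n_missing = 0
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = set(vcf.header.samples)
        absent = [s for s in by_role.values() if s not in vcf_samples]
        if absent:
            raise ValueError(f"samples not present in VCF: {absent}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            samples = {role: rec.samples[by_role[role]] for role in ROLES}
            gts = {role: _gt_string(s.get("GT")) for role, s in samples.items()}
            ads = {
                role: samples[role].get("AD") for role in ("bulkA", "bulkB")
            }
            if any(g is None for g in gts.values()) or any(
                ad is None or any(d is None for d in ad[:2]) for ad in ads.values()
            ):
                n_missing += 1
                continue
            rows.append(
                (
                    rec.chrom,
                    rec.pos,
                    classify_variant(rec.ref, rec.alts[0]),
                    gts["parent1"],
                    gts["parent2"],
                    int(ads["bulkA"][0]),
                    int(ads["bulkA"][1]),
                    int(ads["bulkB"][0]),
                    int(ads["bulkB"][1]),
                )
            )
    if n_multi or n_missing:
        log.info(
            "read_vcf(%s): dropped %d multi-allelic and %d missing-field records",
            path,
            n_multi,
            n_missing,
        )
    table = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return validate_variant_table(table)


def write_vcf(
    table: pd.DataFrame,
    path: str | Path,
    samples: Iterable[str] = DEFAULT_SAMPLES,
    contig_lengths: Mapping[str, int] | None = None,
    parent_depth: int = 20,
) -> None:
    """Write a VariantTable as VCF 4.2 with FORMAT GT:AD:DP.

    Sample order is (parent1, parent2, bulkA, bulkB).  REF/ALT sequences
    are synthesized (``A``/``T`` for SNPs, ``A``/``AT`` for indels) — the
    statistic only needs type and depths.  Parents get depths consistent
    with their fixed homozygous genotypes.
    """
    table = validate_variant_table(table)
    samples = list(samples)
    if len(samples) != 4:
        raise ValueError("exactly four sample names required")
    if contig_lengths is None:
        contig_lengths = table.groupby("chrom", sort=False)["pos"].max().to_dict()

    def fmt_parent(gt: str) -> str:
        ref_d = parent_depth if gt == "0/0" else 0
        alt_d = parent_depth - ref_d
        return f"{gt}:{ref_d},{alt_d}:{parent_depth}"

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bulkmap\n")
        for chrom in sorted(contig_lengths, key=lambda c: str(c)):
            fh.write(f"##contig=<ID={chrom},length={int(contig_lengths[chrom])}>\n")
        fh.write('##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for row in table.itertuples(index=False):
            ref, alt = ("A", "T") if row.variant_type == "SNP" else ("A", "AT")
            a_dp = row.bulkA_ref_depth + row.bulkA_alt_depth
            b_dp = row.bulkB_ref_depth + row.bulkB_alt_depth
            fields = [
                str(row.chrom),
                str(int(row.pos)),
                ".",
                ref,
                alt,
                ".",
                "PASS",
                f"VT={row.variant_type}",
                "GT:AD:DP",
                fmt_parent(row.parent1_gt),
                fmt_parent(row.parent2_gt),
                f"{_bulk_gt(row.bulkA_ref_depth, row.bulkA_alt_depth)}:"
                f"{row.bulkA_ref_depth},{row.bulkA_alt_depth}:{a_dp}",
                f"{_bulk_gt(row.bulkB_ref_depth, row.bulkB_alt_depth)}:"
                f"{row.bulkB_ref_depth},{row.bulkB_alt_depth}:{b_dp}",
            ]
            fh.write("\t".join(fields) + "\n")


def _bulk_gt(ref_depth: int, alt_depth: int) -> str:
    """Nominal pooled genotype (pools are mixtures; GT is informational)."""
    if alt_depth == 0:
        return "0/0"
    if ref_depth == 0:
        return "1/1"
    return "0/1"


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene models (``type == gene`` features only) from GFF3."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gene_id, feat.seqid, feat.start, feat.end, feat.strand or "."))
    if not rows:
        log.warning("read_gff3(%s): no gene features found", path)
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id in GFF3: {dups[:5]}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene with start > end")
    return sort_by_position(genes, pos_col="start")


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a gene-model table as GFF3 (gene features only)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tbulkmap\tgene\t{int(row.start)}\t{int(row.end)}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene-count TSV (gene_id + one column per bulk), gene_id as index."""
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    if (counts < 0).any().any():
        raise ValueError("negative counts")
    return counts


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_qpcr_tsv(path: str | Path) -> pd.DataFrame:
    """Read a qPCR table with columns gene, sample, part, replicate, ct."""
    panel = pd.read_csv(path, sep="\t")
    required = {"gene", "sample", "part", "ct"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if (panel["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return panel
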