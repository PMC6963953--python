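"""Delta-index genome scan: the core bulked-segregant statistic.

Stages
------
1. :func:`filter_variants` — depth and parent-informativeness filters.
2. :func:`compute_index` — per-bulk allele index (alt / total depth) and
   their difference ``delta = index_A - index_B``.
3. :func:`window_scan` — sliding-window means along each chromosome,
   LOESS-smoothed.
4. :func:`null_threshold` — Monte-Carlo null: both bulks resampled as
   Binomial(observed depth, 1/2), the pooled no-QTL F2 expectation; the
   per-window quantile of |window mean| at the requested confidence,
   smoothed with the same LOESS settings, is the threshold track.
5. :func:`call_regions` — maximal runs of windows whose smoothed |delta|
   exceeds the threshold, merged across single missing windows.

The scan applies identically to DNA-derived and RNA-derived variant
tables; SNPs and indels are scanned separately by default (see
:func:`run_scan`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from bulkmap._util import natural_key, sort_by_position
from bulkmap.io_formats import validate_variant_table
from bulkmap.simdata import haldane_r

log = logging.getLogger(__name__)

_OPPOSITE_HOM = {("0/0", "1/1"), ("1/1", "0/0")}


@dataclass
class FilterConfig:
    """Variant retention rules (depth bound is exclusive: keep if > min_depth)."""

    min_depth: int = 5
    require_parent_informative: bool = True

    def __post_init__(self):
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class ScanConfig:
    window_size: int = 100_000
    step: int = 10_000
    loess_span: float = 0.3
    min_variants_per_window: int = 3

    def __post_init__(self):
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must lie in (0, 1]")
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if self.window_size <= 0 or self.step <= 0:
            raise ValueError("window_size and step must be positive")


@dataclass
class ThresholdConfig:
    """Monte-Carlo null settings.

    With ``n_per_bulk`` unset the null redraws both bulks' alt counts as
    Binomial(observed depth, 1/2).  Setting it switches to the full
    bulk-sampling null: each replicate simulates both bulks' individual
    genotypes along the chromosome (recombination from ``cm_per_mb`` via
    the Haldane map) before the read draw, which also captures the
    chromosome-scale allele-frequency drift of finite bulks.
    """

    confidence: float = 0.99
    null_reps: int = 10_000
    seed: int = 0
    n_per_bulk: int | None = None
    cm_per_mb: float = 4.0

    def __post_init__(self):
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")
        if self.null_reps < 100:
            log.warning("null_reps=%d < 100: quantile will be unstable", self.null_reps)


@dataclass
class WindowProfile:
    """Per-chromosome window tracks.

    ``frames[chrom]`` has columns ``center, n_variants, mean_delta,
    smoothed_delta``; windows with fewer than ``min_variants_per_window``
    variants carry NaN (missing, never zero).
    """

    frames: dict[str, pd.DataFrame] = field(default_factory=dict)
    window_size: int = 100_000
    step: int = 10_000


def filter_variants(table: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Keep variants deep enough in both bulks and (optionally) with
    opposite-homozygous parents.  Returns a new sorted table; logs the
    audit counts."""
    table = validate_variant_table(table)
    n_in = len(table)
    depth_a = table["bulkA_ref_depth"] + table["bulkA_alt_depth"]
    depth_b = table["bulkB_ref_depth"] + table["bulkB_alt_depth"]
    keep = (depth_a > cfg.min_depth) & (depth_b > cfg.min_depth)
    n_depth = int(keep.sum())
    if cfg.require_parent_informative:
        informative = [
            (p1, p2) in _OPPOSITE_HOM
            for p1, p2 in zip(table["parent1_gt"], table["parent2_gt"])
        ]
        keep &= pd.Series(informative, index=table.index)
    out = table.loc[keep].reset_index(drop=True)
    log.info(
        "filter_variants: %d in, %d pass depth > %d, %d retained",
        n_in,
        n_depth,
        cfg.min_depth,
        len(out),
    )
    return out


def compute_index(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variant allele index for each bulk and their difference.

    index = alt_depth / (ref_depth + alt_depth) per bulk;
    delta = index_A - index_B (head bulk minus non-head bulk).
    """
    depth_a = (table["bulkA_ref_depth"] + table["bulkA_alt_depth"]).to_numpy()
    depth_b = (table["bulkB_ref_depth"] + table["bulkB_alt_depth"]).to_numpy()
    if (depth_a == 0).any() or (depth_b == 0).any():
        raise AssertionError("zero-total-depth rows must be filtered out upstream")
    index_a = table["bulkA_alt_depth"].to_numpy() / depth_a
    index_b = table["bulkB_alt_depth"].to_numpy() / depth_b
    track = pd.DataFrame(
        {
            "chrom": table["chrom"].to_numpy(),
            "pos": table["pos"].to_numpy(),
            "variant_type": table["variant_type"].to_numpy(),
            "index_A": index_a,
            "index_B": index_b,
            "delta": index_a - index_b,
            "depth_A": depth_a,
            "depth_B": depth_b,
        }
    )
    return sort_by_position(track)


def window_centers(chrom_length: int, cfg: ScanConfig) -> np.ndarray:
    """Centers of sliding windows [c - w/2, c + w/2) covering the chromosome."""
    half = cfg.window_size // 2
    last = max(chrom_length - half, half)
    return np.arange(half, last + 1, cfg.step, dtype=np.int64)


def _window_bounds(pos: np.ndarray, centers: np.ndarray, window_size: int):
    half = window_size // 2
    lo = np.searchsorted(pos, centers - half, side="left")
    hi = np.searchsorted(pos, centers + half, side="left")
    return lo, hi


def _loess(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    if len(x) == 0:
        return np.array([])
    if len(x) == 1:
        return y.astype(float).copy()
    return lowess(y, x, frac=span, it=0, return_sorted=False)


def _chrom_lengths_from(track: pd.DataFrame, chrom_lengths) -> dict[str, int]:
    if chrom_lengths is not None:
        return dict(chrom_lengths)
    return track.groupby("chrom", sort=False)["pos"].max().to_dict()


def window_scan(
    track: pd.DataFrame,
    cfg: ScanConfig,
    chrom_lengths: Mapping[str, int] | None = None,
) -> WindowProfile:
    """Sliding-window mean of delta per chromosome, LOESS-smoothed.

    Windows with fewer than ``cfg.min_variants_per_window`` variants are
    NaN; the LOESS fit uses only populated windows and is evaluated at
    their centers (missing windows stay missing).
    """
    lengths = _chrom_lengths_from(track, chrom_lengths)
    profile = WindowProfile(window_size=cfg.window_size, step=cfg.step)
    for chrom in sorted(lengths, key=natural_key):
        sub = track[track["chrom"] == chrom]
        if sub.empty:
            log.warning("window_scan: no retained variants on %s", chrom)
            continue
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        centers = window_centers(int(lengths[chrom]), cfg)
        lo, hi = _window_bounds(pos, centers, cfg.window_size)
        counts = hi - lo
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        with np.errstate(invalid="ignore", divide="ignore"):
            means = (csum[hi] - csum[lo]) / counts
        means[counts < cfg.min_variants_per_window] = np.nan
        smoothed = np.full_like(means, np.nan)
        ok = ~np.isnan(means)
        smoothed[ok] = _loess(centers[ok].astype(float), means[ok], cfg.loess_span)
        profile.frames[chrom] = pd.DataFrame(
            {
                "center": centers,
                "n_variants": counts,
                "mean_delta": means,
                "smoothed_delta": smoothed,
            }
        )
    return profile


def null_threshold(
    track: pd.DataFrame,
    scan_cfg: ScanConfig,
    thr_cfg: ThresholdConfig,
    chrom_lengths: Mapping[str, int] | None = None,
    chunk: int = 1000,
) -> dict[str, pd.DataFrame]:
    """Depth-aware Monte-Carlo null threshold per window.

    For every retained variant, both bulks' alt counts are redrawn as
    Binomial(observed depth, 1/2) — the pooled F2 expectation with no
    causal locus — and the window means recomputed.  The threshold is
    the ``confidence`` quantile of |window mean| over ``null_reps``
    replicates, then smoothed with the scan's LOESS settings.

    Returns ``{chrom: DataFrame(center, threshold_raw, threshold)}``.
    """
    rng = np.random.default_rng(thr_cfg.seed)
    lengths = _chrom_lengths_from(track, chrom_lengths)
    out: dict[str, pd.DataFrame] = {}
    for chrom in sorted(lengths, key=natural_key):
        sub = track[track["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        depth_a = sub["depth_A"].to_numpy().astype(np.int64)
        depth_b = sub["depth_B"].to_numpy().astype(np.int64)
        centers = window_centers(int(lengths[chrom]), scan_cfg)
        lo, hi = _window_bounds(pos, centers, scan_cfg.window_size)
        counts = hi - lo
        valid = counts >= scan_cfg.min_variants_per_window
        raw = np.full(len(centers), np.nan)
        if valid.any():
            nvar = len(pos)
            lo_v, hi_v, cnt_v = lo[valid], hi[valid], counts[valid]
            if thr_cfg.n_per_bulk is not None:
                chunk = min(chunk, max(1, 50_000_000 // (4 * thr_cfg.n_per_bulk * max(nvar, 1))))
                r = haldane_r(np.diff(pos) / 1e6 * thr_cfg.cm_per_mb)
            abs_means = np.empty((thr_cfg.null_reps, int(valid.sum())), dtype=np.float32)
            done = 0
            while done < thr_cfg.null_reps:
                n = min(chunk, thr_cfg.null_reps - done)
                if thr_cfg.n_per_bulk is None:
                    f_a = f_b = 0.5
                else:
                    f_a = _null_bulk_freqs(rng, r, thr_cfg.n_per_bulk, n, nvar)
                    f_b = _null_bulk_freqs(rng, r, thr_cfg.n_per_bulk, n, nvar)
                alt_a = rng.binomial(depth_a, f_a, size=(n, nvar))
                alt_b = rng.binomial(depth_b, f_b, size=(n, nvar))
                delta = alt_a / depth_a - alt_b / depth_b
                csum = np.concatenate(
                    [np.zeros((n, 1)), np.cumsum(delta, axis=1)], axis=1
                )
                abs_means[done : done + n] = np.abs(
                    (csum[:, hi_v] - csum[:, lo_v]) / cnt_v
                )
                done += n
            raw[valid] = np.quantile(abs_means, thr_cfg.confidence, axis=0)
        smoothed = np.full(len(centers), np.nan)
        smoothed[valid] = _loess(
            centers[valid].astype(float), raw[valid], scan_cfg.loess_span
        )
        out[chrom] = pd.DataFrame(
            {"center": centers, "threshold_raw": raw, "threshold": smoothed}
        )
    return out


def _null_bulk_freqs(
    rng, r: np.ndarray, n_per_bulk: int, reps: int, nvar: int
) -> np.ndarray:
    """Per-replicate true allele frequencies of a simulated F2 bulk.

    Simulates ``2 * n_per_bulk`` gametes per replicate with crossover
    probability *r* between adjacent variants; the bulk frequency is the
    gamete mean, so linked drift along the chromosome is preserved.
    """
    n_gam = 2 * n_per_bulk
    first = rng.integers(0, 2, size=(reps * n_gam, 1), dtype=np.int8)
    if nvar > 1:
        crossover = (rng.random((reps * n_gam, nvar - 1)) < r).astype(np.int8)
        switched = np.cumsum(crossover, axis=1, dtype=np.int32) % 2
        alleles = np.concatenate([first, first ^ switched.astype(np.int8)], axis=1)
    else:
        alleles = first
    return alleles.reshape(reps, n_gam, nvar).mean(axis=1)


def region_size_mb(start: int, end: int) -> float:
    """Reported region size in Mb, (end - start)/1e6 rounded to 2 decimals."""
    return round((int(end) - int(start)) / 1e6, 2)


REGION_COLUMNS = ["chrom", "start", "end", "size_mb", "sign", "n_windows"]


def call_regions(
    profile: WindowProfile,
    thresholds: Mapping[str, pd.DataFrame],
    merge_gap: int = 1,
) -> pd.DataFrame:
    """Maximal runs of windows with |smoothed delta| > threshold.

    Runs separated by at most *merge_gap* missing (not merely
    sub-threshold) windows are merged.  Region span is the outermost
    window edges; size is reported via :func:`region_size_mb`.
    """
    half = profile.window_size // 2
    rows = []
    for chrom in sorted(profile.frames, key=natural_key):
        frame = profile.frames[chrom]
        thr = thresholds.get(chrom)
        if thr is None:
            continue
        if not np.array_equal(frame["center"].to_numpy(), thr["center"].to_numpy()):
            raise ValueError(f"profile/threshold window grids differ on {chrom}")
        smoothed = frame["smoothed_delta"].to_numpy()
        t = thr["threshold"].to_numpy()
        valid = ~np.isnan(smoothed) & ~np.isnan(t)
        above = valid & (np.abs(smoothed) > t)
        centers = frame["center"].to_numpy()

        runs: list[list[int]] = []
        for i in np.flatnonzero(above):
            if runs and _mergeable(runs[-1][-1], i, valid, merge_gap):
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            i0, i1 = run[0], run[-1]
            start = max(int(centers[i0]) - half, 1)
            end = int(centers[i1]) + half
            sign = 1 if np.nanmean(smoothed[i0 : i1 + 1]) >= 0 else -1
            rows.append(
                (chrom, start, end, region_size_mb(start, end), sign, i1 - i0 + 1)
            )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def _mergeable(prev: int, cur: int, valid: np.ndarray, merge_gap: int) -> bool:
    gap = range(prev + 1, cur)
    if len(gap) == 0:
        return True
    return len(gap) <= merge_gap and not valid[list(gap)].any()


@dataclass
class ScanResult:
    regions: pd.DataFrame
    profiles: dict[str, WindowProfile]
    thresholds: dict[str, dict[str, pd.DataFrame]]
    track: pd.DataFrame


def run_scan(
    table: pd.DataFrame,
    filter_cfg: FilterConfig | None = None,
    scan_cfg: ScanConfig | None = None,
    thr_cfg: ThresholdConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    split_types: bool = True,
) -> ScanResult:
    """Filter -> index -> windows -> threshold -> regions.

    With ``split_types`` SNPs and indels are scanned separately and the
    regions table carries ``method`` values ``SNP-index`` /
    ``indel-index``; otherwise a single joint scan tagged ``joint``.
    """
    filter_cfg = filter_cfg or FilterConfig()
    scan_cfg = scan_cfg or ScanConfig()
    thr_cfg = thr_cfg or ThresholdConfig()
    filtered = filter_variants(table, filter_cfg)
    track = compute_index(filtered)
    if split_types:
        subsets = [
            ("SNP-index", track[track["variant_type"] == "SNP"]),
            ("indel-index", track[track["variant_type"] == "indel"]),
        ]
    else:
        subsets = [("joint", track)]
    region_frames, profiles, thresholds = [], {}, {}
    for method, sub in subsets:
        if sub.empty:
            continue
        profile = window_scan(sub, scan_cfg, chrom_lengths)
        thr = null_threshold(sub, scan_cfg, thr_cfg, chrom_lengths)
        regions = call_regions(profile, thr)
        regions.insert(0, "method", method)
        region_frames.append(regions)
        profiles[method] = profile
        thresholds[method] = thr
    regions = (
        pd.concat(region_frames, ignore_index=True)
        if region_frames
        else pd.DataFrame(columns=["method", *REGION_COLUMNS])
    )
    return ScanResult(regions=regions, profiles=profiles, thresholds=thresholds, track=track)


def plot_scan(
    track: pd.DataFrame,
    profile: WindowProfile,
    thresholds: Mapping[str, pd.DataFrame],
    path: str,
) -> None:
    """Per-chromosome scatter of delta with the smoothed track (black)
    and the +/- threshold lines (red, dashed).  Writes a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = [c for c in sorted(profile.frames, key=natural_key) if c in thresholds]
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 2.5 * len(chroms)), squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = track[track["chrom"] == chrom]
        frame = profile.frames[chrom]
        thr = thresholds[chrom]
        ax.scatter(sub["pos"] / 1e6, sub["delta"], s=4, alpha=0.4, color="grey")
        ax.plot(frame["center"] / 1e6, frame["smoothed_delta"], color="black", lw=1.5)
        for sign in (1, -1):
            ax.plot(thr["center"] / 1e6, sign * thr["threshold"], "r--", lw=1)
        ax.set_ylim(-1.05, 1.05)
        ax.set_ylabel("delta index")
        ax.set_title(chrom, fontsize=9)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def total_genes(regions: pd.DataFrame, method: str | None = None) -> int:
    """Sum the per-region gene counts of a region report (``n_genes`` column)."""
    sub = regions if method is None else regions[regions["method"] == method]
    return int(sub["n_genes"].sum())


def count_regions(*region_tables: pd.DataFrame) -> int:
    """Total number of candidate regions across one or more region reports."""
    return int(sum(len(t) for t in region_tables))
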