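"""Between-bulk expression analysis: FPKM, fixed-dispersion exact DEG
test with BH FDR, and 2^-ddCt relative quantification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: relative tolerance when comparing outcome probabilities for the
#: "no more probable than observed" tail of the exact test; guards
#: symmetric ties against floating-point jitter
_TIE_RTOL = 1e-8


@dataclass
class DEGConfig:
    dispersion: float = 0.1
    alpha_fdr: float = 0.05
    min_abs_log2fc: float = 1.0
    pseudocount: float = 0.5

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def fpkm(
    counts: np.ndarray | pd.DataFrame,
    lengths: np.ndarray | pd.Series,
    library_sizes: np.ndarray | pd.Series | float,
) -> np.ndarray | pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM = count * 1e9 / (library_size * length); *lengths* is per gene
    (rows), *library_sizes* per sample (columns).
    """
    lengths = np.asarray(lengths, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    if isinstance(counts, pd.DataFrame):
        values = counts.to_numpy(dtype=float)
        out = values * 1e9 / (library_sizes[np.newaxis, :] * lengths[:, np.newaxis])
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    counts = np.asarray(counts, dtype=float)
    return counts * 1e9 / (library_sizes * lengths)


def _conditional_probs(s: int, dispersion: float) -> np.ndarray:
    """P(X = x | X + Y = s) for iid NB(mean s/2, dispersion), x = 0..s."""
    n = 1.0 / dispersion
    p = n / (n + s / 2.0)
    x = np.arange(s + 1)
    logpmf = stats.nbinom.logpmf(x, n, p)
    logjoint = logpmf + logpmf[::-1]
    joint = np.exp(logjoint - logjoint.max())
    return joint / joint.sum()


def nb_exact_test(count_a: int, count_b: int, dispersion: float) -> float:
    """Two-sided conditional exact test for one NB count per group.

    Under the null both counts share one negative-binomial mean with the
    given fixed dispersion.  Conditioning on s = a + b, the p-value is
    the total conditional probability of splits (x, s - x) no more
    probable than the observed one.  Counts must be library-size
    adjusted upstream.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    a, b = int(count_a), int(count_b)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    s = a + b
    if s == 0:
        return 1.0
    probs = _conditional_probs(s, dispersion)
    p_obs = probs[a]
    p = probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum()
    return float(min(p, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    adjusted[i] = min over j with p[j] >= p[i] of min(1, p[j]*m/rank(j))
    — implemented as the running minimum over descending ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_degs(
    counts: pd.DataFrame,
    cfg: DEGConfig | None = None,
    library_sizes: tuple[float, float] | None = None,
    bulk_cols: tuple[str, str] = ("bulkA", "bulkB"),
) -> pd.DataFrame:
    """DEG table for a two-bulk count matrix (one observation per bulk).

    Counts are normalized to a common library scale by total-count
    ratio, the exact test run at the configured fixed dispersion, BH-FDR
    adjusted, and genes called ``up``/``down``/``ns`` by
    |log2FC| >= min_abs_log2fc (inclusive) and FDR < alpha (strict).
    Positive log2FC means higher in the first-listed bulk.
    """
    cfg = cfg or DEGConfig()
    a = counts[bulk_cols[0]].to_numpy(dtype=float)
    b = counts[bulk_cols[1]].to_numpy(dtype=float)
    if library_sizes is None:
        library_sizes = (a.sum(), b.sum())
    lib = np.asarray(library_sizes, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    scale = lib.mean() / lib
    a_norm = a * scale[0]
    b_norm = b * scale[1]
    log2fc = np.log2((a_norm + cfg.pseudocount) / (b_norm + cfg.pseudocount))
    a_int = np.rint(a_norm).astype(np.int64)
    b_int = np.rint(b_norm).astype(np.int64)
    p = np.array(
        [nb_exact_test(ai, bi, cfg.dispersion) for ai, bi in zip(a_int, b_int)]
    )
    fdr = bh_fdr(p)
    call = classify_calls(log2fc, fdr, cfg)
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "fdr": fdr, "call": call},
        index=counts.index,
    )


def classify_calls(log2fc, fdr, cfg: DEGConfig | None = None) -> np.ndarray:
    """up/down/ns calls: |log2FC| >= threshold (inclusive), FDR < alpha (strict)."""
    cfg = cfg or DEGConfig()
    log2fc = np.asarray(log2fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    significant = fdr < cfg.alpha_fdr
    return np.where(
        (log2fc >= cfg.min_abs_log2fc) & significant,
        "up",
        np.where((log2fc <= -cfg.min_abs_log2fc) & significant, "down", "ns"),
    )


def deg_summary(deg_table: pd.DataFrame) -> dict[str, int]:
    """Tally of a DEG report: up, down, ns and total significant."""
    calls = deg_table["call"]
    up = int((calls == "up").sum())
    down = int((calls == "down").sum())
    return {
        "up": up,
        "down": down,
        "ns": int((calls == "ns").sum()),
        "total_deg": up + down,
    }


def ddct(
    panel: pd.DataFrame,
    reference_gene: str,
    calibrator: tuple[str, str],
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    *panel* is long-format with columns ``gene, sample, part, ct``
    (technical replicates averaged per (gene, sample, part) first).
    dCt = Ct_target - Ct_reference within each (sample, part);
    ddCt = dCt - dCt at the *calibrator* (sample, part); relative
    expression = 2^-ddCt, identically 1.0 at the calibrator.
    """
    mean_ct = (
        panel.groupby(["gene", "sample", "part"], sort=False)["ct"].mean().reset_index()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index(["sample", "part"])["ct"]
    targets = mean_ct[mean_ct["gene"] != reference_gene].copy()
    keys = list(zip(targets["sample"], targets["part"]))
    missing = sorted({k for k in keys if k not in ref.index})
    if missing:
        raise ValueError(f"reference gene {reference_gene!r} not measured for {missing}")
    targets["dct"] = targets["ct"].to_numpy() - ref.loc[keys].to_numpy()

    cal_sample, cal_part = calibrator
    rows = []
    for gene, sub in targets.groupby("gene", sort=False):
        cal = sub[(sub["sample"] == cal_sample) & (sub["part"] == cal_part)]
        if cal.empty:
            raise ValueError(
                f"calibrator {calibrator} not measured for gene {gene!r}"
            )
        ddct_vals = sub["dct"] - float(cal["dct"].iloc[0])
        out = sub[["gene", "sample", "part"]].copy()
        out["ddct"] = ddct_vals
        out["rel_expr"] = 2.0 ** (-ddct_vals)
        rows.append(out)
    return pd.concat(rows, ignore_index=True)
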