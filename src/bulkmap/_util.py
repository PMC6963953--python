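"""Small shared helpers."""

from __future__ import annotations

import re

_CHUNK = re.compile(r"(\d+)")


def natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically (A02 < A05 < A10)."""
    return tuple(
        int(part) if part.isdigit() else part for part in _CHUNK.split(str(name))
    )


def sort_by_position(df, chrom_col="chrom", pos_col="pos"):
    """Return *df* sorted by natural chromosome order, then position."""
    key = df[chrom_col].map(natural_key)
    order = sorted(range(len(df)), key=lambda i: (key.iloc[i], df[pos_col].iloc[i]))
    return df.iloc[order].reset_index(drop=True)
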