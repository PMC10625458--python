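"""Agreement diagnostics between screening engines.

Bland-Altman limits of agreement on paired standardized coefficients, and
cross-tabulation of p-value threshold calls.  The difference direction is
fixed as (gold standard - comparator), i.e. values_a should be the full
Cox PH screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlandAltmanSummary",
    "DiscordanceTable",
    "bland_altman",
    "discordance_table",
    "bland_altman_plot",
]


@dataclass
class BlandAltmanSummary:
    bias: float
    sd_diff: float
    level: float
    lower: float
    upper: float
    n_pairs: int
    n_below: int
    n_above: int


@dataclass
class DiscordanceTable:
    threshold: float
    counts: np.ndarray  # 2x2: rows method A (<=, >), cols method B (<=, >)
    discordant: int
    max_abs_p_diff: float

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())


def bland_altman(values_a, values_b, level: float = 0.99) -> BlandAltmanSummary:
    """Limits of agreement for paired measurements (differences a - b).

    Limits are bias +/- q * sd(diff) with q the two-sided normal quantile
    for ``level``; counts of pairs falling outside each limit are reported.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be equal-length 1-d vectors")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite entries in paired vectors")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0,1)")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    q = float(stats.norm.ppf(0.5 + level / 2.0))
    lower = bias - q * sd
    upper = bias + q * sd
    return BlandAltmanSummary(
        bias=bias, sd_diff=sd, level=level, lower=lower, upper=upper,
        n_pairs=int(d.size), n_below=int((d < lower).sum()), n_above=int((d > upper).sum()),
    )


def discordance_table(p_a, p_b, threshold: float) -> DiscordanceTable:
    """Cross-tabulate significance calls (p <= threshold) of two engines."""
    pa = np.asarray(p_a, dtype=float)
    pb = np.asarray(p_b, dtype=float)
    if pa.shape != pb.shape or pa.ndim != 1:
        raise ValueError("p-vectors must be equal-length 1-d")
    if np.any((pa < 0) | (pa > 1) | (pb < 0) | (pb > 1)):
        raise ValueError("p-values must lie in [0,1]")
    sig_a = pa <= threshold
    sig_b = pb <= threshold
    counts = np.array(
        [
            [int(np.sum(sig_a & sig_b)), int(np.sum(sig_a & ~sig_b))],
            [int(np.sum(~sig_a & sig_b)), int(np.sum(~sig_a & ~sig_b))],
        ]
    )
    disc = sig_a != sig_b
    max_diff = float(np.max(np.abs(pa - pb)[disc])) if disc.any() else 0.0
    return DiscordanceTable(
        threshold=threshold, counts=counts,
        discordant=int(counts[0, 1] + counts[1, 0]), max_abs_p_diff=max_diff,
    )


def summary_frame(ba: BlandAltmanSummary, tables: list[DiscordanceTable]) -> pd.DataFrame:
    """Flat numeric summary for TSV output."""
    rows = [
        {"metric": "bias", "value": ba.bias},
        {"metric": "sd_diff", "value": ba.sd_diff},
        {"metric": f"loa_lower_{ba.level}", "value": ba.lower},
        {"metric": f"loa_upper_{ba.level}", "value": ba.upper},
        {"metric": "n_pairs", "value": ba.n_pairs},
        {"metric": "n_below", "value": ba.n_below},
        {"metric": "n_above", "value": ba.n_above},
    ]
    for t in tables:
        rows += [
            {"metric": f"discordant_at_{t.threshold:g}", "value": t.discordant},
            {"metric": f"max_abs_p_diff_at_{t.threshold:g}", "value": t.max_abs_p_diff},
        ]
    return pd.DataFrame(rows)


def bland_altman_plot(values_a, values_b, level: float = 0.99, path: str | None = None):
    """Best-effort Bland-Altman scatter (mean vs difference) with limit lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    ba = bland_altman(a, b, level)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a + b) / 2.0, a - b, s=6, alpha=0.5)
    for y, style in [(ba.bias, "-"), (ba.lower, "--"), (ba.upper, "--")]:
        ax.axhline(y, color="crimson", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of paired values")
    ax.set_ylabel("difference (A - B)")
    ax.set_title(f"Bland-Altman, {level:.0%} limits of agreement")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return path
    return fig
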