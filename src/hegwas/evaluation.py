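"""Accuracy metrics: thresholded disagreement counts and best-fit line.

Two ways of comparing the modified algorithm's effects b' against the
original algorithm's b (or any two per-SNP vectors): count entries that
differ by more than a threshold e, and fit an ordinary least-squares line
of b' on b (ideal: slope 1, intercept 0).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = ["AccuracyReport", "accuracy_count", "best_fit", "compare_results"]


@dataclass
class AccuracyReport:
    """Disagreement count at threshold e, plus the optional best-fit line."""

    error_threshold: float
    n_diff: int
    n_total: int
    accuracy_pct: float
    slope: float | None = None
    intercept: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def accuracy_count(b, b_prime, e: float) -> AccuracyReport:
    """Count entries with |b - b'| > e; accuracy is the complementary %."""
    b = np.asarray(b, dtype=float).ravel()
    bp = np.asarray(b_prime, dtype=float).ravel()
    if b.shape != bp.shape:
        raise ValueError(f"length mismatch: {b.shape[0]} vs {bp.shape[0]}")
    diff = np.abs(b - bp)
    # NaN pairs (flagged SNPs) count as disagreements unless both are NaN
    both_nan = np.isnan(b) & np.isnan(bp)
    n_diff = int(np.sum((diff > e) | (np.isnan(diff) & ~both_nan)))
    k = b.shape[0]
    return AccuracyReport(
        error_threshold=e,
        n_diff=n_diff,
        n_total=k,
        accuracy_pct=100.0 * (k - n_diff) / k,
    )


def best_fit(b, b_prime) -> tuple[float, float]:
    """OLS degree-1 fit of b' on b; returns (slope, intercept).

    Non-finite pairs are dropped.  Raises on fewer than two usable points
    or a constant b (undefined slope).
    """
    b = np.asarray(b, dtype=float).ravel()
    bp = np.asarray(b_prime, dtype=float).ravel()
    if b.shape != bp.shape:
        raise ValueError(f"length mismatch: {b.shape[0]} vs {bp.shape[0]}")
    ok = np.isfinite(b) & np.isfinite(bp)
    b, bp = b[ok], bp[ok]
    if b.shape[0] < 2:
        raise ValueError("need at least two finite pairs for a line fit")
    if np.ptp(b) == 0:
        raise ValueError("b is constant; slope undefined")
    slope, intercept = np.polyfit(b, bp, 1)
    return float(slope), float(intercept)


def compare_results(tsv_a, tsv_b, thresholds=(0.1, 0.01, 0.005), plot_path=None) -> list:
    """Compare two result TSVs (beta columns) at several thresholds.

    Returns one AccuracyReport per threshold, each carrying the shared
    best-fit line; optionally writes a scatter plot with the y=x and
    best-fit lines.
    """
    a = pd.read_csv(tsv_a, sep="\t")
    b = pd.read_csv(tsv_b, sep="\t")
    if len(a) != len(b):
        raise ValueError(f"result files differ in length: {len(a)} vs {len(b)}")
    ba, bb = a["beta"].to_numpy(), b["beta"].to_numpy()
    slope, intercept = best_fit(ba, bb)
    reports = []
    for e in thresholds:
        r = accuracy_count(ba, bb, e)
        r.slope, r.intercept = slope, intercept
        reports.append(r)
    if plot_path is not None:
        _scatter(ba, bb, slope, intercept, plot_path)
    return reports


def _scatter(b, b_prime, slope, intercept, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(b, b_prime, s=6, alpha=0.5)
    lo = np.nanmin([np.nanmin(b), np.nanmin(b_prime)])
    hi = np.nanmax([np.nanmax(b), np.nanmax(b_prime)])
    grid = np.linspace(lo, hi, 2)
    ax.plot(grid, grid, "k--", lw=1, label="y = x")
    ax.plot(grid, slope * grid + intercept, "r-", lw=1,
            label=f"y = {slope:.4g}x + {intercept:.4g}")
    ax.set_xlabel("b (reference)")
    ax.set_ylabel("b' (comparison)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
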