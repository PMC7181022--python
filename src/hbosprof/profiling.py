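"""Dataset-level HBOS statistics.

A dataset's score distribution is summarized as an area-normalized
probability histogram (bin width 0.1 by default), so curves from datasets of
different sizes are directly comparable: the height of the peak reflects how
popular the peak score is, independent of dataset size.  Per-residue-type
outlier rates are reported per 1000 residues of the same type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .hbos_model import DEFAULT_THRESHOLD, ScoreResult


@dataclass(frozen=True)
class ProbabilityHistogram:
    """Area-normalized score histogram: sum(height * bin_width) == 1."""

    bin_width: float
    edges: np.ndarray
    heights: np.ndarray  # density units (probability mass / bin width)

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    @property
    def masses(self) -> np.ndarray:
        """Per-bin probability mass (height * bin width)."""
        return self.heights * self.bin_width

    @property
    def area(self) -> float:
        return float(np.sum(self.heights) * self.bin_width)


class Peak(NamedTuple):
    center: float
    height: float  # density
    mass: float  # per-bin probability


def probability_histogram(scores: Sequence[float], bin_width: float = 0.1) -> ProbabilityHistogram:
    """Histogram of HBOS scores normalized to unit area.

    The domain is [0, ceil(max score)] so no score is dropped; heights are
    count / (n * bin_width).
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("no scores to histogram")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    hi = max(float(math.ceil(scores.max())), bin_width)
    n_bins = max(int(round(hi / bin_width)), 1)
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(scores, bins=edges)
    heights = counts / (scores.size * bin_width)
    return ProbabilityHistogram(bin_width=bin_width, edges=edges, heights=heights)


def find_peak(hist: ProbabilityHistogram) -> Peak:
    """Modal bin of the histogram; ties break toward the lowest bin center."""
    idx = int(np.argmax(hist.heights))  # argmax returns the first (lowest) tie
    return Peak(
        center=float(hist.centers[idx]),
        height=float(hist.heights[idx]),
        mass=float(hist.masses[idx]),
    )


def fraction_above(scores: Sequence[float], threshold: float = DEFAULT_THRESHOLD) -> float:
    """Fraction of scores strictly greater than *threshold*."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("no scores")
    return float(np.count_nonzero(scores > threshold) / scores.size)


def outlier_rate_per_1000(results: Iterable[ScoreResult]) -> pd.DataFrame:
    """Per-residue-type outlier rate per 1000 residues of the same type.

    Unscored residues are excluded from both numerator and denominator.
    Returns a DataFrame with columns res_type, n_residues, n_outliers,
    rate_per_1000, sorted by res_type.
    """
    counts: dict[str, list[int]] = {}
    for res in results:
        if res.unscored:
            continue
        entry = counts.setdefault(res.res_type, [0, 0])
        entry[0] += 1
        entry[1] += int(res.outlier)
    if not counts:
        raise ValueError("no scored residues")
    rows = [
        {
            "res_type": rt,
            "n_residues": n,
            "n_outliers": k,
            "rate_per_1000": 1000.0 * k / n,
        }
        for rt, (n, k) in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def write_histogram_tsv(hist: ProbabilityHistogram, path) -> None:
    df = pd.DataFrame(
        {
            "bin_lo": hist.edges[:-1],
            "bin_hi": hist.edges[1:],
            "center": hist.centers,
            "density": hist.heights,
            "probability": hist.masses,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def plot_probability_histograms(curves: dict[str, ProbabilityHistogram], path=None):
    """Overlay probability-histogram curves (cosmetic helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, hist in curves.items():
        ax.plot(hist.centers, hist.masses, label=label, lw=1.2)
    ax.set_xlabel("HBOS")
    ax.set_ylabel("probability (per 0.1 bin)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
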