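"""Spike-train statistics: rates, inter-spike-interval variability,
histograms, autocorrelograms, and the population-level tests.

The coefficient of variation (CV) of the inter-spike intervals is the
conventional regularity index: sample standard deviation (N-1 denominator)
over mean of the ISIs, i.e. moments computed as for a normal distribution so
the values are directly comparable with the in-vitro literature.  A CV near
zero means clock-like firing; values above ~0.5 indicate pronounced
irregularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "mean_rate",
    "isis",
    "isi_cv",
    "isi_histogram",
    "autocorrelogram",
    "PopulationStats",
    "population_stats",
    "rate_cv_correlation",
    "compare_distributions",
    "normality_test",
]

#: Shapiro-Wilk is applied to at most this many ISIs (larger samples are
#: subsampled with a fixed seed; the test's small-deviation sensitivity at
#: huge n adds nothing here).
SHAPIRO_MAX_N = 5000

#: Minimum spike count for a defined ISI CV (at least two intervals).
MIN_SPIKES_FOR_CV = 3


def mean_rate(train: np.ndarray, duration_ms: float) -> float:
    """Mean firing rate in Hz: spike count over duration."""
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    return len(train) / (duration_ms / 1000.0)


def isis(train: np.ndarray) -> np.ndarray:
    """Inter-spike intervals (ms) of a sorted spike train."""
    return np.diff(np.asarray(train, dtype=float))


def isi_cv(train: np.ndarray) -> float:
    """ISI coefficient of variation; ``nan`` if fewer than 3 spikes."""
    train = np.asarray(train, dtype=float)
    if len(train) < MIN_SPIKES_FOR_CV:
        return math.nan
    iv = np.diff(train)
    return float(np.std(iv, ddof=1) / np.mean(iv))


def isi_histogram(train: np.ndarray, bin_width_ms: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of ISIs with fixed-width bins starting at 0.

    Returns ``(counts, bin_edges)``; the counts sum to the number of ISIs.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    iv = isis(train)
    if len(iv) == 0:
        return np.zeros(0, dtype=np.int64), np.array([0.0])
    n_bins = int(np.floor(iv.max() / bin_width_ms)) + 1
    edges = np.arange(n_bins + 1) * bin_width_ms
    counts, _ = np.histogram(iv, bins=edges)
    return counts.astype(np.int64), edges


def autocorrelogram(
    train: np.ndarray, bin_width_ms: float = 1.0, max_lag_ms: float = 100.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Counts of ordered spike-pair lags in ``(0, max_lag]``.

    Zero-lag self-pairs are excluded.  Each ordered pair ``(s, t)`` with
    ``0 < t - s <= max_lag`` contributes one count to the bin containing
    ``t - s``; the display can be mirrored for the negative side.  Bin
    ``j`` covers ``(j*bw, (j+1)*bw]``.
    """
    if bin_width_ms <= 0 or max_lag_ms <= 0:
        raise ValueError("bin width and max lag must be positive")
    train = np.asarray(train, dtype=float)
    n_bins = int(math.ceil(max_lag_ms / bin_width_ms))
    counts = np.zeros(n_bins, dtype=np.int64)
    edges = np.arange(n_bins + 1) * bin_width_ms
    for i, s in enumerate(train):
        j = np.searchsorted(train, s + max_lag_ms, side="right")
        lags = train[i + 1 : j] - s
        lags = lags[lags > 0]
        if len(lags):
            # right-closed bins: lag exactly on an edge falls in the lower bin
            idx = np.ceil(lags / bin_width_ms).astype(int) - 1
            np.add.at(counts, np.clip(idx, 0, n_bins - 1), 1)
    return counts, edges


def _summary(values: np.ndarray) -> Dict[str, float]:
    values = values[~np.isnan(values)]
    if len(values) == 0:
        return {k: math.nan for k in ("mean", "sd", "median", "q1", "q3")} | {"n": 0}
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else math.nan,
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
        "n": int(len(values)),
    }


@dataclass
class PopulationStats:
    """Per-neuron rate/CV table plus population summaries.

    Neurons with fewer than 3 spikes have an undefined CV (``nan``) and are
    excluded from the CV summary but kept in the rate summary.
    """

    per_neuron: pd.DataFrame  # columns: neuron_id, rate_hz, isi_cv, n_spikes
    rate: Dict[str, float]
    cv: Dict[str, float]

    @property
    def n(self) -> int:
        return len(self.per_neuron)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            self.per_neuron.to_csv(fh, index=False)
            fh.write("# population summary\n")
            pd.DataFrame([{"measure": "rate_hz", **self.rate},
                          {"measure": "isi_cv", **self.cv}]).to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "PopulationStats":
        text = open(path).read().split("# population summary\n")
        per_neuron = pd.read_csv(pd.io.common.StringIO(text[0]))
        summ = pd.read_csv(pd.io.common.StringIO(text[1])).set_index("measure")
        return cls(
            per_neuron=per_neuron,
            rate=summ.loc["rate_hz"].to_dict(),
            cv=summ.loc["isi_cv"].to_dict(),
        )


def population_stats(
    trains: Mapping[int, np.ndarray], duration_ms: float
) -> PopulationStats:
    rows = []
    for nid in sorted(trains):
        t = trains[nid]
        rows.append(
            {
                "neuron_id": nid,
                "rate_hz": mean_rate(t, duration_ms),
                "isi_cv": isi_cv(t),
                "n_spikes": len(t),
            }
        )
    df = pd.DataFrame(rows, columns=["neuron_id", "rate_hz", "isi_cv", "n_spikes"])
    return PopulationStats(
        per_neuron=df,
        rate=_summary(df["rate_hz"].to_numpy(dtype=float)),
        cv=_summary(df["isi_cv"].to_numpy(dtype=float)),
    )


def rate_cv_correlation(stats: PopulationStats) -> Tuple[float, float]:
    """Spearman rank correlation between per-neuron mean rate and ISI CV.

    Neurons without a defined CV are dropped; ties get average ranks.
    """
    df = stats.per_neuron.dropna(subset=["isi_cv"])
    if len(df) < 3:
        raise ValueError("need at least 3 neurons with a defined CV")
    rho, p = sps.spearmanr(df["rate_hz"], df["isi_cv"])
    return float(rho), float(p)


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test (U statistic for ``a`` vs ``b``)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def normality_test(
    samples: Sequence[float], max_n: int = SHAPIRO_MAX_N, subsample_seed: int = 0
) -> Tuple[float, float]:
    """Shapiro-Wilk test of normality ``(W, p)``.

    Samples larger than ``max_n`` are subsampled without replacement with a
    fixed seed, keeping the test well inside its validated range.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 samples")
    if len(x) > max_n:
        x = np.random.default_rng(subsample_seed).choice(x, size=max_n, replace=False)
    w, p = sps.shapiro(x)
    return float(w), float(p)
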