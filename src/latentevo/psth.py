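"""Peri-stimulus time histograms and temporal response analyses.

PSTHs are built on a 1 ms grid over the recording window by convolving
discretized spike times with a truncated, edge-renormalized Gaussian kernel
(2 ms s.d. by default), so spike mass is conserved exactly.  On top of that:

* :func:`temporal_attribution` — which post-onset time windows carry the
  activation increase between the first and the best block (normalized
  difference PSTH, binned 5–50 ms).
* :func:`time_binned_trajectory` — per-time-bin optimization trajectories
  with paired per-block tests, Benjamini–Hochberg corrected.
* :func:`psth_distance` — absolute-area and signed-area distances between
  two normalized PSTHs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .neurons import WINDOW_MS, SpikeRecord

__all__ = [
    "PSTH",
    "AttributionVector",
    "compute_psth",
    "temporal_attribution",
    "time_binned_trajectory",
    "psth_distance",
]


@dataclass
class PSTH:
    """Trial-averaged smoothed firing rate on a 1 ms grid (spikes/s)."""

    times: np.ndarray           # bin left edges, ms
    rates: np.ndarray           # spikes/s
    sigma_ms: float
    n_trials: int
    bin_ms: float = 1.0

    def mean_rate(self, lo: float, hi: float) -> float:
        """Mean rate over the half-open window [lo, hi) ms."""
        sel = (self.times >= lo) & (self.times < hi)
        return float(self.rates[sel].mean())

    def total_spikes(self) -> float:
        """Smoothed spike mass per trial within the grid."""
        return float(self.rates.sum() * self.bin_ms / 1000.0)


@dataclass
class AttributionVector:
    """Fraction of the activation increase attributed to each time window."""

    bin_edges: np.ndarray       # ms, over [0, 200]
    weights: np.ndarray
    best_block: int
    defined: bool = True


@lru_cache(maxsize=8)
def _smoothing_matrix(n_bins: int, sigma_ms: float, bin_ms: float) -> np.ndarray:
    """Column-normalized truncated Gaussian smoother (mass conserving)."""
    centers = np.arange(n_bins) * bin_ms
    diff = centers[:, None] - centers[None, :]
    w = np.exp(-0.5 * (diff / sigma_ms) ** 2)
    radius = 5.0 * sigma_ms
    w[np.abs(diff) > radius] = 0.0
    return w / w.sum(axis=0, keepdims=True)


def compute_psth(records: list[SpikeRecord], bin_ms: float = 1.0,
                 sigma_ms: float = 2.0) -> PSTH:
    """Build a smoothed PSTH from spike records (one record per trial).

    Spike times are discretized to the grid, convolved with a symmetric
    Gaussian pdf (s.d. ``sigma_ms``, truncated and renormalized at the
    window edges), averaged over trials, and scaled to spikes/s.
    """
    if not records:
        raise ValueError("need at least one spike record")
    lo, hi = WINDOW_MS
    edges = np.arange(lo, hi + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    for rec in records:
        c, _ = np.histogram(rec.spike_times, bins=edges)
        counts += c
    smoothed = _smoothing_matrix(counts.size, float(sigma_ms), float(bin_ms)) @ counts
    rates = smoothed / len(records) / (bin_ms / 1000.0)
    return PSTH(edges[:-1].astype(float), rates, float(sigma_ms),
                len(records), float(bin_ms))


def _bin_means(psth: PSTH, edges: np.ndarray) -> np.ndarray:
    return np.array([psth.mean_rate(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])])


def temporal_attribution(block_psths: list[PSTH],
                         bin_width_ms: int = 10) -> AttributionVector:
    """Attribute the first-to-best-block activation change to time windows.

    The best block maximizes the 50–200 ms mean rate.  The per-bin PSTH
    difference (best minus first) over 0–200 ms is normalized by its summed
    difference, so defined weights sum to 1.
    """
    if len(block_psths) < 2:
        raise ValueError("need at least 2 block PSTHs")
    if bin_width_ms not in (5, 10, 20, 25, 50):
        raise ValueError("bin_width_ms must be one of 5, 10, 20, 25, 50")
    best = int(np.argmax([p.mean_rate(50.0, 200.0) for p in block_psths]))
    edges = np.arange(0.0, 200.0 + bin_width_ms, bin_width_ms)
    diff = (_bin_means(block_psths[best], edges)
            - _bin_means(block_psths[0], edges))
    denom = diff.sum()
    if np.isclose(denom, 0.0):
        return AttributionVector(edges, np.full(diff.size, np.nan), best, False)
    return AttributionVector(edges, diff / denom, best)


def _session_bin_block(session, thread_label: str, edges: np.ndarray,
                       sigma_ms: float) -> np.ndarray:
    thread = session.threads[thread_label]
    out = np.empty((edges.size - 1, thread.n_blocks))
    for b in range(thread.n_blocks):
        recs = [r for per_image in thread.spike_records[b] for r in per_image]
        psth = compute_psth(recs, sigma_ms=sigma_ms)
        out[:, b] = _bin_means(psth, edges)
    return out


def time_binned_trajectory(sessions, bin_width_ms: int = 10,
                           alpha: float = 0.05,
                           sigma_ms: float = 2.0) -> dict:
    """Per-time-bin evolution trajectories with paired per-block tests.

    For each session, thread, block and time bin the mean binned rate is
    normalized by the session's maximum bin-block value over both threads
    restricted to bins inside (50, 200) ms.  Across sessions, each
    (bin, block) pair gets a paired t-test between threads; p-values are
    Benjamini–Hochberg corrected within each time bin (family = blocks).
    """
    sessions = [s for s in sessions if s.n_blocks > 0]
    if not sessions:
        raise ValueError("need at least one session with blocks")
    edges = np.arange(0.0, 200.0 + bin_width_ms, bin_width_ms)
    n_bins = edges.size - 1
    n_blocks = min(s.n_blocks for s in sessions)
    in_window = (edges[:-1] >= 50.0) & (edges[:-1] < 200.0)

    stacks = {"a": [], "b": []}
    for s in sessions:
        per = {lab: _session_bin_block(s, lab, edges, sigma_ms)[:, :n_blocks]
               for lab in ("a", "b")}
        norm = max(float(per[lab][in_window].max()) for lab in ("a", "b"))
        norm = norm if norm > 0 else 1.0
        for lab in ("a", "b"):
            stacks[lab].append(per[lab] / norm)
    arr = {lab: np.stack(stacks[lab]) for lab in ("a", "b")}  # (S, bins, blocks)

    pvals = np.full((n_bins, n_blocks), np.nan)
    rejected = np.zeros((n_bins, n_blocks), dtype=bool)
    if len(sessions) >= 2:
        for i in range(n_bins):
            for b in range(n_blocks):
                va, vb = arr["a"][:, i, b], arr["b"][:, i, b]
                if np.allclose(va, vb):
                    pvals[i, b] = 1.0
                else:
                    pvals[i, b] = stats.ttest_rel(va, vb).pvalue
            rejected[i], _, _, _ = multipletests(pvals[i], alpha=alpha,
                                                 method="fdr_bh")[:4]
    out = {"bin_edges": edges, "n_blocks": n_blocks, "pvalues": pvals,
           "significant": rejected}
    for lab in ("a", "b"):
        a = arr[lab]
        out[lab] = {"values": a, "mean": a.mean(axis=0),
                    "sem": (a.std(axis=0, ddof=1) / np.sqrt(a.shape[0])
                            if a.shape[0] > 1 else np.zeros(a.shape[1:]))}
    return out


def psth_distance(pa: PSTH, pb: PSTH) -> tuple[float, float]:
    """Absolute-area and signed-area distances between two PSTHs.

    Callers normalize both PSTHs by the neuron's maximum block-average rate
    beforehand; time is integrated in seconds, so ``d_psth >= |d_act|`` with
    equality iff the difference never changes sign.
    """
    if pa.times.shape != pb.times.shape or not np.allclose(pa.times, pb.times):
        raise ValueError("PSTH grids differ")
    dt_s = pa.bin_ms / 1000.0
    diff = pa.rates - pb.rates
    d_psth = float(np.abs(diff).sum() * dt_s)
    d_act = float(diff.sum() * dt_s)
    return d_psth, d_act
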