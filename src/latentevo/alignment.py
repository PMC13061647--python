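"""Alignment metrics: hill-climbing success, trajectories, speed, win rates.

Quantifies how readily a neuron guides optimization in a given latent space:

* :func:`evolution_success` — did firing in some pair of consecutive blocks
  significantly exceed the first two blocks?
* :func:`normalize_and_pad` — session-normalized, length-aligned trajectories
  with population mean ± s.e.m.
* :func:`convergence_time` — first block at which the GPR-smoothed trajectory
  reaches 80% of its increase above the first-block level.
* :func:`win_rate` — per-generation fraction of sessions in which one thread
  significantly out-drives the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SuccessResult",
    "Trajectory",
    "ConvergenceResult",
    "WinRate",
    "evolution_success",
    "thread_block_scores",
    "normalize_and_pad",
    "convergence_time",
    "win_rate",
    "pooled_success_rate",
    "wilson_interval",
]


@dataclass(frozen=True)
class SuccessResult:
    success: bool
    p_value: float
    t_statistic: float
    best_pair: tuple[int, int]      # 0-based block indices of the best pair


@dataclass
class Trajectory:
    """Block-mean score trajectory of one thread, session-normalized."""

    values: np.ndarray
    sems: np.ndarray
    norm_const: float
    label: str


@dataclass(frozen=True)
class ConvergenceResult:
    block: int | None               # 1-based; None when undefined
    defined: bool
    smoothed: np.ndarray
    threshold: float


@dataclass(frozen=True)
class WinRate:
    frac_a: float
    frac_b: float
    frac_tie: float
    n_sessions: int
    n_skipped: int


def thread_block_scores(thread) -> list[np.ndarray]:
    """Per-block image-score arrays from an EvolutionThread or a raw list."""
    if hasattr(thread, "scores"):
        return list(thread.scores)
    return [np.asarray(b, float) for b in thread]


def evolution_success(thread, alpha: float = 0.01,
                      alternative: str = "two-sided") -> SuccessResult:
    """Test whether any two consecutive blocks exceed the first two.

    Pools the image scores of the first two blocks as baseline, pools each
    candidate pair of consecutive later blocks, selects the pair with the
    highest pooled mean, and runs a Welch two-sample t-test against the
    baseline.  Success requires both a mean increase and ``p < alpha``.
    Note the max-over-pairs selection inflates the null rate above the
    nominal level; the companion calibration test quantifies this.
    """
    blocks = thread_block_scores(thread)
    if len(blocks) < 4:
        raise ValueError("need at least 4 blocks")
    baseline = np.concatenate(blocks[:2])
    best_pair, best_mean = None, -np.inf
    for b in range(2, len(blocks) - 1):
        pooled = np.concatenate([blocks[b], blocks[b + 1]])
        m = np.nanmean(pooled)
        if m > best_mean:
            best_mean, best_pair = m, (b, b + 1)
    pooled = np.concatenate([blocks[best_pair[0]], blocks[best_pair[1]]])
    t_stat, p = stats.ttest_ind(pooled, baseline, equal_var=False,
                                alternative=alternative, nan_policy="omit")
    increase = np.nanmean(pooled) > np.nanmean(baseline)
    return SuccessResult(bool(increase and p < alpha), float(p), float(t_stat),
                         best_pair)


def _session_thread_means(session) -> dict[str, np.ndarray]:
    return {label: np.array([np.nanmean(s) for s in thread.scores])
            for label, thread in session.threads.items()}


def normalize_and_pad(sessions) -> dict:
    """Align trajectories across sessions for population averaging.

    Each thread's block means are normalized by the session's maximum block
    mean across both threads (so the session max is exactly 1), shorter
    trajectories are padded to the longest with the mean of their last two
    blocks, and per-generator mean ± s.e.m. across sessions is returned.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("need at least one session")
    per_session = []
    max_len = 0
    for s in sessions:
        means = _session_thread_means(s)
        norm = max(float(np.nanmax(v)) for v in means.values())
        norm = norm if norm > 0 else 1.0
        traj = {}
        for label, thread in s.threads.items():
            vals = means[label] / norm
            sems = thread.block_sems() / norm
            traj[label] = Trajectory(vals, sems, norm, thread.generator_name)
            max_len = max(max_len, vals.size)
        per_session.append(traj)

    padded: dict[str, list[np.ndarray]] = {"a": [], "b": []}
    for traj in per_session:
        for label, t in traj.items():
            v = t.values
            if v.size < max_len:
                pad = np.mean(v[-2:])
                v = np.concatenate([v, np.full(max_len - v.size, pad)])
            padded[label].append(v)
    out = {"per_session": per_session, "length": max_len}
    for label, rows in padded.items():
        mat = np.vstack(rows)
        sem = (mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
               if mat.shape[0] > 1 else np.zeros(max_len))
        out[label] = {"matrix": mat, "mean": mat.mean(axis=0), "sem": sem}
    return out


def _gpr_smooth(values: np.ndarray, seed: int = 0) -> np.ndarray:
    x = np.arange(1.0, values.size + 1)[:, None]
    span = float(np.ptp(values))
    noise = max(span ** 2 * 1e-4, 1e-10)
    kernel = (ConstantKernel(1.0, (1e-4, 1e4))
              * RBF(length_scale=values.size / 5.0,
                    length_scale_bounds=(1.0, values.size * 2.0))
              + WhiteKernel(noise, (1e-12, max(span ** 2, 1e-6))))
    gpr = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                   n_restarts_optimizer=2, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gpr.fit(x, values)
    return gpr.predict(x)


def _moving_average(values: np.ndarray, window: int = 3) -> np.ndarray:
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def convergence_time(values, smoother: str = "gpr",
                     threshold_frac: float = 0.8,
                     mode: str = "increase") -> ConvergenceResult:
    """First block at which the smoothed trajectory reaches the 80% level.

    ``mode='increase'`` (default, scale-invariant) takes the threshold as
    ``first + frac * (max - first)`` of the smoothed curve;
    ``mode='maximum'`` uses ``frac * max`` instead.
    A flat or decreasing trajectory (no positive increase) is flagged
    undefined.  Falls back to moving-average smoothing if the GPR fit
    degenerates.
    """
    if hasattr(values, "values"):
        values = values.values
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 blocks")
    if smoother == "gpr":
        try:
            smoothed = _gpr_smooth(values)
            if not np.all(np.isfinite(smoothed)):
                raise FloatingPointError
        except Exception:
            smoothed = _moving_average(values)
    elif smoother == "moving-average":
        smoothed = _moving_average(values)
    elif smoother == "none":
        smoothed = values
    else:
        raise ValueError(f"unknown smoother {smoother!r}")

    first, peak = smoothed[0], float(np.max(smoothed))
    increase = peak - first
    if increase <= 0:
        return ConvergenceResult(None, False, smoothed, np.nan)
    if mode == "increase":
        threshold = first + threshold_frac * increase
    elif mode == "maximum":
        threshold = threshold_frac * peak
    else:
        raise ValueError(f"unknown mode {mode!r}")
    idx = int(np.argmax(smoothed >= threshold))
    return ConvergenceResult(idx + 1, True, smoothed, float(threshold))


def win_rate(sessions, generation: int, alpha: float = 0.05) -> WinRate:
    """Fractions of sessions each thread significantly wins at a generation.

    ``generation`` is a 0-based block index; sessions lacking that block are
    skipped and counted.  Per session a Welch two-sample t-test compares the
    two threads' image scores; a win requires direction plus significance.
    Fractions (a-wins, b-wins, ties) sum to 1 over eligible sessions.
    """
    wins_a = wins_b = ties = skipped = 0
    for s in sessions:
        if s.n_blocks <= generation or s.thread_b.n_blocks <= generation:
            skipped += 1
            continue
        sa = s.thread_a.scores[generation]
        sb = s.thread_b.scores[generation]
        _, p = stats.ttest_ind(sa, sb, equal_var=False, nan_policy="omit")
        if p < alpha and np.nanmean(sa) > np.nanmean(sb):
            wins_a += 1
        elif p < alpha and np.nanmean(sb) > np.nanmean(sa):
            wins_b += 1
        else:
            ties += 1
    n = wins_a + wins_b + ties
    if n == 0:
        raise ValueError("no eligible sessions at this generation")
    return WinRate(wins_a / n, wins_b / n, ties / n, n, skipped)


def pooled_success_rate(counts: list[tuple[int, int]]) -> float:
    """Pool per-stratum (successes, total) counts into an overall percentage."""
    k = sum(c[0] for c in counts)
    n = sum(c[1] for c in counts)
    if n == 0:
        raise ValueError("empty count table")
    return 100.0 * k / n


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    lo, hi = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)
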