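"""Tuning landscapes along pullback-metric eigen-axes.

Workflow: pull an image-distance function back to the latent space as a
finite-difference Hessian at the evolved endpoint, eigendecompose its
class/noise sub-blocks to get principal image-change axes, place stimuli at
matched signed image distances along each axis with a bracketing/bisection
line search, measure simulated tuning curves, and classify their shapes
(bell vs ramp) with ANOVA gating plus linear / Gaussian / GPR fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .evolution import score_image
from .generators import GeneratorContract
from .neurons import simulate_spikes

__all__ = [
    "DEFAULT_DISTANCES",
    "PullbackMetric",
    "TuningAxis",
    "AxisStimuli",
    "TuningCurve",
    "squared_pixel_distance",
    "rms_pixel_distance",
    "l2_pixel_distance",
    "pullback_hessian",
    "subspace_eigendecomposition",
    "line_search_alpha",
    "build_axis_stimuli",
    "measure_and_analyze",
    "summarize_population",
    "two_proportion_ztest",
    "beta_interval",
]

log = logging.getLogger(__name__)

#: Signed image-distance targets for axis stimuli (center plus eight flanks;
#: note the deliberate asymmetry of the negative branch).
DEFAULT_DISTANCES = (0.40, 0.32, 0.24, 0.16, 0.0, -0.16, -0.24, -0.36, -0.40)


# -- image metrics ----------------------------------------------------------

def squared_pixel_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Sum of squared pixel differences (the pullback-Hessian default)."""
    return float(np.sum((np.asarray(a, float) - np.asarray(b, float)) ** 2))


def l2_pixel_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(squared_pixel_distance(a, b)))


def rms_pixel_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square pixel distance; bounded ~[0, 1] for [0, 1] images."""
    a = np.asarray(a, float)
    return float(np.sqrt(squared_pixel_distance(a, b) / a.size))


# -- pullback metric --------------------------------------------------------

@dataclass
class PullbackMetric:
    """Image-space distance pulled back to the latent tangent space at z0."""

    z0: np.ndarray
    H: np.ndarray
    metric_name: str
    step: float

    def eigenvalues_clipped(self) -> np.ndarray:
        return np.maximum(np.linalg.eigvalsh(self.H), 0.0)


def pullback_hessian(gen: GeneratorContract, metric, z0, h: float = 1e-2,
                     use_preclip: bool = False) -> PullbackMetric:
    """Central finite-difference Hessian of ``δz ↦ metric(G(z0), G(z0+δz))``.

    The result is symmetrized as ``(H + Hᵀ)/2``.  ``metric`` must vanish on
    identical images and be symmetric.  Raises on non-finite entries, naming
    the offending coordinate pair.
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    z0 = np.asarray(z0.values if hasattr(z0, "values") else z0, float)
    render = gen.render_preclip if use_preclip else gen.render
    img0 = render(z0)
    if abs(metric(img0, img0)) > 1e-12:
        raise ValueError("metric(a, a) must be 0")

    d = z0.size

    def g(delta: np.ndarray) -> float:
        return metric(img0, render(z0 + delta))

    H = np.empty((d, d))
    e = np.eye(d) * h
    gp = np.array([g(e[i]) for i in range(d)])
    gm = np.array([g(-e[i]) for i in range(d)])
    for i in range(d):
        H[i, i] = (gp[i] + gm[i]) / h ** 2          # g(0) = 0
        for j in range(i + 1, d):
            val = (g(e[i] + e[j]) - g(e[i] - e[j])
                   - g(-e[i] + e[j]) + g(-e[i] - e[j])) / (4 * h ** 2)
            H[i, j] = H[j, i] = val
    if not np.all(np.isfinite(H)):
        i, j = np.argwhere(~np.isfinite(H))[0]
        raise FloatingPointError(f"non-finite Hessian entry at ({i}, {j})")
    H = (H + H.T) / 2.0
    name = getattr(metric, "__name__", "metric")
    return PullbackMetric(z0, H, name, h)


@dataclass(frozen=True)
class TuningAxis:
    """Unit latent direction with its pullback eigenvalue."""

    subspace: str
    index: int
    eigenvalue: float
    vector: np.ndarray          # full latent dimension, zeros off-block


def subspace_eigendecomposition(pm: PullbackMetric,
                                partition: dict[str, tuple[int, int]] | None = None
                                ) -> dict[str, list[TuningAxis]]:
    """Eigen-axes of the Hessian's diagonal sub-blocks, sorted descending.

    With no partition the full matrix is decomposed under the label
    ``"full"``.  Axes are embedded back into full latent coordinates.
    """
    H = pm.H
    d = H.shape[0]
    blocks = dict(partition) if partition else {"full": (0, d)}
    out: dict[str, list[TuningAxis]] = {}
    for label, (start, stop) in blocks.items():
        if not (0 <= start < stop <= d):
            raise ValueError(f"partition block {label!r} out of range")
        sub = H[start:stop, start:stop]
        eigvals, eigvecs = np.linalg.eigh(sub)
        order = np.argsort(eigvals)[::-1]
        axes = []
        for rank, idx in enumerate(order):
            v = np.zeros(d)
            v[start:stop] = eigvecs[:, idx]
            axes.append(TuningAxis(label, rank, float(eigvals[idx]), v))
        out[label] = axes
    return out


# -- distance-matched line search ------------------------------------------

def line_search_alpha(gen: GeneratorContract, metric, z0, v, d_target: float,
                      direction: int = 1, tol: float = 1e-3,
                      max_alpha: float = 1e3, alpha0: float = 1e-3) -> float:
    """Signed step α with ``|metric(G(z0), G(z0+αv)) − d_target| ≤ tol``.

    Brackets by doubling α until the metric reaches the target (error if it
    plateaus below it within ``max_alpha``), verifies approximate
    monotonicity of the coarse scan, then bisects.
    """
    if d_target <= 0:
        raise ValueError("d_target must be positive")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    z0 = np.asarray(z0.values if hasattr(z0, "values") else z0, float)
    v = np.asarray(v.vector if isinstance(v, TuningAxis) else v, float)
    img0 = gen.render(z0)

    def f(a_abs: float) -> float:
        return metric(img0, gen.render(z0 + direction * a_abs * v))

    a = alpha0
    scan = [(0.0, 0.0)]
    while f(a) < d_target:
        scan.append((a, f(a)))
        a *= 2.0
        if a > max_alpha:
            raise ValueError(
                f"target distance {d_target} unreachable within |alpha| <= "
                f"{max_alpha} (max achieved {max(v for _, v in scan):.4g})")
    scan.append((a, f(a)))
    vals = [val for _, val in scan]
    drop = np.max(np.maximum.accumulate(vals) - vals)
    if drop > 0.25 * d_target:
        raise ValueError(
            f"metric not monotone along the scan (max drop {drop:.4g} "
            f"against target {d_target}); scan={scan}")

    lo, hi = scan[-2][0], scan[-1][0]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val - d_target) <= tol:
            return direction * mid
        if val < d_target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("bisection failed to reach tolerance")


@dataclass
class AxisStimuli:
    """Nine distance-matched images along one tuning axis."""

    axis: TuningAxis
    center: np.ndarray                  # z*
    targets: np.ndarray                 # signed target distances
    alphas: np.ndarray
    achieved: np.ndarray                # signed achieved distances
    latents: np.ndarray                 # (n_levels, dim)
    images: list[np.ndarray] = field(repr=False, default_factory=list)


def build_axis_stimuli(gen: GeneratorContract, z_star, axes,
                       distances=DEFAULT_DISTANCES,
                       metric=rms_pixel_distance,
                       tol: float = 1e-3) -> list[AxisStimuli]:
    """Generate the image sequence at the target distances for each axis.

    The center stimulus (d = 0) is exactly ``G(z*)``.  Axes for which any
    distance is unreachable are dropped with a log message.
    """
    z_star = np.asarray(z_star.values if hasattr(z_star, "values") else z_star,
                        float)
    img0 = gen.render(z_star)
    out = []
    for axis in axes:
        targets = np.asarray(distances, float)
        alphas = np.zeros(targets.size)
        achieved = np.zeros(targets.size)
        latents = np.tile(z_star, (targets.size, 1))
        images = []
        try:
            for k, d in enumerate(targets):
                if d == 0:
                    images.append(img0)
                    continue
                a = line_search_alpha(gen, metric, z_star, axis, abs(d),
                                      direction=int(np.sign(d)), tol=tol)
                alphas[k] = a
                z = z_star + a * axis.vector
                latents[k] = z
                img = gen.render(z)
                achieved[k] = np.sign(d) * metric(img0, img)
                images.append(img)
        except ValueError as err:
            log.warning("dropping axis %s/%d: %s", axis.subspace, axis.index, err)
            continue
        out.append(AxisStimuli(axis, z_star, targets, alphas, achieved,
                               latents, images))
    return out


# -- tuning-curve measurement and classification ----------------------------

@dataclass
class TuningCurve:
    """Responses along one axis at the nine signed distances, with fits."""

    axis: TuningAxis
    distances: np.ndarray
    responses: np.ndarray               # (n_levels, reps) spikes/s
    anova_f: float
    anova_p: float
    d_max: float
    fits: dict
    label: str                          # bell | ramp | other | nonsignificant
    group: str | None = None            # e.g. evolution success flag

    @property
    def trial_means(self) -> np.ndarray:
        return self.responses.mean(axis=1)


def _gaussian(d, base, amp, mu, width):
    return base + amp * np.exp(-0.5 * ((d - mu) / width) ** 2)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def _fit_gpr_curve(d: np.ndarray, y: np.ndarray, grid: np.ndarray,
                   seed: int = 0) -> np.ndarray:
    span = float(np.ptp(y)) or 1.0
    # cap the white-noise variance so a narrow peak cannot be explained away
    kernel = (ConstantKernel(span ** 2, (1e-6, 1e6))
              * RBF(0.2, (0.05, 2.0))
              + WhiteKernel(span ** 2 * 0.01, (1e-10, span ** 2 * 0.25)))
    gpr = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                   n_restarts_optimizer=2, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gpr.fit(d[:, None], y)
    return gpr.predict(grid[:, None])


def _is_unimodal(curve: np.ndarray, tol_frac: float = 0.03) -> bool:
    """Rises to a single interior maximum then falls, within tolerance."""
    tol = tol_frac * (np.ptp(curve) or 1.0)
    peak = int(np.argmax(curve))
    if peak == 0 or peak == curve.size - 1:
        return False
    rising = np.all(np.diff(curve[:peak + 1]) > -tol)
    falling = np.all(np.diff(curve[peak:]) < tol)
    return bool(rising and falling)


def _is_monotone(curve: np.ndarray, tol_frac: float = 0.03) -> bool:
    tol = tol_frac * (np.ptp(curve) or 1.0)
    inc = np.diff(curve)
    return bool(np.all(inc > -tol) or np.all(inc < tol))


def measure_and_analyze(neuron, stimuli: AxisStimuli, reps: int = 6,
                        seed: int = 0, alpha: float = 0.01,
                        group: str | None = None) -> TuningCurve:
    """Measure a tuning curve along one axis and classify its shape.

    Simulates ``reps`` trials per distance level, gates on a one-way ANOVA
    across levels, then fits linear, Gaussian and GPR models.  A curve is
    *bell* when the Gaussian fit peaks in the interior (|mu| < 0.4),
    out-fits the line by ≥ 0.05 R² and the GPR mean is unimodal; *ramp*
    when the linear slope is significant and the GPR mean is monotone.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    d = stimuli.targets
    n_levels = d.size
    rng = np.random.SeedSequence(seed).spawn(n_levels)
    responses = np.empty((n_levels, reps))
    for k in range(n_levels):
        recs = simulate_spikes(neuron, stimuli.images[k], reps, rng[k],
                               latent=stimuli.latents[k],
                               image_id=f"axis{stimuli.axis.index}-d{k}")
        responses[k] = [score_image([r]) for r in recs]

    means = responses.mean(axis=1)
    d_max = float(d[np.argmax(means)])
    if np.allclose(responses, responses.flat[0]):
        return TuningCurve(stimuli.axis, d, responses, np.nan, 1.0, d_max,
                           {}, "nonsignificant", group)
    f_stat, p = stats.f_oneway(*responses)
    fits: dict = {}
    if p >= alpha:
        return TuningCurve(stimuli.axis, d, responses, float(f_stat), float(p),
                           d_max, fits, "nonsignificant", group)

    # linear fit on all trials
    d_all = np.repeat(d, reps)
    y_all = responses.ravel()
    lin = stats.linregress(d_all, y_all)
    lin_pred = lin.intercept + lin.slope * d
    fits["linear"] = {"slope": lin.slope, "intercept": lin.intercept,
                      "p": lin.pvalue, "r2": _r_squared(means, lin_pred)}

    # Gaussian fit on trial means
    gauss_ok = False
    try:
        p0 = [float(means.min()), float(np.ptp(means)) or 1.0, d_max, 0.2]
        popt, _ = optimize.curve_fit(
            _gaussian, d, means, p0=p0,
            bounds=([-np.inf, -np.inf, -0.8, 0.02], [np.inf, np.inf, 0.8, 2.0]),
            maxfev=20000)
        gauss_pred = _gaussian(d, *popt)
        fits["gaussian"] = {"base": popt[0], "amp": popt[1], "mu": popt[2],
                            "width": popt[3], "r2": _r_squared(means, gauss_pred)}
        gauss_ok = True
    except RuntimeError:
        fits["gaussian"] = None

    grid = np.linspace(d.min(), d.max(), 81)
    gpr_mean = _fit_gpr_curve(d, means, grid, seed=seed)
    fits["gpr"] = {"grid": grid, "mean": gpr_mean}

    label = "other"
    if (gauss_ok and fits["gaussian"]["amp"] > 0
            and abs(fits["gaussian"]["mu"]) < 0.4
            and fits["gaussian"]["r2"] >= fits["linear"]["r2"] + 0.05
            and _is_unimodal(gpr_mean)):
        label = "bell"
    elif lin.pvalue < 0.05 and _is_monotone(gpr_mean):
        label = "ramp"
    return TuningCurve(stimuli.axis, d, responses, float(f_stat), float(p),
                       d_max, fits, label, group)


# -- population summaries ---------------------------------------------------

def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int
                         ) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test (two-sided p)."""
    if min(n1, n2) <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def beta_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Jeffreys (beta-distribution) confidence interval for a proportion."""
    a = (1 - conf) / 2
    lo = stats.beta.ppf(a, k + 0.5, n - k + 0.5) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a, k + 0.5, n - k + 0.5) if k < n else 1.0
    return float(lo), float(hi)


def summarize_population(curves: list[TuningCurve], groups=None,
                         conf: float = 0.95) -> dict:
    """Shape fractions, peak-location histograms and group contrasts.

    ``groups`` assigns each curve to a group (e.g. evolution success flag);
    defaults to the curves' own ``group`` attribute.  Fractions are computed
    among significant curves with beta CIs; peak-location histograms carry
    Wilson CIs; between the first two groups, two-proportion z-tests compare
    bell and ramp fractions and a rank-sum test compares ``|d_max|``.
    """
    from .alignment import wilson_interval

    if groups is None:
        groups = [c.group for c in curves]
    by_group: dict = {}
    for curve, grp in zip(curves, groups):
        by_group.setdefault(grp, []).append(curve)

    summary: dict = {"groups": {}}
    for grp, members in by_group.items():
        sig = [c for c in members if c.label != "nonsignificant"]
        n = len(sig)
        if n == 0:
            raise ValueError(f"group {grp!r} has no significant curves")
        n_bell = sum(c.label == "bell" for c in sig)
        n_ramp = sum(c.label == "ramp" for c in sig)
        levels = sig[0].distances
        peak_counts = {float(d): sum(c.d_max == d for c in sig) for d in levels}
        summary["groups"][grp] = {
            "n_total": len(members),
            "n_significant": n,
            "bell": {"count": n_bell, "fraction": n_bell / n,
                     "ci": beta_interval(n_bell, n, conf)},
            "ramp": {"count": n_ramp, "fraction": n_ramp / n,
                     "ci": beta_interval(n_ramp, n, conf)},
            "peak_histogram": {
                d: {"count": k, "fraction": k / n,
                    "ci": wilson_interval(k, n, conf)}
                for d, k in peak_counts.items()},
            "abs_peak_mean": float(np.mean([abs(c.d_max) for c in sig])),
        }

    keys = list(summary["groups"])
    if len(keys) >= 2:
        g1, g2 = summary["groups"][keys[0]], summary["groups"][keys[1]]
        contrasts = {}
        for shape in ("bell", "ramp"):
            z, p = two_proportion_ztest(g1[shape]["count"], g1["n_significant"],
                                        g2[shape]["count"], g2["n_significant"])
            contrasts[shape] = {"z": z, "p": p}
        s1 = [abs(c.d_max) for c in by_group[keys[0]]
              if c.label != "nonsignificant"]
        s2 = [abs(c.d_max) for c in by_group[keys[1]]
              if c.label != "nonsignificant"]
        rs = stats.ranksums(s1, s2)
        contrasts["abs_peak_ranksum"] = {"z": float(rs.statistic),
                                         "p": float(rs.pvalue)}
        summary["contrasts"] = contrasts
    return summary
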