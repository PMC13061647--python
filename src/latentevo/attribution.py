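"""Spatial attribution of neuronal responses to image regions.

A fixed, seeded bank of oriented/color filters stands in for a pretrained
convolutional extractor: it maps images to a spatial grid of local feature
vectors with documented receptive-field geometry (patch size and stride).
Downstream machinery — per-location regressions yielding adjusted-R²
attribution masks, representative weight vectors from the largest connected
high-R² region, mask correlations, total-variation smoothness, patchwise
perceptual-similarity heatmaps with concentration scores, and encoding-model
feature exemplars — is extractor-agnostic: anything obeying the
:class:`FeatureMapGrid` contract can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

from .optim import CmaEs

__all__ = [
    "FilterBankExtractor",
    "FeatureMapGrid",
    "AttributionMask",
    "SimilarityHeatmap",
    "ExemplarResult",
    "extract_local_features",
    "spatial_attribution_mask",
    "mask_weight_vector",
    "mask_correlation",
    "compare_mask_correlations",
    "total_variation",
    "perceptual_similarity_map",
    "concentration_score",
    "feature_exemplar",
]


@dataclass
class FeatureMapGrid:
    """Spatial grid of local feature vectors for a batch of images."""

    values: np.ndarray          # (n_images, grid_h, grid_w, channels)
    extractor_name: str
    patch_size: int
    stride: int

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:3]

    @property
    def channels(self) -> int:
        return self.values.shape[3]


class FilterBankExtractor:
    """Seeded bank of oriented band-pass and color filters on local patches.

    Each grid cell's feature vector is the full-wave-rectified response of
    every filter to the image patch at that cell, so translating content by
    one stride translates the response by exactly one cell.
    """

    def __init__(self, patch_size: int = 16, stride: int = 4,
                 channels: int = 16, seed: int = 7):
        if patch_size < 2 or stride < 1 or channels < 2:
            raise ValueError("invalid extractor geometry")
        self.patch_size = patch_size
        self.stride = stride
        self.channels = channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        yy, xx = np.mgrid[0:patch_size, 0:patch_size].astype(float)
        cy = cx = (patch_size - 1) / 2.0
        filters = np.empty((channels, patch_size, patch_size, 3))
        for k in range(channels):
            theta = rng.uniform(0, np.pi)
            freq = rng.uniform(0.06, 0.30)
            phase = rng.uniform(0, 2 * np.pi)
            sig = rng.uniform(0.28, 0.45) * patch_size
            u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
            v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
            g = np.exp(-(u ** 2 + v ** 2) / (2 * sig ** 2)) \
                * np.cos(2 * np.pi * freq * u + phase)
            color = rng.normal(size=3)
            color /= np.linalg.norm(color)
            filt = g[:, :, None] * color[None, None, :]
            filters[k] = filt / np.linalg.norm(filt)
        self._filters = filters.reshape(channels, -1)
        self.name = f"filterbank-p{patch_size}s{stride}c{channels}"

    def grid_shape(self, height: int, width: int) -> tuple[int, int]:
        gh = (height - self.patch_size) // self.stride + 1
        gw = (width - self.patch_size) // self.stride + 1
        return gh, gw

    def __call__(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, float)
        if images.ndim == 3:
            images = images[None]
        n, h, w, _ = images.shape
        gh, gw = self.grid_shape(h, w)
        if gh < 1 or gw < 1:
            raise ValueError("image smaller than the filter patch")
        out = np.empty((n, gh, gw, self.channels))
        p, s = self.patch_size, self.stride
        for gi in range(gh):
            for gj in range(gw):
                patch = images[:, gi * s:gi * s + p, gj * s:gj * s + p, :]
                out[:, gi, gj, :] = np.abs(
                    patch.reshape(n, -1) @ self._filters.T)
        return out


_DEFAULT_EXTRACTOR: FilterBankExtractor | None = None


def default_extractor() -> FilterBankExtractor:
    global _DEFAULT_EXTRACTOR
    if _DEFAULT_EXTRACTOR is None:
        _DEFAULT_EXTRACTOR = FilterBankExtractor()
    return _DEFAULT_EXTRACTOR


def extract_local_features(images, extractor=None) -> FeatureMapGrid:
    """Deterministic spatial grid of local feature vectors per image."""
    extractor = extractor or default_extractor()
    images = np.asarray(images, float)
    if images.ndim == 3:
        images = images[None]
    if len({img.shape for img in images}) > 1:
        raise ValueError("images must share one size")
    values = extractor(images)
    return FeatureMapGrid(values, extractor.name,
                          extractor.patch_size, extractor.stride)


# -- attribution masks ------------------------------------------------------

@dataclass
class AttributionMask:
    """Per-location regression fit quality and weights."""

    adj_r2: np.ndarray          # (grid_h, grid_w)
    r2: np.ndarray
    weights: np.ndarray         # (grid_h, grid_w, channels)
    n_images: int
    flags: dict = field(default_factory=dict)


def spatial_attribution_mask(features: FeatureMapGrid,
                             responses) -> AttributionMask:
    """OLS of responses on each location's channel vector, with intercept.

    Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1).  Constant responses give
    R² = 0 (flagged).  Under-determined fits (n ≤ channels + 1) fall back to
    trace-normalized ridge regression, flagged in the output.
    """
    y = np.asarray(responses, float)
    n = features.n_images
    if y.shape != (n,):
        raise ValueError("need one response per image")
    gh, gw = features.grid_shape
    p = features.channels
    flags: dict = {}
    if np.ptp(y) == 0:
        flags["constant_responses"] = True
        return AttributionMask(np.zeros((gh, gw)), np.zeros((gh, gw)),
                               np.zeros((gh, gw, p)), n, flags)
    ridge = n <= p + 1
    if ridge:
        flags["ridge_fallback"] = True
    r2 = np.empty((gh, gw))
    adj = np.empty((gh, gw))
    weights = np.empty((gh, gw, p))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    for i in range(gh):
        for j in range(gw):
            x = features.values[:, i, j, :]
            xc = x - x.mean(axis=0)
            yc = y - y.mean()
            if ridge:
                lam = 1e-3 * np.trace(xc.T @ xc) / p
                beta = np.linalg.solve(xc.T @ xc + lam * np.eye(p), xc.T @ yc)
            else:
                beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
            resid = yc - xc @ beta
            r2[i, j] = 1.0 - float(np.sum(resid ** 2)) / ss_tot
            dof = n - p - 1
            adj[i, j] = (1.0 - (1.0 - r2[i, j]) * (n - 1) / dof
                         if dof > 0 else r2[i, j])
            weights[i, j] = beta
    return AttributionMask(adj, r2, weights, n, flags)


def mask_weight_vector(mask: AttributionMask,
                       percentile: float = 80.0) -> np.ndarray:
    """Average weights over the largest high-R² connected region.

    Thresholds the adjusted-R² map at the given percentile, labels
    above-threshold cells with 8-connectivity, picks the largest region
    (ties broken by the region containing the first above-threshold cell in
    row-major order), and averages that region's weight vectors.
    """
    adj = mask.adj_r2
    thresh = np.percentile(adj, percentile)
    above = adj > thresh        # strict: ties at the threshold are excluded
    if not above.any():
        raise ValueError("no cells above the percentile threshold")
    labels, n_regions = ndimage.label(above, structure=np.ones((3, 3)))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n_regions + 1))
    best_size = sizes.max()
    candidates = [k + 1 for k, s in enumerate(sizes) if s == best_size]
    if len(candidates) > 1:
        order = labels.ravel()
        first = {k: np.argmax(order == k) for k in candidates}
        best = min(candidates, key=lambda k: first[k])
    else:
        best = candidates[0]
    region = labels == best
    return mask.weights[region].mean(axis=0)


def mask_correlation(wa, wb) -> float:
    """Pearson correlation of two weight vectors; NaN on zero variance."""
    wa, wb = np.asarray(wa, float), np.asarray(wb, float)
    if wa.shape != wb.shape:
        raise ValueError("weight vectors differ in length")
    if np.ptp(wa) == 0 or np.ptp(wb) == 0:
        return float("nan")
    return float(stats.pearsonr(wa, wb).statistic)


def compare_mask_correlations(same_pairs, cross_pairs) -> dict:
    """Rank test of same-driver vs cross-driver weight correlations."""
    same = [c for c in same_pairs if np.isfinite(c)]
    cross = [c for c in cross_pairs if np.isfinite(c)]
    res = stats.ranksums(same, cross)
    return {"z": float(res.statistic), "p": float(res.pvalue),
            "same_mean": float(np.mean(same)), "cross_mean": float(np.mean(cross))}


def total_variation(arr) -> float:
    """Sum of Euclidean norms of forward-difference gradients."""
    arr = np.asarray(arr, float)
    if arr.ndim != 2:
        raise ValueError("total variation is defined for 2-D maps")
    dx = np.zeros_like(arr)
    dy = np.zeros_like(arr)
    dx[:, :-1] = np.diff(arr, axis=1)
    dy[:-1, :] = np.diff(arr, axis=0)
    return float(np.sqrt(dx ** 2 + dy ** 2).sum())


# -- perceptual similarity --------------------------------------------------

@dataclass
class SimilarityHeatmap:
    """Patchwise similarity map, ``similarity = 1 − distance``, bounded by 1."""

    values: np.ndarray
    metric_name: str


def perceptual_similarity_map(img_a, img_b, extractor=None) -> SimilarityHeatmap:
    """Patchwise perceptual similarity between two same-sized images.

    The default metric is the normalized feature-bank patch distance
    ``‖fa − fb‖ / (‖fa‖ + ‖fb‖)`` per grid cell (an LPIPS stand-in),
    mapped to similarity = 1 − distance.  Symmetric in its arguments.
    """
    img_a, img_b = np.asarray(img_a, float), np.asarray(img_b, float)
    if img_a.shape != img_b.shape:
        raise ValueError("images must share one size")
    extractor = extractor or default_extractor()
    fa = extractor(img_a[None])[0]
    fb = extractor(img_b[None])[0]
    num = np.linalg.norm(fa - fb, axis=-1)
    den = np.linalg.norm(fa, axis=-1) + np.linalg.norm(fb, axis=-1)
    dist = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    return SimilarityHeatmap(1.0 - dist, f"1-normdist[{extractor.name}]")


def concentration_score(heatmap, sizes=(1, 2, 3, 5, 8)) -> float:
    """Mean over filter sizes of the maximum local average of the heatmap.

    Each size-k uniform filter is normalized to sum 1 and convolved in
    valid mode; the score is the mean of the per-size maxima.  High values
    indicate similarity concentrated in compact regions.
    """
    values = heatmap.values if isinstance(heatmap, SimilarityHeatmap) else \
        np.asarray(heatmap, float)
    if min(sizes) < 1:
        raise ValueError("filter sizes must be >= 1")
    if max(sizes) > min(values.shape):
        raise ValueError("filter size exceeds map dimensions")
    maxima = []
    for k in sizes:
        filt = np.ones((k, k)) / (k * k)
        conv = signal.convolve2d(values, filt, mode="valid")
        maxima.append(float(conv.max()))
    return float(np.mean(maxima))


# -- encoding-model feature exemplars ---------------------------------------

@dataclass
class ExemplarResult:
    image: np.ndarray
    latent: np.ndarray
    predicted_response: float
    spatial_weights: np.ndarray
    channel_weights: np.ndarray
    screen_channels: np.ndarray
    predict: object = None      # callable: batch of images -> predictions


def _factorized_fit(F: np.ndarray, y: np.ndarray, n_iter: int = 20
                    ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Alternating least squares for pred = scale * (s ⊗ c) · F + offset."""
    n, gh, gw, C = F.shape
    Fm = F.reshape(n, gh * gw, C)
    yc = y - y.mean()
    corr = np.einsum("nsc,n->sc", Fm - Fm.mean(axis=0), yc)
    u, sv, vt = np.linalg.svd(corr, full_matrices=False)
    s_vec, c_vec = u[:, 0], vt[0]
    if (s_vec @ corr @ c_vec) < 0:
        c_vec = -c_vec
    for _ in range(n_iter):
        a = Fm @ c_vec                       # (n, S)
        s_vec, *_ = np.linalg.lstsq(a - a.mean(axis=0), yc, rcond=None)
        b = np.einsum("nsc,s->nc", Fm, s_vec)
        c_vec, *_ = np.linalg.lstsq(b - b.mean(axis=0), yc, rcond=None)
    raw = np.einsum("nsc,s,c->n", Fm, s_vec, c_vec)
    lin = stats.linregress(raw, y)
    return s_vec, c_vec, float(lin.slope), float(lin.intercept)


def feature_exemplar(images, responses, extractor=None, generator=None,
                     seed: int = 0, screen_threshold: float = 0.1,
                     generations: int = 60, popsize: int = 20,
                     sigma0: float | None = None) -> ExemplarResult:
    """Fit a factorized encoding model and re-optimize its preferred image.

    Screens feature channels by response correlation, initializes a
    factorized (spatial × channel) readout from the correlation structure,
    refines it by alternating least squares, and maximizes the model's
    predicted response over the generator latent with CMA-ES.
    """
    if generator is None:
        raise ValueError("a generator contract is required")
    y = np.asarray(responses, float)
    if y.size < 50:
        raise ValueError("need at least 50 (image, response) pairs")
    extractor = extractor or default_extractor()
    grid = extract_local_features(images, extractor)
    F = grid.values
    n, gh, gw, C = F.shape

    flat = F.reshape(n, -1)
    with np.errstate(invalid="ignore"):
        cors = np.array([
            stats.pearsonr(flat[:, k], y).statistic if np.ptp(flat[:, k]) > 0
            else 0.0 for k in range(flat.shape[1])])
    chan_max = np.nanmax(np.abs(cors).reshape(gh * gw, C), axis=0)
    screen = chan_max > screen_threshold
    if not screen.any():
        raise ValueError("no feature channel passes the correlation screen")

    Fs = F[..., screen]
    s_vec, c_vec, scale, offset = _factorized_fit(Fs, y)

    def predict(imgs: np.ndarray) -> np.ndarray:
        feats = extractor(np.asarray(imgs, float))[..., screen]
        raw = np.einsum("nsc,s,c->n",
                        feats.reshape(feats.shape[0], gh * gw, -1),
                        s_vec, c_vec)
        return scale * raw + offset

    sigma0 = sigma0 if sigma0 is not None else \
        {"texture": 3.0, "object": 0.09}.get(generator.meta.get("kind"), 1.0)
    opt = CmaEs(np.zeros(generator.latent_dim), sigma0, popsize=popsize,
                seed=seed)
    best_latent, best_pred = opt.mean.copy(), -np.inf
    for _ in range(generations):
        latents = opt.ask()
        imgs = generator.render_batch(latents)
        preds = predict(imgs)
        k = int(np.argmax(preds))
        if preds[k] > best_pred:
            best_pred, best_latent = float(preds[k]), latents[k].copy()
        opt.tell(latents, preds)
    mean_pred = float(predict(generator.render(opt.mean)[None])[0])
    if mean_pred > best_pred:
        best_pred, best_latent = mean_pred, opt.mean.copy()

    full_c = np.zeros(C)
    full_c[screen] = c_vec
    return ExemplarResult(generator.render(best_latent), best_latent,
                          best_pred, s_vec.reshape(gh, gw), full_c, screen,
                          predict)
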