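"""Synthetic image generators with contrasting latent-space priors.

Two bundled generators emulate the flexibility-vs-prior contrast that the
closed-loop pipeline exploits:

* :func:`make_texture_generator` — a high-dimensional *linear* map over a
  dictionary of localized, oriented band-pass (Gabor) elements.  Flexible,
  analytically invertible on its span, and amenable to closed-form oracles.
* :func:`make_object_generator` — a low-dimensional *parametric* scene
  (background gradient plus a coherent blob object) whose latent space is
  partitioned into a "class" sub-block controlling identity features and a
  "noise" sub-block controlling pose.

Both generators are deterministic and continuous, render RGB images in
``[0, 1]``, and expose enough internal structure (basis matrices, parameter
maps) for the test-suite oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "LatentPoint",
    "GeneratorContract",
    "make_texture_generator",
    "make_object_generator",
    "check_determinism",
    "estimate_continuity_constant",
]


@dataclass(frozen=True)
class LatentPoint:
    """A vector in a named generator latent space.

    Parameters
    ----------
    space_id:
        Token naming the latent space (matches ``GeneratorContract.name``).
    values:
        The latent coordinates; finite floats.
    partition:
        Optional mapping of sub-block name to half-open index range
        ``(start, stop)``.  Ranges must be disjoint.
    """

    space_id: str
    values: np.ndarray
    partition: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("latent values must be a 1-D vector")
        if not np.all(np.isfinite(vals)):
            raise ValueError("latent values must be finite")
        object.__setattr__(self, "values", vals)
        if self.partition is not None:
            seen: set[int] = set()
            for name, (start, stop) in self.partition.items():
                if not (0 <= start < stop <= vals.size):
                    raise ValueError(f"partition {name!r} out of range")
                block = set(range(start, stop))
                if block & seen:
                    raise ValueError("partition ranges overlap")
                seen |= block

    @property
    def dim(self) -> int:
        return int(self.values.size)

    def block(self, name: str) -> np.ndarray:
        """Return the sub-vector for a named partition block."""
        if self.partition is None or name not in self.partition:
            raise KeyError(f"no partition block named {name!r}")
        start, stop = self.partition[name]
        return self.values[start:stop]


@dataclass
class GeneratorContract:
    """Deterministic continuous map from latent vectors to images.

    ``render`` accepts a plain vector or a :class:`LatentPoint` and returns
    an ``(H, W, 3)`` float array in ``[0, 1]``.  ``render_preclip`` (when
    present) exposes the un-clipped synthesis, used by linearity oracles.
    """

    name: str
    latent_dim: int
    height: int
    width: int
    render_fn: Callable[[np.ndarray], np.ndarray]
    partition: dict[str, tuple[int, int]] | None = None
    preclip_fn: Callable[[np.ndarray], np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def _coerce(self, z) -> np.ndarray:
        if isinstance(z, LatentPoint):
            z = z.values
        z = np.asarray(z, dtype=float)
        if z.shape != (self.latent_dim,):
            raise ValueError(
                f"latent must have shape ({self.latent_dim},), got {z.shape}"
            )
        if not np.all(np.isfinite(z)):
            raise ValueError("latent must be finite")
        return z

    def render(self, z) -> np.ndarray:
        img = self.render_fn(self._coerce(z))
        return np.clip(img, 0.0, 1.0)

    def render_preclip(self, z) -> np.ndarray:
        if self.preclip_fn is None:
            raise NotImplementedError(f"{self.name} has no pre-clip synthesis")
        return self.preclip_fn(self._coerce(z))

    def render_batch(self, zs: np.ndarray) -> np.ndarray:
        zs = np.atleast_2d(np.asarray(zs, dtype=float))
        return np.stack([self.render(z) for z in zs])

    def latent(self, values, ) -> LatentPoint:
        return LatentPoint(self.name, np.asarray(values, float), self.partition)


def check_determinism(gen: GeneratorContract, n_probes: int = 20,
                      seed: int = 0, scale: float = 1.0) -> bool:
    """Render random latents twice and require bit-identical images."""
    rng = np.random.default_rng(seed)
    for _ in range(n_probes):
        z = rng.normal(scale=scale, size=gen.latent_dim)
        if not np.array_equal(gen.render(z), gen.render(z)):
            return False
    return True


def estimate_continuity_constant(gen: GeneratorContract, n_probes: int = 100,
                                 eps: float = 1e-3, seed: int = 0,
                                 scale: float = 1.0,
                                 preclip: bool = False) -> float:
    """Empirical Lipschitz ratio ``‖ΔI‖ / ‖δz‖`` over random probe pairs.

    Returns the maximum observed ratio (an estimate of the modulus of
    continuity constant K); callers assert it is finite and bounded.
    """
    rng = np.random.default_rng(seed)
    render = gen.render_preclip if preclip else gen.render
    worst = 0.0
    for _ in range(n_probes):
        z = rng.normal(scale=scale, size=gen.latent_dim)
        dz = rng.normal(size=gen.latent_dim)
        dz *= eps / np.linalg.norm(dz)
        d_img = np.linalg.norm(render(z + dz) - render(z))
        worst = max(worst, d_img / eps)
    return worst


# ---------------------------------------------------------------------------
# Texture generator: linear Gabor-dictionary map
# ---------------------------------------------------------------------------

def _gabor_dictionary(height: int, width: int, n_basis: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Build an (n_basis, height*width*3) dictionary of localized Gabors.

    Centers tile the image on a jittered grid so that mass anywhere in the
    image is reachable; orientations, frequencies and color axes are random
    but fixed by the seed.
    """
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    side = int(np.ceil(np.sqrt(n_basis)))
    step_y, step_x = height / side, width / side
    elements = np.empty((n_basis, height * width * 3))
    for k in range(n_basis):
        gy, gx = divmod(k % (side * side), side)
        cy = (gy + 0.5) * step_y + rng.uniform(-0.25, 0.25) * step_y
        cx = (gx + 0.5) * step_x + rng.uniform(-0.25, 0.25) * step_x
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(0.08, 0.25)
        sigma = rng.uniform(0.9, 1.4) * max(step_y, step_x)
        phase = rng.uniform(0, 2 * np.pi)
        u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        envelope = np.exp(-(u ** 2 + v ** 2) / (2.0 * sigma ** 2))
        carrier = np.cos(2 * np.pi * freq * u + phase)
        patch = envelope * carrier
        # peak-normalized so every element has the same visible amplitude
        patch /= np.abs(patch).max()
        color = rng.normal(size=3)
        color /= np.linalg.norm(color)
        elements[k] = (patch[:, :, None] * color[None, None, :]).ravel()
    return elements


def make_texture_generator(height: int = 64, width: int = 64,
                           n_basis: int = 256, seed: int = 0,
                           gain: float = 0.12) -> GeneratorContract:
    """Flexible texture-prior generator: linear map over a Gabor dictionary.

    The rendered image is ``clip(0.5 + gain * Bᵀ z)`` where ``B`` holds the
    dictionary elements.  The zero latent renders uniform mid-gray.

    Parameters
    ----------
    n_basis:
        Latent dimensionality (one coefficient per dictionary element);
        must be at least 16.
    gain:
        Amplitude of a unit coefficient, chosen so latents at the default
        evolution step size produce visible, non-saturated patterns.
    """
    if height <= 0 or width <= 0:
        raise ValueError("image dimensions must be positive")
    if n_basis < 16:
        raise ValueError("n_basis must be >= 16")
    rng = np.random.default_rng(seed)
    basis = _gabor_dictionary(height, width, n_basis, rng) * gain
    shape = (height, width, 3)

    def preclip(z: np.ndarray) -> np.ndarray:
        return 0.5 + (z @ basis).reshape(shape)

    return GeneratorContract(
        name="texture",
        latent_dim=n_basis,
        height=height,
        width=width,
        render_fn=preclip,
        preclip_fn=preclip,
        meta={"basis": basis, "gain": gain, "seed": seed,
              "kind": "texture", "n_basis": n_basis},
    )


# ---------------------------------------------------------------------------
# Object generator: parametric blob scene with class/noise partition
# ---------------------------------------------------------------------------

def _squash(z: np.ndarray, w: np.ndarray, lo: float, hi: float,
            gain: float = 2.0) -> float:
    """Map a latent block through a fixed linear readout and tanh to [lo, hi]."""
    t = np.tanh(gain * float(w @ z))
    return lo + (hi - lo) * 0.5 * (t + 1.0)


def make_object_generator(height: int = 64, width: int = 64,
                          class_dim: int = 16, noise_dim: int = 16,
                          seed: int = 0) -> GeneratorContract:
    """Object-prior generator: background gradient plus one coherent blob.

    The latent space is partitioned into a ``class`` block (first
    ``class_dim`` coordinates) controlling identity — superellipse shape
    exponent, aspect ratio, hue, internal part layout, background colors —
    and a ``noise`` block controlling pose: position, rotation, scale and
    brightness.  A weak per-dimension spatial detail field guarantees every
    latent coordinate has image-visible effect, so distance-matched line
    searches along arbitrary axes are well posed.

    With a zero noise block the object is centered at the image midpoint.
    """
    if height <= 0 or width <= 0:
        raise ValueError("image dimensions must be positive")
    if class_dim < 2 or noise_dim < 2:
        raise ValueError("class_dim and noise_dim must be >= 2")
    rng = np.random.default_rng(seed)
    dim = class_dim + noise_dim
    partition = {"class": (0, class_dim), "noise": (class_dim, dim)}

    # Fixed random readout vectors: one per scene parameter.
    def w(block_dim: int) -> np.ndarray:
        v = rng.normal(size=block_dim)
        return v / np.linalg.norm(v)

    wc = {name: w(class_dim) for name in
          ("exp", "aspect", "hue_r", "hue_g", "hue_b", "part_angle",
           "part_size", "part_shade", "bg_top", "bg_bot", "bg_tint")}
    wn = {name: w(noise_dim) for name in
          ("pos_x", "pos_y", "rot", "scale", "bright", "bg_shift")}

    # Per-dimension detail bumps tiling the image (weak, linear).
    side = int(np.ceil(np.sqrt(dim)))
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    bumps = np.empty((dim, height, width))
    for k in range(dim):
        gy, gx = divmod(k, side)
        cy = (gy + 0.5) * height / side
        cx = (gx + 0.5) * width / side
        s = 0.85 * max(height, width) / side
        bumps[k] = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s ** 2))
    detail_colors = rng.normal(size=(dim, 3))
    detail_colors /= np.linalg.norm(detail_colors, axis=1, keepdims=True)
    detail_gain = 0.45

    xg = (xx - (width - 1) / 2.0) / (width / 2.0)
    yg = (yy - (height - 1) / 2.0) / (height / 2.0)

    def params_from_latent(z: np.ndarray) -> dict:
        zc, zn = z[:class_dim], z[class_dim:]
        return {
            # identity (class block)
            "exponent": _squash(zc, wc["exp"], 0.8, 4.0),
            "aspect": _squash(zc, wc["aspect"], 0.55, 1.8),
            "hue": np.array([_squash(zc, wc["hue_r"], 0.55, 0.95),
                             _squash(zc, wc["hue_g"], 0.55, 0.95),
                             _squash(zc, wc["hue_b"], 0.55, 0.95)]),
            "part_angle": _squash(zc, wc["part_angle"], -np.pi, np.pi),
            "part_size": _squash(zc, wc["part_size"], 0.18, 0.38),
            "part_shade": _squash(zc, wc["part_shade"], -0.35, 0.35),
            "bg_top": _squash(zc, wc["bg_top"], 0.02, 0.40),
            "bg_bot": _squash(zc, wc["bg_bot"], 0.02, 0.40),
            "bg_tint": _squash(zc, wc["bg_tint"], -0.18, 0.18),
            # pose (noise block)
            "pos_x": _squash(zn, wn["pos_x"], -0.45, 0.45),
            "pos_y": _squash(zn, wn["pos_y"], -0.45, 0.45),
            "rot": _squash(zn, wn["rot"], -np.pi / 2, np.pi / 2),
            "scale": _squash(zn, wn["scale"], 0.30, 0.62),
            "bright": _squash(zn, wn["bright"], -0.22, 0.22),
            "bg_shift": _squash(zn, wn["bg_shift"], -0.15, 0.15),
        }

    def preclip(z: np.ndarray) -> np.ndarray:
        p = params_from_latent(z)
        # background: vertical gradient with a channel tint
        t = (yg + 1.0) / 2.0
        bg_level = p["bg_top"] + (p["bg_bot"] - p["bg_top"]) * t + p["bg_shift"]
        bg = np.stack([bg_level + p["bg_tint"],
                       bg_level,
                       bg_level - p["bg_tint"]], axis=-1)
        # object support: rotated, scaled, translated superellipse
        cx, cy, th = p["pos_x"], p["pos_y"], p["rot"]
        u = (xg - cx) * np.cos(th) + (yg - cy) * np.sin(th)
        v = -(xg - cx) * np.sin(th) + (yg - cy) * np.cos(th)
        a = p["scale"] * p["aspect"]
        b = p["scale"] / p["aspect"]
        n = p["exponent"]
        r = (np.abs(u / a) ** n + np.abs(v / b) ** n)
        mask = 1.0 / (1.0 + np.exp(np.clip(12.0 * (r - 1.0), -40, 40)))
        body = p["hue"][None, None, :] + p["bright"]
        # internal part: a smaller disc offset along a class-set angle
        px = cx + 0.5 * a * np.cos(p["part_angle"] + th)
        py = cy + 0.5 * b * np.sin(p["part_angle"] + th)
        pr = p["part_size"] * p["scale"]
        part = np.exp(-(((xg - px) ** 2 + (yg - py) ** 2) / (2 * pr ** 2)))
        img = bg * (1 - mask[:, :, None]) + mask[:, :, None] * body
        img += (mask * part * p["part_shade"])[:, :, None]
        # weak linear detail field: one bump per latent coordinate
        img += detail_gain * np.einsum("k,kij,kc->ijc", z, bumps, detail_colors)
        return img

    return GeneratorContract(
        name="object",
        latent_dim=dim,
        height=height,
        width=width,
        render_fn=preclip,
        preclip_fn=preclip,
        partition=partition,
        meta={"params_from_latent": params_from_latent, "seed": seed,
              "kind": "object", "class_dim": class_dim,
              "noise_dim": noise_dim},
    )
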