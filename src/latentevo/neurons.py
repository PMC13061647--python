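"""Synthetic visually tuned spiking neurons.

A :class:`NeuronModel` prefers one or more local image features (templates at
a spatial locus), each bound to a temporal response kernel (e.g. an early
transient and a late sustained component), and emits inhomogeneous-Poisson
spike trains.  :class:`LatentTunedNeuron` implements the same response
protocol but is tuned directly on a generator's latent coordinates — used by
optimizer parameter-recovery tests where the ground-truth peak must be known
exactly.

All times are milliseconds relative to image onset; the recording window is
the half-open interval ``[-50, 400)`` with 1 ms resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WINDOW_MS",
    "TIME_GRID",
    "TemporalKernel",
    "NeuronModel",
    "LatentTunedNeuron",
    "SpikeRecord",
    "simulate_response",
    "simulate_spikes",
]

#: Recording window [start, stop) in ms relative to image onset.
WINDOW_MS = (-50, 400)

#: Left edges of the 1 ms bins spanning the recording window.
TIME_GRID = np.arange(WINDOW_MS[0], WINDOW_MS[1], dtype=float)


@dataclass(frozen=True)
class TemporalKernel:
    """Gaussian-in-time response component bound to one feature preference."""

    latency_ms: float
    width_ms: float
    gain: float = 1.0
    preference: str = "early"

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak temporal envelope on the given time grid."""
        return np.exp(-0.5 * ((t - self.latency_ms) / self.width_ms) ** 2)

    def to_dict(self) -> dict:
        return {"latency_ms": self.latency_ms, "width_ms": self.width_ms,
                "gain": self.gain, "preference": self.preference}


def _default_kernels() -> tuple[TemporalKernel, ...]:
    return (TemporalKernel(80.0, 20.0, 1.0, "early"),
            TemporalKernel(160.0, 35.0, 0.8, "late"))


@dataclass
class NeuronModel:
    """Spiking neuron tuned to local image patches with temporal dynamics.

    Parameters
    ----------
    templates:
        Mapping from preference name to a preferred image patch
        (``patch × patch × 3`` array).  Temporal kernels reference these by
        name, so early and late components may prefer different features.
    locus:
        ``(row, col)`` of the top-left corner of the neuron's local region.
    tuning_width:
        Scale of the Gaussian similarity in patch (pixel) space.
    """

    templates: dict[str, np.ndarray]
    locus: tuple[int, int]
    tuning_width: float
    baseline_rate: float = 2.0
    peak_rate: float = 60.0
    kernels: tuple[TemporalKernel, ...] = field(default_factory=_default_kernels)
    neuron_id: str = "neuron-0"

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline_rate <= self.peak_rate):
            raise ValueError("need 0 <= baseline_rate <= peak_rate")
        if self.tuning_width <= 0:
            raise ValueError("tuning_width must be positive")
        self.templates = {k: np.asarray(v, float) for k, v in self.templates.items()}
        for kern in self.kernels:
            if kern.preference not in self.templates:
                raise ValueError(f"kernel references unknown template "
                                 f"{kern.preference!r}")
        # evoked envelope when every similarity is 1, used for normalization
        env = sum(k.gain * k.profile(TIME_GRID) for k in self.kernels)
        self._env_peak = float(np.max(env))
        if self._env_peak <= 0:
            raise ValueError("temporal kernels have no support in the window")

    @property
    def patch_shape(self) -> tuple[int, ...]:
        return next(iter(self.templates.values())).shape

    def _patch(self, image: np.ndarray) -> np.ndarray:
        r, c = self.locus
        ph, pw = self.patch_shape[:2]
        if r + ph > image.shape[0] or c + pw > image.shape[1]:
            raise ValueError("neuron locus patch exceeds image bounds")
        return image[r:r + ph, c:c + pw]

    def similarity(self, image: np.ndarray, preference: str) -> float:
        """Gaussian similarity between the locus patch and one template."""
        diff = self._patch(image) - self.templates[preference]
        return float(np.exp(-0.5 * np.sum(diff ** 2) / self.tuning_width ** 2))

    def rate_profile(self, image: np.ndarray, latent=None) -> np.ndarray:
        """Instantaneous firing rate λ(t), spikes/s, on :data:`TIME_GRID`."""
        image = np.asarray(image, dtype=float)
        evoked = np.zeros_like(TIME_GRID)
        for kern in self.kernels:
            sim = self.similarity(image, kern.preference)
            evoked += kern.gain * sim * kern.profile(TIME_GRID)
        scale = (self.peak_rate - self.baseline_rate) / self._env_peak
        lam = self.baseline_rate + scale * evoked
        return np.maximum(lam, 0.0)

    def to_dict(self) -> dict:
        return {
            "neuron_id": self.neuron_id,
            "locus": list(self.locus),
            "tuning_width": self.tuning_width,
            "baseline_rate": self.baseline_rate,
            "peak_rate": self.peak_rate,
            "kernels": [k.to_dict() for k in self.kernels],
            "templates": {k: v.tolist() for k, v in self.templates.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronModel":
        return cls(
            templates={k: np.asarray(v, float) for k, v in d["templates"].items()},
            locus=tuple(d["locus"]),
            tuning_width=d["tuning_width"],
            baseline_rate=d["baseline_rate"],
            peak_rate=d["peak_rate"],
            kernels=tuple(TemporalKernel(**k) for k in d["kernels"]),
            neuron_id=d.get("neuron_id", "neuron-0"),
        )


@dataclass
class LatentTunedNeuron:
    """Neuron with Gaussian tuning defined directly on a latent space.

    ``rate_profile`` requires the proposing latent; the image argument is
    ignored.  The planted peak ``z_star`` is the ground truth for optimizer
    recovery tests.
    """

    z_star: np.ndarray
    tuning_width: float
    baseline_rate: float = 2.0
    peak_rate: float = 120.0
    kernels: tuple[TemporalKernel, ...] = field(default_factory=_default_kernels)
    neuron_id: str = "latent-neuron-0"

    def __post_init__(self) -> None:
        self.z_star = np.asarray(self.z_star, dtype=float)
        env = sum(k.gain * k.profile(TIME_GRID) for k in self.kernels)
        self._env_peak = float(np.max(env))

    def rate_profile(self, image=None, latent=None) -> np.ndarray:
        if latent is None:
            raise ValueError("LatentTunedNeuron requires the proposing latent")
        z = np.asarray(latent, dtype=float)
        if z.shape != self.z_star.shape:
            sim = 0.0   # latents from a different space: baseline response
        else:
            sim = np.exp(-0.5 * np.sum((z - self.z_star) ** 2)
                         / self.tuning_width ** 2)
        env = sum(k.gain * k.profile(TIME_GRID) for k in self.kernels)
        scale = (self.peak_rate - self.baseline_rate) / self._env_peak
        return np.maximum(self.baseline_rate + scale * sim * env, 0.0)


@dataclass(frozen=True)
class SpikeRecord:
    """Spike times (ms from onset) for one trial of one image presentation."""

    image_id: str
    block_id: str
    trial_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        if times.size and (np.any(np.diff(times) < 0)):
            raise ValueError("spike times must be sorted ascending")
        if times.size and (times.min() < WINDOW_MS[0] or times.max() >= WINDOW_MS[1]):
            raise ValueError("spike times outside the recording window")
        object.__setattr__(self, "spike_times", times)


def simulate_response(neuron, image: np.ndarray, latent=None) -> np.ndarray:
    """Rate profile λ(t) in spikes/s over the recording window (1 ms grid)."""
    return neuron.rate_profile(image, latent=latent)


def simulate_spikes(neuron, image: np.ndarray, n_trials: int, seed,
                    latent=None, image_id: str = "img-0",
                    block_id: str = "block-0") -> list[SpikeRecord]:
    """Draw inhomogeneous-Poisson spike trains from the neuron's rate.

    The rate is piecewise constant on the 1 ms grid, so exact per-bin
    Poisson counts with uniform within-bin placement realize the process.
    Deterministic given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    lam = simulate_response(neuron, image, latent=latent)  # spikes/s per 1 ms bin
    per_bin = lam / 1000.0
    records = []
    for trial in range(n_trials):
        counts = rng.poisson(per_bin)
        times = np.repeat(TIME_GRID, counts) + rng.uniform(0.0, 1.0,
                                                           int(counts.sum()))
        # uniform jitter keeps times inside each 1 ms bin; clip guards the
        # half-open upper edge against float round-up
        times = np.sort(np.clip(times, WINDOW_MS[0], np.nextafter(WINDOW_MS[1], 0)))
        records.append(SpikeRecord(image_id, block_id, f"trial-{trial}", times))
    return records
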