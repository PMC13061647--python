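"""Closed-loop paired evolution driver.

Runs two interleaved optimization threads — one per generator latent space —
against a single synthetic driver neuron.  Per block, both threads propose a
population of latents, the rendered images (plus a fixed set of interleaved
reference images) are presented, spike trains are simulated, and each image's
score (mean firing rate in the 50–200 ms window) is fed back to its thread's
optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .generators import GeneratorContract
from .neurons import SpikeRecord, simulate_spikes
from .optim import CmaEs

__all__ = [
    "EvolutionConfig",
    "EvolutionThread",
    "EvolutionSession",
    "score_image",
    "run_paired_evolution",
    "default_sigma",
]

#: Initial CMA-ES step size per bundled generator kind.  The texture space
#: uses a large step (3.0) and the low-dimensional object space a small one
#: (0.09); per-space step calibration is the central optimizer manipulation.
DEFAULT_SIGMA = {"texture": 3.0, "object": 0.09}

SCORE_WINDOW_MS = (50.0, 200.0)


def default_sigma(gen: GeneratorContract) -> float:
    return DEFAULT_SIGMA.get(gen.meta.get("kind", gen.name), 1.0)


@dataclass
class EvolutionConfig:
    """Session-level knobs for :func:`run_paired_evolution`."""

    blocks: int = 40
    popsize: int = 30
    trials_per_image: int = 1
    n_reference: int = 10
    sigma_a: float | None = None
    sigma_b: float | None = None
    score_window: tuple[float, float] = SCORE_WINDOW_MS
    presentation_on_ms: float = 100.0   # rapid-serial timing, metadata only
    presentation_off_ms: float = 150.0

    def __post_init__(self) -> None:
        if not (10 <= self.blocks <= 60):
            raise ValueError("blocks must be within 10-60")
        if self.popsize < 2:
            raise ValueError("popsize must be >= 2")
        if self.trials_per_image < 1:
            raise ValueError("trials_per_image must be >= 1")

    def to_dict(self) -> dict:
        return {
            "blocks": self.blocks, "popsize": self.popsize,
            "trials_per_image": self.trials_per_image,
            "n_reference": self.n_reference,
            "sigma_a": self.sigma_a, "sigma_b": self.sigma_b,
            "score_window": list(self.score_window),
            "presentation_on_ms": self.presentation_on_ms,
            "presentation_off_ms": self.presentation_off_ms,
        }


@dataclass
class EvolutionThread:
    """Per-generator record of one evolution: latents, scores, optimizer trace."""

    generator_name: str
    latents: list[np.ndarray] = field(default_factory=list)    # (popsize, dim)
    scores: list[np.ndarray] = field(default_factory=list)     # (popsize,)
    image_ids: list[list[str]] = field(default_factory=list)
    spike_records: list[list[list[SpikeRecord]]] = field(default_factory=list)
    mean_trace: list[np.ndarray] = field(default_factory=list)
    sigma_trace: list[float] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.scores)

    def block_means(self) -> np.ndarray:
        """Mean image score per block, spikes/s."""
        return np.array([np.nanmean(s) for s in self.scores])

    def block_sems(self) -> np.ndarray:
        return np.array([np.nanstd(s, ddof=1) / np.sqrt(np.sum(~np.isnan(s)))
                         for s in self.scores])

    def final_mean(self) -> np.ndarray:
        """Mean latent of the final generation (the evolved endpoint z*)."""
        return self.latents[-1].mean(axis=0)


@dataclass
class EvolutionSession:
    """Full record of one paired closed-loop session."""

    neuron_id: str
    thread_a: EvolutionThread
    thread_b: EvolutionThread
    reference_latents: list[tuple[str, np.ndarray]]
    reference_scores: list[np.ndarray]          # per block, (n_reference,)
    reference_spike_records: list[list[list[SpikeRecord]]]
    presentation_orders: list[list[str]]
    config: dict
    master_seed: int

    @property
    def threads(self) -> dict[str, EvolutionThread]:
        return {"a": self.thread_a, "b": self.thread_b}

    @property
    def n_blocks(self) -> int:
        return self.thread_a.n_blocks


def score_image(records: list[SpikeRecord],
                window: tuple[float, float] = SCORE_WINDOW_MS) -> float:
    """Mean firing rate (spikes/s) in the scoring window across trials.

    Counts spikes in the half-open window per trial, divides by the window
    length, and averages over trials.
    """
    if not records:
        raise ValueError("need at least one trial record")
    lo, hi = window
    width_s = (hi - lo) / 1000.0
    rates = [np.count_nonzero((r.spike_times >= lo) & (r.spike_times < hi))
             / width_s for r in records]
    return float(np.mean(rates))


def _present(neuron, gen: GeneratorContract, latent: np.ndarray, image_id: str,
             block_id: str, n_trials: int, seed, window) -> tuple[float, list]:
    try:
        image = gen.render(latent)
    except Exception:
        return float("nan"), []
    recs = simulate_spikes(neuron, image, n_trials, seed, latent=latent,
                           image_id=image_id, block_id=block_id)
    return score_image(recs, window), recs


def run_paired_evolution(neuron, gen_a: GeneratorContract,
                         gen_b: GeneratorContract,
                         config: EvolutionConfig | None = None,
                         seed: int = 0) -> EvolutionSession:
    """Run a full paired closed-loop evolution session.

    Both threads share block indexing; per block the two populations plus
    the fixed reference images are presented in a seeded random interleave
    (recorded as metadata; trials are simulated independently).  Returns a
    byte-identical session for identical ``(config, seed)``.
    """
    config = config or EvolutionConfig()
    if (gen_a.height, gen_a.width) != (gen_b.height, gen_b.width):
        raise ValueError("paired generators must share the image size")
    patch_shape = getattr(neuron, "patch_shape", None)
    if patch_shape is not None:
        r, c = neuron.locus
        if r + patch_shape[0] > gen_a.height or c + patch_shape[1] > gen_a.width:
            raise ValueError("neuron locus does not fit the session image size")

    master = np.random.SeedSequence(seed)
    ss_opt_a, ss_opt_b, ss_ref, ss_order, ss_trials = master.spawn(5)

    sigma_a = config.sigma_a if config.sigma_a is not None else default_sigma(gen_a)
    sigma_b = config.sigma_b if config.sigma_b is not None else default_sigma(gen_b)
    opt_a = CmaEs(np.zeros(gen_a.latent_dim), sigma_a,
                  popsize=config.popsize, seed=ss_opt_a)
    opt_b = CmaEs(np.zeros(gen_b.latent_dim), sigma_b,
                  popsize=config.popsize, seed=ss_opt_b)

    # fixed reference stimuli: half from each generator's prior
    ref_rng = np.random.default_rng(ss_ref)
    n_ref_a = config.n_reference // 2
    reference_latents: list[tuple[str, np.ndarray]] = []
    for i in range(config.n_reference):
        gen = gen_a if i < n_ref_a else gen_b
        sig = sigma_a if i < n_ref_a else sigma_b
        reference_latents.append(
            (gen.name, ref_rng.normal(scale=sig, size=gen.latent_dim)))
    gens = {gen_a.name: gen_a, gen_b.name: gen_b}

    order_rng = np.random.default_rng(ss_order)
    trial_rng = np.random.default_rng(ss_trials)

    thread_a = EvolutionThread(gen_a.name)
    thread_b = EvolutionThread(gen_b.name)
    reference_scores: list[np.ndarray] = []
    reference_records: list[list[list[SpikeRecord]]] = []
    presentation_orders: list[list[str]] = []

    for block in range(config.blocks):
        block_id = f"block-{block:03d}"
        lat_a, lat_b = opt_a.ask(), opt_b.ask()
        ids_a = [f"{block_id}-a-{i:03d}" for i in range(config.popsize)]
        ids_b = [f"{block_id}-b-{i:03d}" for i in range(config.popsize)]
        ids_r = [f"{block_id}-ref-{i:02d}" for i in range(config.n_reference)]
        manifest = ([("a", i) for i in range(config.popsize)]
                    + [("b", i) for i in range(config.popsize)]
                    + [("ref", i) for i in range(config.n_reference)])
        order = order_rng.permutation(len(manifest))
        presentation_orders.append(
            [{"a": ids_a, "b": ids_b, "ref": ids_r}[manifest[j][0]][manifest[j][1]]
             for j in order])

        scores_a = np.empty(config.popsize)
        scores_b = np.empty(config.popsize)
        scores_r = np.empty(config.n_reference)
        recs_a, recs_b, recs_r = [], [], []
        for j in order:
            kind, i = manifest[j]
            trial_seed = trial_rng.integers(2 ** 63)
            if kind == "a":
                scores_a[i], recs = _present(neuron, gen_a, lat_a[i], ids_a[i],
                                             block_id, config.trials_per_image,
                                             trial_seed, config.score_window)
                recs_a.append((i, recs))
            elif kind == "b":
                scores_b[i], recs = _present(neuron, gen_b, lat_b[i], ids_b[i],
                                             block_id, config.trials_per_image,
                                             trial_seed, config.score_window)
                recs_b.append((i, recs))
            else:
                gname, rlat = reference_latents[i]
                scores_r[i], recs = _present(neuron, gens[gname], rlat, ids_r[i],
                                             block_id, config.trials_per_image,
                                             trial_seed, config.score_window)
                recs_r.append((i, recs))

        for thread, lat, ids, sc, recs, opt in (
                (thread_a, lat_a, ids_a, scores_a, recs_a, opt_a),
                (thread_b, lat_b, ids_b, scores_b, recs_b, opt_b)):
            thread.latents.append(lat)
            thread.image_ids.append(ids)
            thread.scores.append(sc)
            thread.spike_records.append(
                [r for _, r in sorted(recs, key=lambda t: t[0])])
            thread.mean_trace.append(opt.mean.copy())
            thread.sigma_trace.append(opt.sigma)
            opt.tell(lat, sc)
        reference_scores.append(scores_r)
        reference_records.append([r for _, r in sorted(recs_r, key=lambda t: t[0])])

    return EvolutionSession(
        neuron_id=getattr(neuron, "neuron_id", "neuron-0"),
        thread_a=thread_a,
        thread_b=thread_b,
        reference_latents=reference_latents,
        reference_scores=reference_scores,
        reference_spike_records=reference_records,
        presentation_orders=presentation_orders,
        config=config.to_dict(),
        master_seed=seed,
    )
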