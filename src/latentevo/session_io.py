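"""Serialization of evolution sessions: JSON + CSV with checksummed manifest.

A saved session directory holds ``session.json`` (config, seeds, latents,
scores, optimizer traces, reference set, presentation orders, optional
neuron and generator configs), ``spikes.csv`` (one row per spike), and a
``manifest.json`` inventory with SHA-256 checksums.  Loading verifies every
checksum and reconstructs the session field-for-field; stimuli are not
stored as pixels but re-rendered from latents by the (deterministic)
generators when needed.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evolution import EvolutionSession, EvolutionThread
from .generators import (GeneratorContract, make_object_generator,
                         make_texture_generator)
from .neurons import SpikeRecord

__all__ = [
    "ARTIFACT_VERSION",
    "SessionManifest",
    "save_session",
    "load_session",
    "generator_to_config",
    "generator_from_config",
    "export_images",
]

ARTIFACT_VERSION = "0.1.0"


@dataclass
class SessionManifest:
    outdir: Path
    version: str
    files: dict[str, str]       # relative path -> sha256

    @property
    def path(self) -> Path:
        return self.outdir / "manifest.json"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generator_to_config(gen: GeneratorContract) -> dict:
    kind = gen.meta.get("kind")
    cfg = {"kind": kind, "height": gen.height, "width": gen.width,
           "seed": gen.meta.get("seed", 0)}
    if kind == "texture":
        cfg["n_basis"] = gen.meta["n_basis"]
        cfg["gain"] = gen.meta["gain"]
    elif kind == "object":
        cfg["class_dim"] = gen.meta["class_dim"]
        cfg["noise_dim"] = gen.meta["noise_dim"]
    else:
        raise ValueError(f"generator {gen.name!r} is not serializable")
    return cfg


def generator_from_config(cfg: dict) -> GeneratorContract:
    kind = cfg.get("kind")
    if kind == "texture":
        return make_texture_generator(cfg["height"], cfg["width"],
                                      cfg["n_basis"], cfg["seed"],
                                      cfg.get("gain", 0.12))
    if kind == "object":
        return make_object_generator(cfg["height"], cfg["width"],
                                     cfg["class_dim"], cfg["noise_dim"],
                                     cfg["seed"])
    raise ValueError(f"unknown generator kind {kind!r}")


def _thread_payload(t: EvolutionThread) -> dict:
    return {
        "generator_name": t.generator_name,
        "latents": [lat.tolist() for lat in t.latents],
        "scores": [s.tolist() for s in t.scores],
        "image_ids": t.image_ids,
        "mean_trace": [m.tolist() for m in t.mean_trace],
        "sigma_trace": list(t.sigma_trace),
    }


def _thread_from_payload(d: dict) -> EvolutionThread:
    return EvolutionThread(
        generator_name=d["generator_name"],
        latents=[np.asarray(x, float) for x in d["latents"]],
        scores=[np.asarray(x, float) for x in d["scores"]],
        image_ids=[list(ids) for ids in d["image_ids"]],
        mean_trace=[np.asarray(x, float) for x in d["mean_trace"]],
        sigma_trace=[float(x) for x in d["sigma_trace"]],
    )


def _write_spikes_csv(path: Path, session: EvolutionSession) -> None:
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "block_id", "trial_id", "spike_time_ms"])
        def rows(per_image_lists):
            for per_image in per_image_lists:
                for rec in per_image:
                    for t in rec.spike_times:
                        w.writerow([rec.image_id, rec.block_id, rec.trial_id,
                                    f"{t:.17g}"])
        for thread in (session.thread_a, session.thread_b):
            for block_recs in thread.spike_records:
                rows(block_recs)
        for block_recs in session.reference_spike_records:
            rows(block_recs)


def _read_spikes_csv(path: Path) -> dict[tuple[str, str], list[float]]:
    spikes: dict[tuple[str, str], list[float]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            key = (row["image_id"], row["trial_id"])
            spikes.setdefault(key, []).append(float(row["spike_time_ms"]))
    return spikes


def save_session(session: EvolutionSession, outdir, neuron=None,
                 generators: dict | None = None) -> SessionManifest:
    """Write a session to ``outdir`` and return its checksum manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "version": ARTIFACT_VERSION,
        "neuron_id": session.neuron_id,
        "master_seed": session.master_seed,
        "config": session.config,
        "thread_a": _thread_payload(session.thread_a),
        "thread_b": _thread_payload(session.thread_b),
        "reference_latents": [[name, lat.tolist()]
                              for name, lat in session.reference_latents],
        "reference_scores": [s.tolist() for s in session.reference_scores],
        "presentation_orders": session.presentation_orders,
    }
    if neuron is not None and hasattr(neuron, "to_dict"):
        payload["neuron"] = neuron.to_dict()
    if generators:
        payload["generators"] = {k: generator_to_config(g)
                                 for k, g in generators.items()}
    (outdir / "session.json").write_text(json.dumps(payload))
    _write_spikes_csv(outdir / "spikes.csv", session)

    files = {name: _sha256(outdir / name)
             for name in ("session.json", "spikes.csv")}
    manifest = SessionManifest(outdir, ARTIFACT_VERSION, files)
    manifest.path.write_text(json.dumps(
        {"version": ARTIFACT_VERSION, "files": files}))
    return manifest


def _rebuild_records(image_ids: list[list[str]], block_ids: list[str],
                     n_trials: int, spikes) -> list[list[list[SpikeRecord]]]:
    out = []
    for ids, block_id in zip(image_ids, block_ids):
        block = []
        for image_id in ids:
            per_image = []
            for trial in range(n_trials):
                times = sorted(spikes.get((image_id, f"trial-{trial}"), []))
                per_image.append(SpikeRecord(image_id, block_id,
                                             f"trial-{trial}",
                                             np.asarray(times, float)))
            block.append(per_image)
        out.append(block)
    return out


def load_session(manifest_or_dir) -> EvolutionSession:
    """Load a saved session, verifying checksums.

    Accepts a :class:`SessionManifest`, a manifest path, or a session
    directory.  Raises ``FileNotFoundError`` for missing inventory files and
    ``ValueError`` (naming the file) on checksum mismatch or schema gaps.
    """
    if isinstance(manifest_or_dir, SessionManifest):
        outdir, files = manifest_or_dir.outdir, manifest_or_dir.files
    else:
        p = Path(manifest_or_dir)
        outdir = p.parent if p.name == "manifest.json" else p
        mpath = outdir / "manifest.json"
        if not mpath.exists():
            raise FileNotFoundError(f"no manifest at {mpath}")
        files = json.loads(mpath.read_text())["files"]
    for name, digest in files.items():
        fpath = outdir / name
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing file {name}")
        if _sha256(fpath) != digest:
            raise ValueError(f"checksum mismatch for {name}")

    payload = json.loads((outdir / "session.json").read_text())
    for key in ("config", "thread_a", "thread_b", "master_seed"):
        if key not in payload:
            raise ValueError(f"session.json missing required field {key!r}")
    thread_a = _thread_from_payload(payload["thread_a"])
    thread_b = _thread_from_payload(payload["thread_b"])
    spikes = _read_spikes_csv(outdir / "spikes.csv")
    n_trials = int(payload["config"]["trials_per_image"])
    n_blocks = thread_a.n_blocks
    block_ids = [f"block-{b:03d}" for b in range(n_blocks)]
    thread_a.spike_records = _rebuild_records(thread_a.image_ids, block_ids,
                                              n_trials, spikes)
    thread_b.spike_records = _rebuild_records(thread_b.image_ids, block_ids,
                                              n_trials, spikes)
    n_ref = int(payload["config"]["n_reference"])
    ref_ids = [[f"block-{b:03d}-ref-{i:02d}" for i in range(n_ref)]
               for b in range(n_blocks)]
    ref_records = _rebuild_records(ref_ids, block_ids, n_trials, spikes)

    session = EvolutionSession(
        neuron_id=payload["neuron_id"],
        thread_a=thread_a,
        thread_b=thread_b,
        reference_latents=[(name, np.asarray(lat, float))
                           for name, lat in payload["reference_latents"]],
        reference_scores=[np.asarray(s, float)
                          for s in payload["reference_scores"]],
        reference_spike_records=ref_records,
        presentation_orders=payload["presentation_orders"],
        config=payload["config"],
        master_seed=payload["master_seed"],
    )
    session.extras = {k: payload[k] for k in ("neuron", "generators")
                      if k in payload}
    return session


def export_images(session: EvolutionSession, generators: dict, outdir,
                  blocks: list[int] | None = None) -> list[Path]:
    """Render and export session stimuli as PNG files (optional artifact)."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for label, thread in session.threads.items():
        gen = generators[thread.generator_name]
        for b in (blocks if blocks is not None else range(thread.n_blocks)):
            for i, image_id in enumerate(thread.image_ids[b]):
                img = (gen.render(thread.latents[b][i]) * 255).astype(np.uint8)
                path = outdir / f"{image_id}.png"
                Image.fromarray(img).save(path)
                written.append(path)
    return written
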