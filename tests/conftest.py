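import numpy as np
import pytest

from latentevo import (EvolutionConfig, NeuronModel, TemporalKernel,
                       make_object_generator, make_texture_generator,
                       run_paired_evolution)


@pytest.fixture(scope="session")
def texture_gen():
    return make_texture_generator(32, 32, n_basis=32, seed=0)


@pytest.fixture(scope="session")
def object_gen():
    return make_object_generator(32, 32, class_dim=8, noise_dim=8, seed=0)


def make_patch_neuron(gen, seed=0, peak_rate=120.0, locus=(8, 8), patch=12,
                      tuning_width=1.5, baseline_rate=2.0):
    """Neuron preferring a local patch of a random render of ``gen``."""
    rng = np.random.default_rng(seed)
    scale = 3.0 if gen.meta.get("kind") == "texture" else 0.3
    img = gen.render(rng.normal(scale=scale, size=gen.latent_dim))
    r, c = locus
    template = img[r:r + patch, c:c + patch]
    late = gen.render(rng.normal(scale=scale, size=gen.latent_dim))[
        r:r + patch, c:c + patch]
    return NeuronModel(
        templates={"early": template, "late": late},
        locus=locus, tuning_width=tuning_width,
        baseline_rate=baseline_rate, peak_rate=peak_rate,
        kernels=(TemporalKernel(80.0, 20.0, 1.0, "early"),
                 TemporalKernel(160.0, 35.0, 0.8, "late")),
        neuron_id=f"patch-neuron-{seed}")


@pytest.fixture(scope="session")
def patch_neuron(texture_gen):
    return make_patch_neuron(texture_gen)


@pytest.fixture(scope="session")
def small_session(patch_neuron, texture_gen, object_gen):
    """A quick real paired session shared by analysis tests."""
    cfg = EvolutionConfig(blocks=10, popsize=8, trials_per_image=1,
                          n_reference=4)
    return run_paired_evolution(patch_neuron, texture_gen, object_gen,
                                cfg, seed=11)
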