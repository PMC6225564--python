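import numpy as np
import pytest

from siftreg import evaluation, phantom, pipeline


def small_spec(seed: int, **overrides) -> phantom.PhantomSpec:
    """A reduced-extent phantom for fast unit tests.

    Same scene content and modality differences as the default spec, but a
    smaller field of view and gentler pose change so registration runs in
    a few seconds.
    """
    kwargs = dict(
        ct_extent=(220.0, 220.0, 280.0),
        cbct_fov=(150.0, 130.0),
        max_rotation_deg=5.0,
        max_translation_mm=10.0,
        max_scale_change=0.02,
        nonlinear_amplitude=3.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return phantom.PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_pair():
    return phantom.generate_phantom_pair(small_spec(seed=7))


def small_config(seed: int) -> pipeline.RegistrationConfig:
    """Pipeline config for the reduced phantom: the small field of view has a
    higher bone fraction, which compresses the soft-tissue intensity range
    after percentile normalization, so detection needs a lower contrast gate."""
    return pipeline.RegistrationConfig(seed=seed, contrast_threshold=0.005)


@pytest.fixture(scope="session")
def small_registration(small_pair):
    result = pipeline.register(small_pair.ct, small_pair.cbct, small_config(7))
    assert result.success, f"small-phantom registration failed at {result.failed_stage}"
    return result


@pytest.fixture(scope="session")
def default_batch():
    """Ten default-condition phantom pairs (seeds 1-10), each registered with
    the default pipeline configuration; per-pair landmark errors for the
    stage-1 affine, stage-2 affine, and final TPS maps."""
    runs = []
    for seed in range(1, 11):
        pair = phantom.generate_phantom_pair(phantom.PhantomSpec(seed=seed))
        result = pipeline.register(pair.ct, pair.cbct, pipeline.RegistrationConfig(seed=seed))
        errors = {}
        if result.success:
            for name, t in (
                ("affine_stage1", result.affine_stage1),
                ("affine_stage2", result.affine_stage2),
                ("tps", result.tps),
            ):
                errors[name] = evaluation.landmark_errors(
                    pair.landmarks_cbct, pair.landmarks_ct, t
                )
        runs.append({"seed": seed, "pair": pair, "result": result, "errors": errors})
    return runs


def make_blob_volume(shape, centers, sigmas, amplitudes, spacing=1.0, noise_rng=None):
    """Sum of isotropic Gaussian blobs on a grid; optional mild noise."""
    from siftreg import Volume

    shape = np.asarray(shape)
    axes = [np.arange(n) * spacing for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    data = np.zeros(tuple(shape))
    for c, s, a in zip(np.atleast_2d(centers), np.atleast_1d(sigmas), np.atleast_1d(amplitudes)):
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        data += a * np.exp(-r2 / (2.0 * s**2))
    if noise_rng is not None:
        data += 0.01 * noise_rng.standard_normal(data.shape)
    return Volume(data, np.full(3, float(spacing)), np.zeros(3), np.eye(3))
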