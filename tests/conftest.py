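import numpy as np
import pytest

from blastotrack import synth


@pytest.fixture(scope="session")
def default_truth():
    """The default blastocyst preset: 12 shell founders + 4 inner nuclei,
    6 scheduled divisions, 40 frames."""
    return synth.make_preset(seed=3)


@pytest.fixture(scope="session")
def default_labels(default_truth):
    """Noise-free ground-truth label movie of the default preset."""
    return synth.rasterize_labels(default_truth)


@pytest.fixture(scope="session")
def default_truth_forest(default_truth):
    return synth.truth_lineage(default_truth)


@pytest.fixture(scope="session")
def single_frame_render():
    """One rendered frame of 8 well-separated shell nuclei at SNR ~ 10,
    with its ground-truth labels."""
    truth = synth.make_blastocyst(n_outer=8, n_inner=0, n_frames=1,
                                  kappa=0.8, seed=5)
    frames, labels = synth.render(truth, seed=5)
    return truth, frames[0], labels[0]


def random_spd(rng, scale=4.0):
    """Random SPD 3x3 covariance for mixture tests."""
    A = rng.normal(size=(3, 3))
    return A @ A.T * scale / 3.0 + 0.3 * np.eye(3)


def random_mixture(rng, n, spread=20.0):
    from blastotrack.track import GaussianComponent
    w = rng.uniform(0.2, 1.0, n)
    w /= w.sum()
    return [GaussianComponent(weight=float(w[i]),
                              mean=rng.uniform(-spread, spread, 3),
                              covariance=random_spd(rng),
                              source_label=i + 1)
            for i in range(n)]
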