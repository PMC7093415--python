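import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

OMEGA = 2.0 * np.pi / 12.5  # rad/ns at the 12.5 ns repetition period


@pytest.fixture(scope="session")
def omega():
    return OMEGA


def mono_decay(tau_ns, n_bins=256, period_ns=12.5, photons=1e6):
    """Monoexponential decay histogram sampled at bin centers.

    Up to normalization this equals the pulse-wrapped periodic decay, whose
    phasor is exactly G = 1/(1+(wt)^2), S = wt/(1+(wt)^2).
    """
    t = (np.arange(n_bins) + 0.5) * (period_ns / n_bins)
    h = np.exp(-t / tau_ns)
    return photons * h / h.sum()


@pytest.fixture(scope="session")
def small_flim():
    """Deterministic 6x5x64 FLIM cube with a 2 ns decay everywhere."""
    from phasormix import FLIMImage

    hist = np.round(mono_decay(2.0, n_bins=64, photons=3000)).astype(np.uint16)
    counts = np.tile(hist, (6, 5, 1))
    return FLIMImage(counts=counts, n_time_bins=64, repetition_period_ns=12.5,
                     pixel_size_um=2.5, metadata={"excitation_nm": 780})


def isotropic_cluster(center, label="ref", color=(255, 255, 255), scale=1.0):
    """Four-point cluster with center exactly at `center` and isotropic
    sample covariance scale**2 * I."""
    from phasormix import ReferenceCluster

    a = scale * np.sqrt(1.5)
    c = np.asarray(center, dtype=float)
    pts = np.stack([c + (a, 0), c - (a, 0), c + (0, a), c - (0, a)])
    return ReferenceCluster(label=label, points=pts, color=color)


def cluster_with_variance(center, variance, label="ref", color=(255, 255, 255)):
    """Two-point cluster with prescribed center and scalar variance."""
    from phasormix import ReferenceCluster

    d = np.sqrt(variance)
    c = np.asarray(center, dtype=float)
    pts = np.stack([c + (d, 0.0), c - (d, 0.0)])
    return ReferenceCluster(label=label, points=pts, color=color)
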