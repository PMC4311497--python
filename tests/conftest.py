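import numpy as np
import pytest

from homeostat.spikedata import RecordingSession, SpikeTrain, TimeSegment
from homeostat.synthdata import Perturbation, SynthConfig, gen_session


@pytest.fixture
def seg_10min() -> TimeSegment:
    return TimeSegment(0.0, 600.0)


@pytest.fixture
def poisson_train() -> SpikeTrain:
    """Homogeneous Poisson train, 1 Hz over 1200 s, fixed seed."""
    rng = np.random.default_rng(1234)
    seg = TimeSegment(0.0, 1200.0)
    n = rng.poisson(1200)
    return SpikeTrain("p1", np.sort(rng.uniform(0, 1200, n)), seg)


@pytest.fixture(scope="session")
def bursty_session():
    """Default synthetic bursty session (30 units, 20 min) with truth."""
    cfg = SynthConfig(n_units=30, duration=1200.0, seed=7)
    return gen_session(cfg)


@pytest.fixture(scope="session")
def perturbed_session():
    """Session with acute suppression and dispersed per-unit recovery.

    Fast recovery time constant so that within the 6-h session the
    population mean returns to baseline while units scatter.
    """
    cfg = SynthConfig(
        n_units=40, duration=6 * 3600.0, seed=11,
        perturbation=Perturbation(onset=3600.0, suppression_factor=0.012,
                                  recovery_tau=1800.0, unit_dispersion=0.8))
    return gen_session(cfg)


def make_session(trains: dict[str, np.ndarray], duration: float,
                 **kwargs) -> RecordingSession:
    seg = TimeSegment(0.0, duration)
    return RecordingSession(
        trains={u: SpikeTrain(u, np.asarray(t, dtype=float), seg)
                for u, t in trains.items()},
        duration=duration, **kwargs)
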