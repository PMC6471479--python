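import numpy as np
import pytest

import smdroutes as sr


@pytest.fixture(scope="session")
def flat_ensemble():
    """Short flat-model ensemble shared by filtering/force/io tests."""
    model = sr.flat_model(domain=(-10.0, 20.0))
    proto = sr.PullingProtocol(duration=175.0, seed=5)
    return sr.generate_ensemble(model, proto, 30, route_id="flat")


@pytest.fixture(scope="session")
def harmonic_slow_ensemble():
    """Slow pulling on a harmonic well; PMF has a closed-form oracle."""
    model = sr.harmonic_model(2.0, domain=(-30.0, 30.0))
    proto = sr.PullingProtocol(velocity=0.002, duration=1000.0, seed=11)
    return sr.generate_ensemble(model, proto, 12, route_id="harm")


@pytest.fixture(scope="session")
def two_bump_profile():
    """PMF of a two-barrier landscape, for state decomposition tests."""
    model = sr.ModelPMF(terms=(
        sr.PMFTerm("gaussian_bump", center=3.0, height=4.0, width=1.0),
        sr.PMFTerm("gaussian_bump", center=8.0, height=6.0, width=1.2),
    ), domain=(-30.0, 50.0))
    proto = sr.PullingProtocol(velocity=0.004, duration=3000.0, seed=21)
    ens = sr.generate_ensemble(model, proto, 8, route_id="bumpy")
    filt, _ = sr.filter_replicas(ens)
    profile = sr.build_pmf(filt, bin_width=0.25, estimator="cumulant2",
                           n_boot=50, seed=4)
    return model, profile


def make_trajectory(s, w, *, route_id="toy", replica_id=0, completed=True,
                    force=None, xi=None):
    """WorkTrajectory from explicit displacement/work samples (v = 1 Å/ps)."""
    s = np.asarray(s, dtype=float)
    w = np.asarray(w, dtype=float)
    return sr.WorkTrajectory(
        route_id=route_id, replica_id=replica_id,
        t=s.copy(), lam=s.copy(),
        xi=s.copy() if xi is None else np.asarray(xi, dtype=float),
        force=np.zeros_like(s) if force is None else np.asarray(force, dtype=float),
        work=w, completed=completed)


def make_ensemble(trajs, kbt=0.6186, route_id="toy"):
    duration = max(max(float(tr.t[-1]) for tr in trajs), 1.0)
    proto = sr.PullingProtocol(duration=duration)
    return sr.WorkEnsemble(route_id=route_id, trajectories=list(trajs),
                           protocol=proto, beta=1.0 / kbt)


def make_profile(centers, values, *, route_id="toy", estimator="cumulant2"):
    centers = np.asarray(centers, dtype=float)
    values = np.asarray(values, dtype=float)
    return sr.PMFProfile(route_id=route_id, bin_centers=centers,
                         delta_F=values, stderr=np.zeros_like(values),
                         n_contributing=np.full(len(values), 2),
                         estimator=estimator)
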