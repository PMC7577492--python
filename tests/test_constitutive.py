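"""Constitutive point-level tests: Hooke/Kelvin-Voigt, J2 radial return, Ludwik."""

import numpy as np
import pytest

from squeezefem.constitutive import (
    _kv_stress,
    _ludwik,
    _radial_return,
    kelvin_voigt_update,
    lame,
    radial_return_update,
    stress_stiffening_update,
    von_mises,
)
from squeezefem.config import StiffeningLaw


def test_lame_standard_values():
    lam, mu = lame(1000.0, 0.3)
    assert mu == pytest.approx(1000.0 / 2.6)
    assert lam == pytest.approx(1000.0 * 0.3 / (1.3 * 0.4))


def test_von_mises_uniaxial():
    # pure uniaxial sigma_xx = s: vm = s
    s = np.array([100.0, 0.0, 0.0, 0.0])
    assert von_mises(s) == pytest.approx(100.0)


def test_von_mises_pure_shear():
    s = np.array([0.0, 0.0, 0.0, 30.0])
    assert von_mises(s) == pytest.approx(np.sqrt(3.0) * 30.0)


def test_kv_stress_reduces_to_hooke_at_zero_rate():
    lam, mu = lame(1200.0, 0.3)
    eps = np.array([1e-3, -2e-4, 0.0, 3e-4])
    rate = np.zeros(4)
    s = _kv_stress(eps, rate, lam, mu, 0.0)
    tr = eps[0] + eps[1] + eps[2]
    assert s[0] == pytest.approx(lam * tr + 2 * mu * eps[0])
    assert s[2] == pytest.approx(lam * tr + 2 * mu * eps[2])
    assert s[3] == pytest.approx(2 * mu * eps[3])


def test_kv_stress_viscous_term_additive():
    lam, mu = lame(1000.0, 0.0)
    eps = np.zeros(4)
    rate = np.array([0.1, 0.0, 0.0, 0.0])
    s = _kv_stress(eps, rate, lam, mu, 50.0)
    assert s[0] == pytest.approx(5.0)


def test_ludwik_values():
    assert _ludwik(0.0, 41.0, 17.0, 2.89) == pytest.approx(41.0)
    assert _ludwik(1.0, 41.0, 17.0, 2.89) == pytest.approx(58.0)


def test_radial_return_elastic_below_yield():
    lam, mu = lame(1000.0, 0.3)
    stress = np.zeros(4)
    eps_p = np.zeros(4)
    deps = np.array([1e-5, 0.0, 0.0, 0.0])  # far below yield
    s, ep_out, epq, dgamma, ok = _radial_return(
        stress, eps_p, 0.0, deps, lam, mu, 41.0, 17.0, 2.89)
    assert ok
    assert dgamma == 0.0
    assert epq == 0.0
    tr = deps[0]
    assert s[0] == pytest.approx(lam * tr + 2 * mu * deps[0])


def test_radial_return_stays_on_yield_surface():
    lam, mu = lame(1000.0, 0.3)
    stress = np.zeros(4)
    eps_p = np.zeros(4)
    epq = 0.0
    rng = np.random.default_rng(3)
    for _ in range(50):
        deps = rng.normal(scale=5e-3, size=4)
        deps[2] = 0.0
        stress, eps_p, epq, dgamma, ok = _radial_return(
            stress, eps_p, epq, deps, lam, mu, 41.0, 17.0, 2.89)
        assert ok
        vm = von_mises(stress)
        flow = _ludwik(epq, 41.0, 17.0, 2.89)
        # after a plastic step the stress sits on the hardened yield surface
        if dgamma > 0:
            assert vm == pytest.approx(flow, rel=1e-8)
        else:
            assert vm <= flow * (1 + 1e-10)


def test_radial_return_plastic_flow_is_isochoric():
    lam, mu = lame(1000.0, 0.3)
    stress = np.zeros(4)
    eps_p = np.zeros(4)
    epq = 0.0
    deps = np.array([0.05, -0.01, 0.0, 0.02])  # large: well past yield
    stress, eps_p, epq, dgamma, ok = _radial_return(
        stress, eps_p, epq, deps, lam, mu, 41.0, 17.0, 2.89)
    assert ok and dgamma > 0
    assert eps_p[0] + eps_p[1] + eps_p[2] == pytest.approx(0.0, abs=1e-12)


def test_radial_return_unload_is_elastic():
    lam, mu = lame(1000.0, 0.3)
    stress = np.zeros(4)
    eps_p = np.zeros(4)
    epq = 0.0
    load = np.array([0.06, 0.0, 0.0, 0.0])
    stress, eps_p, epq, *_ = _radial_return(
        stress, eps_p, epq, load, lam, mu, 41.0, 17.0, 2.89)
    assert epq > 0
    epq_before = epq
    small_unload = np.array([-1e-5, 0.0, 0.0, 0.0])
    stress2, eps_p2, epq2, dgamma, ok = _radial_return(
        stress, eps_p, epq, small_unload, lam, mu, 41.0, 17.0, 2.89)
    assert ok
    assert dgamma == 0.0
    assert epq2 == pytest.approx(epq_before)  # permanent strain persists


def test_stress_stiffening_ratchet():
    law = StiffeningLaw()
    e0 = 1.0
    # below threshold: unchanged
    assert stress_stiffening_update(e0, 10.0, law) == e0
    # above threshold: increases, clamped to [E_min, E_max]
    e1 = stress_stiffening_update(e0, 25.0, law)
    assert law.E_min <= e1 <= law.E_max
    # ratchet: never decreases even when the stress drops again
    e2 = stress_stiffening_update(e1, 1.0, law)
    assert e2 >= e1
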