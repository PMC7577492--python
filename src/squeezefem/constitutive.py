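"""Material-point updates.

Stress state is the plane-strain Cauchy tensor stored as
``(s_xx, s_yy, s_zz, t_xy)``; the out-of-plane shears vanish identically.
Membranes, cytoplasm and tissues follow a Kelvin-Voigt law (plane-strain
Hooke on the total strain plus a component-wise viscous term on the
in-plane strain rate).  The nucleus is J2-elastoplastic with Ludwik
power-law isotropic hardening, integrated by an elastic predictor /
radial-return corrector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from squeezefem.config import PlasticMaterial, StiffeningLaw, ViscoelasticMaterial

XX, YY, ZZ, XY = 0, 1, 2, 3


@dataclass
class MaterialPointState:
    """Strain decomposition bookkeeping for a single material point."""

    stress: np.ndarray = field(default_factory=lambda: np.zeros(4))
    eps_total: np.ndarray = field(default_factory=lambda: np.zeros(4))
    eps_plastic: np.ndarray = field(default_factory=lambda: np.zeros(4))
    eps_plastic_eq: float = 0.0

    @property
    def eps_elastic(self) -> np.ndarray:
        return self.eps_total - self.eps_plastic

    def copy(self) -> "MaterialPointState":
        return MaterialPointState(
            self.stress.copy(), self.eps_total.copy(), self.eps_plastic.copy(), self.eps_plastic_eq
        )


def lame(E: float, nu: float) -> tuple[float, float]:
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


@njit(cache=True)
def von_mises(stress: np.ndarray) -> float:
    """Equivalent (von Mises) stress of a plane-strain state.

    sqrt(1/2 [(sxx-syy)^2 + (syy-szz)^2 + (szz-sxx)^2] + 3 txy^2).
    """
    sxx, syy, szz, txy = stress[0], stress[1], stress[2], stress[3]
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2) + 3.0 * txy * txy
    )


@njit(cache=True)
def _kv_stress(eps: np.ndarray, rate: np.ndarray, lam: float, mu: float, eta: float) -> np.ndarray:
    """Plane-strain Hooke on the total strain + eta * in-plane strain rate."""
    out = np.empty(4)
    tr = eps[0] + eps[1]  # eps_zz = 0 in plane strain
    out[0] = lam * tr + 2.0 * mu * eps[0] + eta * rate[0]
    out[1] = lam * tr + 2.0 * mu * eps[1] + eta * rate[1]
    out[2] = lam * tr  # sigma_zz = nu (sxx + syy) for the elastic part
    out[3] = 2.0 * mu * eps[3] + eta * rate[3]
    return out


def kelvin_voigt_update(
    state: MaterialPointState,
    strain_increment: np.ndarray,
    dt: float,
    m: ViscoelasticMaterial,
) -> MaterialPointState:
    """Advance a Kelvin-Voigt point by one strain increment over dt > 0."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    new = state.copy()
    inc = np.asarray(strain_increment, dtype=np.float64)
    new.eps_total = state.eps_total + inc
    lam, mu = lame(m.E, m.nu)
    new.stress = _kv_stress(new.eps_total, inc / dt, lam, mu, m.eta)
    return new


@njit(cache=True)
def _ludwik(ep: float, a: float, b: float, n: float) -> float:
    return a + b * ep**n


@njit(cache=True)
def _radial_return(
    stress: np.ndarray,
    eps_p: np.ndarray,
    ep_eq: float,
    deps: np.ndarray,
    lam: float,
    mu: float,
    a: float,
    b: float,
    n: float,
):
    """Elastic predictor / radial-return corrector for one increment.

    Returns (stress, eps_p, ep_eq, dgamma, converged).  The plane-strain
    kinematic constraint (deps_zz = 0) is kept; plastic flow still develops
    eps_p_zz, compensated elastically through sigma_zz.
    """
    # elastic predictor
    tr = deps[0] + deps[1]
    s = stress.copy()
    s[0] += lam * tr + 2.0 * mu * deps[0]
    s[1] += lam * tr + 2.0 * mu * deps[1]
    s[2] += lam * tr
    s[3] += 2.0 * mu * deps[3]

    p = (s[0] + s[1] + s[2]) / 3.0
    dev = np.empty(4)
    dev[0] = s[0] - p
    dev[1] = s[1] - p
    dev[2] = s[2] - p
    dev[3] = s[3]
    vm = np.sqrt(1.5 * (dev[0] ** 2 + dev[1] ** 2 + dev[2] ** 2 + 2.0 * dev[3] ** 2))
    sy = _ludwik(ep_eq, a, b, n)
    if vm <= sy or vm <= 0.0:
        return s, eps_p, ep_eq, 0.0, True

    # solve vm - 3 mu dg = a + b (ep + dg)^n  by safeguarded Newton
    lo = 0.0
    hi = vm / (3.0 * mu)
    dg = min((vm - sy) / (3.0 * mu), hi)
    converged = False
    for _ in range(100):
        f = vm - 3.0 * mu * dg - _ludwik(ep_eq + dg, a, b, n)
        if abs(f) < 1e-10 * max(a, 1.0):
            converged = True
            break
        if f > 0.0:
            lo = dg
        else:
            hi = dg
        dfdx = -3.0 * mu - b * n * (ep_eq + dg) ** (n - 1.0) if ep_eq + dg > 0 else -3.0 * mu
        step = dg - f / dfdx
        dg = step if lo < step < hi else 0.5 * (lo + hi)
    vm_new = vm - 3.0 * mu * dg
    scale = vm_new / vm
    out = np.empty(4)
    out[0] = dev[0] * scale + p
    out[1] = dev[1] * scale + p
    out[2] = dev[2] * scale + p
    out[3] = dev[3] * scale
    # flow direction from the updated deviator (radial: same direction)
    fac = 1.5 * dg / vm  # = dg * (3/2) s_trial/vm / s... applied to trial deviator
    epn = eps_p.copy()
    epn[0] += fac * dev[0]
    epn[1] += fac * dev[1]
    epn[2] += fac * dev[2]
    epn[3] += fac * dev[3]
    return out, epn, ep_eq + dg, dg, converged


class PlasticIntegrationError(RuntimeError):
    pass


def radial_return_update(
    state: MaterialPointState, strain_increment: np.ndarray, m: PlasticMaterial
) -> MaterialPointState:
    """Advance an elastoplastic point by one (plane-strain) strain increment."""
    lam, mu = lame(m.E, m.nu)
    deps = np.asarray(strain_increment, dtype=np.float64)
    s, ep, ep_eq, dg, ok = _radial_return(
        state.stress,
        state.eps_plastic,
        state.eps_plastic_eq,
        deps,
        lam,
        mu,
        m.yield_stress,
        m.hardening_coefficient,
        m.hardening_exponent,
    )
    if not ok:
        resid = von_mises(s) - m.flow_stress(ep_eq)
        raise PlasticIntegrationError(f"return mapping failed to converge (residual {resid:.3e})")
    new = MaterialPointState(s, state.eps_total + deps, ep, ep_eq)
    return new


def stress_stiffening_update(current_Ec: float, sigma_shear_kpa: float, law: StiffeningLaw) -> float:
    """Ratcheted cytoplasmic modulus update (never decreases, capped at E_max)."""
    target = law.evaluate(sigma_shear_kpa)
    return max(current_Ec, target)
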