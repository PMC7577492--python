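"""Post-processing observables computed from recorded trajectories.

Everything here is a pure function of a :class:`~squeezefem.solver.RunResult`
(or of plain arrays), so observables can be unit-tested on synthetic data
without running the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from squeezefem.solver import RunResult, Snapshot, nucleus_entered


class ObservableError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pore entry and kinematics
# ---------------------------------------------------------------------------

def nucleus_rear_x(snap: Snapshot) -> float:
    """Trailing-edge coordinate of the nuclear envelope."""
    return float(snap.nm_outer_xy[:, 0].min())


def detect_pore_entry(result: RunResult) -> tuple[float, float]:
    """(T_entry, F_entry): when the whole nuclear envelope passes x = 0.

    The crossing time is linearly interpolated between the snapshots
    bracketing the event; F_entry is the applied-ramp resultant at that
    time.  Raises :class:`ObservableError` if the nucleus never entered.
    """
    snaps = result.snapshots
    for i, s in enumerate(snaps):
        if nucleus_entered(s):
            if i == 0:
                return s.t, s.F
            a, b = snaps[i - 1], snaps[i]
            xa, xb = nucleus_rear_x(a), nucleus_rear_x(b)
            w = 0.0 if xb == xa else (0.0 - xa) / (xb - xa)
            t = a.t + w * (b.t - a.t)
            f = a.F + w * (b.F - a.F)
            return float(t), float(f)
    raise ObservableError("nucleus never fully entered the pore in this run")


def velocity_trace(result: RunResult) -> tuple[np.ndarray, np.ndarray]:
    """(times, v_x) of the nucleus centroid (central finite differences)."""
    t = result.times
    xc = np.array([s.nucleus_centroid[0] for s in result.snapshots])
    if len(t) < 3:
        raise ObservableError("trajectory too short for a velocity trace")
    v = np.gradient(xc, t)
    return t, v


def stretch_ratios(result: RunResult) -> dict[str, np.ndarray]:
    """Axial and transverse nuclear stretch L/D0, D/D0 over time."""
    D0 = result.config.geometry.nucleus_diameter
    L = np.array([np.ptp(s.nm_outer_xy[:, 0]) for s in result.snapshots])
    D = np.array([np.ptp(s.nm_outer_xy[:, 1]) for s in result.snapshots])
    return {"t": result.times, "axial": L / D0, "transverse": D / D0}


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def circularity(ring_xy: np.ndarray) -> float:
    """Nuclear circularity D/L: transverse extent over axial extent.

    1 for the undeformed circle; < 1 for the bullet/pill shapes adopted
    during squeezing (migration is along +x).
    """
    ring_xy = np.asarray(ring_xy, dtype=float)
    if ring_xy.ndim != 2 or ring_xy.shape[0] < 3:
        raise ObservableError("need at least 3 ring points")
    L = np.ptp(ring_xy[:, 0])
    D = np.ptp(ring_xy[:, 1])
    if L <= 0:
        raise ObservableError("degenerate ring: zero axial extent")
    return float(D / L)


def circularity_trace(result: RunResult) -> tuple[np.ndarray, np.ndarray]:
    t = result.times
    c = np.array([circularity(s.nm_outer_xy) for s in result.snapshots])
    return t, c


def min_circularity(result: RunResult) -> float:
    """Minimum nuclear circularity D/L over the recorded trajectory."""
    _, c = circularity_trace(result)
    return float(c.min())


# ---------------------------------------------------------------------------
# tissue and membrane fields
# ---------------------------------------------------------------------------

def tissue_displacement_profile(
    result: RunResult, which: int = 1, t: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(rest x positions, u_y) along the pore wall of tissue 1 or 2.

    Positive u_y on tissue 1 (above the channel) means opening; the
    snapshot closest to ``t`` (or the final one) is used.
    """
    if which not in (1, 2):
        raise ObservableError("which must be 1 or 2")
    mesh = result.mesh
    wall = mesh.node_sets[f"tissue{which}_wall"]
    xs = mesh.nodes[wall, 0]
    snaps = result.snapshots
    i = -1 if t is None else int(np.argmin(np.abs(result.times - t)))
    uy = snaps[i].wall1_uy if which == 1 else snaps[i].wall2_uy
    return xs, uy


def rotate_to_polar(stress4: np.ndarray, theta: float) -> tuple[float, float, float]:
    """(sigma_rr, sigma_tt, sigma_rt) of an (xx, yy, zz, xy) state at angle theta."""
    c, s = np.cos(theta), np.sin(theta)
    sxx, syy, txy = stress4[0], stress4[1], stress4[3]
    srr = c * c * sxx + s * s * syy + 2 * c * s * txy
    stt = s * s * sxx + c * c * syy - 2 * c * s * txy
    srt = (syy - sxx) * c * s + (c * c - s * s) * txy
    return float(srr), float(stt), float(srt)


def membrane_stress_trace(
    result: RunResult, layer: str = "outer", angle_deg: float = 0.0
) -> dict[str, np.ndarray]:
    """Radial/hoop stress history at a material point of the nuclear membrane.

    The element whose rest centroid is closest to ``angle_deg`` on the
    requested layer (inner or outer) is tagged at t = 0 and followed as a
    material point; stresses are rotated into the instantaneous radial/
    tangential frame about the nucleus centroid.
    """
    if layer not in ("inner", "outer"):
        raise ObservableError("layer must be 'inner' or 'outer'")
    snaps = result.snapshots
    cent0 = snaps[0].nm_inner_cent if layer == "inner" else snaps[0].nm_outer_cent
    c0 = snaps[0].nucleus_centroid
    th0 = np.arctan2(cent0[:, 1] - c0[1], cent0[:, 0] - c0[0])
    target = np.deg2rad(angle_deg)
    k = int(np.argmin(np.abs(np.angle(np.exp(1j * (th0 - target))))))

    srr = np.empty(len(snaps))
    stt = np.empty(len(snaps))
    for i, s in enumerate(snaps):
        sig = s.nm_inner_sig[k] if layer == "inner" else s.nm_outer_sig[k]
        cen = s.nm_inner_cent[k] if layer == "inner" else s.nm_outer_cent[k]
        th = np.arctan2(cen[1] - s.nucleus_centroid[1], cen[0] - s.nucleus_centroid[0])
        srr[i], stt[i], _ = rotate_to_polar(sig, th)
    return {"t": result.times, "sigma_rr": srr, "sigma_tt": stt, "element_index": k}


# ---------------------------------------------------------------------------
# kinks and plasticity
# ---------------------------------------------------------------------------

def turning_angles(ring_xy: np.ndarray) -> np.ndarray:
    """Signed exterior (turning) angle at each vertex of a closed polyline."""
    p = np.asarray(ring_xy, dtype=float)
    e = np.roll(p, -1, axis=0) - p  # edge k: p[k] -> p[k+1]
    a = np.arctan2(e[:, 1], e[:, 0])
    turn = np.angle(np.exp(1j * (a - np.roll(a, 1))))  # at vertex k
    return turn


def detect_kinks(ring_xy: np.ndarray, threshold_deg: float = 60.0) -> np.ndarray:
    """Vertices where the envelope turns more sharply than ``threshold_deg``.

    For a smooth convex ring the turning angle per vertex is 360/n degrees;
    localized buckles ("kinks") concentrate curvature far beyond that.
    Returns the vertex indices exceeding the threshold in magnitude.
    """
    turn = np.abs(turning_angles(ring_xy))
    return np.flatnonzero(turn > np.deg2rad(threshold_deg))


def kink_count_trace(result: RunResult, threshold_deg: float = 60.0) -> tuple[np.ndarray, np.ndarray]:
    t = result.times
    n = np.array(
        [len(detect_kinks(s.nm_outer_xy, threshold_deg)) for s in result.snapshots]
    )
    return t, n


def plasticity_report(result: RunResult, threshold: float = 1e-4) -> dict:
    """Residual plastic deformation of the nucleus at the end of the run."""
    m = result.model
    epq = m.epq[m.is_plastic]
    max_epq = float(epq.max()) if epq.size else 0.0
    frac = float((epq > threshold).mean()) if epq.size else 0.0
    return {
        "max_eps_plastic_eq": max_epq,
        "plastic_gauss_point_fraction": frac,
        "plastic": bool(max_epq > threshold),
        "plastic_work": float(result.snapshots[-1].wplast),
        "flow_stress_at_max": float(
            m.hardening[0] + m.hardening[1] * max_epq ** m.hardening[2]
        ),
    }


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

@dataclass
class RunSummary:
    label: str
    status: str
    n_elements: int
    n_steps: int
    wall_time: float
    t_end: float
    T_entry: float | None
    F_entry: float | None
    min_circularity: float
    max_eps_plastic_eq: float
    plastic: bool
    max_qs_ratio: float
    max_qs_loading: float
    qs_transient_start: float | None
    max_energy_err: float
    max_penetration: float
    accepted: bool
    materials: dict

    def as_dict(self) -> dict:
        return asdict(self)


QS_RATIO_LIMIT = 0.05
ENERGY_ERR_LIMIT = 0.02
# KE/IE is meaningless while the internal energy is a sliver of its final
# value (startup transients divided by a near-zero denominator), so the
# monitor opens once IE exceeds both the absolute floor and 1% of the final
# internal energy.
IE_GATE_FRACTION = 0.01


def _quasi_static_check(result: RunResult, active: list) -> tuple[bool, float, float | None]:
    """Apply the quasi-staticity acceptance rule.

    Energy balance must hold everywhere.  KE/IE <= 5% is enforced strictly
    during the loading/approach phase; a single contiguous *terminal* window of
    exceedance is permitted only when it brackets the detected pore-entry
    event, because the entry snap-through is a physical dynamic instability of
    the model (stored elastic energy converts to kinetic energy as the nucleus
    shoots through the pore) and its KE magnitude reflects the scaled mass,
    not solution quality.

    Returns (qs_accepted, max_qs_loading, transient_start_time).
    """
    exceed = [i for i, s in enumerate(active) if s.qs_ratio > QS_RATIO_LIMIT]
    if not exceed:
        max_loading = max((s.qs_ratio for s in active), default=0.0)
        return True, max_loading, None
    contiguous = exceed == list(range(exceed[0], exceed[-1] + 1))
    terminal = exceed[-1] == len(active) - 1
    t_start = active[exceed[0]].t
    brackets_entry = (
        result.entry_time is not None and t_start <= result.entry_time
    )
    ok = contiguous and terminal and brackets_entry
    max_loading = max(
        (s.qs_ratio for i, s in enumerate(active) if i < exceed[0]), default=0.0
    )
    return ok, max_loading, t_start


def summarize(result: RunResult) -> RunSummary:
    """Condense a run into the headline observables and solver health metrics."""
    snaps = result.snapshots
    floor = result.config.solver.ie_monitor_floor
    wint_final = max((s.wint for s in snaps), default=0.0)
    gate = max(floor, IE_GATE_FRACTION * wint_final)
    active = [s for s in snaps if s.wint > gate]
    max_qs = max((s.qs_ratio for s in active), default=0.0)
    max_err = max((s.energy_err for s in active), default=0.0)
    max_pen = max(s.max_penetration for s in snaps)
    qs_ok, max_qs_loading, qs_t0 = _quasi_static_check(result, active)
    accepted = qs_ok and max_err <= ENERGY_ERR_LIMIT
    try:
        T_entry, F_entry = detect_pore_entry(result)
    except ObservableError:
        T_entry, F_entry = None, None
    rep = plasticity_report(result)
    return RunSummary(
        label=result.config.label,
        status=result.status,
        n_elements=result.mesh.n_elements,
        n_steps=result.n_steps,
        wall_time=result.wall_time,
        t_end=float(result.times[-1]),
        T_entry=T_entry,
        F_entry=F_entry,
        min_circularity=min_circularity(result),
        max_eps_plastic_eq=rep["max_eps_plastic_eq"],
        plastic=rep["plastic"],
        max_qs_ratio=float(max_qs),
        max_qs_loading=float(max_qs_loading),
        qs_transient_start=qs_t0,
        max_energy_err=float(max_err),
        max_penetration=float(max_pen),
        accepted=bool(accepted),
        materials=result.config.material_summary(),
    )
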