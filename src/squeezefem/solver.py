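"""Explicit central-difference solver with selective mass scaling.

The model is quasi-static: inertia is a vehicle for explicit integration,
not physics.  Per-element densities are scaled so the target time step is
stable (Courant condition on the P-wave modulus plus the filtered viscous
stiffness plus any active distortion-control stiffness), masses only ever
increase, and the energy injected by scaling a moving node is tracked so
the global balance W_ext + E_injected = W_int + KE + E_contact can be
audited.  Kinetic energy is monitored against internal work to confirm
the quasi-static regime.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from squeezefem import _kernels
from squeezefem.config import SimulationConfig, SolverParams
from squeezefem.constitutive import lame
from squeezefem.contact import apply_boundary_conditions, leading_edge_weights
from squeezefem.geometry import PART_IDS
from squeezefem.meshing import Mesh, mesh_from_config

#: nominal density (mass per unit area per unit depth) before scaling
RHO_BASE = 1.0
#: extra safety applied to the distortion-control tangent in mass scaling
#: (the tangent steepens between mass updates, so budget well ahead of it)
DC_MASS_SAFETY = 8.0
#: cadence (simulated seconds) of the Python-side global mass/distortion
#: updates; fast local collapse is chased per-step inside the kernel
UPDATE_INTERVAL = 0.25
#: cap on the distortion-control pressure, in units of distortion_stiffness
DC_PRESSURE_CAP = 50.0
#: viscosity multiplier for aspect-ratio-flagged elements
DISTORTION_VISCOSITY_BOOST = 5.0
#: candidate master segments kept per slave node
CONTACT_CANDIDATES = 6

_DN = _kernels.shape_gradients()


class SolverError(RuntimeError):
    pass


@dataclass
class ExplicitModel:
    """All state needed to advance the explicit dynamics."""

    nodes0: np.ndarray
    x: np.ndarray
    v: np.ndarray
    f: np.ndarray
    mass: np.ndarray
    elems: np.ndarray
    lam_el: np.ndarray
    mu_el: np.ndarray
    eta_el: np.ndarray
    eta_boost: np.ndarray
    rho_el: np.ndarray
    lmin_el: np.ndarray
    is_plastic: np.ndarray
    is_cyto: np.ndarray
    hardening: tuple[float, float, float]
    stress: np.ndarray
    eps: np.ndarray
    epsp: np.ndarray
    epq: np.ndarray
    Gf: np.ndarray
    detJ0: np.ndarray
    Ec_el: np.ndarray
    nu_el: np.ndarray
    stiffening: tuple  # (on, thresh, slope, inter, emin, emax)
    fixed_x: np.ndarray
    fixed_y: np.ndarray
    vpx: np.ndarray
    vpy: np.ndarray
    load_nodes: np.ndarray
    load_amp: np.ndarray
    fmode: int
    Fmax: float
    rampT: float
    slave: np.ndarray
    msegs: np.ndarray
    scand: np.ndarray
    rslave: np.ndarray
    rsegs: np.ndarray
    rcand: np.ndarray
    kpen: float
    solver: SolverParams
    dt: float
    q_rest: np.ndarray = field(default=None)
    rho_base: float = RHO_BASE
    t: float = 0.0
    step_count: int = 0
    einj: float = 0.0
    acc: np.ndarray = field(default_factory=lambda: np.zeros(9))
    meta: dict = field(default_factory=dict)

    # ---- derived quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elems.shape[0]

    @property
    def Tf(self) -> float:
        if self.solver.rate_filter_steps is not None:
            return max(self.solver.rate_filter_steps, 1.0) * self.dt
        return max(self.solver.rate_filter_time, self.dt)

    def kinetic_energy(self) -> float:
        return float(0.5 * (self.mass[:, None] * self.v**2).sum())

    def external_force(self) -> float:
        """Current resultant of the applied load ramp."""
        if self.fmode == 1:
            s = 1.0
        else:
            u = min(max(self.t / self.rampT, 0.0), 1.0)
            s = u**3 * (10 - 15 * u + 6 * u * u) if self.fmode == 0 else u
        return self.Fmax * s

    def element_areas(self) -> np.ndarray:
        return self.gp_detj().sum(axis=1)

    def gp_detj(self) -> np.ndarray:
        out = np.empty((self.n_elements, 4))
        _kernels.gp_detj(self.x, self.elems, _DN, out)
        return out

    def element_quality(self) -> np.ndarray:
        xe = self.x[self.elems]
        edges = np.stack([xe[:, (i + 1) % 4] - xe[:, i] for i in range(4)], axis=1)
        lengths = np.linalg.norm(edges, axis=2)
        return lengths.min(axis=1) / np.maximum(lengths.max(axis=1), 1e-300)

    def update_lmin(self) -> None:
        xe = self.x[self.elems]
        edges = np.stack([xe[:, (i + 1) % 4] - xe[:, i] for i in range(4)], axis=1)
        lengths = np.linalg.norm(edges, axis=2)
        # characteristic length: element area / longest edge (robust for slivers)
        areas = np.abs(self.gp_detj()).sum(axis=1)
        self.lmin_el[:] = np.minimum(lengths.min(axis=1), areas / lengths.max(axis=1))
        np.maximum(self.lmin_el, 1e-6, out=self.lmin_el)

    def refresh_cytoplasm_moduli(self) -> None:
        """Push ratcheted cytoplasmic moduli into the Lame arrays."""
        idx = np.flatnonzero(self.is_cyto)
        if idx.size == 0:
            return
        nu = self.nu_el[idx]
        E = self.Ec_el[idx]
        self.lam_el[idx] = E * nu / ((1 + nu) * (1 - 2 * nu))
        self.mu_el[idx] = E / (2 * (1 + nu))


def stab_modulus(m: ExplicitModel) -> np.ndarray:
    """Per-element stiffness governing the stable time step.

    P-wave modulus + filtered-dashpot stiffness eta/T_f + (for elements in
    or near the distortion-control regime) the control-pressure tangent.
    """
    Ep = m.lam_el + 2.0 * m.mu_el
    Ev = m.eta_el * m.eta_boost / m.Tf
    ratio = np.min(m.gp_detj() / m.detJ0, axis=1)
    jf = m.solver.distortion_area_floor
    near = ratio < 5.0 * jf
    Edc = np.zeros_like(Ep)
    if near.any():
        r = np.maximum(ratio[near], 1e-3)
        Edc[near] = DC_MASS_SAFETY * np.minimum(
            m.solver.distortion_stiffness * jf / r**2, 1.0e7
        )
    return Ep + Ev + Edc


def stable_dt(m: ExplicitModel) -> float:
    """Largest stable step at the current masses (Courant with safety)."""
    cd = np.sqrt(stab_modulus(m) / m.rho_el)
    return float(m.solver.courant_safety * (m.lmin_el / cd).min())


def mass_scale(m: ExplicitModel) -> float:
    """Raise densities/nodal masses so m.dt is stable; returns energy injected.

    Masses are monotone non-decreasing; the kinetic energy added by scaling
    nodes that are already moving is returned and accumulated in m.einj.
    """
    m.update_lmin()
    Es = stab_modulus(m)
    gamma = m.solver.courant_safety
    rho_req = Es * (m.dt / (gamma * m.lmin_el)) ** 2
    m.rho_el = np.maximum.reduce([m.rho_el, rho_req, np.full_like(rho_req, m.rho_base)])
    areas = np.abs(m.gp_detj()).sum(axis=1)
    m_req = np.zeros(m.n_nodes)
    contrib = (m.rho_el * areas / 4.0)[:, None].repeat(4, axis=1)
    np.add.at(m_req, m.elems.ravel(), contrib.ravel())
    # reserve for the contact penalty springs: central-difference stability
    # needs m >= j*k*dt^2/4 for j springs on a node (j <= 3 across the two
    # passes); 2*k*dt^2 keeps a >2.5x margin without flooding the interface
    # with artificial inertia.
    if m.msegs.shape[0] > 0:
        cn = np.unique(np.concatenate([m.slave, m.msegs.ravel(), m.rslave, m.rsegs.ravel()]))
        m_req[cn] += 2.0 * m.kpen * m.dt**2
    dm = np.maximum(m_req - m.mass, 0.0)
    de = float(0.5 * (dm * (m.v**2).sum(axis=1)).sum())
    m.mass += dm
    m.einj += de
    return de


def distortion_update(m: ExplicitModel) -> int:
    """Flag badly distorted elements and boost their viscosity.

    An element is flagged when its min/max edge ratio falls below the
    configured threshold *and* below half its rest-shape ratio (membrane
    elements are thin by construction and must not be flagged at rest).
    """
    q = m.element_quality()
    thresh = np.minimum(m.solver.distortion_ratio_min, 0.5 * m.q_rest)
    flagged = q < thresh
    m.eta_boost[:] = np.where(flagged, DISTORTION_VISCOSITY_BOOST, 1.0)
    # plastic elements have no dashpot; give flagged ones a small artificial one
    plastic_flagged = flagged & m.is_plastic
    if plastic_flagged.any():
        m.eta_el[plastic_flagged] = np.maximum(
            m.eta_el[plastic_flagged], 0.02 * (m.lam_el + 2 * m.mu_el)[plastic_flagged]
        )
    return int(flagged.sum())


def step(m: ExplicitModel, n: int = 1) -> int:
    """Advance n explicit steps; returns the kernel status code."""
    status = _kernels.run_chunk(
        m.x, m.v, m.f, m.mass,
        m.elems, m.lam_el, m.mu_el, m.eta_el, m.eta_boost, m.rho_el, m.lmin_el,
        m.is_plastic, m.is_cyto,
        m.hardening[0], m.hardening[1], m.hardening[2],
        m.stress, m.eps, m.epsp, m.epq, m.Gf, m.detJ0,
        m.Ec_el,
        m.stiffening[0], m.stiffening[1], m.stiffening[2],
        m.stiffening[3], m.stiffening[4], m.stiffening[5],
        m.solver.bulk_viscosity_linear, m.solver.bulk_viscosity_quadratic,
        m.solver.distortion_area_floor, m.solver.distortion_stiffness,
        DC_PRESSURE_CAP * m.solver.distortion_stiffness,
        m.fixed_x, m.fixed_y, m.vpx, m.vpy,
        m.load_nodes, m.load_amp, m.fmode, m.Fmax, m.rampT,
        m.slave, m.msegs, m.scand, m.rslave, m.rsegs, m.rcand,
        m.kpen, m.solver.contact_search_every, m.step_count,
        m.t, m.dt, n, m.Tf, m.solver.courant_safety, DC_MASS_SAFETY, _DN, m.acc,
    )
    m.step_count += n
    m.t += n * m.dt
    return status


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------

def build_model(
    nodes: np.ndarray,
    elements: np.ndarray,
    *,
    E_el: np.ndarray,
    eta_el: np.ndarray,
    nu_el: np.ndarray,
    is_plastic: np.ndarray,
    hardening: tuple[float, float, float] = (41.0, 17.0, 2.89),
    is_cyto: np.ndarray | None = None,
    stiffening: tuple | None = None,
    dt: float,
    solver: SolverParams | None = None,
    fixed_x: np.ndarray | None = None,
    fixed_y: np.ndarray | None = None,
    vpx: np.ndarray | None = None,
    vpy: np.ndarray | None = None,
    load_nodes: np.ndarray | None = None,
    load_amp: np.ndarray | None = None,
    fmode: int = 0,
    Fmax: float = 0.0,
    rampT: float = 1.0,
    contact: tuple | None = None,  # (slave, master_segments, rslave, rsegs)
    kpen: float = 0.0,
    rho_base: float = RHO_BASE,
) -> ExplicitModel:
    """Assemble an ExplicitModel from raw arrays (used by the cell model and
    by the verification benchmarks alike)."""
    nodes = np.asarray(nodes, dtype=np.float64)
    elements = np.ascontiguousarray(elements, dtype=np.int32)
    nn, ne = len(nodes), len(elements)
    solver = solver or SolverParams()

    lam = np.empty(ne)
    mu = np.empty(ne)
    for i in range(ne):
        lam[i], mu[i] = lame(E_el[i], nu_el[i])

    z4 = lambda: np.zeros((ne, 4, 4))
    detJ0 = np.empty((ne, 4))
    _kernels.gp_detj(nodes, elements, _DN, detJ0)
    if (detJ0 <= 0).any():
        raise SolverError("initial mesh has non-positive Gauss-point Jacobians")

    if is_cyto is None:
        is_cyto = np.zeros(ne, dtype=bool)
    if stiffening is None:
        stiffening = (False, 1e30, 0.0, 0.0, 1.0, 1.0)
    empty_i = np.empty(0, dtype=np.int64)
    empty_seg = np.empty((0, 2), dtype=np.int64)
    if contact is None:
        slave, msegs, rslave, rsegs = empty_i, empty_seg, empty_i, empty_seg
    else:
        slave, msegs, rslave, rsegs = (np.asarray(a, dtype=np.int64) for a in contact)
        msegs = msegs.reshape(-1, 2)
        rsegs = rsegs.reshape(-1, 2)

    m = ExplicitModel(
        nodes0=nodes.copy(),
        x=nodes.copy(),
        v=np.zeros((nn, 2)),
        f=np.zeros((nn, 2)),
        mass=np.zeros(nn),
        elems=elements,
        lam_el=lam,
        mu_el=mu,
        eta_el=np.asarray(eta_el, dtype=np.float64).copy(),
        eta_boost=np.ones(ne),
        rho_el=np.full(ne, rho_base),
        lmin_el=np.ones(ne),
        is_plastic=np.asarray(is_plastic, dtype=bool),
        is_cyto=np.asarray(is_cyto, dtype=bool),
        hardening=tuple(float(h) for h in hardening),
        stress=z4(),
        eps=z4(),
        epsp=z4(),
        epq=np.zeros((ne, 4)),
        Gf=z4(),
        detJ0=detJ0,
        Ec_el=np.asarray(E_el, dtype=np.float64).copy(),
        nu_el=np.asarray(nu_el, dtype=np.float64).copy(),
        stiffening=stiffening,
        fixed_x=fixed_x if fixed_x is not None else np.zeros(nn, dtype=bool),
        fixed_y=fixed_y if fixed_y is not None else np.zeros(nn, dtype=bool),
        vpx=vpx if vpx is not None else np.zeros(nn),
        vpy=vpy if vpy is not None else np.zeros(nn),
        load_nodes=load_nodes if load_nodes is not None else empty_i,
        load_amp=load_amp if load_amp is not None else np.zeros((0, 2)),
        fmode=fmode,
        Fmax=Fmax,
        rampT=rampT,
        slave=slave,
        msegs=msegs,
        scand=np.full((len(slave), CONTACT_CANDIDATES), -1, dtype=np.int64),
        rslave=rslave,
        rsegs=rsegs,
        rcand=np.full((len(rslave), CONTACT_CANDIDATES), -1, dtype=np.int64),
        kpen=float(kpen),
        solver=solver,
        dt=float(dt),
        rho_base=float(rho_base),
    )
    m.load_nodes = np.asarray(m.load_nodes, dtype=np.int64)
    m.load_amp = np.asarray(m.load_amp, dtype=np.float64).reshape(-1, 2)
    m.q_rest = m.element_quality()
    mass_scale(m)  # initial assembly (v = 0, injects nothing)
    m.einj = 0.0
    return m


def model_from_mesh(cfg: SimulationConfig, mesh: Mesh) -> ExplicitModel:
    """Build the confined-migration model (materials, contact, load, BCs)."""
    mats = cfg.materials
    part = mesh.part
    ne = mesh.n_elements

    E_of = {
        "cell_membrane": mats.cell_membrane.E,
        "cytoplasm": mats.cytoplasm.E,
        "nuclear_membrane": mats.nuclear_membrane.E,
        "nucleus": mats.nucleus.E,
        "tissue1": mats.tissue1.E,
        "tissue2": mats.tissue2.E,
    }
    eta_of = {
        "cell_membrane": mats.cell_membrane.eta,
        "cytoplasm": mats.cytoplasm.eta,
        "nuclear_membrane": mats.nuclear_membrane.eta,
        "nucleus": 0.0,
        "tissue1": mats.tissue1.eta,
        "tissue2": mats.tissue2.eta,
    }
    nu_of = {
        "cell_membrane": mats.cell_membrane.nu,
        "cytoplasm": mats.cytoplasm.nu,
        "nuclear_membrane": mats.nuclear_membrane.nu,
        "nucleus": mats.nucleus.nu,
        "tissue1": mats.tissue1.nu,
        "tissue2": mats.tissue2.nu,
    }
    E_el = np.empty(ne)
    eta_el = np.empty(ne)
    nu_el = np.empty(ne)
    for name, pid in PART_IDS.items():
        sel = part == pid
        E_el[sel] = E_of[name]
        eta_el[sel] = eta_of[name]
        nu_el[sel] = nu_of[name]
    is_plastic = part == PART_IDS["nucleus"]
    is_cyto = part == PART_IDS["cytoplasm"]

    fx, fy = apply_boundary_conditions(mesh)

    lead_all = mesh.rings["cell_outer_ring"]
    th = mesh.ring_thetas
    arc = np.deg2rad(cfg.loading.leading_edge_arc_degrees)
    wrapped = np.angle(np.exp(1j * th))
    sel = np.abs(wrapped) <= arc + 1e-12
    lead_nodes = lead_all[sel].astype(np.int64)
    w = leading_edge_weights(th[sel], cfg.loading.leading_edge_arc_degrees)
    load_amp = np.zeros((len(lead_nodes), 2))
    load_amp[:, 0] = w

    ring = mesh.rings["cell_outer_ring"]
    rsegs = np.stack([ring, np.roll(ring, -1)], axis=1)
    contact = (
        ring.astype(np.int64),
        mesh.contact_master_segments.astype(np.int64),
        mesh.node_sets["pore_faces"].astype(np.int64),
        rsegs.astype(np.int64),
    )
    # Penalty stiffness scales with the bulk bodies that govern interface
    # compliance (tissues and nucleus); the membranes' large in-plane shell
    # modulus does not set the contact scale, and using it would demand huge
    # stability mass reserves on every contact node.
    kpen = cfg.solver.penalty_factor * max(
        mats.tissue1.E, mats.tissue2.E, mats.nucleus.E
    )

    sl = cfg.materials.stiffening
    n_mem = cfg.mesh.resolve()["membrane_layers"]
    n_theta = cfg.mesh.resolve()["n_circumferential"]
    n_side = n_theta // 4
    n_core_rad = cfg.mesh.resolve()["core_radial_layers"]
    nucleus_count = n_side * n_side + n_theta * n_core_rad

    m = build_model(
        mesh.nodes,
        mesh.elements,
        E_el=E_el,
        eta_el=eta_el,
        nu_el=nu_el,
        is_plastic=is_plastic,
        hardening=(
            mats.nucleus.yield_stress,
            mats.nucleus.hardening_coefficient,
            mats.nucleus.hardening_exponent,
        ),
        is_cyto=is_cyto,
        stiffening=(sl.enabled, sl.threshold_kpa, sl.slope, sl.intercept, sl.E_min, sl.E_max),
        dt=cfg.effective_dt,
        solver=cfg.solver,
        fixed_x=fx,
        fixed_y=fy,
        load_nodes=lead_nodes,
        load_amp=load_amp,
        fmode=0,
        Fmax=cfg.loading.F_max,
        rampT=cfg.loading.ramp_duration,
        contact=contact,
        kpen=kpen,
    )
    m.meta = {
        "nm_elem_start": nucleus_count,
        "n_theta": n_theta,
        "n_mem_layers": n_mem,
        "mesh": mesh,
        "config": cfg,
    }
    return m


# ---------------------------------------------------------------------------
# trajectory recording and the simulation driver
# ---------------------------------------------------------------------------

@dataclass
class Snapshot:
    t: float
    F: float
    ke: float
    wint: float
    wext: float
    wplast: float
    econtact: float
    einj: float
    max_penetration: float
    qs_ratio: float
    energy_err: float
    n_flagged: int
    max_epq: float
    Ec_max: float
    lead_x: float
    nucleus_centroid: np.ndarray
    nm_outer_xy: np.ndarray
    cell_outer_xy: np.ndarray
    wall1_uy: np.ndarray
    wall2_uy: np.ndarray
    nm_inner_sig: np.ndarray  # (n_theta, 4) per-element mean stress, inner layer
    nm_outer_sig: np.ndarray
    nm_inner_cent: np.ndarray  # (n_theta, 2) element centroids
    nm_outer_cent: np.ndarray


@dataclass
class RunResult:
    config: SimulationConfig
    mesh: Mesh
    model: ExplicitModel
    snapshots: list
    status: str  # entered | t_max | inverted | diverged
    entry_time: float | None
    wall_time: float
    n_steps: int
    field_frames: list = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])


def _take_snapshot(m: ExplicitModel, maxpen: float, n_flagged: int) -> Snapshot:
    mesh: Mesh = m.meta["mesh"]
    ke = m.kinetic_energy()
    wext, wint, wplast = m.acc[0], m.acc[1], m.acc[2]
    econ = m.acc[5]
    einj = m.einj + m.acc[8]
    floor = m.solver.ie_monitor_floor
    qs = ke / max(wint, floor)
    denom = max(wext + einj, wint + ke + econ, floor)
    err = abs(wext + einj - (wint + ke + econ)) / denom

    n_theta = m.meta["n_theta"]
    n_mem = m.meta["n_mem_layers"]
    e0 = m.meta["nm_elem_start"]
    inner = slice(e0, e0 + n_theta)
    outer = slice(e0 + (n_mem - 1) * n_theta, e0 + n_mem * n_theta)
    cent = lambda sl: m.x[m.elems[sl]].mean(axis=1)
    sig = lambda sl: m.stress[sl].mean(axis=1)

    nuc_nodes = np.unique(m.elems[m.is_plastic])
    ring_o = mesh.rings["nuclear_membrane_outer_ring"]
    return Snapshot(
        t=m.t,
        F=m.external_force(),
        ke=ke,
        wint=float(wint),
        wext=float(wext),
        wplast=float(wplast),
        econtact=float(econ),
        einj=float(einj),
        max_penetration=maxpen,
        qs_ratio=float(qs),
        energy_err=float(err),
        n_flagged=n_flagged,
        max_epq=float(m.epq.max()),
        Ec_max=float(m.Ec_el[m.is_cyto].max()) if m.is_cyto.any() else 0.0,
        lead_x=float(m.x[m.load_nodes, 0].max()) if len(m.load_nodes) else 0.0,
        nucleus_centroid=m.x[nuc_nodes].mean(axis=0),
        nm_outer_xy=m.x[ring_o].copy(),
        cell_outer_xy=m.x[mesh.rings["cell_outer_ring"]].copy(),
        wall1_uy=(m.x[mesh.node_sets["tissue1_wall"], 1] - m.nodes0[mesh.node_sets["tissue1_wall"], 1]).copy(),
        wall2_uy=(m.x[mesh.node_sets["tissue2_wall"], 1] - m.nodes0[mesh.node_sets["tissue2_wall"], 1]).copy(),
        nm_inner_sig=sig(inner),
        nm_outer_sig=sig(outer),
        nm_inner_cent=cent(inner),
        nm_outer_cent=cent(outer),
    )


def nucleus_entered(snap: Snapshot) -> bool:
    """True when the whole nuclear envelope has passed the entrance plane x=0."""
    return bool(snap.nm_outer_xy[:, 0].min() >= 0.0)


def run_simulation(
    cfg: SimulationConfig,
    mesh: Mesh | None = None,
    save_fields: bool = False,
    progress: bool = False,
) -> RunResult:
    """Run the confined-migration simulation to pore entry or t_max."""
    if mesh is None:
        mesh = mesh_from_config(cfg)
    m = model_from_mesh(cfg, mesh)

    dt = m.dt
    snap_T = cfg.solver.snapshot_interval
    # mass-scaling / distortion updates must chase element collapse closely
    sub = max(1, int(round(snap_T / UPDATE_INTERVAL)))
    steps_sub = max(1, int(round(snap_T / sub / dt)))
    t_max = cfg.effective_t_max
    field_T = cfg.solver.field_snapshot_interval

    snaps: list[Snapshot] = [_take_snapshot(m, 0.0, 0)]
    frames = []
    status = "t_max"
    entry_time = None
    entry_deadline = None
    next_field = 0.0
    t_start = time.perf_counter()

    while m.t < t_max - 0.5 * dt:
        maxpen = 0.0
        n_flagged = 0
        bad = False
        for _ in range(sub):
            m.acc[3] = 0.0
            code = step(m, steps_sub)
            maxpen = max(maxpen, m.acc[3])
            if code == _kernels.INVERTED:
                status = "inverted"
                bad = True
                break
            if not np.isfinite(m.x).all() or not np.isfinite(m.v).all():
                status = "diverged"
                bad = True
                break
            n_flagged = distortion_update(m)
            m.refresh_cytoplasm_moduli()
            mass_scale(m)
        snaps.append(_take_snapshot(m, maxpen, n_flagged))
        if bad:
            break
        if save_fields and m.t >= next_field:
            vm_el = _von_mises_elements(m)
            frames.append((m.t, m.x.copy(), vm_el, m.epq.mean(axis=1)))
            next_field += field_T
        if progress:
            s = snaps[-1]
            nm = s.nm_outer_xy
            dl = np.ptp(nm[:, 1]) / max(np.ptp(nm[:, 0]), 1e-12)
            print(
                f"t={s.t:8.1f}s F={s.F:8.1f} lead_x={s.lead_x:7.3f} "
                f"nuc=[{nm[:, 0].min():6.2f},{nm[:, 0].max():6.2f}] D/L={dl:.3f} "
                f"ke/ie={s.qs_ratio:.3e} err={s.energy_err:.3e} "
                f"pen={s.max_penetration:.2e} flag={s.n_flagged} epq={s.max_epq:.3f}",
                flush=True,
            )
        if snaps[-1].lead_x > cfg.geometry.tissue_block_width + cfg.geometry.cell_diameter:
            status = "transited"
            break
        if entry_deadline is None and nucleus_entered(snaps[-1]):
            entry_time = m.t
            if cfg.solver.end_on_entry:
                entry_deadline = m.t + cfg.solver.entry_tail
                # the modeled assay ends at entry; keeping maximum thrust on
                # a cell that has cleared the pore only accelerates it as a
                # rigid body, injecting kinetic energy with no counterpart in
                # the experiment, so the load is released for the tail
                m.Fmax = 0.0
        if entry_deadline is not None and m.t >= entry_deadline:
            status = "entered"
            break
    else:
        status = "t_max" if entry_time is None else "entered"
    if entry_time is not None and status not in ("inverted", "diverged"):
        status = "entered"

    return RunResult(
        config=cfg,
        mesh=mesh,
        model=m,
        snapshots=snaps,
        status=status,
        entry_time=entry_time,
        wall_time=time.perf_counter() - t_start,
        n_steps=m.step_count,
        field_frames=frames,
    )


def _von_mises_elements(m: ExplicitModel) -> np.ndarray:
    s = m.stress.mean(axis=1)
    sxx, syy, szz, txy = s[:, 0], s[:, 1], s[:, 2], s[:, 3]
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2) + 3 * txy**2
    )
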