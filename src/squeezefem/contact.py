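"""Frictionless node-to-segment penalty contact, protrusive loading and
boundary conditions.

These are the reference (pure-Python/numpy) implementations of the contact
search, penalty force, load ramp and boundary-condition rules; the explicit
solver's compiled inner loop applies exactly the same formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from squeezefem.config import LoadingParams


@dataclass
class Contact:
    node: int
    segment: int
    gap: float  # negative = penetration
    normal: np.ndarray  # unit, points from master outward (toward the slave side)
    t: float  # projection parameter along the segment, clamped to [0, 1]


def segment_normal(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Outward normal of a master segment traversed CCW around its body."""
    t = p1 - p0
    n = np.array([t[1], -t[0]])
    ln = np.linalg.norm(n)
    if ln == 0:
        raise ValueError("degenerate master segment")
    return n / ln


def detect_contacts(
    slave_xy: np.ndarray,
    segments_xy: np.ndarray,
    tolerance: float,
    slave_ids: np.ndarray | None = None,
) -> list[Contact]:
    """All slave nodes within ``tolerance`` of their nearest master segment.

    ``segments_xy`` is (M, 2, 2): per segment, the two endpoint coordinates
    in CCW order around the master body.  Nodes projecting beyond segment
    endpoints clamp to the endpoint, so adjacent segments cover corners
    without gap discontinuities.  The search bins segment boxes on a grid
    (O(N log N) overall).
    """
    slave_xy = np.atleast_2d(slave_xy)
    ns, nm = len(slave_xy), len(segments_xy)
    if slave_ids is None:
        slave_ids = np.arange(ns)
    p0, p1 = segments_xy[:, 0], segments_xy[:, 1]
    seg_len = np.linalg.norm(p1 - p0, axis=1)
    cell = max(seg_len.max(), tolerance, 1e-12) * 2.0

    # bin segment midpoints
    mids = 0.5 * (p0 + p1)
    keys = np.floor(mids / cell).astype(np.int64)
    bins: dict[tuple[int, int], list[int]] = {}
    for m, (i, j) in enumerate(keys):
        bins.setdefault((int(i), int(j)), []).append(m)

    out: list[Contact] = []
    for s in range(ns):
        xs = slave_xy[s]
        ci, cj = int(np.floor(xs[0] / cell)), int(np.floor(xs[1] / cell))
        best = None
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for m in bins.get((ci + di, cj + dj), ()):
                    d = p1[m] - p0[m]
                    L2 = d @ d
                    t = np.clip((xs - p0[m]) @ d / L2, 0.0, 1.0)
                    proj = p0[m] + t * d
                    n = np.array([d[1], -d[0]]) / np.sqrt(L2)
                    g = (xs - proj) @ n
                    dist = np.linalg.norm(xs - proj)
                    if best is None or dist < best[0]:
                        best = (dist, m, g, n, t)
        if best is not None and best[2] < tolerance:
            out.append(Contact(int(slave_ids[s]), best[1], float(best[2]), best[3], float(best[4])))
    return out


def penalty_forces(
    contacts: list[Contact], penalty_stiffness: float, n_slave_nodes: int, segments: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normal penalty forces: F = k * |gap| along the master normal.

    Returns (slave_forces indexed by slave node id, master_forces (M, 2, 2)
    per segment endpoint).  Compression only; separated pairs carry zero
    force; tangential components are identically zero.
    """
    f_slave = np.zeros((n_slave_nodes, 2))
    f_master = np.zeros((len(segments), 2, 2))
    for c in contacts:
        if c.gap >= 0:
            continue
        fn = penalty_stiffness * (-c.gap)
        f = fn * c.normal
        f_slave[c.node] += f
        f_master[c.segment, 0] -= (1.0 - c.t) * f
        f_master[c.segment, 1] -= c.t * f
    return f_slave, f_master


def smooth_step(u: float | np.ndarray) -> float | np.ndarray:
    """Quintic smooth-step 10u^3 - 15u^4 + 6u^5, clamped to [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u * u)


def leading_edge_weights(thetas: np.ndarray, arc_degrees: float) -> np.ndarray:
    """Cosine weights over the loaded arc (reference angles, radians).

    Nodes with |theta| <= arc get w ~ cos(pi/2 * theta/arc); weights are
    normalized to unit resultant along +x and are symmetric about the axis.
    """
    arc = np.deg2rad(arc_degrees)
    th = np.angle(np.exp(1j * thetas))  # wrap to (-pi, pi]
    w = np.where(np.abs(th) <= arc + 1e-12, np.cos(0.5 * np.pi * th / arc), 0.0)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("no nodes inside the leading-edge arc")
    return w / tot


def protrusive_force(
    t: float, p: LoadingParams, lead_weights: np.ndarray
) -> np.ndarray:
    """Nodal +x forces with resultant F_max * S(t / ramp_duration)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    resultant = p.F_max * smooth_step(t / p.ramp_duration)
    f = np.zeros((len(lead_weights), 2))
    f[:, 0] = resultant * lead_weights
    return f


def apply_boundary_conditions(mesh) -> tuple[np.ndarray, np.ndarray]:
    """Roller supports on tissue outer boundaries.

    Lateral (vertical) outer faces are fixed in x; transverse (horizontal)
    outer faces fixed in y; everything else — including the cell — is free.
    Returns boolean (fixed_x, fixed_y) masks over all nodes.
    """
    fixed_x = np.zeros(mesh.n_nodes, dtype=bool)
    fixed_y = np.zeros(mesh.n_nodes, dtype=bool)
    fixed_x[mesh.node_sets["tissue_outer_lateral"]] = True
    fixed_y[mesh.node_sets["tissue_outer_transverse"]] = True
    return fixed_x, fixed_y
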