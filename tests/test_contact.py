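"""Node-to-segment contact detection, penalty forces, and load distribution."""

import numpy as np
import pytest

from squeezefem.contact import (
    detect_contacts,
    leading_edge_weights,
    penalty_forces,
    segment_normal,
    smooth_step,
)


def test_segment_normal_unit_and_outward():
    # CCW traversal keeps the body on the left, so the outward normal is on
    # the right of the travel direction: +x travel -> normal (0, -1)
    n = segment_normal(np.array([0.0, 0.0]), np.array([2.0, 0.0]))
    assert np.linalg.norm(n) == pytest.approx(1.0)
    assert n[0] == pytest.approx(0.0)
    assert n[1] == pytest.approx(-1.0)


def test_detect_contacts_penetrating_node():
    # master body above the segment (CCW traversal along +x)
    segs = np.array([[[0.0, 0.0], [2.0, 0.0]]])
    nodes = np.array([[1.0, 0.05], [1.0, -0.5]])  # first inside, second away
    contacts = detect_contacts(nodes, segs, 0.0)
    assert len(contacts) == 1
    c = contacts[0]
    assert c.node == 0
    assert c.gap == pytest.approx(-0.05, rel=1e-6)
    assert c.t == pytest.approx(0.5, abs=1e-6)


def test_penalty_forces_balance_and_direction():
    segs = np.array([[[0.0, 0.0], [2.0, 0.0]]])
    nodes = np.array([[0.5, 0.1]])  # penetrated 0.1 into the body above
    contacts = detect_contacts(nodes, segs, 0.0)
    k = 1000.0
    f_slave, f_master = penalty_forces(contacts, k, 1, segs)
    # slave pushed out along the outward normal (0, -1), magnitude k*|gap|
    assert f_slave[0, 1] == pytest.approx(-k * 0.1, rel=1e-6)
    # equal and opposite total reaction on the master endpoints
    total_master = f_master.sum(axis=(0, 1))
    assert np.allclose(f_slave[0] + total_master, 0.0, atol=1e-10)
    # reaction is split by the barycentric coordinate (t = 0.25)
    assert np.linalg.norm(f_master[0, 0]) == pytest.approx(0.75 * k * 0.1, rel=1e-6)


def test_separated_pairs_carry_no_force():
    segs = np.array([[[0.0, 0.0], [2.0, 0.0]]])
    nodes = np.array([[1.0, -0.3]])  # outside the body
    contacts = detect_contacts(nodes, segs, 0.0)
    f_slave, f_master = penalty_forces(contacts, 1000.0, 1, segs)
    assert np.allclose(f_slave, 0.0)
    assert np.allclose(f_master, 0.0)


def test_smooth_step_endpoints_and_midpoint():
    assert smooth_step(0.0) == 0.0
    assert smooth_step(1.0) == 1.0
    assert smooth_step(0.5) == pytest.approx(0.5)
    assert smooth_step(-1.0) == 0.0  # clamped
    assert smooth_step(2.0) == 1.0
    # zero slope at the ends (quintic)
    eps = 1e-6
    assert smooth_step(eps) / eps < 1e-3
    assert (1.0 - smooth_step(1.0 - eps)) / eps < 1e-3


def test_leading_edge_weights_normalized_and_symmetric():
    thetas = np.linspace(-np.pi, np.pi, 73)
    w = leading_edge_weights(thetas, 30.0)
    assert w.sum() == pytest.approx(1.0)
    assert np.allclose(w, w[::-1], atol=1e-12)  # symmetric about theta = 0
    outside = np.abs(thetas) > np.deg2rad(30.0) + 1e-9
    assert np.allclose(w[outside], 0.0)


def test_leading_edge_weights_empty_arc_raises():
    thetas = np.array([np.pi])  # trailing edge only
    with pytest.raises(ValueError):
        leading_edge_weights(thetas, 30.0)
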