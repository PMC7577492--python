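"""Shape, kink and stress-rotation observables on synthetic geometry."""

import numpy as np
import pytest

from squeezefem.observables import (
    ObservableError,
    circularity,
    detect_kinks,
    rotate_to_polar,
    turning_angles,
)


def _ring(n=64, a=1.0, b=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(th), b * np.sin(th)])


def test_circularity_circle_is_one():
    assert circularity(_ring()) == pytest.approx(1.0)


def test_circularity_ellipse():
    # axial semi-axis 2, transverse 1 -> D/L = 0.5
    assert circularity(_ring(a=2.0, b=1.0)) == pytest.approx(0.5)


def test_circularity_rejects_degenerate():
    with pytest.raises(ObservableError):
        circularity(np.array([[0.0, 0.0], [1.0, 1.0]]))
    with pytest.raises(ObservableError):
        circularity(np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 2.0]]))


def test_turning_angles_sum_to_full_turn():
    turn = turning_angles(_ring(n=32))
    assert turn.sum() == pytest.approx(2 * np.pi)


def test_detect_kinks_smooth_ring_none():
    assert len(detect_kinks(_ring(n=64), threshold_deg=60.0)) == 0


def test_detect_kinks_finds_notch():
    ring = _ring(n=64)
    ring[10] = 0.3 * ring[10]  # pull one vertex sharply inward
    kinks = detect_kinks(ring, threshold_deg=60.0)
    assert len(kinks) >= 1
    assert any(abs(int(k) - 10) <= 1 for k in kinks)


def test_rotate_to_polar_identity_at_zero_angle():
    s4 = np.array([10.0, -4.0, 2.0, 3.0])
    srr, stt, srt = rotate_to_polar(s4, 0.0)
    assert srr == pytest.approx(10.0)
    assert stt == pytest.approx(-4.0)
    assert srt == pytest.approx(3.0)


def test_rotate_to_polar_ninety_degrees_swaps():
    s4 = np.array([10.0, -4.0, 2.0, 0.0])
    srr, stt, srt = rotate_to_polar(s4, np.pi / 2)
    assert srr == pytest.approx(-4.0)
    assert stt == pytest.approx(10.0)
    assert srt == pytest.approx(0.0, abs=1e-12)


def test_rotate_to_polar_invariants():
    s4 = np.array([7.0, 1.0, 0.0, -2.5])
    for th in np.linspace(0, np.pi, 7):
        srr, stt, srt = rotate_to_polar(s4, th)
        assert srr + stt == pytest.approx(s4[0] + s4[1])  # trace invariant
        # in-plane von Mises invariant of the 2x2 block
        j2_orig = (s4[0] - s4[1]) ** 2 / 4 + s4[3] ** 2
        j2_rot = (srr - stt) ** 2 / 4 + srt ** 2
        assert j2_rot == pytest.approx(j2_orig)


def test_hydrostatic_state_is_isotropic():
    s4 = np.array([5.0, 5.0, 5.0, 0.0])
    for th in (0.3, 1.1, 2.7):
        srr, stt, srt = rotate_to_polar(s4, th)
        assert srr == pytest.approx(5.0)
        assert stt == pytest.approx(5.0)
        assert srt == pytest.approx(0.0, abs=1e-12)
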