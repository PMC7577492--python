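"""Power-law fitters, closed forms, sweep grid plumbing and phase logic."""

import numpy as np
import pandas as pd
import pytest

from squeezefem.scaling import (
    DomainError,
    FitError,
    LaminaPlateParams,
    NuclearTransportParams,
    ScalingInputs,
    SweepGrid,
    assert_phase_monotone_in_tissue,
    circularity_scaling,
    config_hash,
    fit_force_time_power_law,
    fit_nondimensional_force_law,
    flexural_rigidity,
    phase_diagram,
    theil_sen_power_law,
    water_influx_timescale,
)


# ---------------------------------------------------------------------------
# power-law fitters
# ---------------------------------------------------------------------------

def test_cubic_recovered_exactly():
    t = np.linspace(1.0, 10.0, 10)
    fit = fit_force_time_power_law(zip(t, 2.0 * t ** 3))
    assert fit.exponent == pytest.approx(3.0, rel=1e-10)
    assert fit.prefactor == pytest.approx(2.0, rel=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_linear_recovered_exactly():
    t = np.linspace(0.5, 4.0, 8)
    fit = fit_force_time_power_law(zip(t, 5.0 * t))
    assert fit.exponent == pytest.approx(1.0, rel=1e-10)
    assert fit.prefactor == pytest.approx(5.0, rel=1e-10)


def test_fit_requires_three_points():
    with pytest.raises(FitError):
        fit_force_time_power_law([(1.0, 1.0), (2.0, 8.0)])


def test_fit_rejects_degenerate_x():
    with pytest.raises(FitError):
        fit_force_time_power_law([(2.0, 1.0), (2.0, 3.0), (2.0, 9.0)])


def test_fit_rejects_nonpositive():
    with pytest.raises(FitError):
        fit_force_time_power_law([(1.0, 1.0), (2.0, -8.0), (3.0, 27.0)])


def test_ols_unbiased_on_lognormal_noise():
    rng = np.random.default_rng(42)
    x = np.logspace(0, 2, 60)
    y = 2.78 * x ** 3 * np.exp(rng.normal(0, 0.1, x.size))
    fit = fit_force_time_power_law(zip(x, y))
    # slope standard error for this design is tiny; 2 SE band
    lx = np.log(x)
    se = 0.1 / np.sqrt(((lx - lx.mean()) ** 2).sum())
    assert abs(fit.exponent - 3.0) < 2 * se
    assert fit.r_squared > 0.99


def test_theil_sen_matches_on_clean_data():
    x = np.linspace(1, 9, 9)
    fit = theil_sen_power_law(x, 4.0 * x ** 0.5)
    assert fit.exponent == pytest.approx(0.5, rel=1e-8)
    assert fit.prefactor == pytest.approx(4.0, rel=1e-8)


def test_nondimensional_self_consistency():
    # points exactly on Pi_out = Pi_in^0.43
    ins = []
    for x in (1.0, 2.0, 5.0, 10.0, 50.0):
        pi_in = 3.0 * x  # (E1+E2+En)/Ec=3, L/D=x, t/tau_c=1
        ins.append(ScalingInputs(F=pi_in ** 0.43 * 1.0 * 3.0, E1=1, E2=1, En=1,
                                 Ec=1.0, L=3.0 * x, D=3.0, t=1.0, tau_c=1.0))
    fit = fit_nondimensional_force_law(ins)
    assert fit.exponent == pytest.approx(0.43, rel=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_nondimensional_fixed_point():
    third = 1.0 / 3.0
    s = ScalingInputs(F=3.0, E1=third, E2=third, En=third, Ec=1.0,
                      L=3.0, D=3.0, t=1.0, tau_c=1.0)
    assert s.pi_in == pytest.approx(1.0)
    assert s.pi_out == pytest.approx(1.0)  # Pi_in = 1 -> Pi_out = 1 for any exponent


def test_scaling_inputs_reject_nonpositive():
    with pytest.raises(DomainError):
        ScalingInputs(F=-1.0, E1=1, E2=1, En=1, Ec=1, L=1, D=1, t=1, tau_c=1)


def test_circularity_scaling_groups():
    triples = [(2.0 * c ** 0.5, c, 1000.0) for c in (1.0, 2.0, 4.0)]
    triples += [(3.0, c, 5000.0) for c in (1.0, 2.0, 4.0)]
    tab = circularity_scaling(triples)
    row1 = tab[tab.En == 1000.0].iloc[0]
    row5 = tab[tab.En == 5000.0].iloc[0]
    assert row1.slope == pytest.approx(0.5, rel=1e-10)
    assert row5.slope == pytest.approx(0.0, abs=1e-12)  # identical D/L -> slope 0
    # distinct intercepts: the groups do not collapse onto one curve
    assert row1.prefactor != pytest.approx(row5.prefactor)


def test_circularity_scaling_reports_per_group_errors():
    # second group has only 2 points: error recorded, not fatal
    triples = [(1.0, c, 200.0) for c in (1.0, 2.0, 4.0)]
    triples += [(1.0, c, 5000.0) for c in (1.0, 2.0)]
    tab = circularity_scaling(triples)
    bad = tab[tab.En == 5000.0].iloc[0]
    assert bad.error != ""
    assert np.isnan(bad.slope)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def test_flexural_rigidity_values():
    assert flexural_rigidity(LaminaPlateParams(E=1.0, h=1.0, nu=0.0)) == 1.0
    assert flexural_rigidity(
        LaminaPlateParams(E=1000.0, h=0.05, nu=0.3)
    ) == pytest.approx(0.1374, abs=5e-5)


def test_flexural_rigidity_cubic_in_thickness():
    base = flexural_rigidity(LaminaPlateParams(E=100.0, h=0.1, nu=0.3))
    double_h = flexural_rigidity(LaminaPlateParams(E=100.0, h=0.2, nu=0.3))
    assert double_h == pytest.approx(8.0 * base)


def test_lamina_params_domain():
    with pytest.raises(DomainError):
        LaminaPlateParams(E=1000.0, h=0.05, nu=1.2)
    with pytest.raises(DomainError):
        LaminaPlateParams(E=-1.0, h=0.05, nu=0.3)


def test_water_influx_timescale():
    assert water_influx_timescale(NuclearTransportParams(r_n=2.5, D_c=50.0)) == pytest.approx(0.125)
    assert water_influx_timescale(NuclearTransportParams(r_n=1.0, D_c=1.0)) == 1.0
    assert water_influx_timescale(NuclearTransportParams(r_n=5.0, D_c=50.0)) == pytest.approx(0.5)
    with pytest.raises(DomainError):
        NuclearTransportParams(r_n=0.0, D_c=1.0)


# ---------------------------------------------------------------------------
# sweep grid and phase diagram
# ---------------------------------------------------------------------------

def test_one_cell_grid_one_config():
    g = SweepGrid(tissue_E=[2000.0], nucleus_E=[1000.0], confinement=[5.0 / 3.0],
                  mesh_preset="test")
    cfgs = g.configs()
    assert len(cfgs) == 1
    cfg = cfgs[0]
    assert cfg.materials.tissue1.E == 2000.0
    assert cfg.materials.tissue2.E == 2000.0
    assert cfg.materials.nucleus.E == 1000.0
    assert cfg.geometry.confinement_ratio == pytest.approx(5.0 / 3.0)


def test_grid_cardinality_and_hash_uniqueness():
    g = SweepGrid(tissue_E=[1000.0, 2000.0], nucleus_E=[200.0, 1000.0],
                  confinement=[1.0, 5.0 / 3.0], mesh_preset="test")
    cfgs = g.configs()
    assert len(cfgs) == 8
    hashes = {config_hash(c) for c in cfgs}
    assert len(hashes) == 8


def test_grid_rejects_empty_or_invalid():
    with pytest.raises(ValueError):
        SweepGrid(tissue_E=[], nucleus_E=[1000.0])
    with pytest.raises(ValueError):
        SweepGrid(tissue_E=[-5.0], nucleus_E=[1000.0])
    with pytest.raises(ValueError):
        SweepGrid(tissue_E=[1000.0], nucleus_E=[1000.0], confinement=[0.5])


def _phase_table(rows):
    return pd.DataFrame(rows, columns=["E1", "E2", "En", "confinement",
                                       "status", "max_eps_plastic_eq"])


def test_phase_diagram_threshold():
    tab = _phase_table([
        [2000.0, 2000.0, 200.0, 5 / 3, "entered", 0.0],
        [2000.0, 2000.0, 2000.0, 5 / 3, "entered", 0.4],
    ])
    ph = phase_diagram(tab)
    assert list(ph["plastic"]) == [False, True]


def test_phase_monotone_assertion():
    good = _phase_table([
        [500.0, 500.0, 1000.0, 5 / 3, "entered", 0.0],
        [1000.0, 1000.0, 1000.0, 5 / 3, "entered", 0.2],
        [5000.0, 5000.0, 1000.0, 5 / 3, "entered", 0.5],
    ])
    assert_phase_monotone_in_tissue(good)  # no raise
    bad = _phase_table([
        [500.0, 500.0, 1000.0, 5 / 3, "entered", 0.3],
        [1000.0, 1000.0, 1000.0, 5 / 3, "entered", 0.0],
        [5000.0, 5000.0, 1000.0, 5 / 3, "entered", 0.5],
    ])
    with pytest.raises(AssertionError):
        assert_phase_monotone_in_tissue(bad)
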