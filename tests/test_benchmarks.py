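"""Analytic verification benchmarks and canonical reference cases."""

import numpy as np
import pytest

from squeezefem.benchmarks import (
    make_creep_benchmark,
    make_patch_and_contact_benchmarks,
    make_reference_cases,
    make_uniaxial_plasticity_benchmark,
    plasticity_oracle_comparison,
    random_strain_paths,
)


def test_creep_benchmark_passes():
    res = make_creep_benchmark(K=1000.0, eta=125.0, sigma0=5.0).run()
    assert res.passed, f"creep error {res.error:.3e} > {res.tolerance:.0e}"


def test_uniaxial_plasticity_benchmark_passes():
    res = make_uniaxial_plasticity_benchmark().run()
    assert res.passed, f"uniaxial error {res.error:.3e} > {res.tolerance:.0e}"


def test_patch_and_contact_benchmarks_pass():
    for case in make_patch_and_contact_benchmarks():
        res = case.run()
        assert res.passed, f"{res.name} error {res.error:.3e} > {res.tolerance:.0e}"


def test_random_strain_paths_deterministic():
    p1 = random_strain_paths(n_paths=5, seed=7)
    p2 = random_strain_paths(n_paths=5, seed=7)
    assert len(p1) == 5
    for a, b in zip(p1, p2):
        assert np.array_equal(a, b)


def test_oracle_small_sample_agrees():
    # quick 10-path smoke check; the full 100-path run is an acceptance test
    res = plasticity_oracle_comparison(n_paths=10, seed=3)
    assert res["n_paths"] == 10
    assert res["n_plastic_paths"] > 0
    assert res["max_rel_stress_err"] <= 1e-4


def test_reference_cases_are_five_valid_configs():
    cases = make_reference_cases()
    assert len(cases) == 5
    labels = {c.label for c in cases}
    assert len(labels) == 5
    for c in cases:
        assert c.mesh.preset == "coarse"
    # four confined canonical combos plus one unconfined
    confined = [c for c in cases if c.geometry.pore_diameter == 3.0]
    assert len(confined) == 4
    combos = {(c.materials.nucleus.E, c.materials.tissue1.E) for c in confined}
    assert combos == {(200.0, 2000.0), (1000.0, 5000.0),
                      (2000.0, 2000.0), (5000.0, 1000.0)}
    (unconf,) = [c for c in cases if c.geometry.pore_diameter == 5.0]
    assert unconf.materials.nucleus.E == 1000.0
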