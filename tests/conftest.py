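"""Shared fixtures: the scaled-down acceptance run battery.

The qualitative acceptance checks need eight pore-entry simulations.  At the
coarse preset each takes ~9 minutes, which cannot fit the test-suite time
budget, so the battery runs on the small "test" preset with dt = 1e-3 s.
The checks are qualitative (trends, phase pattern, kink presence, stress
signs), which are preserved across mesh presets.
"""

import pytest

from squeezefem.config import SimulationConfig
from squeezefem.observables import summarize
from squeezefem.solver import run_simulation

BATTERY_DT = 1.0e-3


def _cfg(label, En, ET, pore=3.0):
    return SimulationConfig(
        mesh={"preset": "test"},
        geometry={"pore_diameter": pore},
        materials={
            "nucleus": {"E": En},
            "tissue1": {"E": ET},
            "tissue2": {"E": ET},
        },
        solver={"target_dt": BATTERY_DT},
        label=label,
    )


BATTERY = {
    # (i) trend in E_T at the two confinements (En = 1 kPa)
    "conf1_ET1k": _cfg("conf1_ET1k", 1000.0, 1000.0, pore=5.0),
    "conf1_ET5k": _cfg("conf1_ET5k", 1000.0, 5000.0, pore=5.0),
    "conf167_ET1k": _cfg("conf167_ET1k", 1000.0, 1000.0),
    "conf167_ET2k": _cfg("conf167_ET2k", 1000.0, 2000.0),
    "conf167_ET5k": _cfg("conf167_ET5k", 1000.0, 5000.0),
    # (ii)-(iv) phase-diagram corners
    "soft_nucleus": _cfg("soft_nucleus", 200.0, 2000.0),
    "stiff_both": _cfg("stiff_both", 2000.0, 2000.0),
    "stiffest_nucleus": _cfg("stiffest_nucleus", 5000.0, 1000.0),
}


@pytest.fixture(scope="session")
def battery():
    """Run the eight-case battery once per session; label -> (result, summary)."""
    out = {}
    for label, cfg in BATTERY.items():
        result = run_simulation(cfg)
        out[label] = (result, summarize(result))
    return out
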