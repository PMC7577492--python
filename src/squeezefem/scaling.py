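"""Parameter sweeps and the derived scaling relationships.

Orchestrates grids over (tissue stiffness, nuclear stiffness, confinement),
collects :class:`~squeezefem.observables.RunSummary` rows into tidy tables,
and implements the analytical relations built on top of the runs: the
nondimensional entry-force power law, the cubic entry force-time fit, the
circularity scaling per nuclear stiffness, the lamina flexural rigidity and
the water-influx timescale.

All fits are ordinary least squares on log-transformed data; R^2 values are
therefore computed on the log scale.  A robust Theil-Sen alternative is
provided for diagnostics on noisy sweeps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from squeezefem.config import SimulationConfig
from squeezefem.observables import RunSummary, summarize

log = logging.getLogger("squeezefem")


class FitError(ValueError):
    """Raised when a regression has too few or degenerate data."""


class DomainError(ValueError):
    """Raised when closed-form inputs are outside their physical domain."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepGrid:
    """Cartesian sweep over tissue stiffness, nuclear stiffness and confinement.

    ``tissue_E`` values are applied to both blocks (E_1 = E_2 = E_T) unless
    ``tissue_pairs`` is given, in which case each (E_1, E_2) pair is a grid
    axis entry of its own.  ``confinement`` entries are D0/phi ratios; the
    pore diameter is derived from the (fixed) nucleus diameter.
    """

    tissue_E: Sequence[float] = (130.0, 500.0, 1000.0, 2000.0, 5000.0)
    nucleus_E: Sequence[float] = (200.0, 1000.0, 2000.0, 5000.0)
    confinement: Sequence[float] = (5.0 / 3.0,)
    tissue_pairs: Optional[Sequence[tuple[float, float]]] = None
    mesh_preset: str = "coarse"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = self.pairs
        if not pairs or not list(self.nucleus_E) or not list(self.confinement):
            raise ValueError("sweep grid must be non-empty on every axis")
        for e1, e2 in pairs:
            if e1 <= 0 or e2 <= 0:
                raise ValueError("tissue moduli must be positive")
        if any(e <= 0 for e in self.nucleus_E):
            raise ValueError("nuclear moduli must be positive")
        if any(c < 1.0 for c in self.confinement):
            raise ValueError("confinement D0/phi must be >= 1")

    @property
    def pairs(self) -> list[tuple[float, float]]:
        if self.tissue_pairs is not None:
            return list(self.tissue_pairs)
        return [(e, e) for e in self.tissue_E]

    def configs(self) -> list[SimulationConfig]:
        """One validated configuration per grid cell."""
        return [
            self.make_config(e1, e2, en, conf)
            for e1, e2 in self.pairs
            for en in self.nucleus_E
            for conf in self.confinement
        ]

    def make_config(self, e1: float, e2: float, en: float, conf: float) -> SimulationConfig:
        base = SimulationConfig(**self.overrides) if self.overrides else SimulationConfig()
        d0 = base.geometry.nucleus_diameter
        payload = base.model_dump()
        payload["mesh"] = {**payload["mesh"], "preset": self.mesh_preset}
        payload["geometry"] = {**payload["geometry"], "pore_diameter": d0 / conf}
        payload["materials"] = {
            **payload["materials"],
            "tissue1": {**payload["materials"]["tissue1"], "E": e1},
            "tissue2": {**payload["materials"]["tissue2"], "E": e2},
            "nucleus": {**payload["materials"]["nucleus"], "E": en},
        }
        payload["label"] = f"E1={e1:g}_E2={e2:g}_En={en:g}_conf={conf:.3g}"
        return SimulationConfig(**payload)


@dataclass(frozen=True)
class ScalingInputs:
    """Per-run symbols of the nondimensional entry-force law.

    F in pN/um (per unit depth), moduli in Pa, lengths in um, times in s.
    ``tau_c`` is the cytoplasm Kelvin-Voigt time constant eta_c / E_c; ``t``
    is the entry time and (L, D) the nucleus extents at entry.
    """

    F: float
    E1: float
    E2: float
    En: float
    Ec: float
    L: float
    D: float
    t: float
    tau_c: float

    def __post_init__(self) -> None:
        vals = (self.F, self.E1, self.E2, self.En, self.Ec,
                self.L, self.D, self.t, self.tau_c)
        if any(v <= 0 for v in vals):
            raise DomainError("all scaling inputs must be positive")

    @property
    def pi_out(self) -> float:
        """Dimensionless force F / (E_c D)."""
        return self.F / (self.Ec * self.D)

    @property
    def pi_in(self) -> float:
        """Dimensionless drive (E1+E2+En)/Ec * L/D * t/tau_c."""
        return ((self.E1 + self.E2 + self.En) / self.Ec
                * (self.L / self.D) * (self.t / self.tau_c))


@dataclass(frozen=True)
class LaminaPlateParams:
    """Nuclear lamina treated as a thin elastic plate (modulus E, thickness h)."""

    E: float
    h: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0 or self.h <= 0:
            raise DomainError("E and h must be positive")
        if self.nu < 0 or self.nu >= 1.0:
            raise DomainError("Poisson ratio must satisfy 0 <= nu < 1")


@dataclass(frozen=True)
class NuclearTransportParams:
    """Water transport across the nuclear envelope: radius and diffusivity."""

    r_n: float
    D_c: float

    def __post_init__(self) -> None:
        if self.r_n <= 0 or self.D_c <= 0:
            raise DomainError("r_n and D_c must be positive")

    @property
    def tau(self) -> float:
        return self.r_n ** 2 / self.D_c


@dataclass(frozen=True)
class PowerLawFit:
    """y = prefactor * x**exponent fitted on log-log axes."""

    prefactor: float
    exponent: float
    r_squared: float
    n: int
    residuals: Optional[np.ndarray] = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# sweep orchestration
# ---------------------------------------------------------------------------

def config_hash(cfg: SimulationConfig) -> str:
    """Stable short hash of the full validated configuration."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _summary_row(cfg: SimulationConfig, summary: RunSummary | None,
                 error: str | None = None) -> dict:
    row = {
        "config_hash": config_hash(cfg),
        "E1": cfg.materials.tissue1.E,
        "E2": cfg.materials.tissue2.E,
        "En": cfg.materials.nucleus.E,
        "Ec": cfg.materials.cytoplasm.E,
        "tau_c": cfg.materials.cytoplasm.tau,
        "confinement": cfg.geometry.confinement_ratio,
        "D0": cfg.geometry.nucleus_diameter,
        "error": error or "",
    }
    if summary is not None:
        row.update(summary.as_dict())
        row.pop("materials", None)
    else:
        row["status"] = "error"
    return row


def run_sweep(grid: SweepGrid, out_csv: str | Path | None = None,
              progress: bool = False) -> pd.DataFrame:
    """Run every grid cell and collect the summaries into a tidy table.

    Failed or non-quasi-static runs are recorded with their status/error in
    their row; they are never silently dropped.  When ``out_csv`` is given
    the table is also written to disk.
    """
    from squeezefem.solver import run_simulation  # deferred: heavy import

    rows = []
    configs = grid.configs()
    for i, cfg in enumerate(configs):
        if progress:
            log.info("sweep %d/%d: %s", i + 1, len(configs), cfg.label)
        try:
            result = run_simulation(cfg)
            rows.append(_summary_row(cfg, summarize(result)))
        except Exception as exc:  # record, never drop
            log.exception("sweep cell %s failed", cfg.label)
            rows.append(_summary_row(cfg, None, error=f"{type(exc).__name__}: {exc}"))
    table = pd.DataFrame(rows)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_csv, index=False)
    return table


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def _loglog_ols(x: np.ndarray, y: np.ndarray) -> PowerLawFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise FitError("need at least 3 points for a power-law fit")
    if np.any(x <= 0) or np.any(y <= 0):
        raise FitError("power-law fit requires strictly positive data")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0:
        raise FitError("degenerate fit: all x values identical")
    if np.ptp(ly) == 0:
        # exactly constant y: slope 0, perfect fit
        return PowerLawFit(float(np.exp(ly[0])), 0.0, 1.0, x.size, np.zeros(x.size))
    A = np.vstack([lx, np.ones_like(lx)]).T
    coef, _, _, _ = np.linalg.lstsq(A, ly, rcond=None)
    slope, intercept = coef
    resid = ly - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(float(np.exp(intercept)), float(slope), float(r2),
                       x.size, resid)


def theil_sen_power_law(x: Iterable[float], y: Iterable[float]) -> PowerLawFit:
    """Robust (median-slope) alternative to the OLS log-log fit."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 3:
        raise FitError("need at least 3 points for a power-law fit")
    if np.any(x <= 0) or np.any(y <= 0):
        raise FitError("power-law fit requires strictly positive data")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0:
        raise FitError("degenerate fit: all x values identical")
    res = stats.theilslopes(ly, lx)
    resid = ly - (res.slope * lx + res.intercept)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(float(np.exp(res.intercept)), float(res.slope), float(r2),
                       x.size, resid)


def fit_force_time_power_law(pairs: Iterable[tuple[float, float]]) -> PowerLawFit:
    """Fit F_entry = prefactor * T_entry**exponent over (T_entry, F_entry) pairs.

    The prefactor is reported with F in pN/um and T in s.
    """
    pairs = list(pairs)
    t = np.array([p[0] for p in pairs], dtype=float)
    f = np.array([p[1] for p in pairs], dtype=float)
    return _loglog_ols(t, f)


def fit_nondimensional_force_law(inputs: Iterable[ScalingInputs]) -> PowerLawFit:
    """Fit Pi_out = Pi_in**exponent on log-log axes over a sweep.

    Pi_out = F/(E_c D) and Pi_in = (E1+E2+En)/Ec * L/D * t/tau_c; the
    returned prefactor should be ~1 when the law holds in its pure form.
    """
    inputs = list(inputs)
    x = np.array([s.pi_in for s in inputs])
    y = np.array([s.pi_out for s in inputs])
    return _loglog_ols(x, y)


def scaling_inputs_from_table(table: pd.DataFrame) -> list[ScalingInputs]:
    """Build the nondimensional-law inputs from a sweep table (entered runs).

    D is the pore diameter (the nucleus is squeezed to the pore width at
    entry) and L follows from the minimum aspect ratio D/L, whose minimum
    occurs at entry for confined cases.
    """
    out = []
    for _, row in table.iterrows():
        t_entry = row.get("T_entry")
        if row.get("status") != "entered" or t_entry is None or not np.isfinite(t_entry):
            continue
        D = row["D0"] / row["confinement"]
        dl = row["min_circularity"]
        L = D / dl if dl and dl > 0 else D
        out.append(ScalingInputs(
            F=row["F_entry"], E1=row["E1"], E2=row["E2"], En=row["En"],
            Ec=row["Ec"], L=L, D=D, t=float(t_entry), tau_c=row["tau_c"],
        ))
    return out


def circularity_scaling(triples: Iterable[tuple[float, float, float]]) -> pd.DataFrame:
    """Per-E_n power-law slopes of D/L against the coupling E1*E2/En^2.

    ``triples`` are (circularity D/L, E1*E2/En^2, E_n).  Returns one row per
    E_n group with slope, prefactor, R^2 and count; groups whose fit fails
    carry the error message instead of being dropped.
    """
    groups: dict[float, list[tuple[float, float]]] = {}
    for dl, coupling, en in triples:
        groups.setdefault(float(en), []).append((coupling, dl))
    rows = []
    for en in sorted(groups):
        data = groups[en]
        x = np.array([d[0] for d in data])
        y = np.array([d[1] for d in data])
        try:
            fit = _loglog_ols(x, y)
            rows.append({"En": en, "slope": fit.exponent, "prefactor": fit.prefactor,
                         "r_squared": fit.r_squared, "n": fit.n, "error": ""})
        except FitError as exc:
            rows.append({"En": en, "slope": np.nan, "prefactor": np.nan,
                         "r_squared": np.nan, "n": len(data), "error": str(exc)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def flexural_rigidity(p: LaminaPlateParams) -> float:
    """Plate flexural rigidity F_D = E h^3 / (1 - nu^2), in Pa*um^3.

    Thickness enters cubically and so dominates over the linear modulus
    dependence: doubling h multiplies F_D by 8, doubling E only by 2.
    """
    return p.E * p.h ** 3 / (1.0 - p.nu ** 2)


def water_influx_timescale(p: NuclearTransportParams) -> float:
    """Diffusive water exchange time tau = r_n^2 / D_c, in seconds."""
    return p.tau


# ---------------------------------------------------------------------------
# phase diagram
# ---------------------------------------------------------------------------

def phase_diagram(table: pd.DataFrame, threshold: float = 1e-4) -> pd.DataFrame:
    """Classify each sweep cell as plastic/non-plastic from residual strain.

    A run is plastic when its max equivalent plastic strain exceeds
    ``threshold``.  Returns a copy of the table with the boolean ``plastic``
    column re-derived so the criterion is explicit here.
    """
    out = table.copy()
    out["plastic"] = out["max_eps_plastic_eq"].fillna(0.0) > threshold
    return out


def assert_phase_monotone_in_tissue(table: pd.DataFrame) -> None:
    """Check: at fixed E_n >= 1 kPa, once plastic at some E_T, plastic for larger E_T.

    Applies to equal-block sweeps (E1 == E2).  Raises AssertionError with
    the offending group when violated.
    """
    tab = phase_diagram(table)
    tab = tab[(tab["E1"] == tab["E2"]) & (tab["status"] == "entered")
              & (tab["En"] >= 1000.0)]
    for (en, conf), grp in tab.groupby(["En", "confinement"]):
        grp = grp.sort_values("E1")
        flags = grp["plastic"].to_numpy().astype(int)
        if np.any(np.diff(flags) < 0):
            raise AssertionError(
                f"phase diagram not monotone in tissue stiffness at En={en}, "
                f"conf={conf}: {list(zip(grp['E1'], flags))}"
            )
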