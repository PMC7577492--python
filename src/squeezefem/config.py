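"""Configuration schema, validation and YAML I/O.

All quantities use a consistent unit system: lengths in micrometres (um),
time in seconds, stress/moduli in pascals.  In plane strain the model is
one unit (1 um) deep, so forces are per unit depth with
1 Pa*um = 1 pN/um; the default protrusive force of 6400 pN/um therefore
corresponds to a total of ~6.4 nN over the nominal depth.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

log = logging.getLogger("squeezefem")

#: confinement ratios studied: nucleus diameter / pore diameter
CONFINEMENT_RATIOS = (1.0, 1.2, 5.0 / 3.0)


class ConfigError(ValueError):
    """Raised when a configuration file is missing keys or physically invalid."""


class GeometryParams(BaseModel):
    """Planar geometry of the cell, nucleus and the two tissue blocks.

    The two tissue blocks are rectangles separated by a straight channel of
    height ``pore_diameter`` running the full block width along +x; the pore
    entrance plane is x = 0.  The cell is a disk (with a thin annular
    membrane) concentric with a nuclear disk (with its own annular
    membrane), placed on the channel axis ``initial_standoff`` short of the
    entrance.
    """

    cell_diameter: float = 10.0
    nucleus_diameter: float = 5.0
    pore_diameter: float = 3.0
    membrane_thickness: float = 0.05
    tissue_block_width: float = 30.0
    tissue_block_height: float = 15.0
    pore_channel_length: float = 10.0
    initial_standoff: float = 0.5

    @field_validator(
        "cell_diameter",
        "nucleus_diameter",
        "pore_diameter",
        "membrane_thickness",
        "tissue_block_width",
        "tissue_block_height",
        "pore_channel_length",
    )
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("geometry lengths must be positive")
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "GeometryParams":
        if self.initial_standoff < 0:
            raise ValueError("initial_standoff must be >= 0 (regions would interpenetrate)")
        if self.membrane_thickness >= self.nucleus_diameter / 10.0:
            raise ValueError("membrane_thickness must be < nucleus_diameter/10")
        if self.pore_diameter >= self.cell_diameter:
            raise ValueError("pore must be narrower than the cell")
        if self.nucleus_diameter >= self.cell_diameter:
            raise ValueError("nucleus must fit inside the cell")
        if self.pore_channel_length > self.tissue_block_width:
            raise ValueError("pore_channel_length cannot exceed tissue_block_width")
        return self

    @property
    def confinement_ratio(self) -> float:
        """Degree of confinement D0/phi (>1 means the nucleus must deform)."""
        return self.nucleus_diameter / self.pore_diameter


#: mesh presets: (n_theta, core divisions per quadrant, core radial layers,
#:  membrane layers, cytoplasm radial layers, tissue nx, tissue ny, min quality)
_MESH_PRESETS = {
    "test": dict(n_circumferential=48, core_divisions=12, core_radial_layers=4,
                 membrane_layers=2, cytoplasm_layers=6, tissue_nx=22, tissue_ny=10,
                 min_quality=0.03),
    "coarse": dict(n_circumferential=80, core_divisions=20, core_radial_layers=6,
                   membrane_layers=2, cytoplasm_layers=12, tissue_nx=44, tissue_ny=20,
                   min_quality=0.05),
    "medium": dict(n_circumferential=128, core_divisions=32, core_radial_layers=8,
                   membrane_layers=2, cytoplasm_layers=12, tissue_nx=48, tissue_ny=22,
                   min_quality=0.05),
    "reference": dict(n_circumferential=256, core_divisions=64, core_radial_layers=16,
                      membrane_layers=10, cytoplasm_layers=18, tissue_nx=96, tissue_ny=68,
                      min_quality=0.04),
}


class MeshSpec(BaseModel):
    """Mesh resolution controls.

    ``preset`` selects a coherent set of structured-mesh divisions; any
    explicitly supplied field overrides the preset value.  The *reference*
    preset reproduces the published element counts (~31k bilinear quads);
    the *coarse* preset (~4k) is what routine runs and the acceptance
    analyses use; *test* (~1.2k) is for fast checks.
    """

    preset: Literal["test", "coarse", "medium", "reference"] = "reference"
    target_min_element: float = 0.005
    target_max_element: float = 20.0
    membrane_through_thickness_elements: Optional[int] = None
    n_circumferential: Optional[int] = None
    core_divisions: Optional[int] = None
    core_radial_layers: Optional[int] = None
    cytoplasm_layers: Optional[int] = None
    tissue_nx: Optional[int] = None
    tissue_ny: Optional[int] = None
    min_quality: Optional[float] = None

    @model_validator(mode="after")
    def _bounds(self) -> "MeshSpec":
        if self.target_min_element <= 0 or self.target_max_element < self.target_min_element:
            raise ValueError("require 0 < target_min_element <= target_max_element")
        if (
            self.membrane_through_thickness_elements is not None
            and self.membrane_through_thickness_elements < 1
        ):
            raise ValueError("membrane_through_thickness_elements must be >= 1")
        return self

    def resolve(self) -> dict:
        """Return the effective resolution parameters (preset + overrides)."""
        eff = dict(_MESH_PRESETS[self.preset])
        if self.membrane_through_thickness_elements is not None:
            eff["membrane_layers"] = self.membrane_through_thickness_elements
        for key in ("n_circumferential", "core_divisions", "core_radial_layers",
                    "cytoplasm_layers", "tissue_nx", "tissue_ny", "min_quality"):
            v = getattr(self, key)
            if v is not None:
                eff[key] = v
        if eff["n_circumferential"] % 8 != 0:
            raise ValueError("n_circumferential must be a multiple of 8")
        return eff


class ViscoelasticMaterial(BaseModel):
    """Kelvin-Voigt solid: sigma_ij = K eps_ij + eta deps_ij/dt.

    The elastic part is plane-strain Hooke with modulus ``E`` and Poisson
    ratio ``nu``; the dashpot acts component-wise on the in-plane strain
    rate with viscosity ``eta = tau * E`` (``tau`` is the relaxation time).
    """

    E: float
    tau: float = 1.0
    nu: float = 0.3

    @model_validator(mode="after")
    def _valid(self) -> "ViscoelasticMaterial":
        if self.E <= 0:
            raise ValueError("modulus must be positive")
        if self.tau < 0:
            raise ValueError("relaxation time must be >= 0")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must satisfy 0 <= nu < 0.5")
        return self

    @property
    def eta(self) -> float:
        return self.tau * self.E


class PlasticMaterial(BaseModel):
    """Elastoplastic nucleus: J2 yield with Ludwik power-law hardening.

    Flow stress: sigma_y(ep) = a + b * ep**n with equivalent plastic strain
    ep.  Defaults (a, b, n) = (41 Pa, 17 Pa, 2.89) are the published fit to
    nuclear stress-strain data; they are held fixed when the elastic
    modulus is swept, and can be overridden per run.
    """

    E: float = 1000.0
    nu: float = 0.3
    yield_stress: float = 41.0
    hardening_coefficient: float = 17.0
    hardening_exponent: float = 2.89

    @model_validator(mode="after")
    def _valid(self) -> "PlasticMaterial":
        if self.E <= 0:
            raise ValueError("modulus must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must satisfy 0 <= nu < 0.5")
        if self.yield_stress <= 0:
            raise ValueError("yield stress must be positive")
        if self.hardening_coefficient < 0 or self.hardening_exponent <= 0:
            raise ValueError("hardening law sigma = a + b*ep**n requires b >= 0, n > 0")
        return self

    def flow_stress(self, ep_eq: float) -> float:
        return self.yield_stress + self.hardening_coefficient * ep_eq ** self.hardening_exponent


class StiffeningLaw(BaseModel):
    """Shear-triggered cytoplasmic stiffening (a ratchet).

    Above a shear-stress threshold the cytoplasmic modulus follows
    log10(E - 1) = slope * log10(sigma_shear[kPa]) + intercept, clamped to
    [E_min, E_max]; E never decreases along a run.  The kPa/Pa unit split
    is the only one consistent with the published range 1.0001-1.1 Pa at
    the 20 kPa trigger.
    """

    enabled: bool = True
    threshold_kpa: float = 20.0
    slope: float = 49.41
    intercept: float = -68.31
    E_min: float = 1.0001
    E_max: float = 1.1

    def evaluate(self, sigma_shear_kpa: float) -> float:
        """Target modulus (Pa) for a given shear stress (kPa)."""
        if sigma_shear_kpa <= self.threshold_kpa:
            return 0.0  # below trigger: no demand
        e = 1.0 + 10.0 ** (self.slope * math.log10(sigma_shear_kpa) + self.intercept)
        return min(max(e, self.E_min), self.E_max)


class Materials(BaseModel):
    """Part materials.

    Defaults: cytoplasm 1 Pa with an effective viscosity of 1e3 Pa*s
    (tau = 1000 s), the standard order of magnitude for whole-cytoplasm
    rheology; membranes 1 MPa so that at 0.05 um thickness the stretching
    stiffness E*h = 0.05 N/m matches cortical-shell measurements and can
    sustain the full protrusive load at moderate strain.
    """

    cytoplasm: ViscoelasticMaterial = ViscoelasticMaterial(E=1.0, tau=1000.0)
    cell_membrane: ViscoelasticMaterial = ViscoelasticMaterial(E=1.0e6)
    nuclear_membrane: ViscoelasticMaterial = ViscoelasticMaterial(E=1.0e6)
    tissue1: ViscoelasticMaterial = ViscoelasticMaterial(E=2000.0)
    tissue2: ViscoelasticMaterial = ViscoelasticMaterial(E=2000.0)
    nucleus: PlasticMaterial = PlasticMaterial()
    stiffening: StiffeningLaw = StiffeningLaw()


class LoadingParams(BaseModel):
    """Protrusive force ramp applied at the leading edge.

    The resultant follows F(t) = F_max * S(t / ramp_duration) with S the
    quintic smooth-step (zero slope at both ends), distributed over the
    leading-edge arc with cosine weights, directed along +x.
    """

    F_max: float = 6400.0  # pN/um per unit depth (~6.4 nN at 1 um depth)
    ramp_duration: float = 600.0
    leading_edge_arc_degrees: float = 30.0

    @model_validator(mode="after")
    def _valid(self) -> "LoadingParams":
        if self.F_max <= 0 or self.ramp_duration <= 0:
            raise ValueError("F_max and ramp_duration must be positive")
        if not (0 < self.leading_edge_arc_degrees <= 90):
            raise ValueError("leading-edge arc must be in (0, 90] degrees")
        return self


class SolverParams(BaseModel):
    """Explicit central-difference solver controls.

    ``target_dt`` is reached by per-element mass scaling; when left unset
    it is chosen from the mesh preset (finer meshes use smaller steps,
    down to the reference O(1e-4) s).  The quasi-static and energy-balance
    monitors run on every snapshot.
    """

    target_dt: Optional[float] = None
    courant_safety: float = 0.9
    ke_ie_ratio_max: float = 0.05
    ie_monitor_floor: float = 10.0  # pN*um: KE/IE checked once IE exceeds this
    distortion_ratio_min: float = 0.1
    distortion_stiffness: float = 2.0e4  # Pa, stiffness augmentation scale
    distortion_area_floor: float = 0.1  # fraction of initial element area
    snapshot_interval: float = 1.0
    field_snapshot_interval: float = 30.0
    t_max: Optional[float] = None
    end_on_entry: bool = True
    entry_tail: float = 10.0  # seconds simulated past detected entry
    bulk_viscosity_linear: float = 0.06
    bulk_viscosity_quadratic: float = 1.2
    penalty_factor: float = 100.0
    contact_search_every: int = 10
    # viscous strain-rate low-pass window.  A longer window lowers the
    # stability mass added for the dashpots (less spurious kinetic energy);
    # it must stay far below the smallest material relaxation time (0.1 s
    # vs tau >= 1 s here) to leave the constitutive response untouched.
    # ``rate_filter_time`` is in seconds so the window is independent of the
    # mesh preset's time step; ``rate_filter_steps`` (units of dt), when
    # set, overrides it for benchmark problems that need step-level control.
    rate_filter_time: float = 0.1
    rate_filter_steps: Optional[float] = None

    @model_validator(mode="after")
    def _valid(self) -> "SolverParams":
        if self.target_dt is not None and self.target_dt <= 0:
            raise ValueError("target_dt must be positive")
        if not (0 < self.courant_safety <= 1):
            raise ValueError("courant_safety must be in (0, 1]")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot_interval must be positive")
        return self


_DT_BY_PRESET = {"test": 2.0e-3, "coarse": 5.0e-4, "medium": 2.5e-4, "reference": 1.0e-4}


class SimulationConfig(BaseModel):
    geometry: GeometryParams = GeometryParams()
    mesh: MeshSpec = MeshSpec(preset="coarse")
    materials: Materials = Materials()
    loading: LoadingParams = LoadingParams()
    solver: SolverParams = SolverParams()
    label: str = "run"

    @property
    def effective_dt(self) -> float:
        if self.solver.target_dt is not None:
            return self.solver.target_dt
        return _DT_BY_PRESET[self.mesh.preset]

    @property
    def effective_t_max(self) -> float:
        if self.solver.t_max is not None:
            return self.solver.t_max
        return 2.0 * self.loading.ramp_duration

    def dump_effective(self, path: str | Path) -> None:
        """Write the fully-resolved configuration to a YAML sidecar."""
        data = self.model_dump()
        data["_effective"] = {
            "dt": self.effective_dt,
            "t_max": self.effective_t_max,
            "mesh": self.mesh.resolve(),
            "confinement_ratio": self.geometry.confinement_ratio,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def material_summary(self) -> dict:
        m = self.materials
        return {
            "E_c": m.cytoplasm.E,
            "E_cell_membrane": m.cell_membrane.E,
            "E_nuclear_membrane": m.nuclear_membrane.E,
            "E_1": m.tissue1.E,
            "E_2": m.tissue2.E,
            "E_n": m.nucleus.E,
            "tau_c": m.cytoplasm.tau,
            "yield_stress": m.nucleus.yield_stress,
            "D0": self.geometry.nucleus_diameter,
            "phi": self.geometry.pore_diameter,
            "D0_over_phi": self.geometry.confinement_ratio,
        }


def _with_tissue_shorthand(raw: dict) -> dict:
    """Allow `materials: {E_T: ...}` as shorthand for equal tissue moduli."""
    mats = raw.get("materials")
    if isinstance(mats, dict) and "E_T" in mats:
        e_t = mats.pop("E_T")
        mats.setdefault("tissue1", {})
        mats.setdefault("tissue2", {})
        if isinstance(mats["tissue1"], dict):
            mats["tissue1"].setdefault("E", e_t)
        if isinstance(mats["tissue2"], dict):
            mats["tissue2"].setdefault("E", e_t)
    return raw


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration file.

    An empty file yields the all-defaults configuration.  Validation
    failures raise :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - malformed YAML
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    raw = _with_tissue_shorthand(raw)
    try:
        cfg = SimulationConfig(**raw)
    except Exception as exc:
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc
    log.info("effective config: %s", cfg.model_dump())
    return cfg
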