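"""Central configuration: geometric windows, energy weights, typing tables.

Every tunable of the generator lives in one of the dataclasses below so a
whole run is reproducible from a single validated record.  Defaults follow
common crystallographic conventions (H-bond heavy-atom distances around
3.0 Å, ring stacking near 3.8 Å); all of them can be overridden from a
plain-text YAML file via :func:`load_generation_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# vdW radii (Å), Bondi-style values for the whitelisted elements.
VDW_RADII: dict[str, float] = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "P": 1.80,
}

DEFAULT_VDW = 1.70


@dataclass(frozen=True)
class GeometricWindows:
    """Distance / angle windows shared by placement, scoring and IFPs.

    Each distance window is (lower edge, ideal, upper edge) in Å; the switch
    function is 1 at the ideal value and falls linearly to 0 at the edges.
    Angles are in degrees.
    """

    hb_dist: tuple[float, float, float] = (2.6, 3.0, 3.4)
    #: max deviation of the donor H direction from the donor->acceptor axis
    #: (60 deg deviation corresponds to a donor-H...acceptor angle of 120 deg)
    hb_angle_max: float = 60.0
    aromatic_dist: tuple[float, float, float] = (3.5, 3.8, 5.0)
    aromatic_stack_max: float = 30.0
    aromatic_t_range: tuple[float, float] = (60.0, 90.0)
    hydrophobic_dist: tuple[float, float, float] = (3.5, 4.0, 5.5)
    ionic_dist: float = 4.5


@dataclass(frozen=True)
class EnergyParams:
    """Weights and shapes of the empirical interaction score (kcal/mol scale)."""

    w_hb: float = 1.0
    w_aromatic: float = 0.7
    w_hydrophobic: float = 0.3
    #: well depth of the soft 8-4 steric term per heavy-atom pair
    steric_eps: float = 0.05
    steric_cutoff: float = 6.0
    #: pair distance below clash_factor * (r_vdw_i + r_vdw_j) counts as a clash
    clash_factor: float = 0.7
    #: flat penalty per clashing pair, plus a linear ramp into the clash
    clash_penalty: float = 25.0
    clash_ramp: float = 50.0
    #: energies above this value mark the pose as clashed/rejected
    clash_energy_threshold: float = 10.0


# Residue-level typing tables used by hotspot detection.  The acceptor table
# is this package's own convention (carbonyl/hydroxyl/ether/carboxylate O and
# pyridine-type N accept; amide N, pyrrole-type N and quaternary N do not).
AROMATIC_RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

#: protein atoms carrying a formal charge at physiological pH (for the ionic
#: fingerprint bit); sign is the conventional one.
CHARGED_PROTEIN_ATOMS: dict[tuple[str, str], int] = {
    ("LYS", "NZ"): +1,
    ("ARG", "NH1"): +1,
    ("ARG", "NH2"): +1,
    ("ARG", "NE"): +1,
    ("ASP", "OD1"): -1,
    ("ASP", "OD2"): -1,
    ("GLU", "OE1"): -1,
    ("GLU", "OE2"): -1,
    ("HIS", "ND1"): 0,
}


@dataclass(frozen=True)
class HotspotParams:
    """Rules for typing pocket interaction anchors."""

    include_hydrophobic: bool = True
    #: an apolar-carbon cluster needs at least this many members
    hydrophobic_min_carbons: int = 3
    hydrophobic_cluster_dist: float = 5.0
    #: max O/S-H or N-H bond length used to find polar hydrogens
    xh_bond_max: float = 1.3


@dataclass(frozen=True)
class GrowthRules:
    """Toggles and guards for the four linking rules."""

    direct: bool = True
    linker: bool = True
    fuse: bool = True
    spiro: bool = True
    #: SMARTS whose first mapped atom may not be substituted (amide N default)
    forbidden_substitution_smarts: tuple[str, ...] = ("[NX3;$(N[CX3]=[OX1])]",)
    ring_size_min: int = 3
    ring_size_max: int = 8
    #: fused-atom identification requires identical elements by default
    fuse_identical_elements_only: bool = True
    symmetry_reduction: bool = True


@dataclass(frozen=True)
class PlacementParams:
    """Probe placement settings."""

    n_conformers: int = 5
    #: rotations sampled about the feature-hotspot axis per pairing
    n_axis_rotations: int = 12
    pocket_margin: float = 3.0
    dedup_rmsd: float = 1.0
    energy_weight: float = 0.2
    refine_top: int = 20


@dataclass(frozen=True)
class DockingParams:
    """Rigid-body optimizer settings (6 degrees of freedom)."""

    n_restarts: int = 8
    perturb_translation: float = 1.0
    perturb_rotation_deg: float = 15.0
    max_iter: int = 200
    xatol: float = 1e-3
    fatol: float = 1e-5
    #: centroid trust region for probe refinement
    refine_trust_radius: float = 2.0


@dataclass(frozen=True)
class SelectionParams:
    objective: str = "binding_energy"  # or "pli_score"
    mode: str = "plain"  # or "ifp_clustered"
    k: int = 8
    ifp_similarity_threshold: float = 0.6


def _default_alert_file() -> str:
    return str(Path(__file__).parent / "data" / "default_alerts.yaml")


@dataclass
class GenerationConfig:
    """Everything a generation run needs, in one validated record."""

    protein_path: str = ""
    reference_ligand_path: str = ""
    probe_library_path: str = ""
    fragment_library_path: str = ""
    output_dir: str = "fraggrow_out"
    pocket_cutoff: float = 5.0
    max_iterations: int = 2
    mw_ceiling: float = 550.0
    n_conformers: int = 5
    k_probes: int = 4
    seed: int = 0
    windows: GeometricWindows = field(default_factory=GeometricWindows)
    energy: EnergyParams = field(default_factory=EnergyParams)
    hotspots: HotspotParams = field(default_factory=HotspotParams)
    rules: GrowthRules = field(default_factory=GrowthRules)
    placement: PlacementParams = field(default_factory=PlacementParams)
    docking: DockingParams = field(default_factory=DockingParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    filter_rule_file: str = field(default_factory=_default_alert_file)

    def validate(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.pocket_cutoff <= 0:
            raise ValueError("pocket_cutoff must be positive")
        for attr in ("protein_path", "reference_ligand_path",
                     "probe_library_path", "fragment_library_path",
                     "filter_rule_file"):
            p = getattr(self, attr)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _build(f.type, v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


_NESTED = {
    "windows": GeometricWindows,
    "energy": EnergyParams,
    "hotspots": HotspotParams,
    "rules": GrowthRules,
    "placement": PlacementParams,
    "docking": DockingParams,
    "selection": SelectionParams,
}


def load_generation_config(path: str | Path) -> GenerationConfig:
    """Read a run configuration from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED:
            kwargs[key] = _build(_NESTED[key], value)
        else:
            kwargs[key] = value
    cfg = _build(GenerationConfig, kwargs)
    return cfg
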