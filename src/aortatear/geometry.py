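"""Synthetic study geometries, fixture catalogue, sweep grids and file I/O.

The study's "imaged" aortas are stood in for by straight two-layer cylinders:
loaded (80 mmHg diastolic) inner diameters from the five-sample catalogue,
uniform 2.0 mm loaded wall (1.5 mm media + 0.5 mm adventitia).  Catalogue
diameters are taken as *inner* diameters because clinical segmentation
captures the lumen; the arch location maps to the descending-diameter
cylinder (the study found arch and descending behaviour similar once the
branches were removed).

This module also generates perturbed cylinder surfaces for exercising the
recovery driver, builds the default tear sweep grid, runs the full study
pipeline (recover zero-load geometry, then sweep critical pressures), and
reads/writes the YAML vessel and layer-parameter formats.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohesive import DEFAULT_PENALTY_STIFFNESS, CohesiveParams
from .inflation import VesselGeometry
from .material import GOHParameters
from .recovery import recover_cylinder
from .tear import THETA_R, THETA_Z, TearConfig, sweep

__all__ = [
    "AortaFixture",
    "SweepGrid",
    "CylinderSurface",
    "default_layers",
    "default_cohesive",
    "make_fixture_catalog",
    "make_imaged_vessel",
    "imaged_vessel_geometry",
    "default_sweep_grid",
    "run_study",
    "vessel_to_yaml",
    "vessel_from_yaml",
    "layer_from_yaml",
]

IMAGE_PRESSURE_MMHG = 80.0
LOADED_MEDIA_MM = 1.5
LOADED_ADVENTITIA_MM = 0.5

ASCENDING = "ascending"
ARCH = "arch"
DESCENDING = "descending"


@dataclass(frozen=True)
class AortaFixture:
    """One catalogued aorta: loaded inner diameters at the tear locations."""

    aorta_id: str
    ascending_diameter: float  # mm, loaded (80 mmHg)
    descending_diameter: float  # mm, loaded (80 mmHg)
    image_pressure: float = IMAGE_PRESSURE_MMHG

    def __post_init__(self) -> None:
        if self.ascending_diameter <= 0 or self.descending_diameter <= 0:
            raise ValueError("diameters must be positive")
        if self.ascending_diameter <= self.descending_diameter:
            raise ValueError(
                f"{self.aorta_id}: ascending diameter must exceed descending"
            )

    def diameter_at(self, location: str) -> float:
        """Loaded diameter at a tear location; the arch uses the descending value."""
        if location == ASCENDING:
            return self.ascending_diameter
        if location in (ARCH, DESCENDING):
            return self.descending_diameter
        raise ValueError(f"unknown location {location!r}")


# loaded inner diameters (mm) at the ascending / descending tear locations
_CATALOG = (
    ("S1", 26.107, 16.444),
    ("S2", 23.014, 15.681),
    ("S3", 29.005, 24.147),
    ("S4", 40.456, 26.764),
    ("S5", 41.381, 27.096),
)


def make_fixture_catalog() -> list[AortaFixture]:
    """The five study aortas with their catalogued loaded diameters."""
    return [AortaFixture(a, asc, desc) for a, asc, desc in _CATALOG]


def _layer_from_mapping(doc: dict, name: str) -> GOHParameters:
    return GOHParameters(
        c10=float(doc["c10_kPa"]),
        k1=float(doc["k1_kPa"]),
        k2=float(doc["k2"]),
        kappa=float(doc["kappa"]),
        fiber_angle=float(doc["theta_deg"]),
        thickness=float(doc["thickness_mm"]),
        name=name,
    )


def layer_from_yaml(path: str | Path, name: str = "") -> GOHParameters:
    """Read a layer parameter set (Table-style column keys) from YAML."""
    doc = yaml.safe_load(Path(path).read_text())
    return _layer_from_mapping(doc, name or Path(path).stem)


def _packaged_layer(name: str) -> dict:
    ref = importlib.resources.files("aortatear").joinpath(f"data/{name}.yaml")
    return yaml.safe_load(ref.read_text())


def default_layers() -> tuple[GOHParameters, GOHParameters]:
    """Shipped (media, adventitia) parameter sets with loaded thicknesses."""
    return (
        _layer_from_mapping(_packaged_layer("media"), "media"),
        _layer_from_mapping(_packaged_layer("adventitia"), "adventitia"),
    )


def default_cohesive(
    stiffness: float = DEFAULT_PENALTY_STIFFNESS,
) -> CohesiveParams:
    """Cohesive parameters from the shipped media interface values."""
    doc = _packaged_layer("media")
    return CohesiveParams(
        stiffness=(stiffness, stiffness, stiffness),
        critical_tractions=(
            float(doc["tn_cr_kPa"]),
            float(doc["ts_cr_kPa"]),
            float(doc["tt_cr_kPa"]),
        ),
        fracture_energy=float(doc["G_N_per_m"]),
    )


def imaged_vessel_geometry(
    diameter: float,
    layers: tuple[GOHParameters, GOHParameters] | None = None,
) -> VesselGeometry:
    """Loaded-configuration cylinder for a catalogued diameter.

    The returned ``VesselGeometry`` describes the *imaged* (pressure-loaded)
    shape: inner radius = diameter/2 with the loaded layer thicknesses.  Feed
    it to ``recovery.recover_cylinder`` to obtain the zero-load geometry.
    """
    media, adventitia = layers if layers is not None else default_layers()
    return VesselGeometry(diameter / 2.0, (media, adventitia))


@dataclass(frozen=True)
class CylinderSurface:
    """Surface-sampled straight cylinder (inner and outer walls).

    ``inner_radii``/``outer_radii`` have shape (n_z, n_theta); optional
    seeded radial perturbation noise exercises recovery robustness.
    """

    z: np.ndarray
    theta: np.ndarray
    inner_radii: np.ndarray
    outer_radii: np.ndarray

    def nodes(self) -> np.ndarray:
        """Stacked (n, 3) cartesian nodes, inner surface then outer."""
        pts = []
        for radii in (self.inner_radii, self.outer_radii):
            zz, tt = np.meshgrid(self.z, self.theta, indexing="ij")
            pts.append(
                np.column_stack(
                    [radii.ravel() * np.cos(tt.ravel()), radii.ravel() * np.sin(tt.ravel()), zz.ravel()]
                )
            )
        return np.vstack(pts)


def make_imaged_vessel(
    diameter: float,
    wall_thickness: float = LOADED_MEDIA_MM + LOADED_ADVENTITIA_MM,
    noise_amplitude: float = 0.0,
    seed: int | None = None,
    n_theta: int = 64,
    n_z: int = 9,
    length: float = 40.0,
) -> CylinderSurface:
    """Sampled imaged cylinder surface with optional radial noise.

    Noise is uniform in [-noise_amplitude, +noise_amplitude] mm, drawn from a
    seeded generator; the result is deterministic for a fixed seed.
    """
    if noise_amplitude < 0:
        raise ValueError("noise_amplitude must be non-negative")
    r_in = diameter / 2.0
    r_out = r_in + wall_thickness
    z = np.linspace(0.0, length, n_z)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rng = np.random.default_rng(seed)
    inner = np.full((n_z, n_theta), r_in)
    outer = np.full((n_z, n_theta), r_out)
    if noise_amplitude > 0:
        inner = inner + rng.uniform(-noise_amplitude, noise_amplitude, inner.shape)
        outer = outer + rng.uniform(-noise_amplitude, noise_amplitude, outer.shape)
    return CylinderSurface(z=z, theta=theta, inner_radii=inner, outer_radii=outer)


@dataclass(frozen=True)
class SweepGrid:
    """Tear sweep grid: sizes x depths x orientations x locations x aortas."""

    sizes: tuple[float, ...] = (3.0, 6.0, 9.0, 12.0)
    depths: tuple[float, ...] = (0.25, 0.75, 1.25)
    theta_z_locations: tuple[str, ...] = (ASCENDING, DESCENDING)
    theta_r_locations: tuple[str, ...] = (ASCENDING, ARCH, DESCENDING)
    theta_z_aortas: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5")
    theta_r_aortas: tuple[str, ...] = ("S1", "S2", "S3")
    aortas: tuple[AortaFixture, ...] = field(default_factory=lambda: tuple(make_fixture_catalog()))

    def __post_init__(self) -> None:
        if not (self.sizes and self.depths and self.aortas):
            raise ValueError("grid lists must be non-empty")

    def theta_z_cases(self) -> list[tuple[AortaFixture, TearConfig]]:
        """Square theta-z tears (size x size) per depth, location and aorta."""
        by_id = {a.aorta_id: a for a in self.aortas}
        cases = []
        for aid in self.theta_z_aortas:
            for loc in self.theta_z_locations:
                for depth in self.depths:
                    for size in self.sizes:
                        cases.append(
                            (
                                by_id[aid],
                                TearConfig(
                                    THETA_Z, size, size, depth, location=loc, aorta_id=aid
                                ),
                            )
                        )
        return cases

    def theta_r_cases(self) -> list[tuple[AortaFixture, TearConfig]]:
        """Arc-length-sized theta-r tears per depth, location and healthy aorta."""
        by_id = {a.aorta_id: a for a in self.aortas}
        cases = []
        for aid in self.theta_r_aortas:
            for loc in self.theta_r_locations:
                for depth in self.depths:
                    for size in self.sizes:
                        cases.append(
                            (
                                by_id[aid],
                                TearConfig(
                                    THETA_R, size, 0.0, depth, location=loc, aorta_id=aid
                                ),
                            )
                        )
        return cases


def default_sweep_grid() -> SweepGrid:
    """The study's default grid: 120 theta-z cases + 108 theta-r cases."""
    return SweepGrid()


def run_study(
    grid: SweepGrid | None = None,
    cohesive: CohesiveParams | None = None,
    n_layers: int = 3,
    p_max: float = 400.0,
) -> pd.DataFrame:
    """Full pipeline: recover zero-load geometries, sweep critical pressures.

    One zero-load recovery per distinct loaded diameter (arch and descending
    share a fixture cylinder); then the critical pressure of every tear in
    the grid.  Deterministic — reruns are bitwise identical.
    """
    grid = grid if grid is not None else default_sweep_grid()
    cohesive = cohesive if cohesive is not None else default_cohesive()

    recovered: dict[float, VesselGeometry] = {}

    def zero_load_for(diameter: float) -> VesselGeometry:
        if diameter not in recovered:
            imaged = imaged_vessel_geometry(diameter)
            recovered[diameter], _ = recover_cylinder(imaged, IMAGE_PRESSURE_MMHG)
        return recovered[diameter]

    frames = []
    for fixture, config in grid.theta_z_cases() + grid.theta_r_cases():
        diameter = fixture.diameter_at(config.location)
        vessel = zero_load_for(diameter)
        frames.append(
            sweep(
                [(fixture.aorta_id, diameter, vessel)],
                [config],
                cohesive,
                n_layers=n_layers,
                p_max=p_max,
            )
        )
    return pd.concat(frames, ignore_index=True)


def vessel_to_yaml(geom: VesselGeometry, path: str | Path) -> None:
    """Serialise a layered cylinder (9 significant digits) to YAML."""
    doc = {
        "inner_radius_mm": float(f"{geom.inner_radius:.9g}"),
        "axial_stretch": float(f"{geom.axial_stretch:.9g}"),
        "layers": [
            {
                "name": layer.name,
                "c10_kPa": float(f"{layer.c10:.9g}"),
                "k1_kPa": float(f"{layer.k1:.9g}"),
                "k2": float(f"{layer.k2:.9g}"),
                "kappa": float(f"{layer.kappa:.9g}"),
                "theta_deg": float(f"{layer.fiber_angle:.9g}"),
                "thickness_mm": float(f"{layer.thickness:.9g}"),
            }
            for layer in geom.layers
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def vessel_from_yaml(path: str | Path) -> VesselGeometry:
    """Read a layered cylinder from YAML."""
    doc = yaml.safe_load(Path(path).read_text())
    layers = tuple(
        _layer_from_mapping(ld, ld.get("name", f"layer{i}")) for i, ld in enumerate(doc["layers"])
    )
    return VesselGeometry(
        float(doc["inner_radius_mm"]), layers, float(doc.get("axial_stretch", 1.0))
    )
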