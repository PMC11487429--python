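"""Scanner geometries: four-panel flat scanner and reference cylindrical ring.

Crystals are addressed by a flat integer index (panel-major, then
row-major; rows run along the scanner axis Z).  World frame: origin at
the scanner centre, Z axial.  Panel inner faces sit at +/- separation/2
on X and Y (the panel separation is read face-to-face), and the LOR
endpoint of a crystal is its volume centre, i.e. half the crystal
length behind the entrance face -- no depth-of-interaction measurement
is modelled, so parallax emerges naturally from the crystal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class ReadoutLevel(str, Enum):
    """Readout granularity at which deposits are grouped into singles."""

    CRYSTAL = "crystal"
    SUBMODULE = "submodule"


SUBMODULE_SIDE = 5  # submodules are 5x5 crystals in both scanners


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CrystalSpec:
    """Square-cross-section scintillator crystal.

    cross_section and pitch are transverse mm; length is the depth along
    the photon incidence direction.
    """

    cross_section: float
    length: float
    pitch: float

    def __post_init__(self) -> None:
        if not (0.0 < self.cross_section <= self.pitch):
            raise ConfigurationError(
                f"need 0 < cross_section <= pitch, got "
                f"{self.cross_section} / {self.pitch}"
            )
        if self.length <= 0:
            raise ConfigurationError("crystal length must be positive")

    @property
    def volume_mm3(self) -> float:
        return self.cross_section**2 * self.length


class ScannerGeometry:
    """Common interface of both scanner types."""

    crystal: CrystalSpec
    n_crystals: int

    def crystal_center(self, flat_id: int) -> np.ndarray:
        raise NotImplementedError

    def crystal_centers(self, flat_ids: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def locate_crystal(self, point: np.ndarray) -> int:
        raise NotImplementedError

    def readout_group(self, flat_id, level: ReadoutLevel):
        raise NotImplementedError

    def group_centers(self, group_ids: np.ndarray, level: ReadoutLevel) -> np.ndarray:
        raise NotImplementedError

    def total_crystal_volume_dm3(self) -> float:
        """n_crystals * cross_section^2 * length, in dm^3."""
        return self.n_crystals * self.crystal.volume_mm3 / 1e6


@dataclass
class FlatPanelGeometry(ScannerGeometry):
    """Four (by default) flat panels forming a square prism around Z.

    Panel k has inward normal -n_k with n_k = (cos(k*90deg), sin(k*90deg), 0).
    Flat index = panel * n_side^2 + row * n_side + col, where row indexes
    the axial (Z) direction and col the transverse direction.
    """

    crystal: CrystalSpec
    n_panels: int = 4
    separation_mm: float = 400.0
    panel_extent_mm: float = 300.0
    n_side: int = field(init=False)

    def __post_init__(self) -> None:
        n = self.panel_extent_mm / self.crystal.pitch
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"panel extent {self.panel_extent_mm} mm is not divisible by "
                f"pitch {self.crystal.pitch} mm"
            )
        self.n_side = int(round(n))
        if self.n_side % SUBMODULE_SIDE and self.n_side > 1:
            # submodule readout would be ill-defined; allowed but flagged
            pass

    @property
    def n_crystals(self) -> int:
        return self.n_panels * self.n_side**2

    @property
    def face_distance_mm(self) -> float:
        return self.separation_mm / 2.0

    def panel_normal(self, panel: int) -> np.ndarray:
        theta = panel * 2.0 * np.pi / self.n_panels
        return np.array([np.cos(theta), np.sin(theta), 0.0])

    def split_id(self, flat_id):
        flat_id = np.asarray(flat_id)
        per_panel = self.n_side**2
        panel, rem = np.divmod(flat_id, per_panel)
        row, col = np.divmod(rem, self.n_side)
        return panel, row, col

    def flat_id(self, panel, row, col):
        return (panel * self.n_side + row) * self.n_side + col

    def panel_of(self, flat_id):
        return np.asarray(flat_id) // self.n_side**2

    def crystal_centers(self, flat_ids) -> np.ndarray:
        panel, row, col = self.split_id(flat_ids)
        half = (self.n_side - 1) / 2.0
        u = (np.asarray(col) - half) * self.crystal.pitch
        z = (np.asarray(row) - half) * self.crystal.pitch
        theta = panel * 2.0 * np.pi / self.n_panels
        radial = self.face_distance_mm + self.crystal.length / 2.0
        x = np.cos(theta) * radial - np.sin(theta) * u
        y = np.sin(theta) * radial + np.cos(theta) * u
        return np.stack([x, y, np.broadcast_to(z, np.shape(x))], axis=-1)

    def crystal_center(self, flat_id: int) -> np.ndarray:
        if not 0 <= flat_id < self.n_crystals:
            raise IndexError(f"crystal id {flat_id} out of range")
        return self.crystal_centers(np.asarray(flat_id))

    def locate_crystal(self, point) -> int:
        point = np.asarray(point, dtype=float)
        theta = np.arctan2(point[1], point[0])
        step = 2.0 * np.pi / self.n_panels
        panel = int(np.round(theta / step)) % self.n_panels
        th = panel * step
        u = -np.sin(th) * point[0] + np.cos(th) * point[1]
        half = (self.n_side - 1) / 2.0
        col = int(np.round(u / self.crystal.pitch + half))
        row = int(np.round(point[2] / self.crystal.pitch + half))
        if not (0 <= col < self.n_side and 0 <= row < self.n_side):
            raise IndexError(f"point {point} outside panel {panel}")
        return int(self.flat_id(panel, row, col))

    # -- readout grouping ---------------------------------------------------

    @property
    def n_blocks(self) -> int:
        return self.n_side // SUBMODULE_SIDE

    def readout_group(self, flat_id, level: ReadoutLevel):
        if level == ReadoutLevel.CRYSTAL:
            return np.asarray(flat_id)
        panel, row, col = self.split_id(flat_id)
        brow = np.asarray(row) // SUBMODULE_SIDE
        bcol = np.asarray(col) // SUBMODULE_SIDE
        return (panel * self.n_blocks + brow) * self.n_blocks + bcol

    def group_centers(self, group_ids, level: ReadoutLevel) -> np.ndarray:
        if level == ReadoutLevel.CRYSTAL:
            return self.crystal_centers(group_ids)
        per_panel = self.n_blocks**2
        panel, rem = np.divmod(np.asarray(group_ids), per_panel)
        brow, bcol = np.divmod(rem, self.n_blocks)
        # centre crystal offset of a 5x5 block
        mid = (SUBMODULE_SIDE - 1) / 2.0
        half = (self.n_side - 1) / 2.0
        u = (bcol * SUBMODULE_SIDE + mid - half) * self.crystal.pitch
        z = (brow * SUBMODULE_SIDE + mid - half) * self.crystal.pitch
        theta = panel * 2.0 * np.pi / self.n_panels
        radial = self.face_distance_mm + self.crystal.length / 2.0
        x = np.cos(theta) * radial - np.sin(theta) * u
        y = np.sin(theta) * radial + np.cos(theta) * u
        return np.stack([x, y, np.broadcast_to(z, np.shape(x))], axis=-1)

    def sector_difference(self, id1: int, id2: int) -> int:
        raise TypeError("sector difference is only defined for ring geometries")


@dataclass
class RingGeometry(ScannerGeometry):
    """Reference cylindrical scanner.

    Hierarchy: 19 sectors x (2x8 modules) x (4x2 submodules) x (5x5
    crystals) = 60,800 crystals, i.e. 760 transaxial x 80 axial.  Crystals
    are laid out with uniform angular spacing on the bore and uniform
    axial pitch filling the axial FOV; transaxial gaps between sectors
    are not modelled (the paper does not specify them).

    Flat index = transaxial_index * n_axial + axial_index.
    """

    crystal: CrystalSpec = field(
        default_factory=lambda: CrystalSpec(cross_section=3.2, length=20.0, pitch=3.2)
    )
    bore_diameter_mm: float = 780.0
    axial_fov_mm: float = 263.0
    n_sectors: int = 19
    modules_per_sector: tuple = (2, 8)      # (transaxial, axial)
    submodules_per_module: tuple = (4, 2)   # (transaxial, axial)

    def __post_init__(self) -> None:
        self.n_transaxial = (
            self.n_sectors
            * self.modules_per_sector[0]
            * self.submodules_per_module[0]
            * SUBMODULE_SIDE
        )
        self.n_axial = (
            self.modules_per_sector[1]
            * self.submodules_per_module[1]
            * SUBMODULE_SIDE
        )
        self.axial_pitch_mm = self.axial_fov_mm / self.n_axial

    @property
    def n_crystals(self) -> int:
        return self.n_transaxial * self.n_axial

    @property
    def transaxial_per_sector(self) -> int:
        return (
            self.modules_per_sector[0]
            * self.submodules_per_module[0]
            * SUBMODULE_SIDE
        )

    def split_id(self, flat_id):
        return np.divmod(np.asarray(flat_id), self.n_axial)

    def crystal_centers(self, flat_ids) -> np.ndarray:
        t, zi = self.split_id(flat_ids)
        theta = (t + 0.5) * 2.0 * np.pi / self.n_transaxial
        r = self.bore_diameter_mm / 2.0 + self.crystal.length / 2.0
        z = (zi + 0.5) * self.axial_pitch_mm - self.axial_fov_mm / 2.0
        return np.stack(
            [r * np.cos(theta), r * np.sin(theta), np.broadcast_to(z, np.shape(theta))],
            axis=-1,
        )

    def crystal_center(self, flat_id: int) -> np.ndarray:
        if not 0 <= flat_id < self.n_crystals:
            raise IndexError(f"crystal id {flat_id} out of range")
        return self.crystal_centers(np.asarray(flat_id))

    def locate_crystal(self, point) -> int:
        point = np.asarray(point, dtype=float)
        theta = np.arctan2(point[1], point[0]) % (2.0 * np.pi)
        t = int(theta / (2.0 * np.pi / self.n_transaxial)) % self.n_transaxial
        zi = int((point[2] + self.axial_fov_mm / 2.0) / self.axial_pitch_mm)
        if not 0 <= zi < self.n_axial:
            raise IndexError(f"point {point} outside axial FOV")
        return t * self.n_axial + zi

    def sector_of(self, flat_id):
        t, _ = self.split_id(flat_id)
        return t // self.transaxial_per_sector

    def sector_difference(self, id1, id2):
        s1 = np.asarray(self.sector_of(id1))
        s2 = np.asarray(self.sector_of(id2))
        d = np.abs(s1 - s2)
        return np.minimum(d, self.n_sectors - d)

    @property
    def n_blocks_axial(self) -> int:
        return self.n_axial // SUBMODULE_SIDE

    def readout_group(self, flat_id, level: ReadoutLevel):
        if level == ReadoutLevel.CRYSTAL:
            return np.asarray(flat_id)
        t, zi = self.split_id(flat_id)
        return (t // SUBMODULE_SIDE) * self.n_blocks_axial + zi // SUBMODULE_SIDE

    def group_centers(self, group_ids, level: ReadoutLevel) -> np.ndarray:
        if level == ReadoutLevel.CRYSTAL:
            return self.crystal_centers(group_ids)
        bt, bz = np.divmod(np.asarray(group_ids), self.n_blocks_axial)
        mid = (SUBMODULE_SIDE - 1) / 2.0
        t = bt * SUBMODULE_SIDE + mid
        zi = bz * SUBMODULE_SIDE + mid
        theta = (t + 0.5) * 2.0 * np.pi / self.n_transaxial
        r = self.bore_diameter_mm / 2.0 + self.crystal.length / 2.0
        z = (zi + 0.5) * self.axial_pitch_mm - self.axial_fov_mm / 2.0
        return np.stack(
            [r * np.cos(theta), r * np.sin(theta), np.broadcast_to(z, np.shape(theta))],
            axis=-1,
        )


def build_flat_panel(
    crystal_spec: CrystalSpec,
    n_panels: int = 4,
    separation_mm: float = 400.0,
    panel_extent_mm: float = 300.0,
) -> FlatPanelGeometry:
    """Build the flat-panel scanner; raises ConfigurationError if the
    panel extent is not an integer number of pitch cells."""
    return FlatPanelGeometry(
        crystal=crystal_spec,
        n_panels=n_panels,
        separation_mm=separation_mm,
        panel_extent_mm=panel_extent_mm,
    )


def build_reference_ring(**kwargs) -> RingGeometry:
    """Build the reference 78 cm-bore cylindrical scanner."""
    return RingGeometry(**kwargs)


def total_crystal_volume(geometry: ScannerGeometry) -> float:
    """Total scintillator volume in dm^3."""
    return geometry.total_crystal_volume_dm3()
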