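"""CG bilayer trajectory containers, GRO/XTC I/O, and leaflet assignment.

Positions are stored in angstrom, times in picoseconds, with orthorhombic
boxes and the bilayer normal along z.  File I/O goes through MDAnalysis:
a GRO coordinate file (single frame, nm on disk) plus an optional XTC
trajectory.  The site catalog — per-site molecule id, species, and site
name — is parsed from the residue/atom records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

__all__ = [
    "SiteCatalog",
    "Frame",
    "Trajectory",
    "write_trajectory",
    "read_trajectory",
    "assign_leaflets",
]


@dataclass(frozen=True)
class SiteCatalog:
    """Per-site (molecule id, species, site name), constant over frames."""

    molecule_ids: np.ndarray  # (n_sites,) int
    species: np.ndarray       # (n_sites,) str
    site_names: np.ndarray    # (n_sites,) str

    def __post_init__(self):
        n = len(self.molecule_ids)
        if len(self.species) != n or len(self.site_names) != n:
            raise ValueError("catalog arrays must have equal length")

    @property
    def n_sites(self) -> int:
        return len(self.molecule_ids)

    def mask(
        self, species: Optional[str] = None, site_name: Optional[str] = None
    ) -> np.ndarray:
        m = np.ones(self.n_sites, dtype=bool)
        if species is not None:
            m &= self.species == species
        if site_name is not None:
            m &= self.site_names == site_name
        return m

    def select(self, species=None, site_name=None) -> np.ndarray:
        """Indices of sites matching the given species/site name."""
        return np.flatnonzero(self.mask(species, site_name))

    def molecules_of(self, species: str) -> np.ndarray:
        return np.unique(self.molecule_ids[self.species == species])


@dataclass(frozen=True)
class Frame:
    """One trajectory frame: time (ps), positions (Å), box (Å), catalog."""

    time: float
    positions: np.ndarray  # (n_sites, 3)
    box: np.ndarray        # (3,) Lx, Ly, Lz
    catalog: SiteCatalog

    def __post_init__(self):
        if self.positions.shape != (self.catalog.n_sites, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"catalog with {self.catalog.n_sites} sites"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if len(self.box) != 3 or not np.all(np.asarray(self.box) > 0):
            raise ValueError(f"box must be 3 positive lengths, got {self.box}")


class Trajectory:
    """Ordered frames with a shared site catalog.

    Arrays: ``times`` (F,) ps, ``positions`` (F, n_sites, 3) Å,
    ``boxes`` (F, 3) Å.  Times must be strictly increasing.
    """

    def __init__(
        self,
        times: np.ndarray,
        positions: np.ndarray,
        boxes: np.ndarray,
        catalog: SiteCatalog,
    ):
        times = np.asarray(times, dtype=float)
        positions = np.asarray(positions)
        boxes = np.asarray(boxes, dtype=float)
        if times.ndim != 1 or len(times) < 1:
            raise ValueError("need at least one frame")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if positions.shape[0] != len(times) or positions.ndim != 3:
            raise ValueError(
                f"positions shape {positions.shape} inconsistent with "
                f"{len(times)} frames"
            )
        if boxes.shape != (len(times), 3):
            raise ValueError(f"boxes shape {boxes.shape} must be (F, 3)")
        if np.any(boxes <= 0):
            raise ValueError("box dimensions must be positive")
        if positions.shape[1] != catalog.n_sites:
            raise ValueError("positions second axis must match catalog size")
        self.times = times
        self.positions = positions
        self.boxes = boxes
        self.catalog = catalog

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> Frame:
        return Frame(
            time=float(self.times[i]),
            positions=np.asarray(self.positions[i], dtype=float),
            box=self.boxes[i],
            catalog=self.catalog,
        )

    @property
    def n_sites(self) -> int:
        return self.catalog.n_sites

    def frame_interval(self) -> float:
        """Uniform frame spacing in ps; error if sampling is non-uniform."""
        dt = np.diff(self.times)
        if len(dt) == 0:
            raise ValueError("single-frame trajectory has no frame interval")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-6):
            raise ValueError("frame times are not uniformly spaced")
        return float(dt[0])


def _build_universe(catalog: SiteCatalog) -> "mda.Universe":
    mol_ids = np.asarray(catalog.molecule_ids)
    unique_ids, resindex = np.unique(mol_ids, return_inverse=True)
    n_res = len(unique_ids)
    u = mda.Universe.empty(
        n_atoms=catalog.n_sites,
        n_residues=n_res,
        atom_resindex=resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(s) for s in catalog.site_names])
    res_species = [
        str(catalog.species[np.flatnonzero(mol_ids == rid)[0]])
        for rid in unique_ids
    ]
    u.add_TopologyAttr("resnames", res_species)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    return u


def write_trajectory(
    traj: Trajectory,
    gro_path: Union[str, Path],
    xtc_path: Union[str, Path, None] = None,
) -> None:
    """Write frame 0 as GRO (nm on disk) and, optionally, all frames as XTC."""
    u = _build_universe(traj.catalog)

    def _load(i: int):
        u.atoms.positions = np.asarray(traj.positions[i], dtype=np.float32)
        u.dimensions = [*traj.boxes[i], 90.0, 90.0, 90.0]
        u.trajectory.ts.time = float(traj.times[i])

    _load(0)
    u.atoms.write(str(gro_path))
    if xtc_path is not None:
        with mda.Writer(str(xtc_path), n_atoms=traj.n_sites) as w:
            for i in range(len(traj)):
                _load(i)
                u.trajectory.ts.frame = i
                w.write(u.atoms)


def read_trajectory(
    coords_source: Union[str, Path],
    trajectory_source: Union[str, Path, None] = None,
) -> Trajectory:
    """Read a GRO coordinate file and optional XTC trajectory.

    The catalog is taken from the residue records: species = residue name,
    molecule id = 0-based residue index, site name = atom name.
    """
    args = [str(coords_source)]
    if trajectory_source is not None:
        args.append(str(trajectory_source))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(*args)
    catalog = SiteCatalog(
        molecule_ids=u.atoms.resindices.copy(),
        species=u.atoms.resnames.astype(str),
        site_names=u.atoms.names.astype(str),
    )
    times, positions, boxes = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.dimensions is None or np.any(ts.dimensions[:3] <= 0):
                raise ValueError(f"frame {ts.frame} has no valid box")
            times.append(float(ts.time))
            positions.append(ts.positions.copy())
            boxes.append(ts.dimensions[:3].copy())
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(positions),
        boxes=np.asarray(boxes),
        catalog=catalog,
    )


def assign_leaflets(
    frame: Frame, reference_sites: Mapping[str, str]
) -> dict[int, str]:
    """Assign each molecule to the upper or lower leaflet.

    One reference site per species (e.g. PO4 for phospholipids, ROH/KOH
    for sterols); molecules whose reference-site z lies above the median
    reference z are "upper", the rest "lower".  Invariant under rigid
    z-translation.
    """
    cat = frame.catalog
    mol_z: dict[int, float] = {}
    for species, site_name in reference_sites.items():
        idx = cat.select(species=species, site_name=site_name)
        for i in idx:
            mol_z[int(cat.molecule_ids[i])] = float(frame.positions[i, 2])
    present = set()
    for species in reference_sites:
        present.update(int(m) for m in cat.molecules_of(species))
    missing = present - set(mol_z)
    if missing:
        raise ValueError(
            f"molecules missing their reference site: {sorted(missing)[:5]}"
        )
    if not mol_z:
        raise ValueError("no reference sites found for any species")
    zs = np.array(list(mol_z.values()))
    if np.ptp(zs) == 0:
        raise ValueError(
            "degenerate bilayer: all reference sites at identical z"
        )
    median = float(np.median(zs))
    return {
        mol: ("upper" if z > median else "lower") for mol, z in mol_z.items()
    }
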