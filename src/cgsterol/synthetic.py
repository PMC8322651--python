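"""Synthetic CG bilayer trajectories with fully known ground truth.

Generates two-leaflet membrane trajectories in which every analyzer input
is controlled: per-species lateral diffusion is 2D Brownian motion, tail
pseudobond orientations are drawn from a distribution with a prescribed
order parameter, sterol ring axes from a prescribed tilt-angle density,
the lateral box area fluctuates about (lipids per leaflet) × (target area
per lipid), and the phosphate planes sit at the target thickness.  Every
observable is therefore testable by parameter recovery without an MD
engine.

Orientations are resampled independently every frame (no rotational
dynamics): all in-scope observables are static-distribution or
lateral-dynamics quantities, so only the marginal orientation distribution
and the lateral displacement process matter.

Samplers
--------
Bond orientations use the axial density p(u) ∝ exp(λu²) for u = cosθ,
with λ solved numerically so that ⟨(3u² − 1)/2⟩ equals the target order
parameter S ∈ (−0.5, 1).  Sterol tilt angles use
p(θ) ∝ sinθ · exp(κ cos(θ − θ₀)) on [0°, 90°], a von-Mises-like density
over the polar angle with mode parameter θ₀ and concentration κ ≥ 0
(κ = 0 recovers the isotropic sinθ density).  Both are sampled by
inverse-CDF interpolation on a dense grid, and both admit direct numeric
integration of their moments for use as independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .composition import (
    SPECIES,
    BilayerComposition,
    build_bilayer_composition,
    realize_counts,
)
from .templates import TEMPLATES
from .trajectory import Frame, SiteCatalog, Trajectory

__all__ = [
    "GroundTruth",
    "default_ground_truth",
    "generate_membrane",
    "simulate_trajectory",
    "sample_bond_orientation",
    "solve_lambda",
    "expected_p2",
    "tilt_mean_deg",
    "tilt_sd_deg",
    "sample_tilt",
]

_BOND_LENGTH = 4.7       # Å, tail pseudobond length
_RING_STEP = 1.8         # Å, sterol ring-site spacing along the axis
_GRID_N = 32769          # samples for inverse-CDF grids
_LAMBDA_RANGE = (-2000.0, 2000.0)


# ---------------------------------------------------------------------------
# Bond-orientation sampler: p(u) ∝ exp(λ u²), u = cosθ ∈ [0, 1] (folded)
# ---------------------------------------------------------------------------

def _axial_weights(lam: float, u: np.ndarray) -> np.ndarray:
    # Shift the exponent so the largest weight is exp(0): overflow-safe.
    if lam > 0:
        return np.exp(lam * (u * u - 1.0))
    return np.exp(lam * u * u)


def expected_p2(lam: float) -> float:
    """⟨(3u² − 1)/2⟩ under p(u) ∝ exp(λu²) on u ∈ [0, 1]."""
    u = np.linspace(0.0, 1.0, _GRID_N)
    w = _axial_weights(lam, u)
    num = np.trapezoid((1.5 * u * u - 0.5) * w, u)
    den = np.trapezoid(w, u)
    return float(num / den)


def solve_lambda(s_target: float) -> float:
    """Concentration λ such that the axial density has order parameter S.

    S must lie in (−0.5, 1) strictly; the isotropic case S = 0 maps to
    λ = 0 exactly.
    """
    from scipy.optimize import brentq

    lo, hi = _LAMBDA_RANGE
    s_lo, s_hi = expected_p2(lo), expected_p2(hi)
    if not (s_lo < s_target < s_hi):
        raise ValueError(
            f"order target {s_target} outside the solvable range "
            f"({s_lo:.4f}, {s_hi:.4f})"
        )
    if s_target == 0.0:
        return 0.0
    return float(brentq(lambda l: expected_p2(l) - s_target, lo, hi,
                        xtol=1e-10, rtol=1e-12))


_cos_grid_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _cos_inverse_cdf(lam: float) -> tuple[np.ndarray, np.ndarray]:
    key = round(lam, 9)
    if key not in _cos_grid_cache:
        u = np.linspace(0.0, 1.0, _GRID_N)
        w = _axial_weights(lam, u)
        cdf = np.concatenate(([0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(u))))
        cdf /= cdf[-1]
        _cos_grid_cache[key] = (cdf, u)
    return _cos_grid_cache[key]


def sample_bond_orientation(
    s_target: float, seed_or_rng, size: int = 1
) -> np.ndarray:
    """Sample unit bond vectors with prescribed order parameter.

    Draws |cosθ| from p(u) ∝ exp(λu²) with λ solved so that
    ⟨(3cos²θ − 1)/2⟩ = ``s_target``; the azimuth is uniform.  Returns an
    array of shape (size, 3).
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    lam = solve_lambda(s_target)
    u = _sample_cos(lam, size, rng)
    phi = rng.uniform(0.0, 2.0 * math.pi, size)
    sin_t = np.sqrt(np.clip(1.0 - u * u, 0.0, None))
    return np.column_stack(
        (sin_t * np.cos(phi), sin_t * np.sin(phi), u)
    )


def _sample_cos(lam: float, size, rng: np.random.Generator) -> np.ndarray:
    cdf, u = _cos_inverse_cdf(lam)
    return np.interp(rng.random(size), cdf, u)


# ---------------------------------------------------------------------------
# Sterol tilt sampler: p(θ) ∝ sinθ exp(κ cos(θ − θ0)) on [0°, 90°]
# ---------------------------------------------------------------------------

def _tilt_density(theta: np.ndarray, mode_deg: float, kappa: float) -> np.ndarray:
    theta0 = math.radians(mode_deg)
    return np.sin(theta) * np.exp(kappa * (np.cos(theta - theta0) - 1.0))


def _tilt_moments(mode_deg: float, kappa: float) -> tuple[float, float]:
    theta = np.linspace(0.0, math.pi / 2.0, _GRID_N)
    w = _tilt_density(theta, mode_deg, kappa)
    z = np.trapezoid(w, theta)
    m1 = np.trapezoid(theta * w, theta) / z
    m2 = np.trapezoid(theta * theta * w, theta) / z
    return math.degrees(m1), math.degrees(math.sqrt(max(m2 - m1 * m1, 0.0)))


def tilt_mean_deg(mode_deg: float, kappa: float) -> float:
    """Mean tilt angle (deg) of the sampling density, by quadrature."""
    return _tilt_moments(mode_deg, kappa)[0]


def tilt_sd_deg(mode_deg: float, kappa: float) -> float:
    """Standard deviation (deg) of the tilt sampling density."""
    return _tilt_moments(mode_deg, kappa)[1]


_tilt_grid_cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}


def sample_tilt(
    mode_deg: float, kappa: float, size, rng: np.random.Generator
) -> np.ndarray:
    """Sample tilt angles (radians) from the sterol tilt density."""
    if kappa < 0:
        raise ValueError(f"concentration must be >= 0, got {kappa}")
    key = (round(mode_deg, 9), round(kappa, 9))
    if key not in _tilt_grid_cache:
        theta = np.linspace(0.0, math.pi / 2.0, _GRID_N)
        w = _tilt_density(theta, mode_deg, kappa)
        cdf = np.concatenate(
            ([0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(theta)))
        )
        cdf /= cdf[-1]
        _tilt_grid_cache[key] = (cdf, theta)
    cdf, theta = _tilt_grid_cache[key]
    return np.interp(rng.random(size), cdf, theta)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _default_diffusion() -> dict[str, float]:
    # Å^2/ns (1 Å^2/ns = 1e-7 cm^2/s), CG-scale lateral diffusivities.
    return {"POPC": 1.0, "DPPC": 0.8, "SM": 0.7, "CHOL": 0.6, "7KC": 0.9}


def _default_order_targets() -> dict[str, dict[str, tuple[float, ...]]]:
    # Per-bond order parameter targets, decreasing toward the tail ends.
    return {
        "POPC": {"sn2": (0.45, 0.30, 0.20), "sn1": (0.50, 0.40, 0.30)},
        "DPPC": {"sn2": (0.55, 0.45, 0.35), "sn1": (0.55, 0.45, 0.35)},
        "SM": {"sn2": (0.55, 0.40), "sn1": (0.55, 0.45, 0.35)},
    }


def _default_tilt() -> dict[str, tuple[float, float]]:
    # (mode degrees, concentration): cholesterol upright and narrow,
    # 7-ketocholesterol more tilted and broader.
    return {"CHOL": (12.0, 15.0), "7KC": (25.0, 6.0)}


@dataclass(frozen=True)
class GroundTruth:
    """Known parameters behind one synthetic trajectory."""

    composition: BilayerComposition      # realized (with counts)
    apl: float = 44.0                    # Å^2 per lipid (per leaflet)
    thickness: float = 43.0              # Å, phosphate plane separation
    diffusion: Mapping[str, float] = field(default_factory=_default_diffusion)
    order_targets: Mapping[str, Mapping[str, tuple[float, ...]]] = field(
        default_factory=_default_order_targets
    )
    tilt: Mapping[str, tuple[float, float]] = field(default_factory=_default_tilt)
    box_area_sd: Optional[float] = None  # Å^2; default 0.1 % of the box area
    z_jitter_sd: float = 1.0             # Å, phosphate-plane roughness
    frame_interval_ps: float = 100.0
    n_frames: int = 2000
    seed: int = 42

    def __post_init__(self):
        if self.composition.counts_per_leaflet is None:
            raise ValueError("composition must be realized (have counts)")
        if self.apl <= 0 or self.thickness <= 0:
            raise ValueError("apl and thickness must be positive")
        if any(d < 0 for d in self.diffusion.values()):
            raise ValueError("diffusion coefficients must be >= 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    @property
    def n_per_leaflet(self) -> int:
        return sum(self.composition.counts_per_leaflet.values())

    @property
    def box_area(self) -> float:
        return self.n_per_leaflet * self.apl

    def area_sd(self) -> float:
        if self.box_area_sd is not None:
            return self.box_area_sd
        return 1e-3 * self.box_area

    def as_dict(self) -> dict:
        return {
            "composition": dict(self.composition.counts_per_leaflet),
            "apl": self.apl,
            "thickness": self.thickness,
            "diffusion": dict(self.diffusion),
            "order_targets": {
                sp: {tail: list(s) for tail, s in tails.items()}
                for sp, tails in self.order_targets.items()
            },
            "tilt": {sp: list(v) for sp, v in self.tilt.items()},
            "box_area_sd": self.area_sd(),
            "z_jitter_sd": self.z_jitter_sd,
            "frame_interval_ps": self.frame_interval_ps,
            "n_frames": self.n_frames,
            "seed": self.seed,
        }


def default_ground_truth(
    n_per_leaflet: int = 512,
    n_frames: int = 2000,
    seed: int = 42,
    **overrides,
) -> GroundTruth:
    """Desk-scale benchmark ground truth.

    Uses a balanced five-species mixture (POPC 30 / DPPC 15 / SM 15 /
    CHOL 25 / 7KC 15 mol%) so that every species, including the sterols,
    is populated well enough for tight per-species parameter recovery.
    """
    comp = BilayerComposition(
        percents={"POPC": 30.0, "DPPC": 15.0, "SM": 15.0,
                  "CHOL": 25.0, "7KC": 15.0},
        name="recovery-benchmark",
    )
    comp = realize_counts(comp, 2 * n_per_leaflet)
    return GroundTruth(
        composition=comp, n_frames=n_frames, seed=seed, **overrides
    )


# ---------------------------------------------------------------------------
# Membrane construction
# ---------------------------------------------------------------------------

def _build_catalog(comp: BilayerComposition) -> tuple[SiteCatalog, np.ndarray, np.ndarray]:
    """Catalog plus per-molecule species index and leaflet sign (+1/−1)."""
    mol_ids, species_arr, names = [], [], []
    mol_species, mol_sign = [], []
    mol = 0
    for sign in (+1, -1):
        for sp in SPECIES:
            count = comp.counts_per_leaflet.get(sp, 0)
            tmpl = TEMPLATES[sp]
            for _ in range(count):
                for site in tmpl.sites:
                    mol_ids.append(mol)
                    species_arr.append(sp)
                    names.append(site)
                mol_species.append(sp)
                mol_sign.append(sign)
                mol += 1
    cat = SiteCatalog(
        molecule_ids=np.asarray(mol_ids, dtype=np.int64),
        species=np.asarray(species_arr, dtype="U8"),
        site_names=np.asarray(names, dtype="U8"),
    )
    return cat, np.asarray(mol_species, dtype="U8"), np.asarray(mol_sign)


def _lattice_anchors(n: int, box_l: float, rng: np.random.Generator) -> np.ndarray:
    n_side = math.ceil(math.sqrt(n))
    spacing = box_l / n_side
    if spacing < 3.0:
        raise ValueError(
            f"lattice spacing {spacing:.2f} Å too small to host molecule "
            f"footprints; increase the area per lipid or reduce counts"
        )
    order = rng.permutation(n_side * n_side)[:n]
    ix, iy = order % n_side, order // n_side
    return np.column_stack(((ix + 0.5) * spacing, (iy + 0.5) * spacing))


def generate_membrane(gt: GroundTruth) -> Frame:
    """Initial frame: two mirrored leaflets on a square lattice.

    Lattice spacing follows √(area per lipid); the box area is exactly
    (lipids per leaflet) × apl, and the phosphate planes sit at
    ±thickness/2 about the bilayer midplane z = 0.  Orientations are
    sampled from the ground-truth densities with the ground-truth seed.
    """
    rng = np.random.default_rng(gt.seed)
    cat, mol_species, mol_sign = _build_catalog(gt.composition)
    n_leaf = gt.n_per_leaflet
    box_l = math.sqrt(gt.box_area)
    anchors = np.empty((len(mol_species), 2))
    for sign in (+1, -1):
        sel = mol_sign == sign
        anchors[sel] = _lattice_anchors(int(sel.sum()), box_l, rng)
    positions = _assemble(
        gt, cat, mol_species, mol_sign,
        anchors[None, :, :], np.array([[box_l, box_l]]), rng,
        jitter=False,
    )[0]
    box = np.array([box_l, box_l, gt.thickness + 30.0])
    return Frame(time=0.0, positions=positions, box=box, catalog=cat)


def _assemble(
    gt: GroundTruth,
    cat: SiteCatalog,
    mol_species: np.ndarray,
    mol_sign: np.ndarray,
    anchors: np.ndarray,   # (F, M, 2), unwrapped
    box_xy: np.ndarray,    # (F, 2)
    rng: np.random.Generator,
    jitter: bool = True,
) -> np.ndarray:
    """Build site positions (F, n_sites, 3) from anchors and orientations."""
    F = anchors.shape[0]
    n_sites = cat.n_sites
    pos = np.zeros((F, n_sites, 3), dtype=np.float32)
    half = gt.thickness / 2.0

    # Wrap each molecule rigidly so its anchor lies inside the box.
    L = box_xy[:, None, :]
    wrapped = anchors - L * np.floor(anchors / L)

    site_mol = cat.molecule_ids
    # Per-site anchor xy (broadcast molecule anchor onto its sites).
    pos[:, :, 0] = wrapped[:, site_mol, 0]
    pos[:, :, 1] = wrapped[:, site_mol, 1]

    for sp in SPECIES:
        mols = np.flatnonzero(mol_species == sp)
        if len(mols) == 0:
            continue
        tmpl = TEMPLATES[sp]
        sign = mol_sign[mols][None, :]  # (1, M_s)
        M_s = len(mols)
        site_idx = {
            name: np.flatnonzero(
                (cat.species == sp) & (cat.site_names == name)
            )
            for name in tmpl.sites
        }

        def put(name, dx, dy, z):
            idx = site_idx[name]
            pos[:, idx, 0] += dx
            pos[:, idx, 1] += dy
            pos[:, idx, 2] = z

        if not tmpl.is_sterol:
            z_jit = (
                rng.normal(0.0, gt.z_jitter_sd, (F, M_s)) if jitter else 0.0
            )
            z_p = sign * half + z_jit
            put("PO4", 0.0, 0.0, z_p)
            put("NC3", 0.9, 0.0, z_p + sign * 3.0)
            bb = [s for s in tmpl.head_sites if s in ("GL1", "AM1")][0]
            bb2 = [s for s in tmpl.head_sites if s in ("GL2", "AM2")][0]
            z_g = sign * (half - 4.0) + z_jit
            put(bb, -0.9, 0.0, z_g)
            put(bb2, 0.9, 0.9, z_g)
            starts = {"sn1": bb, "sn2": bb2}
            for tail, chain in tmpl.tails.items():
                s_idx = site_idx[starts[tail]]
                cur = pos[:, s_idx, :].astype(np.float64)
                targets = gt.order_targets[sp][tail]
                # Bead k joins bead k-1 via catalogued bond k (1-based);
                # the k=0 glycerol-attachment bond is not catalogued and
                # reuses the first bond's target.
                for k, bead in enumerate(chain):
                    s_val = targets[min(max(k - 1, 0), len(targets) - 1)]
                    lam = solve_lambda(s_val)
                    u = _sample_cos(lam, (F, M_s), rng)
                    phi = rng.uniform(0.0, 2.0 * math.pi, (F, M_s))
                    sin_t = np.sqrt(np.clip(1.0 - u * u, 0.0, None))
                    bond = np.stack(
                        (
                            _BOND_LENGTH * sin_t * np.cos(phi),
                            _BOND_LENGTH * sin_t * np.sin(phi),
                            -sign * _BOND_LENGTH * u,
                        ),
                        axis=-1,
                    )
                    cur = cur + bond
                    pos[:, site_idx[bead], :] = cur
        else:
            mode_deg, kappa = gt.tilt[sp]
            theta = sample_tilt(mode_deg, kappa, (F, M_s), rng)
            phi = rng.uniform(0.0, 2.0 * math.pi, (F, M_s))
            axis = np.stack(
                (
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    sign * np.cos(theta),
                ),
                axis=-1,
            )  # unit vector pointing from the ring toward the head
            head = tmpl.tilt_vector[1]
            z_head = sign * (half - 3.0)
            put(head, 0.0, 0.0, np.broadcast_to(z_head, (F, M_s)).copy())
            head_pos = pos[:, site_idx[head], :].astype(np.float64)
            ring = [s for s in tmpl.sites if s != head]
            for k, name in enumerate(ring, start=1):
                depth = _RING_STEP * k if k <= 5 else 9.0 + 3.2 * (k - 5)
                pos[:, site_idx[name], :] = head_pos - depth * axis
    return pos


def simulate_trajectory(
    initial: Frame, gt: GroundTruth
) -> Trajectory:
    """Brownian-dynamics trajectory from an initial membrane frame.

    Per frame: molecule anchors advance laterally by Gaussian steps with
    variance 4·D·Δt per species (2·D·Δt per axis) and wrap periodically;
    bond and sterol orientations are resampled from their target
    densities; the box area fluctuates about N·apl; phosphate planes stay
    at ±thickness/2 with per-molecule z roughness.  All randomness comes
    from the ground-truth seed — identical inputs give identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([gt.seed, 1]))
    cat = initial.catalog
    # Recover layout (species, leaflet, anchor) from the initial frame.
    mol_ids = np.unique(cat.molecule_ids)
    M = len(mol_ids)
    mol_species = np.empty(M, dtype="U8")
    mol_sign = np.empty(M, dtype=np.int64)
    anchors0 = np.empty((M, 2))
    for m in mol_ids:
        rows = np.flatnonzero(cat.molecule_ids == m)
        sp = str(cat.species[rows[0]])
        ref = TEMPLATES[sp].reference_site
        r = rows[np.flatnonzero(cat.site_names[rows] == ref)[0]]
        mol_species[m] = sp
        mol_sign[m] = 1 if initial.positions[r, 2] > 0 else -1
        anchors0[m] = initial.positions[r, :2]

    F = gt.n_frames
    dt = gt.frame_interval_ps / 1000.0  # ns
    # Box areas (total), then edge lengths.
    area = gt.box_area + rng.normal(0.0, gt.area_sd(), F)
    if np.any(area <= 0):
        raise ValueError("box area fluctuation produced a non-positive area")
    box_l = np.sqrt(area)
    box_xy = np.column_stack((box_l, box_l))

    # Per-species Brownian steps.
    steps = np.zeros((F, M, 2))
    min_l = float(box_l.min())
    for sp in SPECIES:
        sel = mol_species == sp
        if not np.any(sel):
            continue
        d_coef = gt.diffusion.get(sp, 0.0)
        sd = math.sqrt(2.0 * d_coef * dt)
        if 6.0 * sd >= min_l / 4.0:
            raise ValueError(
                f"per-frame Brownian step for {sp} (~{sd:.1f} Å) is too "
                f"large relative to the box; shorten the frame interval"
            )
        if sd > 0:
            steps[1:, sel, :] = rng.normal(0.0, sd, (F - 1, int(sel.sum()), 2))
    anchors = anchors0[None, :, :] + np.cumsum(steps, axis=0)

    positions = _assemble(
        gt, cat, mol_species, mol_sign, anchors, box_xy, rng, jitter=True
    )
    times = np.arange(F, dtype=float) * gt.frame_interval_ps
    boxes = np.column_stack((box_l, box_l, np.full(F, gt.thickness + 30.0)))
    return Trajectory(
        times=times, positions=positions, boxes=boxes, catalog=cat
    )
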