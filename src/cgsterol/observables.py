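"""Structural and dynamical bilayer observables.

Implements the quantities used to characterize sterol-containing CG
bilayers:

* area per lipid — lateral box area divided by the lipid count (per-leaflet
  denominator by default, since a tensionless bilayer's lateral area is
  shared by the two stacked leaflets);
* bilayer thickness — z-distance between the mean phosphate planes;
* lateral mean-square displacement and the diffusion coefficient
  D = (1/4) d/dt MSD(t) from the long-time MSD slope;
* sterol ring tilt-angle distributions (angle between the ring axis and
  the bilayer normal, folded to [0°, 90°] so both leaflets pool);
* tail pseudobond orientational order parameters, in both sign
  conventions: ``standard_P2`` = ⟨(3cos²θ − 1)/2⟩ and ``as_printed`` =
  its negative (the convention in which *decreasing* values indicate
  decreased packing is the printed one; the two are exact negatives and
  neither is silently corrected);
* unpaired two-sided Student's t-tests (pooled variance) for group
  comparisons, with p < 0.05 flagged significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .templates import Bond, REFERENCE_SITES, default_bond_catalog
from .trajectory import Trajectory

__all__ = [
    "TimeSeriesStat",
    "MSDSeries",
    "DiffusionFit",
    "TiltDistribution",
    "OrderParameterResult",
    "TTestResult",
    "area_per_lipid",
    "bilayer_thickness",
    "lateral_msd",
    "fit_diffusion",
    "sterol_tilt",
    "bond_order_parameters",
    "compare_groups",
]


@dataclass(frozen=True)
class TimeSeriesStat:
    """Per-frame values of one observable with mean and sd over frames."""

    values: np.ndarray
    units: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MSDSeries:
    """Origin- and ensemble-averaged lateral MSD versus lag time."""

    lag_ps: np.ndarray   # strictly increasing, starts at 0
    msd: np.ndarray      # Å^2, msd[0] == 0
    species: str
    n_molecules: int

    def __post_init__(self):
        if len(self.lag_ps) != len(self.msd):
            raise ValueError("lag and msd lengths differ")
        if np.any(np.diff(self.lag_ps) <= 0):
            raise ValueError("lag times must be strictly increasing")


@dataclass(frozen=True)
class DiffusionFit:
    """Lateral diffusion coefficient from an OLS fit to the MSD."""

    D: float               # Å^2/ns
    D_se: float            # standard error of D, Å^2/ns
    window_ps: tuple[float, float]
    slope: float           # Å^2/ps
    slope_se: float
    intercept: float

    @property
    def D_cm2_per_s(self) -> float:
        # 1 Å^2/ns = 1e-16 cm^2 / 1e-9 s = 1e-7 cm^2/s
        return self.D * 1e-7


@dataclass(frozen=True)
class TiltDistribution:
    """Sterol tilt-angle distribution over [0°, 90°]."""

    bin_centers: np.ndarray  # degrees
    density: np.ndarray      # per degree; integrates to 1
    bin_width: float
    mean_deg: float
    sd_deg: float
    species: str
    n_samples: int


@dataclass(frozen=True)
class OrderParameterResult:
    """Time- and ensemble-averaged order parameter of one tail pseudobond."""

    bond: Bond
    standard_P2: float  # ⟨(3cos²θ − 1)/2⟩

    @property
    def as_printed(self) -> float:
        return -self.standard_P2

    def value(self, convention: str = "as_printed") -> float:
        if convention == "as_printed":
            return self.as_printed
        if convention == "standard_P2":
            return self.standard_P2
        raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def area_per_lipid(
    traj: Trajectory, n_lipids: int, convention: str = "per_leaflet"
) -> TimeSeriesStat:
    """Area per lipid per frame: Lx·Ly divided by the lipid count.

    ``n_lipids`` is the total number of molecules in the bilayer.  Under
    the default ``per_leaflet`` convention the denominator is
    ``n_lipids/2`` (each leaflet tiles the lateral area independently);
    ``total`` divides by all molecules, the literal reading of "area
    divided by total number of lipids".
    """
    if n_lipids <= 0:
        raise ValueError(f"n_lipids must be positive, got {n_lipids}")
    if convention == "per_leaflet":
        denom = n_lipids / 2.0
    elif convention == "total":
        denom = float(n_lipids)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    areas = traj.boxes[:, 0] * traj.boxes[:, 1] / denom
    return TimeSeriesStat(values=areas, units="Å^2/lipid")


def bilayer_thickness(
    traj: Trajectory, phosphate_site_names: Sequence[str] = ("PO4",)
) -> TimeSeriesStat:
    """Phosphate-plane separation per frame (Å).

    Per frame, phosphate sites are split at their median z; thickness is
    |⟨z⟩_upper − ⟨z⟩_lower|.  Invariant under rigid z-translation.
    """
    cat = traj.catalog
    mask = np.isin(cat.site_names, list(phosphate_site_names))
    if not np.any(mask):
        raise ValueError(
            f"no phosphate sites named {list(phosphate_site_names)} found"
        )
    z = np.asarray(traj.positions[:, mask, 2], dtype=float)  # (F, P)
    med = np.median(z, axis=1, keepdims=True)
    upper = z > med
    n_up = upper.sum(axis=1)
    if np.any(n_up == 0) or np.any(n_up == upper.shape[1]):
        raise ValueError(
            "degenerate frame: could not split phosphates into two leaflets"
        )
    z_up = np.where(upper, z, 0.0).sum(axis=1) / n_up
    z_lo = np.where(~upper, z, 0.0).sum(axis=1) / (upper.shape[1] - n_up)
    return TimeSeriesStat(values=np.abs(z_up - z_lo), units="Å")


def _unwrap_lateral(xy: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from wrapped lateral coordinates.

    Minimum-image displacement accumulation between consecutive frames;
    valid as long as no molecule moves more than half a box edge per
    frame interval.
    """
    disp = np.diff(xy, axis=0)
    L = boxes[1:, None, :2]
    disp = disp - L * np.round(disp / L)
    out = np.empty_like(xy, dtype=np.float64)
    out[0] = xy[0]
    np.cumsum(disp, axis=0, out=out[1:])
    out[1:] += xy[0]
    return out


def _msd_fft(r: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of trajectories ``r`` with shape (F, M, d).

    FFT autocorrelation formulation: MSD(τ) averaged over all F−τ origins,
    O(F log F) per molecule and dimension, then averaged over molecules.
    """
    F, M, d = r.shape
    nfft = 1 << (2 * F - 1).bit_length()
    sq = np.einsum("fmd,fmd->fm", r, r)  # |r_t|^2, shape (F, M)
    # S2(τ) = Σ_t r_t · r_{t+τ} via FFT
    fr = np.fft.rfft(r, n=nfft, axis=0)
    s2 = np.fft.irfft(fr * fr.conj(), n=nfft, axis=0)[:F].sum(axis=2)  # (F, M)
    # S1(τ) = Σ_t (|r_t|^2 + |r_{t+τ}|^2) over valid origins
    sumsq = 2.0 * sq.sum(axis=0)
    s1 = np.empty((F, M))
    q = sumsq.copy()
    s1[0] = q
    for tau in range(1, F):
        q = q - sq[tau - 1] - sq[F - tau]
        s1[tau] = q
    counts = (F - np.arange(F))[:, None]
    msd = (s1 - 2.0 * s2) / counts
    return msd.mean(axis=1)


def lateral_msd(
    traj: Trajectory,
    species: str,
    reference_site: Optional[str] = None,
    max_lag_fraction: float = 0.25,
    remove_com: bool = False,
) -> MSDSeries:
    """Lateral (xy) MSD of one species, averaged over molecules and origins.

    Reference-site positions are unwrapped across the periodic box by
    minimum-image displacement accumulation, then the MSD is computed over
    all time origins for lags up to ``max_lag_fraction`` of the trajectory
    length.  ``remove_com`` subtracts the per-leaflet mean displacement of
    the selected species before accumulating (drift removal).
    """
    if len(traj) < 2:
        raise ValueError("need at least two frames for an MSD")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    if reference_site is None:
        reference_site = REFERENCE_SITES.get(species)
        if reference_site is None:
            raise ValueError(f"no default reference site for {species!r}")
    idx = traj.catalog.select(species=species, site_name=reference_site)
    if len(idx) == 0:
        raise ValueError(
            f"species {species!r} with site {reference_site!r} not present"
        )
    traj.frame_interval()  # validates uniform sampling for origin averaging
    xy = np.asarray(traj.positions[:, idx, :2], dtype=np.float64)
    xy = _unwrap_lateral(xy, traj.boxes)
    if remove_com:
        z0 = traj.positions[0, idx, 2]
        upper = z0 > np.median(z0)
        for leaf in (upper, ~upper):
            if np.any(leaf):
                drift = xy[:, leaf, :].mean(axis=1, keepdims=True)
                xy[:, leaf, :] -= drift - drift[0]
    F = len(traj)
    max_lag = max(1, int(round(max_lag_fraction * (F - 1))))
    msd = _msd_fft(xy)[: max_lag + 1]
    msd[0] = 0.0  # exact by definition
    lags = traj.times[: max_lag + 1] - traj.times[0]
    return MSDSeries(
        lag_ps=lags, msd=msd, species=species, n_molecules=len(idx)
    )


def fit_diffusion(
    msd: MSDSeries, window: tuple[float, float] = (0.2, 0.8)
) -> DiffusionFit:
    """Fit D = slope/4 by OLS over a window of the lag-time range.

    ``window`` is given as fractions of the maximum lag; the default
    20–80 % band excludes the zero-lag point and the poorly sampled
    longest lags.
    """
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise ValueError(f"invalid window {window!r}")
    t_max = msd.lag_ps[-1]
    sel = (msd.lag_ps >= lo * t_max) & (msd.lag_ps <= hi * t_max)
    sel &= msd.lag_ps > 0
    if sel.sum() < 2:
        raise ValueError("fit window contains fewer than two MSD points")
    res = stats.linregress(msd.lag_ps[sel], msd.msd[sel])
    slope_per_ns = res.slope * 1e3  # Å^2/ps -> Å^2/ns
    return DiffusionFit(
        D=slope_per_ns / 4.0,
        D_se=res.stderr * 1e3 / 4.0,
        window_ps=(float(lo * t_max), float(hi * t_max)),
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
    )


def tilt_angles(
    traj: Trajectory,
    species: str,
    tilt_vector: tuple[str, str],
) -> np.ndarray:
    """Per-molecule, per-frame ring tilt angles in degrees, flattened.

    The angle is between the tail→head ring-axis vector and the bilayer
    normal z, folded to [0°, 90°] via |cos| so both leaflets pool.
    """
    tail_name, head_name = tilt_vector
    cat = traj.catalog
    i_tail = cat.select(species=species, site_name=tail_name)
    i_head = cat.select(species=species, site_name=head_name)
    if len(i_tail) == 0 or len(i_head) == 0:
        raise ValueError(
            f"tilt sites {tilt_vector!r} not present for species {species!r}"
        )
    if not np.array_equal(
        cat.molecule_ids[i_tail], cat.molecule_ids[i_head]
    ):
        order_t = np.argsort(cat.molecule_ids[i_tail])
        order_h = np.argsort(cat.molecule_ids[i_head])
        i_tail, i_head = i_tail[order_t], i_head[order_h]
    v = traj.positions[:, i_head, :] - traj.positions[:, i_tail, :]
    v = np.asarray(v, dtype=np.float64)
    norm = np.linalg.norm(v, axis=2)
    if np.any(norm == 0):
        raise ValueError("zero-length ring-axis vector encountered")
    cosang = np.abs(v[:, :, 2]) / norm
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))).ravel()


def sterol_tilt(
    traj: Trajectory,
    species: str,
    tilt_vector: tuple[str, str],
    bin_width: float = 2.0,
) -> TiltDistribution:
    """Normalized sterol tilt-angle histogram over [0°, 90°]."""
    angles = tilt_angles(traj, species, tilt_vector)
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    density, _ = np.histogram(angles, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return TiltDistribution(
        bin_centers=centers,
        density=density,
        bin_width=bin_width,
        mean_deg=float(np.mean(angles)),
        sd_deg=float(np.std(angles)),
        species=species,
        n_samples=len(angles),
    )


def bond_order_parameters(
    traj: Trajectory, bond_catalog: Optional[Iterable[Bond]] = None
) -> list[OrderParameterResult]:
    """Order parameter of each tail pseudobond, time- and ensemble-averaged.

    For each bond, θ is the angle between the inter-bead vector and the
    bilayer normal; ``standard_P2`` = ⟨(3cos²θ − 1)/2⟩ over all molecules
    and frames.  The catalog defaults to the phospholipid tails.
    """
    if bond_catalog is None:
        present = [
            sp
            for sp in ("POPC", "DPPC", "SM")
            if len(traj.catalog.molecules_of(sp)) > 0
        ]
        bond_catalog = default_bond_catalog(tuple(present))
    cat = traj.catalog
    results = []
    for bond in bond_catalog:
        i_a = cat.select(species=bond.species, site_name=bond.site_a)
        i_b = cat.select(species=bond.species, site_name=bond.site_b)
        if len(i_a) == 0 or len(i_b) == 0:
            raise ValueError(f"bond sites missing for {bond.label}")
        v = traj.positions[:, i_b, :] - traj.positions[:, i_a, :]
        v = np.asarray(v, dtype=np.float64)
        norm_sq = np.einsum("fmd,fmd->fm", v, v)
        if np.any(norm_sq == 0):
            raise ValueError(f"zero-length bond encountered for {bond.label}")
        cos_sq = v[:, :, 2] ** 2 / norm_sq
        p2 = float(np.mean(1.5 * cos_sq - 0.5))
        results.append(OrderParameterResult(bond=bond, standard_P2=p2))
    return results


def compare_groups(sample_a, sample_b) -> TTestResult:
    """Two-sided unpaired Student's t-test with pooled variance.

    Degenerate zero-variance pairs: equal means give (t, p) = (0, 1) by
    convention; unequal means give p = 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(t=0.0, p=1.0)
        return TTestResult(t=math.inf * np.sign(np.mean(a) - np.mean(b)), p=0.0)
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue))
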