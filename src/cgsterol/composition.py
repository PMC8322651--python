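"""Bilayer composition arithmetic from sterol lipidomics.

Mass-spectrometric sterol measurements come normalized as pmol sterol per
nmol of lipid phosphate.  Relative to 1000 pmol of phospholipid, a content
of S pmol therefore corresponds to a mole fraction S/(1000 + S) when the
membrane is treated as phospholipid + sterol only.  The functions here turn
such measurements into five-species bilayer compositions
(POPC/DPPC/SM/CHOL/7KC) and into realized per-leaflet molecule counts.

The phospholipid remainder (100 − sterols) is split 70:30 between
phosphatidylcholines and sphingomyelin, with the PC share further split
80:20 between POPC and DPPC — the endothelial-membrane proportions the
model systems are built on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = [
    "SPECIES",
    "SterolMeasurement",
    "BilayerComposition",
    "sterol_molpercent",
    "build_bilayer_composition",
    "realize_counts",
    "round_half_up",
    "reference_systems",
]

#: Canonical species order (also the apportionment tie-break order).
SPECIES = ("POPC", "DPPC", "SM", "CHOL", "7KC")

_PC_OF_REMAINDER = 0.7   # PC share of the phospholipid remainder
_SM_OF_REMAINDER = 0.3   # sphingomyelin share
_POPC_OF_PC = 0.8        # POPC share of the PC component
_DPPC_OF_PC = 0.2


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero-half going up (display convention)."""
    scale = 10.0 ** ndigits
    r = math.floor(x * scale + 0.5) / scale
    return r if ndigits > 0 else int(r)


@dataclass(frozen=True)
class SterolMeasurement:
    """A sterol content measurement in pmol sterol per nmol lipid phosphate."""

    sterol_name: str
    content: float  # pmol / nmol lipid P

    def __post_init__(self) -> None:
        if not math.isfinite(self.content) or self.content < 0:
            raise ValueError(
                f"sterol content must be a finite non-negative number, "
                f"got {self.content!r}"
            )

    @property
    def molpercent(self) -> float:
        return sterol_molpercent(self.content)


def sterol_molpercent(content: float) -> float:
    """Convert sterol content (pmol/nmol lipid P) to mol%.

    The membrane is taken to consist of phospholipid and the sterol only:
    S pmol of sterol per 1000 pmol phospholipid gives
    100·S/(1000 + S) mol%.

    Parameters
    ----------
    content : float
        Sterol content in pmol per nmol lipid phosphate (>= 0).
    """
    if not math.isfinite(content) or content < 0:
        raise ValueError(f"content must be finite and >= 0, got {content!r}")
    return 100.0 * content / (1000.0 + content)


@dataclass(frozen=True)
class BilayerComposition:
    """Mol% per species, optionally realized into per-leaflet counts.

    ``percents`` are the *unrounded* mole percentages; they must sum to 100.
    ``counts_per_leaflet`` (after :func:`realize_counts`) holds the integer
    number of molecules of each species in one leaflet; both leaflets are
    identical, so the system total is twice the leaflet sum.
    """

    percents: Mapping[str, float]
    counts_per_leaflet: Optional[Mapping[str, int]] = None
    total_molecules: Optional[int] = None
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        unknown = set(self.percents) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
        if any(p < 0 for p in self.percents.values()):
            raise ValueError("percents must be non-negative")
        total = sum(self.percents.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"percents must sum to 100, got {total!r}")
        if self.counts_per_leaflet is not None:
            if self.total_molecules is None:
                raise ValueError("realized composition needs total_molecules")
            leaflet = sum(self.counts_per_leaflet.values())
            if 2 * leaflet != self.total_molecules:
                raise ValueError(
                    f"2 x leaflet sum ({2 * leaflet}) != total_molecules "
                    f"({self.total_molecules})"
                )
            if any(c < 0 for c in self.counts_per_leaflet.values()):
                raise ValueError("counts must be non-negative")

    def percent(self, species: str) -> float:
        return float(self.percents.get(species, 0.0))

    def rounded_percents(self) -> dict[str, float]:
        """Display rounding: integer percent for phospholipids and CHOL,
        two decimals for the trace 7KC component."""
        out: dict[str, float] = {}
        for sp in SPECIES:
            p = self.percent(sp)
            out[sp] = round_half_up(p, 2) if sp == "7KC" else round_half_up(p)
        return out


def build_bilayer_composition(
    chol_percent: float, kc7_percent: float, name: str = ""
) -> BilayerComposition:
    """Build a five-species composition from the two sterol mol% values.

    The phospholipid remainder R = 100 − CHOL − 7KC is split
    POPC = 0.8·0.7·R, DPPC = 0.2·0.7·R, SM = 0.3·R.
    """
    if chol_percent < 0 or kc7_percent < 0:
        raise ValueError("sterol percents must be non-negative")
    if chol_percent + kc7_percent >= 100.0:
        raise ValueError(
            f"sterols must total < 100 mol%, got "
            f"{chol_percent + kc7_percent}"
        )
    remainder = 100.0 - chol_percent - kc7_percent
    percents = {
        "POPC": _POPC_OF_PC * _PC_OF_REMAINDER * remainder,
        "DPPC": _DPPC_OF_PC * _PC_OF_REMAINDER * remainder,
        "SM": _SM_OF_REMAINDER * remainder,
        "CHOL": float(chol_percent),
        "7KC": float(kc7_percent),
    }
    return BilayerComposition(percents=percents, name=name)


def realize_counts(
    comp: BilayerComposition, total_molecules: int
) -> BilayerComposition:
    """Apportion ``total_molecules`` into integer per-leaflet counts.

    Largest-remainder apportionment of ``total_molecules / 2`` over the
    species percents, with a floor of one molecule per leaflet for any
    species present at a positive percent (so trace sterols are never
    rounded away).  Ties in the fractional remainders are broken in
    :data:`SPECIES` order.  Both leaflets receive identical counts.
    """
    if total_molecules <= 0 or total_molecules % 2 != 0:
        raise ValueError(
            f"total_molecules must be a positive even integer, "
            f"got {total_molecules}"
        )
    per_leaflet = total_molecules // 2
    targets = {sp: comp.percent(sp) / 100.0 * per_leaflet for sp in SPECIES}
    floors = {
        sp: max(int(math.floor(t)), 1 if comp.percent(sp) > 0 else 0)
        for sp, t in targets.items()
    }
    seats = per_leaflet - sum(floors.values())
    if seats < 0:
        raise ValueError(
            f"cannot host {sum(1 for s in SPECIES if comp.percent(s) > 0)} "
            f"species in {per_leaflet} molecules per leaflet"
        )
    # Assign remaining seats by largest fractional remainder; species whose
    # floor was bumped to 1 already exceed their target and get remainder 0.
    remainders = {
        sp: max(targets[sp] - floors[sp], 0.0) for sp in SPECIES
    }
    order = sorted(SPECIES, key=lambda sp: (-remainders[sp], SPECIES.index(sp)))
    counts = dict(floors)
    for sp in order[:seats]:
        counts[sp] += 1
    if sum(counts.values()) != per_leaflet:
        raise ValueError("apportionment failed to conserve the total")
    return replace(
        comp, counts_per_leaflet=counts, total_molecules=total_molecules
    )


def reference_systems() -> dict[str, BilayerComposition]:
    """The four model bilayer systems built from the measured sterol contents.

    Cholesterol contents measured in endothelial cells were 608, 621 and
    760 pmol/nmol lipid P for control, 50 mg/dl LDL and 250 mg/dl LDL
    exposure; 7-ketocholesterol was 2.41 pmol/nmol at baseline, rising to
    21.03 pmol/nmol after oxLDL exposure.  The control and oxLDL systems
    use the 40 mol% cholesterol value of the published composition table
    (not re-derived from 608 pmol/nmol); LDL systems use the converted and
    display-rounded 38 / 43 mol%.
    """
    kc7_baseline = round_half_up(sterol_molpercent(2.41), 2)    # 0.24
    kc7_oxldl = round_half_up(sterol_molpercent(21.03), 2)      # 2.06
    chol_ldl50 = round_half_up(sterol_molpercent(621))          # 38
    chol_ldl250 = round_half_up(sterol_molpercent(760))         # 43
    return {
        "control": build_bilayer_composition(40.0, kc7_baseline, "control"),
        "oxLDL": build_bilayer_composition(40.0, kc7_oxldl, "oxLDL"),
        "LDL50": build_bilayer_composition(
            float(chol_ldl50), 0.04, "LDL50"
        ),
        "LDL250": build_bilayer_composition(
            float(chol_ldl250), 0.04, "LDL250"
        ),
    }
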