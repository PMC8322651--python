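"""Coarse-grained sterol topologies (MARTINI 2 virtual-site models).

The 7-ketocholesterol model is the virtual-site cholesterol topology with
the third interaction site (an SC3 ring bead) replaced by a heavier, more
polar SNa bead representing the ring ketone.  Only the site table (bead
type, name, mass) lives here; bonded and virtual-site geometry parameters
are inherited from the base cholesterol model and can be spliced in from a
user-supplied ITP file.

Each topology also records the ring-axis ("tilt") vector used by the
orientation analyzer: K5→KOH for 7-ketocholesterol, R5→ROH for cholesterol,
approximating the C17→C3 axis of the sterol ring system.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

__all__ = [
    "BEAD_TYPES",
    "CGSite",
    "CGTopology",
    "build_7kc_topology",
    "build_chol_reference",
    "write_topology",
    "read_topology",
    "diff_sites",
    "splice_into_base",
]

#: MARTINI 2 bead types used by the sterol models (S-prefixed = small beads).
BEAD_TYPES = frozenset({"SP1", "SC1", "SC3", "SNa", "C1"})


@dataclass(frozen=True)
class CGSite:
    """One interaction site: 1-based index, bead type, name, mass (u).

    Zero mass marks a virtual site whose position is constructed
    geometrically from the mass-carrying sites.
    """

    index: int
    bead_type: str
    name: str
    mass: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"site index must be 1-based, got {self.index}")
        if self.bead_type not in BEAD_TYPES:
            raise ValueError(
                f"unknown bead type {self.bead_type!r}; "
                f"expected one of {sorted(BEAD_TYPES)}"
            )
        if self.mass < 0:
            raise ValueError(f"mass must be >= 0, got {self.mass}")


@dataclass(frozen=True)
class CGTopology:
    """Ordered site table for one sterol plus its ring-axis marker sites."""

    sterol_name: str
    sites: tuple[CGSite, ...]
    tilt_vector: tuple[str, str]  # (tail_site_name, head_site_name)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("topology needs at least one site")
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError(f"site names must be unique, got {names}")
        if list(s.index for s in self.sites) != list(
            range(1, len(self.sites) + 1)
        ):
            raise ValueError("site indices must be 1..n in order")
        if self.total_mass <= 0:
            raise ValueError("total mass must be positive")
        for marker in self.tilt_vector:
            if marker not in names:
                raise ValueError(
                    f"tilt-vector site {marker!r} not among sites {names}"
                )

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.sites)

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sites)

    def site(self, name: str) -> CGSite:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)

    def virtual_site_names(self) -> set[str]:
        return {s.name for s in self.sites if s.mass == 0}


# (bead type, name, mass) rows of the published 7-ketocholesterol table.
_7KC_ROWS = (
    ("SP1", "KOH", 77.22),
    ("SC1", "K1", 0.0),
    ("SNa", "K2", 52.66),
    ("SC1", "K3", 159.65),
    ("SC1", "K4", 0.0),
    ("SC1", "K5", 0.0),
    ("SC1", "KC1", 39.44),
    ("C1", "KC2", 72.0),
)

# Virtual-site cholesterol reference.  Masses are embedded defaults chosen
# so that the nonzero masses sum to cholesterol's molecular mass (387.0 u)
# and the site-3 7KC substitution (SC3 -> SNa) carries the ketone mass
# shift (+O, -2H = +13.97 u); supply a base ITP to override.
_CHOL_ROWS = (
    ("SP1", "ROH", 77.22),
    ("SC1", "R1", 0.0),
    ("SC3", "R2", 38.69),
    ("SC1", "R3", 159.65),
    ("SC1", "R4", 0.0),
    ("SC1", "R5", 0.0),
    ("SC1", "C1", 39.44),
    ("C1", "C2", 72.0),
)


def _from_rows(name, rows, tilt):
    sites = tuple(
        CGSite(i + 1, bead, site_name, mass)
        for i, (bead, site_name, mass) in enumerate(rows)
    )
    return CGTopology(sterol_name=name, sites=sites, tilt_vector=tilt)


def build_7kc_topology() -> CGTopology:
    """The eight-site 7-ketocholesterol model with tilt vector (K5, KOH)."""
    return _from_rows("7KC", _7KC_ROWS, ("K5", "KOH"))


def build_chol_reference(sites: Optional[Iterable[CGSite]] = None) -> CGTopology:
    """Virtual-site cholesterol reference with tilt vector (R5, ROH).

    Pass ``sites`` to use masses from an external base model; otherwise
    the embedded defaults are used.
    """
    if sites is None:
        return _from_rows("CHOL", _CHOL_ROWS, ("R5", "ROH"))
    return CGTopology(
        sterol_name="CHOL", sites=tuple(sites), tilt_vector=("R5", "ROH")
    )


def _format_topology(topo: CGTopology) -> str:
    lines = [
        "[ moleculetype ]",
        "; molname  nrexcl",
        f"{topo.sterol_name}  1",
        "",
        "[ atoms ]",
        ";  nr  type  name  mass",
    ]
    for s in topo.sites:
        lines.append(f"{s.index:5d}  {s.bead_type:<4s}  {s.name:<4s}  {s.mass:.2f}")
    return "\n".join(lines) + "\n"


def write_topology(
    topo: CGTopology, destination: Union[str, Path, TextIO, None] = None
) -> str:
    """Serialize ``topo`` as an ITP-style ``[atoms]`` block.

    Returns the text; if ``destination`` is a path or stream, also writes it.
    Masses are formatted to two decimals.
    """
    text = _format_topology(topo)
    if destination is None:
        return text
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)
    return text


class TopologyParseError(ValueError):
    """Malformed topology text; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _infer_tilt_vector(names: Iterable[str]) -> tuple[str, str]:
    names = set(names)
    if {"K5", "KOH"} <= names:
        return ("K5", "KOH")
    if {"R5", "ROH"} <= names:
        return ("R5", "ROH")
    raise ValueError(
        "cannot infer ring-axis marker sites (need K5/KOH or R5/ROH); "
        "pass tilt_vector explicitly"
    )


def read_topology(
    source: Union[str, Path, TextIO],
    tilt_vector: Optional[tuple[str, str]] = None,
) -> CGTopology:
    """Parse an ITP-style topology written by :func:`write_topology`.

    ``source`` may be a path, a file object, or the topology text itself
    (anything containing a newline is treated as text).
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        text = source if "\n" in source else Path(source).read_text()
    else:
        text = source.read()

    section = None
    molname = None
    sites: list[CGSite] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        m = re.match(r"\[\s*(\w+)\s*\]", line)
        if m:
            section = m.group(1).lower()
            continue
        if section == "moleculetype":
            molname = line.split()[0]
        elif section == "atoms":
            parts = line.split()
            if len(parts) < 4:
                raise TopologyParseError(
                    f"atom line needs 4 fields (nr type name mass), "
                    f"got {len(parts)}: {raw!r}",
                    lineno,
                )
            try:
                idx = int(parts[0])
                mass = float(parts[3])
            except ValueError as exc:
                raise TopologyParseError(str(exc), lineno) from None
            try:
                sites.append(CGSite(idx, parts[1], parts[2], mass))
            except ValueError as exc:
                raise TopologyParseError(str(exc), lineno) from None
    if not sites:
        raise TopologyParseError("no [atoms] entries found", 1)
    if tilt_vector is None:
        tilt_vector = _infer_tilt_vector(s.name for s in sites)
    return CGTopology(
        sterol_name=molname or "sterol",
        sites=tuple(sites),
        tilt_vector=tilt_vector,
    )


def diff_sites(a: CGTopology, b: CGTopology) -> list[int]:
    """1-based indices where two topologies differ in (bead type, mass).

    Site names are excluded from the comparison because homologous sterol
    models carry a systematic name-prefix relabel (K* vs R*).
    """
    if len(a.sites) != len(b.sites):
        raise ValueError(
            f"site counts differ: {len(a.sites)} vs {len(b.sites)}"
        )
    return [
        sa.index
        for sa, sb in zip(a.sites, b.sites)
        if (sa.bead_type, sa.mass) != (sb.bead_type, sb.mass)
    ]


def splice_into_base(base_itp_text: str, topo: CGTopology) -> str:
    """Replace the ``[atoms]`` entries of a base sterol ITP with ``topo``'s.

    The bonded/constraint/virtual-site sections of the base model are kept
    verbatim (the adapted sterol inherits all geometry from its parent
    model); only the atom rows and the molecule name are rewritten.  The
    base file must have the same number of atom rows as ``topo`` has sites.
    """
    out_lines: list[str] = []
    section = None
    atom_rows_seen = 0
    replaced_name = False
    for raw in base_itp_text.splitlines():
        stripped = raw.split(";", 1)[0].strip()
        m = re.match(r"\[\s*(\w+)\s*\]", stripped) if stripped else None
        if m:
            section = m.group(1).lower()
            out_lines.append(raw)
            continue
        if section == "moleculetype" and stripped and not replaced_name:
            out_lines.append(f"{topo.sterol_name}  {stripped.split()[-1]}")
            replaced_name = True
            continue
        if section == "atoms" and stripped:
            if atom_rows_seen >= len(topo.sites):
                raise ValueError(
                    "base topology has more atom rows than the new site table"
                )
            s = topo.sites[atom_rows_seen]
            # Preserve any extra columns (residue/charge fields) of the base.
            parts = stripped.split()
            extras = parts[4:] if len(parts) > 4 else []
            row = f"{s.index:5d}  {s.bead_type:<4s}  {s.name:<4s}  {s.mass:.2f}"
            if extras:
                row += "  " + "  ".join(extras)
            out_lines.append(row)
            atom_rows_seen += 1
            continue
        out_lines.append(raw)
    if atom_rows_seen != len(topo.sites):
        raise ValueError(
            f"base topology has {atom_rows_seen} atom rows, "
            f"expected {len(topo.sites)}"
        )
    return "\n".join(out_lines) + "\n"
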