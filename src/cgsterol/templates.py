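"""Per-species coarse-grained site templates and the tail-bond catalog.

The templates are minimal MARTINI-style bead chains: headgroup (NC3),
phosphate (PO4), glycerol/amide backbone (GL1/GL2 or AM1/AM2), and acyl
tail beads.  The sn-2 chain is the A chain, the sn-1 chain the B chain;
pseudobonds connect consecutive tail beads and are indexed from the
glycerol end (bond 1 = first tail bead pair).  Sterols carry ring-axis
marker sites (ROH/R5 or KOH/K5) and no catalogued tail bonds.

Only site names, adjacency, and marker roles matter to the analyzers; the
templates make no claim about physical MARTINI geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Bond",
    "SpeciesTemplate",
    "TEMPLATES",
    "PHOSPHATE_SITE",
    "REFERENCE_SITES",
    "tail_bonds",
    "default_bond_catalog",
]

#: Phosphate bead name shared by all phospholipid templates.
PHOSPHATE_SITE = "PO4"


@dataclass(frozen=True)
class Bond:
    """One tail pseudobond of a species: (tail label, 1-based index, sites)."""

    species: str
    tail: str  # "sn2" (A chain) or "sn1" (B chain)
    index: int
    site_a: str
    site_b: str

    @property
    def label(self) -> str:
        return f"{self.species}/{self.tail}/bond{self.index}"


@dataclass(frozen=True)
class SpeciesTemplate:
    """Site layout of one molecular species."""

    name: str
    head_sites: tuple[str, ...]        # headgroup + backbone, in order
    tails: dict[str, tuple[str, ...]]  # tail label -> bead chain
    reference_site: str                # anchor for diffusion / leaflets
    is_sterol: bool = False
    tilt_vector: tuple[str, str] | None = None  # (deep site, head site)

    @property
    def sites(self) -> tuple[str, ...]:
        out = list(self.head_sites)
        for chain in self.tails.values():
            out.extend(chain)
        return tuple(out)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


TEMPLATES: dict[str, SpeciesTemplate] = {
    "POPC": SpeciesTemplate(
        name="POPC",
        head_sites=("NC3", "PO4", "GL1", "GL2"),
        tails={
            "sn2": ("C1A", "D2A", "C3A", "C4A"),  # oleoyl, D = cis bead
            "sn1": ("C1B", "C2B", "C3B", "C4B"),  # palmitoyl
        },
        reference_site="PO4",
    ),
    "DPPC": SpeciesTemplate(
        name="DPPC",
        head_sites=("NC3", "PO4", "GL1", "GL2"),
        tails={
            "sn2": ("C1A", "C2A", "C3A", "C4A"),
            "sn1": ("C1B", "C2B", "C3B", "C4B"),
        },
        reference_site="PO4",
    ),
    "SM": SpeciesTemplate(
        name="SM",
        head_sites=("NC3", "PO4", "AM1", "AM2"),
        tails={
            "sn2": ("T1A", "C2A", "C3A"),          # sphingosine
            "sn1": ("C1B", "C2B", "C3B", "C4B"),   # stearoyl
        },
        reference_site="PO4",
    ),
    "CHOL": SpeciesTemplate(
        name="CHOL",
        head_sites=("ROH", "R1", "R2", "R3", "R4", "R5", "C1", "C2"),
        tails={},
        reference_site="ROH",
        is_sterol=True,
        tilt_vector=("R5", "ROH"),
    ),
    "7KC": SpeciesTemplate(
        name="7KC",
        head_sites=("KOH", "K1", "K2", "K3", "K4", "K5", "KC1", "KC2"),
        tails={},
        reference_site="KOH",
        is_sterol=True,
        tilt_vector=("K5", "KOH"),
    ),
}

#: Default per-species reference site (leaflet assignment, diffusion anchor).
REFERENCE_SITES = {name: t.reference_site for name, t in TEMPLATES.items()}


def tail_bonds(species: str) -> list[Bond]:
    """Consecutive-bead pseudobonds of one species' tails, indexed from 1."""
    t = TEMPLATES[species]
    bonds = []
    for tail, chain in t.tails.items():
        for i in range(len(chain) - 1):
            bonds.append(Bond(species, tail, i + 1, chain[i], chain[i + 1]))
    return bonds


def default_bond_catalog(
    species: tuple[str, ...] = ("POPC", "DPPC", "SM")
) -> list[Bond]:
    """Tail-bond catalog over the phospholipid species (sterols have none)."""
    out: list[Bond] = []
    for sp in species:
        out.extend(tail_bonds(sp))
    return out
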