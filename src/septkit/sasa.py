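"""Solvent-accessible surface area by the Shrake-Rupley method.

For each heavy atom a quasi-uniform point set is placed on the sphere of
radius (vdW + probe); the accessible fraction is the share of points not
inside any neighbouring atom's expanded sphere, and the atom's SASA is that
fraction times the full sphere area.  Residue areas are atom sums; relative
SASA divides by the residue type's theoretical maximum in a Gly-X-Gly
extended reference (Tien et al. 2013), so a fully exposed residue sits near
100% and an interface residue buried in a complex near 0%.

The burial bands used for septin NC-interface work: deeply buried residues
have relative SASA at or below 7%, exposed ones at or above 25%; the band in
between (e.g. the 14% and 19% crest-adjacent leucines) is "intermediate" —
contributing to, but not essential for, the hydrophobic interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure

__all__ = [
    "SasaParams",
    "SasaProfile",
    "DEFAULT_RADII",
    "MAX_SASA_GXG",
    "atom_sasa",
    "relative_residue_sasa",
    "burial_class",
    "buried_interface_area",
]

# van der Waals radii (Å) for the heavy elements found in protein models
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75,
    "BR": 1.85, "I": 1.98, "MG": 1.73, "ZN": 1.39,
    "CA": 2.31, "NA": 2.27, "K": 2.75, "MN": 1.97, "FE": 1.94,
}

# Theoretical maximum SASA (Å²) per residue in an extended Gly-X-Gly context
# (Tien et al. 2013, "theoretical" column) — the normalisation reference for
# relative SASA.
MAX_SASA_GXG: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

BURIED_MAX_PCT = 7.0    # deeply buried band upper edge
EXPOSED_MIN_PCT = 25.0  # conventional solvent-exposed threshold


@dataclass
class SasaParams:
    """Shrake-Rupley parameters.

    probe_radius: solvent probe in Å (water, 1.4 Å).
    sphere_points: samples per atomic sphere; 960 converges atom areas to
    well under 1%.
    radii_table: element symbol → van der Waals radius in Å.
    """

    probe_radius: float = 1.4
    sphere_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.sphere_points < 60:
            raise ValueError("sphere_points must be >= 60")


@dataclass
class SasaProfile:
    """Per-residue absolute (Å²) and relative (%) SASA in a given context."""

    per_residue: list[tuple[str, int, str, float, float | None]]
    context: str  # "full_complex" or "isolated_chain"

    def lookup(self, residue_number: int) -> tuple[float, float | None]:
        for _, num, _, abs_a, rel in self.per_residue:
            if num == residue_number:
                return abs_a, rel
        raise KeyError(f"residue {residue_number} not in profile")


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral / Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _collect_heavy_atoms(structure: Structure, params: SasaParams):
    coords, radii, owner = [], [], []
    for cid, res, atom in structure.all_atoms():
        el = atom.element.upper()
        if el == "H" or el == "D":
            continue
        if el not in params.radii_table:
            raise ValueError(
                f"no van der Waals radius for element {atom.element!r} "
                f"(atom {atom.name}, residue {res.name}{res.number}, chain {cid})"
            )
        coords.append(atom.position)
        radii.append(params.radii_table[el])
        owner.append((cid, res, atom))
    return np.asarray(coords, float), np.asarray(radii, float), owner


def atom_sasa(structure: Structure, params: SasaParams | None = None
              ) -> list[tuple[str, int, str, str, float]]:
    """Per-heavy-atom SASA as (chain_id, residue_number, residue_name, atom_name, Å²).

    Hydrogens are ignored (crystal structures carry none; comparability).
    """
    params = params or SasaParams()
    coords, radii, owner = _collect_heavy_atoms(structure, params)
    areas = _shrake_rupley(coords, radii, params)
    return [
        (cid, res.number, res.name, atom.name, float(a))
        for (cid, res, atom), a in zip(owner, areas)
    ]


def _shrake_rupley(coords: np.ndarray, radii: np.ndarray, params: SasaParams) -> np.ndarray:
    n = len(coords)
    if n == 0:
        return np.empty(0)
    unit = sphere_points(params.sphere_points)
    expanded = radii + params.probe_radius
    tree = cKDTree(coords)
    areas = np.empty(n)
    for i in range(n):
        r_i = expanded[i]
        pts = coords[i] + r_i * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], r_i + expanded.max())
                     if j != i]
        accessible = np.ones(params.sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * np.pi * r_i**2
    return areas


def relative_residue_sasa(structure: Structure, chain_id: str,
                          params: SasaParams | None = None,
                          context: str = "full_complex") -> SasaProfile:
    """Per-residue SASA of one chain, absolute and relative.

    ``context="full_complex"`` computes atom areas with all chains present
    (interface burial shows up); ``"isolated_chain"`` strips every other
    chain first.  Relative SASA is the residue sum divided by the Gly-X-Gly
    theoretical maximum, in percent; nonstandard residues (no reference
    value) report absolute area only (relative = None).
    """
    params = params or SasaParams()
    chain = structure.chain(chain_id)  # raises KeyError if absent
    if context == "isolated_chain":
        target = Structure(identifier=structure.identifier, chains=[chain])
    elif context == "full_complex":
        target = structure
    else:
        raise ValueError(f"unknown context {context!r}")

    atom_areas = atom_sasa(target, params)
    per_res: dict[tuple[int, str], float] = {}
    for cid, resnum, resname, _, area in atom_areas:
        if cid != chain_id:
            continue
        per_res[(resnum, resname)] = per_res.get((resnum, resname), 0.0) + area

    rows = []
    for res in chain.residues:
        key = (res.number, res.name)
        if key not in per_res:
            continue
        abs_area = per_res[key]
        ref = MAX_SASA_GXG.get(res.name)
        rel = 100.0 * abs_area / ref if ref else None
        rows.append((chain_id, res.number, res.name, abs_area, rel))
    return SasaProfile(per_residue=rows, context=context)


def burial_class(relative_sasa: float, buried_max: float = BURIED_MAX_PCT,
                 exposed_min: float = EXPOSED_MIN_PCT) -> str:
    """Classify a relative SASA percentage as buried / intermediate / exposed."""
    if relative_sasa < 0:
        raise ValueError("relative SASA cannot be negative")
    if relative_sasa <= buried_max:
        return "buried"
    if relative_sasa >= exposed_min:
        return "exposed"
    return "intermediate"


def buried_interface_area(structure: Structure, params: SasaParams | None = None) -> float:
    """Half the SASA lost on complexation: 0.5 * (sum of isolated-chain areas - complex area)."""
    params = params or SasaParams()
    complex_total = sum(a for *_, a in atom_sasa(structure, params))
    isolated_total = 0.0
    for chain in structure.chains:
        sub = Structure(identifier=structure.identifier, chains=[chain])
        isolated_total += sum(a for *_, a in atom_sasa(sub, params))
    return 0.5 * (isolated_total - complex_total)
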