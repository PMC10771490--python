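"""Geometric screening for engineerable inter-chain disulfide bridges.

A pair of residues on opposite sides of an interface can be crosslinked by
mutating both to cysteine when their beta-carbons sit near the ideal
disulfide CB-CB separation of about 4.0 Å.  Because the pre-mutation side
chains are not cysteines, the screen uses a deliberately wide window
(default 3.0-5.5 Å) with a CA-CA <= 7.5 Å secondary filter, and ranks
candidates by |CB-CB - 4.0| Å.  Glycines receive a virtual CB placed at
ideal tetrahedral geometry from their backbone so every position is screened
symmetrically.  No side-chain dihedral modelling is attempted: the output is
a geometric candidate list, not a probability.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import Residue, Structure

__all__ = [
    "DisulfideCandidate",
    "screen_interchain_pairs",
    "virtual_cb",
    "IDEAL_SS_CB_CB",
]

IDEAL_SS_CB_CB = 4.0   # Å, typical CB-CB separation across a disulfide bond
_CB_BOND_LENGTH = 1.53  # Å, CA-CB


@dataclass
class DisulfideCandidate:
    """One inter-chain residue pair geometrically compatible with a disulfide."""

    chain_a: str
    residue_number_a: int
    residue_name_a: str
    chain_b: str
    residue_number_b: int
    residue_name_b: str
    cb_cb_distance: float
    ca_ca_distance: float

    @property
    def geometry_penalty(self) -> float:
        return abs(self.cb_cb_distance - IDEAL_SS_CB_CB)

    @property
    def pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.chain_a, self.residue_number_a),
                (self.chain_b, self.residue_number_b))


def virtual_cb(residue: Residue) -> np.ndarray | None:
    """CB position, reconstructing a virtual one for glycine.

    The virtual CB is placed from N, CA and C at ideal tetrahedral geometry
    (1.53 Å bond): along the negative bisector of the N-CA-C angle, tilted
    out of the N-CA-C plane the way a real CB sits.  Returns None when
    neither a CB nor a complete backbone is available.
    """
    cb = residue.atom("CB")
    if cb is not None:
        return cb.position
    n, ca, c = residue.atom("N"), residue.atom("CA"), residue.atom("C")
    if n is None or ca is None or c is None:
        return None
    u = n.position - ca.position
    v = c.position - ca.position
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    bisector = -(u + v)
    bn = np.linalg.norm(bisector)
    perp = np.cross(u, v)
    pn = np.linalg.norm(perp)
    if bn < 1e-8 or pn < 1e-8:
        return None
    bisector /= bn
    perp /= pn
    # ~54.75 degrees out-of-plane tilt reproduces real CB placement closely
    direction = np.cos(np.deg2rad(54.75)) * bisector + np.sin(np.deg2rad(54.75)) * perp
    return ca.position + _CB_BOND_LENGTH * direction / np.linalg.norm(direction)


def _screen_points(chain) -> list[tuple[Residue, np.ndarray, np.ndarray]]:
    out = []
    for res in chain.polymer_residues():
        ca = res.atom("CA")
        cb = virtual_cb(res)
        if ca is None or cb is None:
            warnings.warn(
                f"chain {chain.chain_id} residue {res.name}{res.number}: "
                "no CB and backbone incomplete; skipped from disulfide screen",
                stacklevel=3,
            )
            continue
        out.append((res, ca.position, cb))
    return out


def screen_interchain_pairs(structure: Structure, chain_a: str, chain_b: str,
                            cb_min: float = 3.0, cb_max: float = 5.5,
                            ca_max: float = 7.5) -> list[DisulfideCandidate]:
    """All inter-chain residue pairs within disulfide-compatible geometry.

    Returns pairs with cb_min <= CB-CB <= cb_max and CA-CA <= ca_max, ranked
    by ascending |CB-CB - 4.0| with a deterministic (chain, resnum) tie-break.
    Screening (A, B) and (B, A) yields the same pairs.
    """
    if cb_min <= 0 or cb_min > cb_max:
        raise ValueError("need 0 < cb_min <= cb_max")
    if chain_a == chain_b:
        raise ValueError("disulfide screen is inter-chain: chains must differ")
    # canonical chain order makes the output orientation-independent
    first, second = sorted((chain_a, chain_b))
    points_a = _screen_points(structure.chain(first))
    points_b = _screen_points(structure.chain(second))

    candidates = []
    for (res_a, ca_a, cb_a), (res_b, ca_b, cb_b) in itertools.product(points_a, points_b):
        cb_d = float(np.linalg.norm(cb_a - cb_b))
        if not cb_min <= cb_d <= cb_max:
            continue
        ca_d = float(np.linalg.norm(ca_a - ca_b))
        if ca_d > ca_max:
            continue
        candidates.append(DisulfideCandidate(
            chain_a=first, residue_number_a=res_a.number, residue_name_a=res_a.name,
            chain_b=second, residue_number_b=res_b.number, residue_name_b=res_b.name,
            cb_cb_distance=cb_d, ca_ca_distance=ca_d,
        ))
    candidates.sort(key=lambda c: (c.geometry_penalty, c.chain_a, c.residue_number_a,
                                   c.chain_b, c.residue_number_b))
    return candidates
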