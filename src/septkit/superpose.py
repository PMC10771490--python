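"""Rigid-body superposition, RMSD-Cα statistics and complex grafting.

Two homologous septin chains (e.g. Shs1 vs Cdc11) rarely share residue
numbering, so superposition starts from an explicit residue pairing: either
identical author numbers (``by_number``) or the non-gap columns of a global
pairwise sequence alignment (``by_alignment``).  The optimal proper rotation
is the closed-form Kabsch solution; reflections are never returned.  The
per-residue deviation profile after global superposition is the quantity
plotted when comparing two conformations of the same fold region by region.

Grafting assembles a larger complex from two partial structures that share a
subunit: the addon structure is rigidly moved so its copy of the shared chain
superposes onto the base's copy, and the remaining addon chains are merged in.
This is how an octameric septin rod is modelled from a crystallographic
tetramer plus a predicted central homodimer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .structure_io import Atom, Chain, Residue, Structure, sequence_string, THREE_TO_ONE

__all__ = [
    "ResiduePairing",
    "SuperpositionResult",
    "RmsdProfile",
    "InsufficientPairsError",
    "pair_residues",
    "kabsch_superpose",
    "per_residue_rmsd",
    "assemble_by_grafting",
    "superpose_chains",
]

# Scoring contract for by_alignment pairing: match +1, mismatch 0, gap -1,
# no affine gap model. Deterministic for the high-identity homologs compared.
_ALIGN_MATCH = 1.0
_ALIGN_MISMATCH = 0.0
_ALIGN_GAP = -1.0


class InsufficientPairsError(ValueError):
    """Fewer than 3 residue pairs — superposition is underdetermined."""


@dataclass
class ResiduePairing:
    """Ordered CA-bearing residue pairs between two chains.

    ``pairs`` holds ``(residue_number_a, residue_number_b)`` tuples, strictly
    increasing in both columns. ``alignment_identity`` is the fraction of
    paired positions with identical one-letter codes.
    """

    pairs: list[tuple[int, int]]
    method: str
    alignment_identity: float

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping *moving* onto *fixed*.

    ``rotation`` is a proper (det=+1) orthonormal 3x3 matrix; a moving point
    x maps to ``rotation @ x + translation``. ``rmsd_ca`` is the minimised
    RMSD over the paired CA atoms.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_ca: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class RmsdProfile:
    """Per-residue CA deviations after global superposition."""

    per_residue: list[tuple[int, int, float]]

    @property
    def deviations(self) -> np.ndarray:
        return np.array([d for _, _, d in self.per_residue])

    def rms(self) -> float:
        d = self.deviations
        return float(np.sqrt(np.mean(d**2)))


def _ca_map(chain: Chain) -> dict[tuple[int, str], np.ndarray]:
    out = {}
    for res in chain.polymer_residues():
        ca = res.ca
        if ca is not None:
            out[res.key] = ca.position
    return out


def _chain_sequence(chain: Chain) -> tuple[str, list[tuple[int, str]]]:
    """One-letter sequence over CA-bearing polymer residues plus their keys."""
    seq = []
    keys = []
    for res in chain.polymer_residues():
        if res.ca is None:
            continue
        seq.append(THREE_TO_ONE.get(res.name, "X"))
        keys.append(res.key)
    return "".join(seq), keys


def pair_residues(chain_a: Chain, chain_b: Chain, method: str = "by_alignment") -> ResiduePairing:
    """Pair CA-bearing residues of two chains.

    ``by_number`` pairs identical (residue_number, insertion_code);
    ``by_alignment`` globally aligns the one-letter sequences (match +1,
    mismatch 0, gap -1) and pairs aligned non-gap columns.
    """
    seq_a, keys_a = _chain_sequence(chain_a)
    seq_b, keys_b = _chain_sequence(chain_b)
    if len(keys_a) < 3 or len(keys_b) < 3:
        raise InsufficientPairsError("both chains need >=3 CA-bearing residues")

    if method == "by_number":
        set_b = {k: i for i, k in enumerate(keys_b)}
        pairs_idx = [(i, set_b[k]) for i, k in enumerate(keys_a) if k in set_b]
    elif method == "by_alignment":
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = _ALIGN_MATCH
        aligner.mismatch_score = _ALIGN_MISMATCH
        aligner.open_gap_score = _ALIGN_GAP
        aligner.extend_gap_score = _ALIGN_GAP
        alignment = aligner.align(seq_a, seq_b)[0]
        pairs_idx = [(int(i), int(j)) for i, j in np.transpose(alignment.indices)
                     if i >= 0 and j >= 0]
    else:
        raise ValueError(f"unknown pairing method {method!r}")

    if len(pairs_idx) < 3:
        raise InsufficientPairsError(f"only {len(pairs_idx)} residue pairs")
    identical = sum(1 for i, j in pairs_idx if seq_a[i] == seq_b[j])
    pairs = [(keys_a[i][0], keys_b[j][0]) for i, j in pairs_idx]
    return ResiduePairing(
        pairs=pairs, method=method, alignment_identity=identical / len(pairs_idx)
    )


def kabsch_superpose(fixed: np.ndarray, moving: np.ndarray) -> SuperpositionResult:
    """Optimal proper rigid superposition of paired point sets (Kabsch).

    Centroids are removed, the cross-covariance is decomposed by SVD, and the
    sign of the smallest singular direction is flipped if the raw optimum is a
    reflection, guaranteeing det(R) = +1.  Degenerate (collinear) input yields
    a warning but still returns the least-squares proper rotation.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ or are not Nx3: {fixed.shape} vs {moving.shape}")
    n = fixed.shape[0]
    if n < 3:
        raise InsufficientPairsError("need >=3 paired points")
    if not (np.all(np.isfinite(fixed)) and np.all(np.isfinite(moving))):
        raise ValueError("non-finite coordinates")

    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    x = moving - cm
    y = fixed - cf
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    # rank deficiency (collinear/coplanar points) leaves a rotation d.o.f. free
    if s[-1] < 1e-10 * max(s[0], 1.0):
        warnings.warn("degenerate (collinear) point set; rotation not unique", stacklevel=2)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cf - rotation @ cm
    moved = x @ rotation.T + cf
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd_ca=rmsd, n_pairs=n)


def _paired_coords(pairing: ResiduePairing, fixed: Chain, moving: Chain):
    map_f = {k[0]: v for k, v in _ca_map(fixed).items()}
    map_m = {k[0]: v for k, v in _ca_map(moving).items()}
    try:
        cf = np.array([map_f[a] for a, _ in pairing.pairs])
        cm = np.array([map_m[b] for _, b in pairing.pairs])
    except KeyError as exc:
        raise ValueError(f"pairing references residue {exc} absent from chain") from exc
    return cf, cm


def superpose_chains(fixed: Chain, moving: Chain, method: str = "by_alignment"
                     ) -> tuple[ResiduePairing, SuperpositionResult]:
    """Pair residues then superpose: the common two-chain entry point."""
    pairing = pair_residues(fixed, moving, method=method)
    cf, cm = _paired_coords(pairing, fixed, moving)
    return pairing, kabsch_superpose(cf, cm)


def per_residue_rmsd(pairing: ResiduePairing, fixed: Chain, moving: Chain,
                     transform: SuperpositionResult) -> RmsdProfile:
    """CA deviation per residue pair after applying ``transform`` to *moving*.

    The RMS of the profile reproduces ``transform.rmsd_ca`` when the transform
    was computed from the same pairing.
    """
    if transform.n_pairs != len(pairing):
        raise ValueError("transform was not produced from this pairing")
    cf, cm = _paired_coords(pairing, fixed, moving)
    moved = transform.apply(cm)
    dev = np.sqrt(np.sum((moved - cf) ** 2, axis=1))
    return RmsdProfile(per_residue=[
        (a, b, float(d)) for (a, b), d in zip(pairing.pairs, dev)
    ])


# heavy-atom centre distance below which two atoms of unrelated chains count
# as a steric clash
_CLASH_CUTOFF = 2.2


def _heavy_atom_coords(structure: Structure, chain_id: str) -> np.ndarray:
    coords = [atom.position for cid, res, atom in structure.all_atoms()
              if cid == chain_id and atom.element != "H"]
    return np.array(coords) if coords else np.empty((0, 3))


def _fresh_chain_id(used: set[str]) -> str:
    for cid in "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789":
        if cid not in used:
            return cid
    i = 0
    while f"X{i}" in used:
        i += 1
    return f"X{i}"


def _copy_chain(chain: Chain, new_id: str) -> Chain:
    return Chain(chain_id=new_id, residues=[
        Residue(number=r.number, name=r.name, insertion_code=r.insertion_code,
                is_polymer=r.is_polymer,
                atoms=[Atom(name=a.name, element=a.element,
                            position=a.position.copy(), occupancy=a.occupancy,
                            b_factor=a.b_factor, altloc=a.altloc)
                       for a in r.atoms])
        for r in chain.residues
    ])


@dataclass
class GraftResult:
    structure: Structure
    graft_rmsd_ca: float
    clash_count: int
    chain_id_map: dict[str, str]


def assemble_by_grafting(base: Structure, addon: Structure,
                         shared_base_chain: str, shared_addon_chain: str,
                         identity_threshold: float = 0.9) -> GraftResult:
    """Merge two structures through a shared subunit.

    The addon is rigidly transformed so its ``shared_addon_chain`` superposes
    onto the base's ``shared_base_chain`` (all-CA Kabsch after alignment
    pairing); the addon's other chains are appended under fresh chain IDs.
    The shared addon chain itself is dropped — the base copy represents it.

    Returns the merged structure, the graft RMSD-Cα, a steric-clash count
    (heavy-atom pairs closer than 2.2 Å between chains that did not coexist in
    either input) and the addon→merged chain ID map.  Refuses to graft if the
    aligned sequence identity of the shared chains is below
    ``identity_threshold`` (default 90%): grafting only makes sense through
    two copies of the same protein.
    """
    base_chain = base.chain(shared_base_chain)
    addon_chain = addon.chain(shared_addon_chain)
    pairing, transform = superpose_chains(base_chain, addon_chain, method="by_alignment")
    if pairing.alignment_identity < identity_threshold:
        raise ValueError(
            f"shared chains are only {pairing.alignment_identity:.0%} identical "
            f"(need >= {identity_threshold:.0%}); they do not look like the same protein"
        )

    merged = Structure(identifier=f"{base.identifier}+{addon.identifier}")
    merged.chains = [_copy_chain(c, c.chain_id) for c in base.chains]
    used = set(merged.chain_ids())
    id_map: dict[str, str] = {shared_addon_chain: shared_base_chain}
    new_ids: list[str] = []
    for chain in addon.chains:
        if chain.chain_id == shared_addon_chain:
            continue
        new_id = _fresh_chain_id(used)
        used.add(new_id)
        id_map[chain.chain_id] = new_id
        new_ids.append(new_id)
        copy = _copy_chain(chain, new_id)
        for res in copy.residues:
            for atom in res.atoms:
                atom.position = transform.rotation @ atom.position + transform.translation
        merged.chains.append(copy)

    clash_count = _count_clashes(merged, base_pairs={
        frozenset((a, b)) for a in base.chain_ids() for b in base.chain_ids() if a != b
    } | {
        frozenset((id_map[a], id_map[b]))
        for a in addon.chain_ids() for b in addon.chain_ids() if a != b
    })
    return GraftResult(structure=merged, graft_rmsd_ca=transform.rmsd_ca,
                       clash_count=clash_count, chain_id_map=id_map)


def _count_clashes(structure: Structure, base_pairs: set[frozenset]) -> int:
    """Heavy-atom pairs < 2.2 Å between chains not interfaced in either input."""
    trees = {}
    coords = {}
    for cid in structure.chain_ids():
        c = _heavy_atom_coords(structure, cid)
        coords[cid] = c
        trees[cid] = cKDTree(c) if len(c) else None
    count = 0
    ids = structure.chain_ids()
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if frozenset((a, b)) in base_pairs:
                continue
            if trees[a] is None or trees[b] is None:
                continue
            count += trees[a].count_neighbors(trees[b], _CLASH_CUTOFF)
    return int(count)
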