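"""Deterministic synthetic fixtures with stored ground truth.

Every generator emulates the *statistical structure* of the data the analysis
pipeline consumes — rigid-body relations between chains, burial contrast at a
packed interface, consensus-conforming motif instances in random sequence
background, Beer-Lambert peak areas on a noisy trace — not septin biology.
Each returns a :class:`FixtureBundle` whose ``truth`` dictionary is a
sufficient statistic for every downstream assertion (applied transform,
buried/exposed residue lists, planted motif offsets, per-peak areas and
concentrations), and identical seed + parameters reproduce the payload
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .nucleotide_quant import Chromatogram
from .structure_io import Atom, Chain, Residue, Structure

__all__ = [
    "FixtureBundle",
    "make_ideal_helix",
    "make_transformed_pair",
    "make_interface_dimer",
    "make_motif_sequences",
    "make_chromatogram",
]


@dataclass
class FixtureBundle:
    payload: Any
    truth: dict = field(default_factory=dict)
    seed: int | None = None


# Ideal alanine geometry, local coordinates centred on CA (bond lengths
# N-CA 1.47, CA-C 1.51, CA-CB 1.53 A; tetrahedral CB).
_ALA_TEMPLATE: dict[str, np.ndarray] = {
    "N": np.array([-1.223, 0.075, 0.808]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([-0.351, -0.401, -1.408]),
    "O": np.array([-1.313, -1.100, -1.615]),
    "CB": np.array([0.947, -1.038, 0.604]),
}
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}

_HELIX_RISE = 1.5        # A per residue along the axis
_HELIX_TWIST = 100.0     # degrees per residue
_HELIX_RADIUS = 2.3      # A, CA radius; gives CA(i)-CA(i+1) ~ 3.8 A


def make_ideal_helix(n_residues: int, chain_id: str = "A",
                     start_number: int = 1) -> Structure:
    """Poly-alanine alpha-helix along +z with full backbone and CB atoms.

    Rise 1.5 A/residue, twist 100 deg/residue, CA radius 2.3 A, so
    consecutive CA-CA distances fall in [3.7, 3.9] A.  Deterministic: no
    randomness is involved.
    """
    if n_residues < 4:
        raise ValueError("a helix needs >= 4 residues")
    chain = Chain(chain_id=chain_id)
    for i in range(n_residues):
        theta = np.deg2rad(_HELIX_TWIST * i)
        rot = Rotation.from_euler("z", theta).as_matrix()
        ca = np.array([_HELIX_RADIUS * np.cos(theta),
                       _HELIX_RADIUS * np.sin(theta),
                       _HELIX_RISE * i])
        atoms = [
            Atom(name=name, element=_ELEMENT[name], position=ca + rot @ local)
            for name, local in _ALA_TEMPLATE.items()
        ]
        chain.residues.append(Residue(number=start_number + i, name="ALA", atoms=atoms))
    return Structure(identifier=f"helix_{chain_id}{n_residues}", chains=[chain])


def _transform_structure(structure: Structure, rotation: np.ndarray,
                         translation: np.ndarray) -> Structure:
    out = Structure(identifier=structure.identifier + "_moved", chains=[])
    for chain in structure.chains:
        new_chain = Chain(chain_id=chain.chain_id)
        for res in chain.residues:
            new_chain.residues.append(Residue(
                number=res.number, name=res.name, insertion_code=res.insertion_code,
                is_polymer=res.is_polymer,
                atoms=[Atom(name=a.name, element=a.element,
                            position=rotation @ a.position + translation,
                            occupancy=a.occupancy, b_factor=a.b_factor)
                       for a in res.atoms],
            ))
        out.chains.append(new_chain)
    return out


def make_transformed_pair(base: Structure, rotation_angles: tuple[float, float, float],
                          translation: tuple[float, float, float],
                          noise_sd: float = 0.0, seed: int = 0
                          ) -> tuple[Structure, Structure, dict]:
    """A structure plus a rigidly transformed, optionally noisy copy.

    ``rotation_angles`` are intrinsic xyz Euler angles in degrees; isotropic
    Gaussian noise of ``noise_sd`` A is added per coordinate of the copy.
    The truth dict records the exact rotation matrix, translation and
    noise_sd.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not base.chains:
        raise ValueError("base structure is empty")
    rot = Rotation.from_euler("xyz", rotation_angles, degrees=True).as_matrix()
    t = np.asarray(translation, dtype=float)
    moved = _transform_structure(base, rot, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for chain in moved.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = atom.position + rng.normal(0.0, noise_sd, 3)
    truth = {"rotation": rot, "translation": t, "noise_sd": noise_sd, "seed": seed}
    return base, moved, truth


def make_interface_dimer(seed: int = 0, n_residues: int = 36) -> FixtureBundle:
    """Two packed helices with known buried and exposed residues.

    Chain B is a copy of chain A's middle third, rotated 180 deg about the
    helix axis and translated sideways until the closest cross-chain CB-CB
    pair sits at exactly 4.0 A (the ideal engineered-disulfide separation) —
    that pair is the planted candidate for the disulfide screen.  Because B
    covers only A's middle, A's terminal residues are far from any B atom.
    The truth lists the "crest" residues of A (any heavy atom within 4.5 A
    of B), the "exposed" residues (all heavy atoms > 10 A from B) and the
    planted pair.
    """
    base = make_ideal_helix(n_residues, chain_id="A")
    chain_a = base.chains[0]
    rng = np.random.default_rng(seed)
    # tiny seeded jitter so different seeds give distinct (but equivalent) fixtures
    for res in chain_a.residues:
        for atom in res.atoms:
            atom.position = atom.position + rng.normal(0.0, 0.01, 3)

    flip = Rotation.from_euler("z", 180.0, degrees=True).as_matrix()

    def cb_coords(chain: Chain) -> np.ndarray:
        return np.array([r.atom("CB").position for r in chain.residues])

    middle = Chain(chain_id="B",
                   residues=chain_a.residues[n_residues // 3: 2 * n_residues // 3])
    cb_a = cb_coords(chain_a)
    cb_mid = cb_coords(middle)

    def min_cb_gap(d: float) -> float:
        cb_b = cb_mid @ flip.T + np.array([d, 0.0, 0.0])
        return float(np.min(np.linalg.norm(cb_a[:, None, :] - cb_b[None, :, :], axis=2))) - 4.0

    d_opt = brentq(min_cb_gap, 4.0, 40.0, xtol=1e-10)
    translation = np.array([d_opt, 0.0, 0.0])
    chain_b_struct = _transform_structure(
        Structure(identifier="B", chains=[middle]), flip, translation)
    chain_b = chain_b_struct.chains[0]

    dimer = Structure(identifier=f"interface_dimer_seed{seed}",
                      chains=[chain_a, chain_b])

    heavy_b = np.array([a.position for r in chain_b.residues for a in r.atoms])
    crest, exposed = [], []
    for res in chain_a.residues:
        coords = np.array([a.position for a in res.atoms])
        dmin = np.min(np.linalg.norm(coords[:, None, :] - heavy_b[None, :, :], axis=2))
        if dmin < 4.5:
            crest.append(res.number)
        elif dmin > 10.0:
            exposed.append(res.number)

    cb_b = cb_coords(chain_b)
    dmat = np.linalg.norm(cb_a[:, None, :] - cb_b[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(dmat), dmat.shape)
    planted = (("A", chain_a.residues[i].number), ("B", chain_b.residues[j].number))

    return FixtureBundle(
        payload=dimer,
        truth={
            "crest_residues_A": crest,
            "exposed_residues_A": exposed,
            "planted_pair": planted,
            "planted_cb_cb": float(dmat[i, j]),
            "separation": float(d_opt),
        },
        seed=seed,
    )


# Crest-consensus residue pools per constrained position; soft positions are
# alanine unless mutate_soft_positions randomises them.
_MOTIF_POOLS: dict[int, str] = {
    1: "VIF", 2: "G", 3: "FI", 6: "LIV", 7: "PIFVL",
    9: "Q", 10: "IFVL", 15: "IFVL", 19: "FI",
}
_SOFT_POSITIONS = (4, 5, 8, 11, 12, 13, 14, 16, 17, 18)
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _make_instance(rng: np.random.Generator, mutate_soft: bool) -> str:
    window = []
    for pos in range(1, 20):
        if pos in _MOTIF_POOLS:
            pool = _MOTIF_POOLS[pos]
            window.append(pool[rng.integers(len(pool))])
        elif mutate_soft:
            window.append(_AMINO_ACIDS[rng.integers(20)])
        else:
            window.append("A")
    return "".join(window)


def _has_spurious_match(sequence: str, planted: set[int]) -> bool:
    from .crest_motif import CREST_MOTIF, scan_motif

    found = {m.start for m in scan_motif(sequence, CREST_MOTIF, mode="strict")}
    return bool(found - planted)


def make_motif_sequences(n_sequences: int, embed_offsets: list[int],
                         mutate_soft_positions: bool = False, seed: int = 0,
                         length: int = 120) -> FixtureBundle:
    """Random sequences carrying crest-motif instances at known offsets.

    ``embed_offsets`` are 1-based start indices applied to every sequence;
    backgrounds are uniform over the 20 residues and resampled if they happen
    to contain a strict motif match outside the planted offsets, so a strict
    scan recovers exactly the planted truth.
    """
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    for off in embed_offsets:
        if not 1 <= off <= length - 18:
            raise ValueError(f"offset {off} leaves no room for a 19-residue window")
    starts = sorted(embed_offsets)
    for a, b in zip(starts, starts[1:]):
        if b - a < 19:
            raise ValueError(f"offsets {a} and {b} overlap")

    rng = np.random.default_rng(seed)
    planted = set(embed_offsets)
    records: list[tuple[str, str]] = []
    for i in range(n_sequences):
        for _attempt in range(50):
            seq = [_AMINO_ACIDS[k] for k in rng.integers(0, 20, size=length)]
            for off in embed_offsets:
                seq[off - 1:off + 18] = _make_instance(rng, mutate_soft_positions)
            candidate = "".join(seq)
            if not _has_spurious_match(candidate, planted):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not generate a background free of spurious matches")
        records.append((f"synth_{i}", candidate))

    return FixtureBundle(
        payload=records,
        truth={"offsets": sorted(planted), "length": length,
               "mutate_soft_positions": mutate_soft_positions},
        seed=seed,
    )


def make_chromatogram(peaks: list[tuple[str, float, float, float]],
                      response_per_molar: float, noise_sd: float = 0.0,
                      seed: int = 0, volume_range: tuple[float, float] = (0.0, 25.0),
                      step: float = 0.01) -> FixtureBundle:
    """Gaussian elution peaks with Beer-Lambert areas plus detector noise.

    ``peaks`` rows are (species, center mL, sd mL, concentration M); each
    peak's area is concentration x response.  Truth stores the exact areas,
    concentrations and suggested integration windows (center +/- 4 sd), and
    flags window overlaps.
    """
    lo, hi = volume_range
    volumes = np.arange(lo, hi + step / 2, step)
    trace = np.zeros_like(volumes)
    truth_peaks = []
    warnings_list = []
    for species, center, sd, conc in peaks:
        if sd <= 0:
            raise ValueError(f"{species}: peak sd must be positive")
        if not lo < center < hi:
            raise ValueError(f"{species}: center {center} outside trace range")
        area = conc * response_per_molar
        amplitude = area / (sd * np.sqrt(2.0 * np.pi))
        trace += amplitude * np.exp(-0.5 * ((volumes - center) / sd) ** 2)
        truth_peaks.append({
            "species": species, "center": center, "sd": sd,
            "concentration": conc, "area": area,
            "window": (max(lo, center - 4 * sd), min(hi, center + 4 * sd)),
        })
    for p, q in zip(truth_peaks, truth_peaks[1:]):
        gap = abs(q["center"] - p["center"])
        if gap < 4.0 * (p["sd"] + q["sd"]):
            warnings_list.append(
                f"peaks {p['species']} and {q['species']} closer than 4 sd: "
                "integration windows overlap"
            )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=trace.shape)

    chrom = Chromatogram(volumes=volumes, absorbances=trace, wavelength_nm=253.0,
                         column_id="synthetic")
    return FixtureBundle(
        payload=chrom,
        truth={"peaks": truth_peaks, "response_per_molar": response_per_molar,
               "noise_sd": noise_sd, "warnings": warnings_list},
        seed=seed,
    )
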