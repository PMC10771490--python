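"""Nucleotide content of septin complexes from ion-exchange chromatograms.

GDP and GTP released from a heat-denatured septin complex are separated on an
anion-exchange column and quantified from the 253 nm trace: each species'
peak is integrated (trapezoid over a baseline-corrected window), converted to
a molar concentration through a calibration line forced through the origin
(Beer-Lambert proportionality), and combined into

    content per subunit =
        ([GDP] + [GTP]) * eps_s
        / ( n_subunits * (eps_s * c_app  -  eps_g * ([GDP] + [GTP])) )

where ``c_app`` is the apparent complex concentration read at 280 nm and
``eps_s``/``eps_g`` are the 280 nm extinction coefficients of the
stoichiometric complex and of a guanine nucleotide.  The denominator corrects
the protein concentration for the absorbance contributed by the bound
nucleotides themselves; with ``eps_g = 0`` the expression collapses to the
uncorrected molar ratio.  The defaults are the tetrameric yeast complex's
constants (eps_s = 113570 M^-1 cm^-1, eps_g = 7720 M^-1 cm^-1, c_app = 15 uM,
4 subunits) but every constant is a parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chromatogram",
    "PeakWindow",
    "CalibrationFactor",
    "NucleotideQuantParams",
    "integrate_peak",
    "calibrate",
    "peak_concentration",
    "per_subunit_content",
    "gdp_fraction",
    "find_peak_maximum",
]

SPECIES = ("GDP", "GTP", "GTPgammaS")


@dataclass
class Chromatogram:
    """An elution trace: strictly increasing volumes (mL) vs absorbance (AU)."""

    volumes: np.ndarray
    absorbances: np.ndarray
    wavelength_nm: float | None = None
    column_id: str = ""

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.volumes.shape != self.absorbances.shape or self.volumes.ndim != 1:
            raise ValueError("volumes and absorbances must be equal-length 1-D arrays")
        if len(self.volumes) < 10:
            raise ValueError("chromatogram needs >= 10 points")
        if not np.all(np.diff(self.volumes) > 0):
            raise ValueError("elution volumes must be strictly increasing")

    @classmethod
    def from_csv(cls, path, wavelength_nm: float | None = None,
                 column_id: str = "") -> "Chromatogram":
        """Read the two-column CSV dialect: header volume_ml,absorbance_au."""
        df = pd.read_csv(path)
        required = {"volume_ml", "absorbance_au"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}, "
                             f"got {list(df.columns)}")
        return cls(df["volume_ml"].to_numpy(), df["absorbance_au"].to_numpy(),
                   wavelength_nm=wavelength_nm, column_id=column_id)

    def to_csv(self, path) -> None:
        pd.DataFrame({"volume_ml": self.volumes,
                      "absorbance_au": self.absorbances}).to_csv(path, index=False)


@dataclass
class PeakWindow:
    """Integration window for one nucleotide species."""

    species: str
    volume_start: float
    volume_end: float
    baseline_mode: str = "linear_endpoints"

    def __post_init__(self) -> None:
        if self.volume_start >= self.volume_end:
            raise ValueError("window start must precede end")
        if self.baseline_mode not in ("linear_endpoints", "flat"):
            raise ValueError(f"unknown baseline mode {self.baseline_mode!r}")


@dataclass
class CalibrationFactor:
    """Detector response (area units per molar) for one species."""

    species: str
    response: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.response <= 0:
            raise ValueError(f"{self.species}: calibration response must be positive")


@dataclass
class NucleotideQuantParams:
    """Constants of the nucleotide-content correction.

    eps_s / eps_g: 280 nm extinction coefficients (M^-1 cm^-1) of the intact
    complex and of a guanine nucleotide; apparent_complex_conc: complex
    concentration (M) determined photometrically before denaturation;
    n_subunits: nucleotide-binding subunits per complex.
    """

    eps_s: float = 113570.0
    eps_g: float = 7720.0
    apparent_complex_conc: float = 15e-6
    n_subunits: int = 4

    def __post_init__(self) -> None:
        if min(self.eps_s, self.apparent_complex_conc) <= 0 or self.eps_g < 0:
            raise ValueError("extinction coefficients and concentration must be positive")
        if self.eps_s <= self.eps_g:
            raise ValueError("complex must absorb more than a single nucleotide")
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")


def integrate_peak(chromatogram: Chromatogram, window: PeakWindow) -> float:
    """Baseline-corrected trapezoidal peak area in AU*mL.

    ``linear_endpoints`` interpolates the baseline between the absorbances at
    the window edges; ``flat`` uses a zero baseline.  A net-negative area is
    clipped to 0 with a warning (the window is then mostly baseline noise).
    """
    v, a = chromatogram.volumes, chromatogram.absorbances
    if window.volume_start < v[0] or window.volume_end > v[-1]:
        raise ValueError(
            f"window [{window.volume_start}, {window.volume_end}] outside "
            f"trace range [{v[0]}, {v[-1]}]"
        )
    # resample window edges onto the trace so the baseline anchors exactly
    edges = np.array([window.volume_start, window.volume_end])
    edge_abs = np.interp(edges, v, a)
    inside = (v > window.volume_start) & (v < window.volume_end)
    vw = np.concatenate(([edges[0]], v[inside], [edges[1]]))
    aw = np.concatenate(([edge_abs[0]], a[inside], [edge_abs[1]]))
    if window.baseline_mode == "linear_endpoints":
        baseline = np.interp(vw, edges, edge_abs)
    else:
        baseline = np.zeros_like(vw)
    area = float(np.trapezoid(aw - baseline, vw))
    if area < 0:
        warnings.warn(
            f"{window.species}: net peak area {area:.3g} AU*mL is negative; "
            "clipping to 0", stacklevel=2,
        )
        return 0.0
    return area


def calibrate(standards: list[tuple[str, float, float]]) -> dict[str, CalibrationFactor]:
    """Per-species calibration from (species, concentration M, area) standards.

    Fits a least-squares line through the origin (Beer-Lambert
    proportionality): response = sum(c*A)/sum(c^2).  Requires >= 2 standards
    per species; a zero-concentration blank counts as one.
    """
    by_species: dict[str, list[tuple[float, float]]] = {}
    for species, conc, area in standards:
        if conc < 0 or area < 0:
            raise ValueError(f"{species}: negative standard ({conc}, {area})")
        by_species.setdefault(species, []).append((conc, area))

    out = {}
    for species, rows in by_species.items():
        if len(rows) < 2:
            raise ValueError(
                f"{species}: calibration needs >= 2 standards, got {len(rows)}"
            )
        c = np.array([r[0] for r in rows])
        a = np.array([r[1] for r in rows])
        if np.all(c == 0):
            raise ValueError(f"{species}: all standards at zero concentration")
        response = float(np.sum(c * a) / np.sum(c * c))
        predicted = response * c
        ss_res = float(np.sum((a - predicted) ** 2))
        ss_tot = float(np.sum((a - a.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot if ss_tot else 0.0
        out[species] = CalibrationFactor(species=species, response=response, r_squared=r2)
    return out


def peak_concentration(area: float, factor: CalibrationFactor) -> float:
    """Molar concentration from a peak area: area / response."""
    if area < 0:
        raise ValueError("peak area cannot be negative")
    return area / factor.response


def per_subunit_content(gdp_conc: float, gtp_conc: float,
                        params: NucleotideQuantParams | None = None) -> float:
    """Guanine nucleotides bound per subunit, absorbance-corrected.

    The complex concentration inferred from 280 nm absorbance overstates the
    protein because bound nucleotide co-absorbs; the denominator removes that
    contribution before dividing the nucleotide pool over the subunits.
    """
    params = params or NucleotideQuantParams()
    if gdp_conc < 0 or gtp_conc < 0:
        raise ValueError("concentrations cannot be negative")
    total = gdp_conc + gtp_conc
    corrected = params.eps_s * params.apparent_complex_conc - params.eps_g * total
    if corrected <= 0:
        raise ValueError(
            "nucleotide absorbance exceeds the total 280 nm signal "
            f"(eps_s*c_app = {params.eps_s * params.apparent_complex_conc:.4g} <= "
            f"eps_g*total = {params.eps_g * total:.4g}); the implied protein "
            "concentration is nonpositive"
        )
    return total * params.eps_s / (params.n_subunits * corrected)


def gdp_fraction(gdp_conc: float, gtp_conc: float) -> float:
    """Fraction of the guanine nucleotide pool that is GDP."""
    if gdp_conc < 0 or gtp_conc < 0:
        raise ValueError("concentrations cannot be negative")
    total = gdp_conc + gtp_conc
    if total == 0:
        raise ValueError("no nucleotide detected: GDP fraction undefined")
    return gdp_conc / total


def find_peak_maximum(chromatogram: Chromatogram, volume_start: float,
                      volume_end: float) -> tuple[float, float]:
    """Helper: (volume, absorbance) of the maximum inside a volume range.

    Provided for interactive window placement; never applied silently by the
    quantification pipeline.
    """
    mask = (chromatogram.volumes >= volume_start) & (chromatogram.volumes <= volume_end)
    if not mask.any():
        raise ValueError("no data points inside the requested range")
    idx = int(np.argmax(np.where(mask, chromatogram.absorbances, -np.inf)))
    return float(chromatogram.volumes[idx]), float(chromatogram.absorbances[idx])
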