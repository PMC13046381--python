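"""Computational screening metrics for designed protein candidates.

The screening funnel narrows a large design library with cheap sequence
and structure metrics before any experiment:

* :func:`gravy` — grand average of hydropathy (Kyte-Doolittle); designs
  with GRAVY <= -0.3 are considered developable (soluble).
* :func:`foldability_gate` — structure-prediction confidence gate:
  pLDDT > 90 and RMSD to the template < 2.0 A.
* :func:`kabsch_rmsd` — minimal C-alpha RMSD after optimal rigid
  superposition.
* :func:`sasa` / :func:`rsasa_profile` — Shrake-Rupley solvent-accessible
  surface area and per-residue relative SASA (residue SASA divided by the
  residue type's theoretical maximum in a Gly-X-Gly tripeptide); the mean
  rSASA and the fraction of residues with rSASA < 0.2 quantify
  hydrophobic-core packing.
* :func:`smd_peak_rank` — rank candidates by mean peak force over steered
  molecular dynamics pulling replicates (the MD itself is external; this
  consumes its force time series).
* :func:`amd_stability` — final-vs-initial RMSD after an annealing MD
  run, as a thermal-stability score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "KYTE_DOOLITTLE",
    "MAX_ASA_THEORETICAL",
    "VDW_RADII",
    "ScreeningRecord",
    "SasaResult",
    "gravy",
    "developability_filter",
    "kabsch_rmsd",
    "foldability_gate",
    "sasa",
    "packing_stats",
    "rsasa_profile",
    "smd_peak_rank",
    "amd_stability",
]

logger = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy values per residue.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Theoretical maximum accessible surface area (A^2) per residue type in an
#: extended Gly-X-Gly tripeptide (Tien et al. 2013, theoretical set);
#: denominator of the relative SASA.
MAX_ASA_THEORETICAL: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Van der Waals radii (A) used in the SASA quadrature.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "SE": 1.90,
}


@dataclass
class ScreeningRecord:
    """One design candidate's funnel metrics and gate outcomes."""

    id: str
    sequence: str = ""
    gravy: float | None = None
    plddt: float | None = None
    rmsd_to_template: float | None = None
    mean_rsasa: float | None = None
    fraction_rsasa_below_0_2: float | None = None
    smd_peak_forces: list[float] = field(default_factory=list)
    amd_final_rmsd: float | None = None
    gates: dict[str, bool] = field(default_factory=dict)
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.plddt is not None and not 0 <= self.plddt <= 100:
            raise ValueError("plddt must lie in [0, 100]")
        if self.rmsd_to_template is not None and self.rmsd_to_template < 0:
            raise ValueError("rmsd_to_template must be non-negative")


@dataclass(frozen=True)
class SasaResult:
    """Per-residue SASA / rSASA profile with packing summary statistics."""

    per_residue_sasa: tuple[float, ...]  # A^2
    per_residue_rsasa: tuple[float, ...]
    mean_rsasa: float
    fraction_below_threshold: float
    threshold: float
    n_clipped: int


# --------------------------------------------------------------------------
# Sequence metrics
# --------------------------------------------------------------------------

def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    if not sequence:
        raise ValueError("sequence is empty")
    seq = sequence.upper()
    bad = sorted({c for c in seq if c not in KYTE_DOOLITTLE})
    if bad:
        raise ValueError(f"non-standard residue letters: {', '.join(bad)}")
    return float(np.mean([KYTE_DOOLITTLE[c] for c in seq]))


def developability_filter(
    records: list[ScreeningRecord],
    threshold: float = -0.3,
    strict: bool = False,
) -> list[ScreeningRecord]:
    """Retain candidates passing the GRAVY solubility gate.

    The default rule is inclusive (gravy <= threshold); ``strict=True``
    switches to strictly-below.  Gate outcomes are recorded per record.
    """
    kept = []
    for rec in records:
        if rec.gravy is None:
            raise ValueError(f"record {rec.id} has no GRAVY value")
        ok = rec.gravy < threshold if strict else rec.gravy <= threshold
        rec.gates["developability"] = ok
        if ok:
            kept.append(rec)
    return kept


# --------------------------------------------------------------------------
# Structure superposition
# --------------------------------------------------------------------------

def kabsch_rmsd(coords_a, coords_b) -> float:
    """Minimal RMSD (A) of paired point sets after optimal rigid alignment.

    Centers both sets, then finds the proper rotation minimizing the
    residual (Kabsch superposition).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"paired Nx3 coordinate sets required, got {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 paired atoms")
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a_c, b_c)
    return float(rssd / np.sqrt(a.shape[0]))


def foldability_gate(
    record: ScreeningRecord,
    plddt_min: float = 90.0,
    rmsd_max: float = 2.0,
    inclusive: bool = False,
) -> bool:
    """Structure-prediction confidence gate: pLDDT above / RMSD below cutoffs.

    The default is strict (pLDDT > 90 and RMSD < 2.0 A); ``inclusive=True``
    uses >= / <=.  A missing metric fails the gate with the reason recorded.
    """
    if record.plddt is None or record.rmsd_to_template is None:
        missing = [m for m in ("plddt", "rmsd_to_template")
                   if getattr(record, m) is None]
        record.gates["foldability"] = False
        record.gates["foldability_missing_" + "_".join(missing)] = False
        return False
    if inclusive:
        ok = record.plddt >= plddt_min and record.rmsd_to_template <= rmsd_max
    else:
        ok = record.plddt > plddt_min and record.rmsd_to_template < rmsd_max
    record.gates["foldability"] = ok
    return ok


# --------------------------------------------------------------------------
# Solvent accessibility
# --------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    coords,
    elements,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom (A^2).

    Each atom's extended sphere (vdW radius + probe) is sampled with a
    golden-spiral point lattice; a point is accessible if it lies outside
    every neighbor's extended sphere.
    """
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
    elems = [str(e).upper() for e in elements]
    if xyz.shape[0] == 0:
        raise ValueError("structure has no atoms")
    if len(elems) != xyz.shape[0]:
        raise ValueError("coords and elements length mismatch")
    unknown = sorted({e for e in elems if e not in VDW_RADII})
    if unknown:
        raise ValueError(f"unknown elements (no vdW radius): {', '.join(unknown)}")

    radii = np.array([VDW_RADII[e] for e in elems]) + probe_radius
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(xyz)
    max_r = radii.max()

    out = np.empty(xyz.shape[0])
    for i in range(xyz.shape[0]):
        pts = xyz[i] + radii[i] * unit
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in tree.query_ball_point(xyz[i], radii[i] + max_r):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            accessible &= d2 > radii[j] ** 2
        out[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return out


def packing_stats(rsasa_values, threshold: float = 0.2) -> tuple[float, float]:
    """Mean rSASA and fraction of residues below the burial threshold."""
    arr = np.asarray(rsasa_values, dtype=float)
    if arr.size == 0:
        raise ValueError("no rSASA values")
    return float(arr.mean()), float((arr < threshold).mean())


def rsasa_profile(
    structure,
    reference_max: dict[str, float] | None = None,
    threshold: float = 0.2,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> SasaResult:
    """Per-residue relative SASA of a biotite ``AtomArray``.

    Hydrogens are ignored; each residue's heavy-atom SASA is divided by
    its type's theoretical maximum accessibility.  Ratios are clipped to
    [0, 1.5] (clip count logged) — values slightly above 1 occur at chain
    termini.  ``fraction_below_threshold`` is the buried-core fraction
    used as a packing score.
    """
    ref = reference_max if reference_max is not None else MAX_ASA_THEORETICAL
    heavy = structure[structure.element != "H"]
    if heavy.array_length() == 0:
        raise ValueError("structure has no heavy atoms")
    atom_sasa = sasa(heavy.coord, heavy.element, probe_radius, n_sphere_points)

    res_sasa: list[float] = []
    res_rsasa: list[float] = []
    n_clipped = 0
    # group consecutive atoms by (chain, residue id, insertion code)
    keys = list(zip(heavy.chain_id, heavy.res_id))
    start = 0
    for i in range(1, len(keys) + 1):
        if i == len(keys) or keys[i] != keys[start]:
            res_name = str(heavy.res_name[start])
            if res_name not in ref:
                raise KeyError(
                    f"residue type {res_name} missing from the reference "
                    "max-accessibility table"
                )
            total = float(atom_sasa[start:i].sum())
            ratio = total / ref[res_name]
            if ratio < 0 or ratio > 1.5:
                n_clipped += 1
                ratio = min(max(ratio, 0.0), 1.5)
            res_sasa.append(total)
            res_rsasa.append(ratio)
            start = i
    if n_clipped:
        logger.info("rSASA: clipped %d residue ratios into [0, 1.5]", n_clipped)

    mean_rsasa, fraction = packing_stats(res_rsasa, threshold)
    return SasaResult(
        per_residue_sasa=tuple(res_sasa),
        per_residue_rsasa=tuple(res_rsasa),
        mean_rsasa=mean_rsasa,
        fraction_below_threshold=fraction,
        threshold=float(threshold),
        n_clipped=n_clipped,
    )


# --------------------------------------------------------------------------
# MD-derived stability scores
# --------------------------------------------------------------------------

def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(y, dtype=float)
    kernel = np.ones(window) / window
    return np.convolve(np.asarray(y, dtype=float), kernel, mode="valid")


def smd_peak_rank(
    candidates: dict[str, list],
    smoothing_window: int = 50,
) -> list[tuple[str, float, float]]:
    """Rank candidates by mean peak force over pulling replicates.

    Each replicate force series is moving-average smoothed and its global
    maximum taken as the peak force; candidates are ordered by descending
    mean peak (sd over replicates reported alongside).  Ties are broken
    by candidate id (logged).
    """
    stats: list[tuple[str, float, float]] = []
    for cid, replicates in candidates.items():
        if not replicates:
            raise ValueError(f"candidate {cid} has no replicate force series")
        peaks = []
        for series in replicates:
            series = np.asarray(series, dtype=float)
            if series.size == 0:
                raise ValueError(f"candidate {cid} has an empty force series")
            window = min(smoothing_window, series.size)
            peaks.append(float(_moving_average(series, window).max()))
        mean = float(np.mean(peaks))
        sd = float(np.std(peaks, ddof=1)) if len(peaks) > 1 else 0.0
        stats.append((cid, mean, sd))

    ranked = sorted(stats, key=lambda t: (-t[1], t[0]))
    means = [m for _, m, _ in ranked]
    if len(set(means)) < len(means):
        logger.info("SMD ranking contains ties; broken by candidate id order")
    return ranked


def amd_stability(initial_coords, final_coords) -> float:
    """Final-vs-initial C-alpha RMSD (A) after an annealing MD run."""
    return kabsch_rmsd(initial_coords, final_coords)
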