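"""Worm-like-chain (WLC) polymer elasticity.

The WLC model relates the tension in a semi-flexible polymer to its
fractional end-to-end extension through two parameters: the persistence
length ``p`` (bending stiffness expressed as a length) and the contour
length ``Lc`` (fully stretched backbone length).  We use the Marko-Siggia
interpolation formula

    F(x) = (kB*T/p) * [ 1/(4*(1 - x/Lc)^2) - 1/4 + x/Lc ],

the de-facto standard for fitting AFM single-molecule force-extension
data.  Forces are in pN, lengths in nm, so kB = 0.0138065 pN nm / K.

The contour-length bookkeeping helper :func:`predict_delta_lc` converts a
domain's residue count into the contour-length increment released when it
unfolds, using 0.36 nm of backbone per stretched residue minus the folded
N-to-C distance the domain already contributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "CONTOUR_PER_RESIDUE_NM",
    "PhysicalContext",
    "WLCModel",
    "wlc_force",
    "wlc_inverse",
    "wlc_stiffness",
    "predict_delta_lc",
]

#: Boltzmann constant in pN nm per kelvin.
BOLTZMANN_PN_NM_PER_K = 0.0138065

#: Contour length gained per stretched amino-acid residue (nm).
CONTOUR_PER_RESIDUE_NM = 0.36


@dataclass(frozen=True)
class PhysicalContext:
    """Thermodynamic context: temperature and the Boltzmann constant.

    At the default room temperature of 298 K the thermal energy
    kB*T is approximately 4.11 pN nm.
    """

    temperature: float = 298.0  # K
    boltzmann_constant: float = BOLTZMANN_PN_NM_PER_K  # pN nm / K

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def thermal_energy(self) -> float:
        """kB*T in pN nm."""
        return self.boltzmann_constant * self.temperature


@dataclass(frozen=True)
class WLCModel:
    """A worm-like chain with fixed persistence and contour length.

    Parameters
    ----------
    persistence_length : float
        Persistence length in nm.  0.4 nm is the canonical value for an
        unfolded polypeptide in SMFS work and is the package default.
    contour_length : float
        Contour length in nm.
    context : PhysicalContext
        Temperature / Boltzmann constant.
    """

    persistence_length: float = 0.4
    contour_length: float = 100.0
    context: PhysicalContext = field(default_factory=PhysicalContext)

    def __post_init__(self) -> None:
        if not self.persistence_length > 0:
            raise ValueError("persistence_length must be positive")
        if not self.contour_length > 0:
            raise ValueError("contour_length must be positive")


def _check_extension(extension: np.ndarray, contour_length: float) -> None:
    if np.any(extension < 0):
        raise ValueError("extension must be non-negative")
    if np.any(extension >= contour_length):
        raise ValueError(
            "extension must be strictly below the contour length "
            f"({contour_length} nm); the WLC force diverges there"
        )


def wlc_force(extension, model: WLCModel):
    """Marko-Siggia WLC force (pN) at the given extension (nm).

    Accepts a scalar or array extension in [0, Lc); raises for negative
    extensions or extensions at/beyond the contour length.
    """
    x = np.asarray(extension, dtype=float)
    _check_extension(x, model.contour_length)
    u = x / model.contour_length
    kt_over_p = model.context.thermal_energy / model.persistence_length
    f = kt_over_p * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
    return float(f) if np.isscalar(extension) or f.ndim == 0 else f


def wlc_stiffness(extension, model: WLCModel):
    """Analytic dF/dx of the Marko-Siggia WLC, in pN/nm.

    Used to convert cantilever retraction speed into a loading rate:
    r = (dF/dx at rupture) * speed.
    """
    x = np.asarray(extension, dtype=float)
    _check_extension(x, model.contour_length)
    u = x / model.contour_length
    kt_over_p = model.context.thermal_energy / model.persistence_length
    lc = model.contour_length
    k = kt_over_p * (0.5 / (lc * (1.0 - u) ** 3) + 1.0 / lc)
    return float(k) if np.isscalar(extension) or k.ndim == 0 else k


def wlc_inverse(force, model: WLCModel, xtol: float = 1e-9):
    """Extension (nm) at which the WLC produces the given force (pN).

    Solved by bracketed root-finding on [0, (1 - 1e-9) * Lc] to an
    absolute tolerance of ``xtol`` nm; exact round-trip partner of
    :func:`wlc_force`.
    """
    f_arr = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(f_arr)):
        raise ValueError("force must be finite")
    if np.any(f_arr < 0):
        raise ValueError("force must be non-negative")

    hi = (1.0 - 1e-9) * model.contour_length

    def solve_one(f: float) -> float:
        if f == 0.0:
            return 0.0
        if wlc_force(hi, model) < f:  # beyond the numerical bracket
            return hi
        return brentq(lambda x: wlc_force(x, model) - f, 0.0, hi, xtol=xtol)

    if f_arr.ndim == 0:
        return solve_one(float(f_arr))
    return np.array([solve_one(f) for f in f_arr.ravel()]).reshape(f_arr.shape)


def predict_delta_lc(n_residues: int, folded_nc_distance: float) -> float:
    """Expected contour-length increment (nm) for unfolding a domain.

    ``n_residues * 0.36 nm`` of backbone is released, minus the folded
    N-to-C distance the domain already spanned while folded.

    Raises if the folded distance exceeds the stretched length (negative
    increments are unphysical and indicate inconsistent inputs).
    """
    if n_residues < 0:
        raise ValueError("n_residues must be non-negative")
    if folded_nc_distance < 0:
        raise ValueError("folded_nc_distance must be non-negative")
    delta = n_residues * CONTOUR_PER_RESIDUE_NM - folded_nc_distance
    if delta < 0:
        raise ValueError(
            f"folded N-C distance ({folded_nc_distance} nm) exceeds the stretched "
            f"length ({n_residues * CONTOUR_PER_RESIDUE_NM} nm)"
        )
    return delta
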