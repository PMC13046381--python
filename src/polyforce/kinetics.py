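"""Unfolding statistics and Bell-Evans dynamic force spectroscopy.

Rupture-force and contour-length-increment populations are summarized by
nonlinear least-squares Gaussian fits to zero-anchored histograms, the
standard presentation for SMFS data (mean +/- SEM from the fit).

Dynamic force spectroscopy uses the Bell-Evans relation between the most
probable rupture force and the loading rate r:

    F = (kB*T / dx) * ln( dx / (k_off * kB*T) ) + (kB*T / dx) * ln(r)

A straight-line fit of mean force against ln(loading rate) across pulling
speeds therefore yields the distance to the transition state
dx = kB*T / slope and the zero-force off-rate
k_off = (dx / kB*T) * exp(-intercept * dx / (kB*T)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .simulate import ForceExtensionTrace
from .traces import UnfoldingEvent
from .wlc import PhysicalContext

__all__ = [
    "GaussianFitResult",
    "BellEvansFit",
    "gaussian_fit_histogram",
    "bell_evans_force",
    "bell_evans_fit",
    "aggregate_by_speed",
    "dfs_fit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaussianFitResult:
    """Gaussian fit of a binned distribution (mean +/- SEM from the fit)."""

    mean: float
    sem: float
    sigma: float
    n: int
    bin_size: float
    converged: bool = True


@dataclass(frozen=True)
class BellEvansFit:
    """Bell-Evans regression result.

    ``points`` holds the per-speed aggregates that entered the fit as
    tuples ``(mean loading rate pN/s, mean force pN, sd rate, sd force, n)``.
    """

    delta_x: float  # nm
    k_off: float  # 1/s
    slope: float  # pN per ln(pN/s)
    intercept: float  # pN
    r_squared: float
    points: tuple[tuple[float, float, float, float, int], ...]


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def gaussian_fit_histogram(values, bin_size: float) -> GaussianFitResult:
    """Gaussian NLS fit of a histogram with bin edges anchored at zero.

    Requires at least 30 values (below that a binned Gaussian fit is not
    meaningful).  On non-convergence the sample mean / SEM are returned
    with ``converged=False`` instead of raising.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 30:
        raise ValueError(f"need >=30 values for a histogram fit, got {values.size}")
    if not bin_size > 0:
        raise ValueError("bin_size must be positive")
    lo = min(0.0, np.floor(values.min() / bin_size) * bin_size)
    edges = np.arange(lo, values.max() + bin_size, bin_size)
    if edges[-1] <= values.max():
        edges = np.append(edges, edges[-1] + bin_size)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    p0 = [counts.max(), float(values.mean()), max(float(values.std()), bin_size / 4)]
    try:
        if np.count_nonzero(counts) < 4:
            # degenerate histogram (population narrower than the binning):
            # a three-parameter Gaussian is under-determined
            raise RuntimeError("fewer than 4 occupied bins")
        popt, pcov = curve_fit(_gauss, centers, counts, p0=p0, maxfev=10000)
        mean, sigma = float(popt[1]), abs(float(popt[2]))
        sem = float(np.sqrt(pcov[1, 1]))
        if not np.isfinite(mean) or not np.isfinite(sem):
            raise RuntimeError("non-finite fit result")
        return GaussianFitResult(
            mean=mean, sem=sem, sigma=sigma, n=int(values.size),
            bin_size=float(bin_size), converged=True,
        )
    except Exception:
        logger.warning("Gaussian histogram fit did not converge; "
                       "falling back to sample mean/SEM")
        return GaussianFitResult(
            mean=float(values.mean()),
            sem=float(values.std(ddof=1) / np.sqrt(values.size)),
            sigma=float(values.std(ddof=1)),
            n=int(values.size),
            bin_size=float(bin_size),
            converged=False,
        )


def bell_evans_force(
    loading_rate,
    delta_x: float,
    k_off: float,
    context: PhysicalContext | None = None,
):
    """Most probable rupture force (pN) at loading rate r (pN/s).

    F = (kB*T/dx) * ln( dx * r / (k_off * kB*T) ).  For very small loading
    rates the logarithm goes negative and the value is returned as-is
    (with a debug log) — physically the domain unfolds before force builds.
    """
    ctx = context if context is not None else PhysicalContext()
    r = np.asarray(loading_rate, dtype=float)
    if not delta_x > 0 or not k_off > 0 or np.any(r <= 0):
        raise ValueError("loading_rate, delta_x and k_off must all be positive")
    kt = ctx.thermal_energy
    f = (kt / delta_x) * np.log(delta_x * r / (k_off * kt))
    if np.any(f < 0):
        logger.debug("Bell-Evans force negative at r=%s (below spontaneous regime)", r)
    return float(f) if f.ndim == 0 else f


def bell_evans_fit(
    points,
    context: PhysicalContext | None = None,
) -> BellEvansFit:
    """Linear Bell-Evans fit of mean force vs ln(mean loading rate).

    ``points`` is an iterable of ``(loading_rate, force)`` pairs (extra
    trailing entries such as error bars are preserved in the result).
    Requires >=3 points spanning at least one decade of loading rate;
    a non-positive slope is rejected as unphysical.
    """
    ctx = context if context is not None else PhysicalContext()
    pts = [tuple(p) for p in points]
    if len(pts) < 3:
        raise ValueError("Bell-Evans fit needs at least 3 (rate, force) points")
    r = np.array([p[0] for p in pts], dtype=float)
    f = np.array([p[1] for p in pts], dtype=float)
    if np.any(r <= 0):
        raise ValueError("loading rates must be positive")
    if r.max() / r.min() < 10.0:
        raise ValueError("loading rates must span at least one decade")

    ln_r = np.log(r)
    slope, intercept = np.polyfit(ln_r, f, 1)
    if slope <= 0:
        raise ValueError(
            f"non-positive Bell-Evans slope ({slope:.3g} pN); "
            "force must increase with loading rate"
        )
    kt = ctx.thermal_energy
    delta_x = kt / slope
    k_off = (delta_x / kt) * np.exp(-intercept * delta_x / kt)

    pred = slope * ln_r + intercept
    ss_res = float(np.sum((f - pred) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    full_points = tuple(
        (
            float(p[0]),
            float(p[1]),
            float(p[2]) if len(p) > 2 else float("nan"),
            float(p[3]) if len(p) > 3 else float("nan"),
            int(p[4]) if len(p) > 4 else 0,
        )
        for p in pts
    )
    return BellEvansFit(
        delta_x=float(delta_x), k_off=float(k_off),
        slope=float(slope), intercept=float(intercept),
        r_squared=r2, points=full_points,
    )


# --------------------------------------------------------------------------
# Per-speed aggregation and the DFS pipeline tail
# --------------------------------------------------------------------------

def aggregate_by_speed(
    dataset: list[tuple[ForceExtensionTrace, list[UnfoldingEvent]]],
    label: str = "target",
) -> list[tuple[float, float, float, float, int]]:
    """Mean loading rate and mean force per pulling speed for one label.

    Returns one tuple ``(mean r, mean F, sd r, sd F, n)`` per speed,
    ordered by speed; standard deviations are the error bars of the
    force-vs-ln(rate) plot.
    """
    by_speed: dict[float, list[tuple[float, float]]] = {}
    for trace, events in dataset:
        for e in events:
            if e.domain_label == label and e.loading_rate is not None:
                by_speed.setdefault(trace.protocol.speed, []).append(
                    (e.loading_rate, e.peak_force)
                )
    out = []
    for speed in sorted(by_speed):
        arr = np.asarray(by_speed[speed], dtype=float)
        out.append(
            (
                float(arr[:, 0].mean()),
                float(arr[:, 1].mean()),
                float(arr[:, 0].std(ddof=1)) if arr.shape[0] > 1 else 0.0,
                float(arr[:, 1].std(ddof=1)) if arr.shape[0] > 1 else 0.0,
                int(arr.shape[0]),
            )
        )
    return out


def dfs_fit(
    dataset: list[tuple[ForceExtensionTrace, list[UnfoldingEvent]]],
    label: str = "target",
    context: PhysicalContext | None = None,
    most_probable_correction: bool = True,
) -> BellEvansFit:
    """Per-speed aggregation followed by the Bell-Evans regression.

    The Bell-Evans line describes the *most probable* rupture force,
    while the per-speed aggregate is a sample mean; for a Bell process
    at near-constant loading rate the rupture-force distribution is
    Gumbel-shaped with scale kB*T/dx, so the mean sits Euler-gamma
    scale units below the mode.  With ``most_probable_correction`` the
    intercept is shifted by gamma * kB*T/dx before extracting the
    off-rate (equivalently k_off is multiplied by exp(-gamma) ~ 0.561);
    the slope, hence dx, is unaffected.
    """
    fit = bell_evans_fit(aggregate_by_speed(dataset, label), context)
    if most_probable_correction:
        gamma = float(np.euler_gamma)
        fit = BellEvansFit(
            delta_x=fit.delta_x,
            k_off=fit.k_off * math.exp(-gamma),
            slope=fit.slope,
            intercept=fit.intercept + gamma * fit.slope,
            r_squared=fit.r_squared,
            points=fit.points,
        )
    return fit
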