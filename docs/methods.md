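# Methods

## The forward model

A pulling trace is generated by a fixed-time-step kinetic Monte-Carlo
integration of a two-state Bell model coupled to worm-like-chain (WLC)
elasticity. The cantilever base retracts at constant speed `v`; at time
`t` its position `z = v·t` is split between polymer extension `x` and
cantilever deflection `F/k` by solving the force balance
`F_WLC(x; L_c) = k·(z − x)` (Newton iteration warm-started from the
previous step, bisection-safeguarded; the balance function is strictly
monotone so the root is unique). `L_c` is the current total contour
length: unstructured linkers plus, for each domain, its folded N–C span
while folded or span + ΔL_c once unfolded, so the fitted contour-length
increment between consecutive events equals the domain's ΔL_c exactly.

Each folded domain unfolds during a step of length `Δt` with probability
`1 − exp(−k_off·e^{FΔx/k_BT}·Δt)`; the handle rupture uses the same
hazard with much stronger parameters and terminates the trace (a short
zero-force baseline is appended, as in a real retraction after
detachment). The Bernoulli-per-step scheme is exact for the integrated
hazard when the force is constant within a step; the default step of
0.1 nm of travel keeps the per-step force change below ~2 pN and the
per-step hazard well below 0.5 at typical rupture forces (a warning is
logged if it is exceeded). Refolding, unfolding intermediates, and
hydrodynamic cantilever dynamics are deliberately out of model.

Gaussian white noise (default σ = 8 pN) is added to the recorded force
only; the rupture log keeps the noise-free ground truth. Extension is
recorded as the polymer end-to-end distance (tip–sample separation), the
axis on which WLC fits are performed.

## Parameters and presets

| parameter | default | why |
|---|---|---|
| persistence length `p` | 0.4 nm | canonical unfolded-polypeptide value in SMFS fitting; the source study does not state one |
| temperature | 298 K (k_BT = 4.114 pN·nm) | room-temperature experiments |
| cantilever spring `k` | 50 pN/nm | typical soft MLCT-class lever; not stated in the study |
| noise σ | 8 pN | visually consistent with published AFM traces; zero allowed for oracle tests |
| contour gain per residue | 0.36 nm | standard stretched-backbone value |
| handle (Δx, k_off) | 0.12 nm, 3×10⁻³ s⁻¹ | produces a ~400 pN mean rupture at 1000 nm/s, the published anchor |

Domain presets: GB1 fingerprint (ΔL_c 18 nm, Δx 0.17 nm, k_off
0.035 s⁻¹), natural spectrin repeat (32 nm, 0.60 nm, 0.22 s⁻¹), and the
designed four-helix series (53 nm, Δx 0.19 nm shared, k_off 0.44 / 0.09 /
0.05 s⁻¹ for parent / salt-bridge / metal-coordination variants). The
designed-series kinetics are the published Bell–Evans constants; GB1 and
spectrin kinetics are not published, so Δx is fixed at literature-typical
values and k_off was tuned once so the simulated Gaussian-mean unfolding
force at 1000 nm/s reproduces the published anchors (213 pN and 56 pN).

## Analysis pipeline choices

**Detection.** Moving-average smoothing (window 5 samples) before peak
picking; peaks require prominence ≥ `min_drop` (default 30 pN — below
the smallest relevant unfolding force, ~4× the post-smoothing noise) and
a drop of at least `min_drop` shortly after. The rupture position is
then refined to the largest single-step drop of the *raw* force near the
smoothed peak: smoothing displaces an apparent peak by about half a
window, while the raw drop localizes the rupture to one sample.

**Per-peak WLC fit.** Bounded least squares on the rising segment with
only `L_c` free; fixing `p` avoids the p/L_c degeneracy on short
segments. The event's rupture force is then read from the fitted WLC at
the rupture extension rather than from the raw (noisy) sample.

**Selection and labels.** An event is a fingerprint if the increment its
rupture releases lies within 18 ± 4 nm (a window that separates the
18 nm fingerprint from the 32 and 52–53 nm populations by several
widths); the last event is the handle if it exceeds 300 pN (between the
largest domain force, ~208 pN, and the ~400 pN handle). A trace is
accepted only with ≥3 *consecutive* fingerprint events followed by a
qualifying handle rupture. Negative increments flag both events of the
pair unassigned; they are excluded from histograms, never silently
dropped.

**Calibration.** The Gaussian mean of fingerprint forces at the
reference speed is pinned to 213 pN and the whole dataset rescaled. The
internal mean estimator bins over `[0, max]` with a count-scaled number
of bins, which makes it exactly scale-equivariant — hence calibration is
idempotent to machine precision. Forces at non-reference speeds reuse
the same factor (the anchor is defined only at 1000 nm/s).

**Loading rate.** `r = slope × v` with two deliberate choices. First,
the "slope of the force peak" is the chord of the fitted WLC over the
last 5 nm before rupture — the line one would fit through the final
force rise — not the endpoint tangent, which diverges toward the contour
length and overstates the rise that actually loaded the domain. Second,
the slope is composed in series with the cantilever spring
(`dF/dt = v·s·k/(s+k)`): piezo travel is shared between polymer
extension and lever deflection. Ground-truth closure tests show the
endpoint-tangent, polymer-only convention overestimates recovered
off-rates by ×4–10 for stiff, high-force domains; with the chord+series
convention the parent-domain recovery is centered on the true value. The
5 nm window was fixed by that closure validation.

**Bell–Evans regression.** Per speed, the mean loading rate and mean
force (sd as error bars) feed an unweighted OLS of `F` on `ln r`;
`bell_evans_fit` is the exact algebraic inverse of the printed relation
and is kept pure. `dfs_fit` additionally applies a most-probable-force
correction by default: the Bell–Evans line describes the distribution
mode while the aggregate is a sample mean, and for a Bell process at
near-constant loading rate the rupture-force distribution is
Gumbel-shaped with scale `k_BT/Δx`, putting the mean `γ·k_BT/Δx` (γ =
0.5772) below the mode. The correction shifts the intercept by `γ·slope`
(equivalently multiplies k_off by `e^{−γ}`); the slope, hence Δx, is
untouched.

**Histograms.** Bin edges anchored at zero; default bin sizes 30 pN for
forces (13.75 pN for the weak spectrin population) and 2 nm for ΔL_c.
Mean, σ and the SEM of the mean come from the nonlinear fit covariance.
When the population is narrower than the binning (fewer than four
occupied bins — routine for the nearly noise-free simulated ΔL_c
distributions) a three-parameter Gaussian is under-determined and the
estimator falls back to the sample mean/SEM with a `converged=False`
flag.

## Screening metrics

GRAVY is the plain Kyte–Doolittle mean; the developability gate defaults
to inclusive (≤ −0.3) with a strict variant by flag, and the foldability
gate to strict (pLDDT > 90, RMSD < 2.0 Å) with an inclusive variant —
both conventions appear in practice and differ only at exact boundary
values. Kabsch RMSD is computed on paired Cα sets after centering via
`scipy`'s rotation alignment. SASA is an in-package Shrake–Rupley with a
golden-spiral quadrature (960 points, probe 1.4 Å, Bondi-type element
radii); it is cross-checked in the tests against an analytic sphere and
an independent implementation (biotite) to ~0.5%. rSASA divides each
residue's heavy-atom SASA by its type's theoretical Gly-X-Gly maximum
(Tien et al. 2013 values, shipped verbatim); ratios are clipped to
[0, 1.5] with the clip count logged. Because the original study does not
state its SASA algorithm, radii, or reference maxima, absolute
rSASA-derived percentages can shift by a few points under different
conventions. SMD ranking smooths each replicate force series (window 50
samples) and takes the global maximum; ties break by candidate id.

## What the synthetic data does and does not show

The generator reproduces the features the analysis depends on: WLC force
ramps with the correct contour ladder, force-dependent Bell kinetics with
published constants, serial-construct selection statistics, cantilever
compliance, handle rupture, and white force noise. It does not emulate
baseline drift, multiple tethers, surface adhesion peaks, 1/f noise,
refolding, or unfolding intermediates — so green tests demonstrate the
estimators' correctness and closure on the modeled physics, not
robustness to every instrumental artifact of real data.

Recovery of k_off is intrinsically the hardest closure: it is the
exponential of a regression intercept extrapolated a decade below the
data. At 250 traces per speed the recovered off-rate scatters by roughly
a factor of e^±0.25 seed-to-seed, and for the strongest (metal-clamp)
domain a residual ~×2 overestimate remains because the loading rate
grows steeply near full extension while the Bell–Evans relation assumes
it constant — the same limitation applies to the published procedure on
real data. Δx recovery is robust (within a few percent, tolerance ±20%).

## Problem sizes

The recovery runs use 250 traces per speed at 4 speeds for each kinetic
construct, 200 traces for the contour-increment statistics, and 120 for
the calibration path; the closed-form rupture-force check uses 500
single-domain repeats. These sizes put Monte-Carlo error comfortably
inside each stated tolerance while keeping a full run to minutes on one
CPU.

## Known limitations

* Two-state, single-pathway unfolding only; no Dudko–Hummer–Szabo or
  maximum-likelihood rupture-force estimators.
* The template-structure packing check (fraction of buried residues in
  the natural spectrin repeat) requires the deposited PDB coordinates,
  which are not redistributable here; the rSASA machinery is validated
  on constructed geometries instead.
* Simultaneous same-step ruptures and spontaneous near-zero-force
  unfolding events are physically legitimate generator outputs that no
  drop detector can resolve; detection accuracy is therefore stated
  against resolvable events.
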