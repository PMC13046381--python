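# polyforce

Simulation and analysis of single-molecule force spectroscopy (AFM–SMFS)
on serial polyprotein constructs, plus the computational screening metrics
used to triage designed protein candidates before any experiment.

The package is aimed at people who analyze constant-velocity pulling data
on engineered polyproteins — a target domain fused in series with
well-characterized fingerprint domains (GB1) and pulled through a
high-strength receptor–ligand handle — and at people who want a fully
synthetic, ground-truth-bearing testbed for such analysis pipelines.

## What it computes

**Polymer elasticity.** Worm-like-chain (WLC) force–extension in the
Marko–Siggia form, `F(x) = (k_BT/p)[1/(4(1−x/L_c)²) − 1/4 + x/L_c]`,
with its inverse and analytic stiffness, and contour-length bookkeeping
(0.36 nm of backbone per stretched residue minus the folded N–C span).

**Pulling simulator.** A kinetic Monte-Carlo emulator of constant-velocity
AFM pulling: at each step the cantilever position is partitioned between
polymer extension and cantilever deflection by a WLC/spring force balance,
and every folded domain carries a two-state Bell hazard
`k(F) = k_off · exp(F·Δx / k_BT)`. Unfolding adds the domain's ΔL_c to the
chain; the trace ends when the ~400 pN handle ruptures. Presets encode a
GB1 fingerprint (ΔL_c = 18 nm, 213 pN at 1000 nm/s), a natural spectrin
repeat (32 nm, 56 pN) and a designed four-helix domain series
(53 nm; k_off = 0.44 / 0.09 / 0.05 s⁻¹, Δx = 0.19 nm). Every simulated
trace carries a noise-free rupture log, so recovery is testable.

**Curve analysis.** Rupture-peak detection on smoothed traces, per-peak WLC
fits (persistence length fixed, contour length free), contour-length
increments ΔL_c, fingerprint-based single-molecule trace selection (≥3
consecutive ~18 nm increments followed by a high-force handle rupture),
internal-standard force calibration against the fingerprint's 213 pN
anchor, and per-event loading rates (force-peak slope × retraction speed,
with the cantilever spring in series).

**Kinetics & statistics.** Gaussian fits of zero-anchored force/ΔL_c
histograms (mean ± SEM from the fit) and the Bell–Evans dynamic force
spectroscopy regression

```
F = (k_BT/Δx) · ln( Δx / (k_off · k_BT) ) + (k_BT/Δx) · ln(r)
```

fitted by ordinary least squares of mean force against ln(mean loading
rate) across pulling speeds: Δx = k_BT/slope,
k_off = (Δx/k_BT)·exp(−intercept·Δx/k_BT).

**Screening funnel.** GRAVY hydropathy (Kyte–Doolittle) with a ≤ −0.3
developability gate, a pLDDT > 90 / RMSD < 2.0 Å foldability gate, Kabsch
superposition RMSD, Shrake–Rupley SASA with per-residue relative SASA
(packing score: fraction of residues with rSASA < 0.2), peak-force ranking
of steered-MD pulling replicates, and annealing-MD final-vs-initial RMSD.

## Worked example

Simulate a dynamic-force-spectroscopy campaign on the designed-domain
construct (100 traces at each of 400/1000/2000/4000 nm/s), run the full
analysis chain, and recover the kinetics:

```python
import polyforce as pf

construct = pf.construct_preset("specai41")
traces = pf.simulate_dfs_dataset(construct, [400, 1000, 2000, 4000], 100, base_seed=7)
dataset = pf.analyze_dataset(traces)   # detect, fit, select, label, rates

forces = [e.peak_force for _, ev in dataset for e in ev if e.domain_label == "target"]
g = pf.gaussian_fit_histogram(forces, 30.0)
print(f"designed-domain unfolding force: {g.mean:.0f} +/- {g.sem:.0f} pN (n = {g.n})")

deltas = [e.delta_lc_to_next for _, ev in dataset for e in ev
          if e.domain_label == "target" and e.delta_lc_to_next is not None]
d = pf.gaussian_fit_histogram(deltas, 2.0)
print(f"designed-domain delta-Lc:        {d.mean:.1f} nm")

fit = pf.dfs_fit(dataset, label="target")
print(f"Bell-Evans: dx = {fit.delta_x:.2f} nm, k_off = {fit.k_off:.2f} /s, R^2 = {fit.r_squared:.3f}")
```

Output:

```
designed-domain unfolding force: 156 +/- 3 pN (n = 298)
designed-domain delta-Lc:        53.0 nm
Bell-Evans: dx = 0.18 nm, k_off = 0.56 /s, R^2 = 0.990
```

The Gaussian-mean unfolding force (156 pN at 1000-nm/s-dominated loading)
and ΔL_c (53 nm, the full ~150-residue domain) are the headline per-event
statistics; the Bell–Evans fit recovers the transition-state distance
(0.19 nm fed to the simulator) and the zero-force off-rate (0.44 s⁻¹ fed,
recovered within the intrinsic scatter of a four-point regression whose
intercept is exponentiated).

The same steps are scriptable from the shell:

```sh
polyforce simulate --preset specai41 --speed 400 --speed 1000 \
    --speed 2000 --speed 4000 --n 100 --seed 7 --out runs/dfs
polyforce dfs-fit --traces runs/dfs --out runs/fit
polyforce screen-seq --fasta designs.fasta --out runs/screen
```

Every CLI run writes a `provenance.json` (config, seed, versions, defaults
used); identical config + seed reproduce identical outputs bit-for-bit.

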