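# Methods

## Scope and model

`poreflux` analyses non-equilibrium MD studies of water transport through
a single channel embedded in a sealed membrane.  The physical model is
the standard linear-response picture of reverse osmosis at the
single-channel scale:

* A hydrostatic pressure difference ΔP across the membrane drives a net
  water flux.  Within the linear regime the per-channel volumetric flow
  is Q = L_P ΔP, defining the hydraulic permeability L_P (here quoted in
  cm⁵ N⁻¹ s⁻¹, i.e. volume flow per unit pressure; the per-area flux
  J_v = Q/A is also reported).
* An osmotic driving force ΔC of an impermeable solute is equivalent to
  ΔP = R T ΔC (van 't Hoff), so the osmotic permeability P_f defined by
  the molar flux J_m = P_f ΔC obeys P_f = L_P R T / V_W exactly, with
  V_W the molar volume of water.  The package treats this as a strict
  unit conversion (default V_W = 18.07 cm³ mol⁻¹, R = 8.314462618
  J mol⁻¹ K⁻¹, T = 300 K; all configurable).
* In a periodic simulation box the pressure difference is produced
  without pistons by the three-region constant-force scheme: a constant
  axial force f on every water oxygen in a slab (region III, thickness
  d) isolated from the membrane faces by regions I and II generates
  ΔP = n f / A = f d / v_W and Δμ = f d.  The package implements the
  arithmetic and per-frame force assignment; it does not integrate
  dynamics.  Region membership uses half-open intervals [z_min, z_max)
  so the partition never double-counts; membrane position restraints
  that accompany the scheme in production MD are carried as config
  metadata only.

Internal units are nm, ns, kJ/mol, MPa; permeabilities are additionally
emitted in cm⁵ N⁻¹ s⁻¹ and cm³ s⁻¹.  Boxes are orthorhombic only;
water is represented by its oxygen for all counting and density work.

## Crossing detection

A crossing is a full traversal from beyond one entry plane (z_lo) to
beyond the other (z_hi) of the channel cylinder, with every frame spent
axially between the planes also radially within the channel radius.
This plane-to-plane definition deliberately ignores midplane and
vestibule fluctuations; a radial excursion out of the cylinder while
between the planes voids the event (strict sealing semantics, which
makes the complementary `seal_check` conservative).  Particles first
seen between the planes acquire an origin side only at their first
exit, a deterministic tie-break.  Re-crossings are retained as
individual events and cancel in the net count, so both raw and net
conventions are recoverable from the event list.

The detector requires axis-unwrapped input (cumulative minimum-image
corrections along the channel axis) and refuses trajectories containing
jumps of half a box edge or more, which are ambiguous under the
minimum-image convention.  The implementation scans the compressed
sequence of outside-channel sightings per particle; an exhaustive
per-frame state machine kept in the test suite re-derives every event
list independently.

Sampling condition: the net count is invariant under subsampling as
long as traversal times span several output intervals; the synthetic
generator's scripted traversals span ≥ 4 intervals at the default
10 ps stride, and the suite checks 2× subsampling invariance.

## Flux uncertainty and the slope fit

`net_flux` reports two standard errors for the net rate J_W:

* a block-averaged SE (5 equal time blocks by default), the generic
  estimator for correlated MD data;
* the counting-statistics SE √(N₊+N₋)/T, exact when crossings form a
  point process (the variance of a difference of independent Poisson
  counts is their summed mean).

`fit_LP` is a weighted least-squares slope through the origin (the
linear law has no intercept), with inverse-variance weights when
per-point SEs are supplied and an unweighted residual-based SE
otherwise; a free-intercept fit is always reported as a linearity
diagnostic, never used as the estimator.

For the end-to-end recovery of a crossing-rate coefficient from event
counts, `fit_crossing_rate` instead uses Poisson working weights with
one IRLS refinement (weights from the model-predicted raw rate
g ΔP + 2 r_b).  The reason is calibration: a 5-block SE carries ~4
degrees of freedom, and inverse-variance weighting by such noisy SEs
produces slope SEs that undercover badly (measured 2-SE coverage ≈ 0.80
versus ≈ 0.95 for the Poisson-weighted fit over hundreds of synthetic
replicates).  For a counting experiment the Poisson variance is the
exact sampling model, so this is the package's default for rate
recovery, while `fit_LP` keeps the general-purpose behaviour for
arbitrary flux tables.

## Structural profiles

All profiles work in cylindrical coordinates (ρ, z) about the channel
axis, optionally after translating each frame so a centering selection
(typically the protein backbone) sits at the axis origin.

* **Radial thickness**: per ρ-bin difference of the mean axial
  positions of upper- and lower-leaflet C2 markers (the carbon
  separating the lipid head from its two tails; the marker atom name is
  user-configured, never hard-coded).  Bins default to 0.25 nm.  Empty
  bins are flagged, not zero-filled.  The biological reference
  thickness h_bio = 2.5 nm is carried on the result for comparison.
* **Axial density**: per z-bin mean count / (A·Δz) (z bins default to
  0.1 nm; any monotone edges accepted), optionally mass-weighted to
  g cm⁻³.  The conservation identity Σ density·bin volume = mean
  in-range count holds to machine precision by construction.
* **Chain elongation**: |z(last tail carbon) − z(first)| per chain,
  binned by the lipid's C2 radius — the quantitative proxy for the
  gauche→trans transition (all-trans chains are maximally extended).
  Dihedral statistics are out of scope.
* **Backbone RMSD**: Cartesian RMSD against a reference frame, with
  optional optimal rigid-body superposition (Kabsch SVD with the
  determinant guard against reflections).  Superposed RMSD never
  exceeds raw RMSD; a rigid motion gives 0 to numerical precision.

Uncertainties on binned profiles follow the block-decorrelation
convention: SE of the mean over frames from 5 blocks by default.

## Synthetic generator

The generator produces the statistical structure the analyses assume,
with analytic ground truth, at desk scale (≲10⁴ particles):

* **Channel runs** (`gen_channel_trajectory`): forward traversals are
  scheduled as a Poisson process at rate g ΔP + r₀ and backward ones at
  r₀, so the expected net rate is exactly g ΔP; each scheduled event is
  executed by a dedicated water as a scripted biased walk through the
  cylinder (completion inside the sampled window is guaranteed, so the
  recorded event log is exact, not approximate).  Remaining waters
  jitter in the reservoirs and never touch the slab — the sealed
  annulus — unless leak paths are planted, each of which crosses once
  outside the channel radius.  Defaults define the baseline study
  conditions: g = 0.2 events ns⁻¹ MPa⁻¹, applied pressures
  10/25/50/75/100 MPa, 10 ns per run sampled every 10 ps, r₀ =
  0.05 ns⁻¹, a 0.4 nm channel through a 2.5 nm slab in a 10×10×12 nm
  box, 100 sparse bulk waters.
* **Lipid shell** (`gen_lipid_shell` / `gen_lipid_trajectory`): leaflet
  C2 markers at z = ±h(ρ)/2 with h(ρ) = h_bio + Δh (ρ/ρ_max)^k
  (defaults 2.5 + 1.5 (ρ/4)² nm) and two tail chains per lipid whose
  axial elongation rises linearly with ρ (0.4 → 1.0 nm, below the chain
  contour length).  Jitter is axial only, so binning by ρ is
  deterministic and the imposed laws averaged over each bin's own
  lipids are exact oracles.
* **Density systems** (`gen_density_system`): waters and ions placed
  i.i.d. per frame by inverse-CDF sampling of a piecewise law — zero
  inside |z| ≤ 1 nm, linear ramp to 4 nm, bulk plateau beyond — at a
  sparse desk-scale bulk density (0.5 nm⁻³ by default) with a
  seawater-like ion/water number fraction of 2.2% (≈3.5% salt by mass).

Same seed ⇒ bit-identical trajectories and logs (single RNG stream per
call).

What the generator does **not** emulate: atomistic water structure and
hydrogen bonding, protein flexibility, channel gating, correlated
single-file transport, lipid diffusion, or insertion dynamics.  Passing
tests therefore demonstrate the correctness of the analysis chain on
data satisfying its stated assumptions, not the fidelity of any MD
force field.

## Statistical conventions in the tests

Recovery checks compare estimates against generator-side oracles (the
imposed law averaged over each bin's actual members, or the exact event
log), z-scored by the reported SEs.  Joint checks over many bins use
the RMS z-score at the 2-SE scale (with a max-|z| sanity cap) rather
than requiring every bin inside ±2 SE: with ~14 bins and small-sample
SEs, the per-bin-AND rule would fail for a perfectly unbiased estimator
roughly half the time, while the RMS form keeps the same sensitivity to
real bias at a negligible false-alarm rate.  The end-to-end rate
recovery instead follows a replicate design: the fitted g must land
within 2 fitted SE of truth in ≥ 90% of 50 seeded sweeps.

## Problem sizes

Default test and acceptance workloads: 10 ns runs at 10 ps stride
(1001 frames, a few hundred particles) per pressure, 50 replicate
sweeps, 20 × 1000 random walkers for the detector cross-check, 40-frame
lipid trajectories (5100 particles), 30-frame density systems.  These
sizes keep every statistical check well-resolved while the full suite
runs in well under a minute.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* Crossing counting uses fixed entry planes in unwrapped coordinates;
  particles that circulate through the periodic image of the membrane
  are not re-counted against the image planes (the synthetic reservoirs
  are bounded, so this does not arise in generated data).
* No collective-diffusion (equilibrium MSD) permeability estimator —
  only directed counting.
* No area-per-lipid, order-parameter, curvature, or secondary-structure
  analyses.
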