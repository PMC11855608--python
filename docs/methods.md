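# Methods

## The diffusivity estimator

A solute harmonically restrained at depth z along the bilayer normal
experiences a restraint force F(z, t) = −k (z(t) − z₀). In the stiff-spring
regime the fluctuation statistics of that force encode the local friction,
and the local diffusion coefficient follows from

    D(z) = (RT)² / ∫₀^∞ ⟨ΔF(z, t) ΔF(z, 0)⟩ dt ,

where ΔF = F − ⟨F⟩. The implementation treats the instantaneous harmonic
restraint force as the force series (the protocol it models restrains
rather than rigidly constrains the solute; the two coincide as k → ∞).

**ACF estimation.** The autocorrelation is the time-average over shifted
origins, ACF(j·dt) = 1/(N−j) · Σᵢ ΔFᵢ ΔFᵢ₊ⱼ. The per-lag 1/(N−j)
normalization is unbiased at every lag; the 1/N variant shrinks the tail,
which biases the integral on ~10 ns windows. Computation is FFT-based
(zero-padded) and verified in the tests against the O(N²) double loop to
1e-10. The default maximum lag is 10% of the window duration — beyond
that the estimator variance dwarfs any remaining signal. ACF(0) equals
the sample variance by construction.

**Truncation.** The literal ∫₀^∞ diverges on noisy data, so the trapezoid
integral stops at the first lag where the ACF is ≤ 0 (integrating the
trapezoid that ends at the crossing, which contributes ~0 for a clean
sign flip). A fixed-lag override exists for analytic or well-characterized
ACFs. If the ACF never crosses zero within the available lags the full
range is integrated and a warning emitted.

**Expected precision.** For an exponential (Ornstein–Uhlenbeck) force ACF
with amplitude k·RT and correlation time τ = RT/(k·D), the trapezoid of
the exact discrete ACF reproduces (RT)²/D identically, so the estimator
is exact up to truncation bias (≈ e^(−t_c/τ), typically 3–5% at the first
zero crossing) and sampling noise. The sampling noise of the ACF integral
on a single window of duration T_w is the dominant error: its relative
standard deviation is ~√(c·τ/T_w) with c ≈ 10–20, i.e. **~13–20% for a
10 ns window at τ ≈ 10–26 ps**. Single-window estimates therefore scatter
at that level regardless of truncation rule (verified empirically; fixed-
lag truncation is no tighter). Quantitative comparisons should average
several windows or seeds: the 5-window median used in the tests carries
~6–8%, and a 24-window region average ~3–4%. This is an intrinsic
property of force-ACF estimation at these correlation times, not an
implementation artifact.

**Units.** D is computed in nm²/ps with R = 8.31446×10⁻³ kJ mol⁻¹ K⁻¹ and
converted once to cm²/s (×10⁻²). All internal quantities follow GROMACS
conventions (nm, ps, kJ/mol).

**Profile and comparison.** One D per umbrella window, sorted by center z;
windows whose estimation fails (zero variance, non-positive integral) are
reported alongside the profile rather than dropped. The region average is
the unweighted mean over windows with z ∈ [−2.3, 2.3] nm, the central
hydrophobic region that forms the main transport barrier; percent change
between systems is 100·(D_t − D_c)/D_c, reported rounded to the nearest
integer with the unrounded value retained. No leaflet symmetrization of
D(z) is applied — measured profiles are generally asymmetric, and
symmetrizing would be an extra assumption.

## Structural observables

**Thickness** is the difference of mean headgroup z between leaflets,
leaflets assigned per frame by the sign of z − midplane with midplane =
mean z of the selected reference atoms (ties go to the upper leaflet with
a warning; an empty leaflet is an error — that is not a bilayer). The
default headgroup selector covers the ceramide and long-chain fatty-acid
head atoms and excludes cholesterol, whose hydroxyl sits below the
headgroup plane; the selector is fully configurable since atom naming
varies between force fields.

**Area per lipid** tessellates each leaflet's reference atoms in the
xy-plane with a 3×3 periodic tiling (all 8 neighbor images), keeps the
cells of central-copy seeds, and takes polygon areas by the shoelace
formula. Tiling makes every central cell closed and exact as long as no
cell spans more than a box length, and guarantees the conservation law —
cell areas per leaflet sum to lx·ly — which is asserted at 1e-9 relative
on every call. The frame value is the unweighted mean of the two leaflet
means (not pooled cells): leaflets can hold unequal lipid counts after
permeant insertion, and the symmetric average avoids weighting one
leaflet by count. Whether the original workflow averaged leaflets or
pooled cells is not documented; this choice is the package's own.

**Hydrogen bonds** use the geometric donor–acceptor distance cutoff
(0.30 nm default) under the minimum-image convention. An optional
donor–hydrogen–acceptor angle criterion (≥ 180° − cutoff) can be enabled
when hydrogen positions are supplied; it is off by default because the
distance-only criterion is the documented method, while the angle test is
what VMD-style tools normally add — both behaviors are exposed. Donors
and acceptors are plain atom selections; no force-field perception is
attempted.

**Replicate statistics.** Summaries are aggregated as mean ± standard
error over replicate means (sample std/√n, zero for a single replicate) —
never over pooled frames, which would understate the error by ignoring
the within-run correlation of frames.

**Permeant depth** is the per-frame minimum over group atoms of
|z − midplane_z| (default) or of the minimum-image 3D distance to the
lipid center of geometry. The midplane is recomputed each frame because
the bilayer drifts under pressure coupling. Replicate curves are averaged
pointwise after linear interpolation onto the first replicate's time grid,
restricted to the overlapping range (interpolation only, never
extrapolation); the band is the population standard deviation.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis
operators consume, at the scales of a body-temperature SC-bilayer study:
T = 310 K, forces stored every 0.1 ps, 10 ns analyzed per window, spring
constants 1000–3000 kJ mol⁻¹ nm⁻², D ~ 10⁻⁴ nm²/ps (≈10⁻⁶ cm²/s),
100-lipid leaflets at ~1 nm² per lipid with headgroup planes ~4.5 nm
apart, and duplicate replicates.

* Restrained windows integrate overdamped Langevin dynamics
  (Euler–Maruyama) in the harmonic restraint; constant-D windows use the
  exact AR(1) form of that recursion, started from the stationary
  distribution. Spatially varying D(z) uses the Itô convention with the
  ∂D/∂z drift correction — without it the stationary density is wrong and
  recovery tests would be biased. The integration step equals the 0.1 ps
  storage interval, safely below τ/10 for all study parameters (a warning
  fires otherwise, and dt ≥ 2τ is rejected as unstable).
* Pseudo-bilayers are single-site headbeads on jittered lattices — the
  observables under test (plane distances, Voronoi areas, pair distances)
  are purely geometric, so chemical realism would add nothing. Residue
  names cycle through the ceramide/cholesterol/fatty-acid species so
  selector logic is exercised. Planted donor–acceptor pairs sit at
  0.28 nm (inside the cutoff) and decoys at 0.35 nm (outside), spaced
  ≥ 0.8 nm apart so no cross-pair contact confounds the count.
* Adsorption traces are a deterministic drift toward the surface plus
  seeded Gaussian noise, clipped at zero.

What passing tests on these inputs shows: the estimator and the
structural operators are correct on data whose ground truth is known
exactly, at realistic parameter scales. What they do not show: behavior
on real all-atom trajectories — force ACFs with multiple relaxation
timescales, anharmonic and drifting bilayers, protonation/naming
idiosyncrasies. The readers and selectors accept such data; the
validation simply cannot vouch for it.

All generators are bit-reproducible given a seed; multi-window runs
derive per-window streams as seed + window index.

## Numerical and design choices

* Orthorhombic boxes only; triclinic cells would complicate the periodic
  Voronoi tiling for no benefit at these geometries.
* Structure dialects: GRO (nm, fixed-width), PDB (Å, CRYST1 box), XYZ
  (Å, box supplied in configuration). Multi-frame GRO uses `t=` title
  times; PDB uses MODEL/ENDMDL. Readers report parse errors with line
  numbers; writers emit deterministic output (byte-identical for equal
  inputs).
* Time series are two-column whitespace text with '#'/'@' comments
  (xvg-compatible); non-uniform sampling is a warning, not an error, and
  non-monotone time is rejected.
* The analysis window defaults to the final 20 ns of a 100 ns run
  (80–100 ns) for structural observables, the equilibrated portion.
* Selection grammar: field tests (==, !=, in {…}) joined by and/or with
  parentheses — deliberately small, deterministic, and topology-free.
* Report rounding: thickness 2 decimals, area-per-lipid 3, H-bonds 2, D
  two significant figures; full precision is kept in the JSON summary and
  log.
* Pipeline bundles are byte-reproducible under a fixed config and seed;
  any stage failure removes partial outputs and names the stage.

## Known limitations

* The stiff-spring identification of restraint forces with constraint
  forces breaks down for soft springs (τ comparable to the slow bilayer
  modes); k ≥ 1000 kJ mol⁻¹ nm⁻² is assumed.
* Single-window D estimates carry ~13–20% sampling scatter at 10 ns (see
  above); the package reports per-window values and leaves averaging
  strategy to the caller or pipeline.
* No potential-of-mean-force or permeability-coefficient calculation;
  the package stops at D(z) and its region averages.
* Donor/acceptor identification is name-based; unusual naming schemes
  need explicit selectors.
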