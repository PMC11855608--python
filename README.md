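# scpermeate

Analysis tools for molecular-dynamics studies of solute permeation through
stratum-corneum (SC) lipid bilayers — the ceramide / cholesterol / free
fatty acid membranes that form the skin's outermost permeability barrier.

The package reimplements, as a tested library, the trajectory-analysis
chain such studies run after the MD engine has done its work:

* **Bilayer structure** — leaflet assignment, bilayer thickness (difference
  of mean headgroup z between leaflets), and area-per-lipid from a periodic
  2D Voronoi tessellation of each leaflet.
* **Molecular interactions** — hydrogen-bond counting with the geometric
  donor–acceptor cutoff (3.0 Å default, optional angle criterion) and
  permeant-to-midplane minimum-distance tracking with replicate averaging.
* **Position-dependent diffusivity** — the core statistic. A permeant held
  at depth *z* by a harmonic restraint exchanges momentum with its local
  lipid environment; the restraint-force fluctuations give the local
  diffusion coefficient

  ```
  D(z) = (RT)^2 / ∫₀^∞ ⟨ΔF(z,t) ΔF(z,0)⟩ dt ,
  ```

  with ΔF the mean-subtracted restraint force, R the gas constant and T
  the temperature. The autocorrelation is estimated per lag (unbiased
  1/(N−j) normalization) and its trapezoidal integral truncated at the
  first zero crossing. Profiles D(z) are assembled across umbrella
  windows, averaged over the bilayer's central hydrophobic region
  (|z| ≤ 2.3 nm by default), and compared between systems as a percent
  change.
* **Synthetic data** — every analysis stage has a generator with known
  ground truth: overdamped-Langevin (Ornstein–Uhlenbeck) restrained
  windows at prescribed D, multi-window simulations on piecewise-linear
  D(z) landscapes (Itô convention with the ∂D/∂z drift correction),
  pseudo-bilayer frames with planted thickness / area / hydrogen-bond
  structure, and replicate adsorption traces.
* **Pipeline & CLI** — a config-driven `run_pipeline` producing the study's
  tables and curves (CSV + JSON + machine-readable log), and a thin
  `scpermeate` command with subcommands for each stage.

Intended users: simulators of skin-lipid (or other) membranes who need the
post-processing chain without the original in-house scripts, and anyone
validating a force-ACF diffusivity estimator against known ground truth.

## Worked example

`examples/estimate_diffusivity.py` simulates one 10 ns restrained window
at a known diffusivity and recovers it from the force ACF:

```
$ python examples/estimate_diffusivity.py
ground truth D : 2.410e-06 cm^2/s
recovered D    : 2.419e-06 cm^2/s
relative error : +0.4%
ACF truncated at 38.0 ps (first zero crossing), 100000 force samples
```

The ground truth is recovered to well within the ~13% sampling scatter a
single 10 ns window carries. `examples/compare_systems.py` runs the full
two-system comparison (flat control landscape vs. a treatment landscape
raised 32% inside |z| ≤ 2.3 nm) and reports the recovered percent change;
`examples/bilayer_metrics.py`, `examples/permeant_depth.py` and
`examples/run_pipeline.py` demonstrate the structural, depth-tracking and
config-driven stages.

Library use in three lines:

```python
from scpermeate import simulate_ou_window, window_diffusivity
series = simulate_ou_window(D_true=2.41e-4, k=1000.0, T=310.0, seed=1)
print(window_diffusivity(series).D)   # cm^2/s
```

## Units

Lengths nm, times ps, energies kJ/mol, forces kJ mol⁻¹ nm⁻¹,
temperatures K. Diffusivities are computed in nm²/ps and reported in
cm²/s (1 nm²/ps = 10⁻² cm²/s). PDB and XYZ files (Å dialects) are
converted on read/write.
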