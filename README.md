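# camkii-ensemble

Geometric ensemble analysis of tethered-kinase holoenzymes from
single-particle coordinates.

CaMKII holoenzymes — the central kinases of synaptic plasticity — are rings
of 12–16 association ("hub") domains, each tethering a kinase domain
through a disordered linker (~31 residues in the α isoform, ~92 in β). In
negative-stain EM projections each particle is a ~11 nm hub ring surrounded
by flexible ~5 nm kinase "petals". Because the kinase positions form a
continuum of conformations rather than discrete classes, the informative
analysis is *geometric*: per-particle distance measurements and
distance-threshold state classification over thousands of particles.

This package implements that analysis as a tested, reusable pipeline:

* a **synthetic ensemble generator** producing 2D particle coordinate sets
  (12/14/16-mer hub rings, Gaussian or polymer-chain kinase radii, dimer
  pairs at 4.5 nm, compact states, pixel-scale noise, multi-holoenzyme
  fields, dose–response data) with ground-truth labels for every
  downstream classifier;
* the **measurement conventions**: kinase radius
  r = ‖kinase − hub center‖ + 2.25 nm, linker extension
  r − (2.25 + 5.5 + 2.25) nm, nearest-clockwise-neighbor separation,
  compact (<10 nm) and dimer (<4.5/5/6 nm) flags, a rotational-symmetry
  census from angular Fourier power, 1.5×-diameter cluster detection, and
  the local kinase concentration c = n / (N_A·(4/3)πr³);
* **ensemble statistics**: Gaussian summaries on 0.5 nm histograms, the
  one-sided 95% positional envelope (mean + 1.96 SD), F-then-Welch isoform
  comparison, and a Monte-Carlo null test for excess short separations;
* the **random-chain linker model** (RMS end-to-end b·√N, with b
  calibrated from observed extensions);
* **cooperative-activation analysis**: variable-slope Hill fitting
  v = Vmax·c^h/(EC50^h + c^h), extra-sum-of-squares F comparison between
  fits, Michaelis–Menten fractional velocities, and a stochastic
  trans-autophosphorylation ring model.

See `docs/methods.md` for the model assumptions, parameter defaults, and
numerical choices.

## Worked example

Run the full pipeline on a β-like synthetic ensemble (1,000 particles, a
200-holoenzyme field at 56% clustering, and a synthetic CaM dose–response
at EC50 14.6 nM, slope 1.64):

```python
from camkii_ensemble import BETA_LIKE, io

rc = io.RunConfig(
    simulation=BETA_LIKE, n_particles=1000, seed=1,
    field_n=200, field_extent=30_000.0, cluster_fraction=0.56,
    dose_response={"ec50": 14.6e-9, "hill_h": 1.64})
report = io.run_pipeline(rc, out_dir="out")
```

The report (`out/report.yaml`) prints, among other fields:

```yaml
kinase_radius:
  n: 12134
  mean_nm: 16.73      # generator mean 16.8 nm recovered
  sd_nm: 3.41
  envelope95_nm: 23.4 # 95% of kinases reach out to ~23 nm
linker_extension_nm: 6.73   # mean radius minus hub and kinase radii
stoichiometry_census:
  percent: {'6': 91.0, '7': 6.2, '8': 0.2, ambiguous: 2.6}
clustering:
  clustered_percent: 56.0   # matches the configured ground truth
polymer:
  step_length_b_nm: 0.702   # b = extension / sqrt(92 residues)
local_concentration_mM: 1.02
mm_fractional_velocity_percent: 99.03
hill_fit:
  ec50_nM: 14.8518          # generating value 14.6 nM
  hill_h: 1.61786           # generating value 1.64
```

Reading it: the measured radius distribution recovers the generating
16.8 ± 3.3 nm ensemble; the census recovers the 12/14/16-mer mixture with
an explicit rejection class; 12 kinases within a 16.7 nm sphere sit at
≈1 mM local concentration, which against a Km of 10 μM runs at ≈99% of
Vmax — why holoenzyme expansion barely changes autophosphorylation speed;
and the Hill fit recovers the generating cooperative activation
parameters from noisy replicates.

The same stages are exposed as a CLI
(`camkii-ensemble simulate | measure | census | stats | null-test |
polymer | fit-hill | compare-fits | mm | report`).

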