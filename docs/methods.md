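# Methods

## The system and the measurement model

CaMKII holoenzymes are rings of association ("hub") domains — six, seven or
eight vertical dimers, hence 12-, 14- or 16-mers — with one kinase domain
tethered to each subunit by an intrinsically disordered linker (~31 residues
in the α isoform, ~92 in β). In negative-stain EM projections the hub
appears as a ring of ~11 nm outer diameter and each kinase as a ~5 nm
blob. The analysis in this package works entirely in that projection plane:
coordinates are 2D, in nm, with x to the right, y increasing downward and
angles clockwise-positive (the image convention), hub pore center at the
origin of each particle.

The measurement conventions are:

* **kinase radius** r = ‖kinase center − hub center‖ + 2.25 nm. The
  2.25 nm append converts the center-to-center distance into the outer
  extension of the kinase density (2.25 nm is the mean kinase-domain
  radius).
* **linker extension** = r − 2.25 − 5.5 − 2.25 nm: undo the append, then
  subtract the hub ring radius (5.5 nm) and one kinase radius, leaving the
  edge-to-edge hub–kinase gap. Negative values are reported as-is (they
  flag apparent overlap under noise).
* **neighbor separation**: center-to-center distance from each kinase to
  the angularly next kinase in clockwise order about the hub center (ties
  in angle break by radius, then index). Every subunit contributes exactly
  one distance, so the distance multiset is invariant to the handedness
  choice.
* **compact state**: r < 10 nm (the radius at which a kinase domain would
  be in steric contact with the hub; equivalently, zero linker extension).
* **dimer candidates**: neighbor separations below 4.5, 5.0 and 6.0 nm
  (the crystal-dimer center distance, and two progressively permissive
  cut-offs up to the maximal interaction distance).
* **clustering**: a holoenzyme is clustered when another hub center lies
  closer than 1.5× the particle diameter; clusters are the transitive
  closure of that relation. The particle diameter defaults to twice the
  ensemble mean kinase radius, since the measurement rule refers to the
  full particle, not the hub.
* **local concentration**: c = n / (N_A · (4/3)πr³) for n kinases in a
  sphere of the mean kinase radius r, reported in mM. For 12 kinases this
  gives ≈2.4 mM at r = 12.6 nm and ≈1.0 mM at r = 16.8 nm.

## The synthetic-ensemble generator

The generator emulates the statistical structure of the measured particle
populations and provides ground-truth labels for every classification
stage. Its defaults are the study conditions: two presets,

| parameter | α-like | β-like |
|---|---|---|
| stoichiometry mix (12/14/16-mer) | 0.88 / 0.052 / — | 0.927 / 0.055 / 0.004 |
| measured radius mean ± SD (nm) | 12.6 ± 1.6 | 16.8 ± 3.3 |
| linker residues | 31 | 92 |
| dimer fraction (subunits) | 0.19 | 0.08 |
| compact fraction (subunits) | 0.03 | 0.01 |
| dimer separation (nm) | 4.5 | 4.5 |
| coordinate noise SD (nm) | 0.437 | 0.437 |

The noise default is one pixel at the 4.37 Å micrograph calibration,
applied isotropically to every vertex and kinase coordinate once, after
labels are assigned.

Two radial models are provided. ``gaussian_radius`` (default) draws the
*measured* radius directly from a normal truncated below at
hub + kinase radius (7.75 nm) and places each kinase at an independent
uniform angle — the measured radius histograms are approximately Gaussian,
and no generative chain model is implied by the data themselves.
``chain`` samples a 3D Gaussian end-to-end displacement (per-axis SD
b·√(N/3)) from the subunit's hub-edge anchor and projects it
orthographically; it exists to generate the polymer null. Dimer pairs form
only between angularly adjacent subunits (disjoint pairs (2i, 2i+1)); the
pair is placed at a shared mean radius with exact center–center separation
4.5 nm and uniformly random axis orientation. Compact subunits draw their
measured radius uniformly from (7.75, 10) nm — the data constrain only the
<10 nm criterion. The stoichiometry-mix remainder (1 − Σ fractions) is
emitted as "ambiguous" particles whose hub vertices sit at uniformly
random angles with 3× positional jitter: a rejection class with no
coherent ring symmetry, mirroring the unclassifiable fraction of a real
dataset. (Jitter alone proved insufficient — at pixel-scale noise a
3×-jittered ring retains enough angular coherence that a large share of
the rejection class would still receive a symmetry call.)

What the generator does *not* emulate: electron optics (CTF, stain
granularity), 3D→2D foreshortening of dimer separations, inter-particle
overlap in crowded fields, or any correlation between a subunit's state
and its neighbors' geometry. Passing recovery tests therefore demonstrate
that the classification stages are correct and well calibrated under the
stated statistical model — not that the model captures every feature of
real micrographs.

## Classification stages

**Symmetry census.** The stoichiometry call uses the angular Fourier power
of the hub vertices, P(k) = |Σ_j exp(i·k·θ_j)|²/m for k ∈ {6, 7, 8}. A
perfect k-ring gives P(k) = m and exactly zero at the other candidate
orders. The call requires both a confidence ratio (top power ≥ 2× the
runner-up) and an absolute coherence floor (top power ≥ 0.5·m); either
failure yields "ambiguous". The floor is essential: a scrambled ring has
all three powers of order 1, so the ratio test alone passes by chance
roughly half the time, while the floor rejects such rings almost surely
and costs well under 2% of true rings at pixel-scale noise. At 0.4 nm
vertex noise the correct-call rate is ≥99% for all three orders.

**Dimer detection and its geometric ceiling.** The per-distance dimer
fractions follow the publication's convention (fraction of
nearest-clockwise separations below each cut-off). Note two structural
properties of that convention: each dimer pair's short distance is
recorded by at most *one* of its two members (the partner's clockwise
neighbor is the next subunit onward), and an unrelated kinase at a
different radius can interleave angularly between the pair. Ground-truth
label recovery is therefore assessed at the pair level — the true
member–member distance against the cut-offs — where the 6 nm cut-off
captures ≈99.8% of labelled pairs at pixel-scale noise. The per-distance
population fractions include a model-dependent random-crowding background
and are reported, not matched to the labelled fractions.

**Compact state.** The <10 nm flag recovers the labelled compact fraction
when the extended radial distribution leaves the compact window empty. At
the α parameters (12.6 ± 1.6 nm) the extended Gaussian itself places ~5%
of subunits below 10 nm; the measured compact fraction is then the sum of
the labelled states and that tail — a distinction between the generative
state and the operational flag that the recovery tests make explicit by
using a narrow radial distribution.

**Cluster detection** uses a KD-tree neighbor query with strict inequality
at the threshold and connected components for the transitive closure;
it is tested against a brute-force all-pairs union-find oracle.

## Statistics

Distribution summaries report moments (SD with n−1, SEM = SD/√n) and a
least-squares Gaussian fit to the 0.5 nm-binned histogram (the form
overlaid on the published histograms); moments are authoritative. The 95%
positional envelope is one-sided, mean + 1.96·SD, which reproduces both
printed envelopes (16 and 23 nm) — the quantity answers "out to what
radius do 95% of kinases reach".

Isoform comparisons use a two-sided variance-ratio F test followed by
Welch's unequal-variance t test with Welch–Satterthwaite degrees of
freedom (verified against the closed-form formulas to 1e-10).

The **null-deviation test** for excess short separations simulates
dimer-free ensembles matched in subunit count to the observed sample and
compares the fraction of separations below 5.0 nm (just above the most
populated short bin). The p-value is the add-one Monte-Carlo form
p = (1 + #{null ≥ obs}) / (1 + n_sims), which is exactly uniform on its
grid under the null and never zero. Calibration is verified by a KS test
of p-uniformity over independent null runs.

## Activation analysis

The Hill fit v = Vmax·c^h/(EC50^h + c^h) is performed on log10
concentration (the natural scale for a dose grid spanning four decades)
with baseline fixed at zero, because activities are normalized as
fractions of maximal activity; a four-parameter variant with a free
baseline sits behind a flag. Initialization: Vmax = max(v), EC50 = the
concentration nearest half-max, h = 1; EC50 is bounded within the data
range ×[1e-2, 1e2]. Standard errors come from the covariance of the
least-squares solution, with the EC50 SE mapped from log space by the
delta method. The fit is exactly scale-equivariant: rescaling all
concentrations by λ rescales EC50 by λ and leaves h unchanged.

The extra-sum-of-squares F test compares the separate fits (six
parameters) against a nested fit sharing any chosen subset of
{Vmax, EC50, h} across the two datasets:
F = ((RSS_shared − RSS_sep)/Δdf)/(RSS_sep/df_sep). Replicate points are
fitted individually (not averaged), so df reflects the full sample.

The Michaelis–Menten fractional velocity S/(Km + S) quantifies why a
two-fold difference in local kinase concentration (≈2 vs ≈1 mM against
Km ≈ 10 μM) cannot produce measurable autophosphorylation-rate
differences: 99.50% vs 99.01% of Vmax. The stochastic
trans-autophosphorylation model makes the same point dynamically: each
unphosphorylated subunit on the ring is a substrate of its two neighbors
(hazard 2·rate, optionally scaled by the MM fractional velocity at the
current substrate level, with substrate depletion tracked as the
unphosphorylated fraction); with depletion off the mean trajectory is
exactly 1 − exp(−2·rate·t). Trajectories at the two isoform local
concentrations differ by under 1% of plateau.

## Dose grid

The generator's default CaM grid is 12 log-spaced concentrations from
0.6 nM to 6 μM. A grid starting at 0.6 μM (forty times the smaller
EC50) cannot constrain a 14.6 nM EC50 at all — the fit needs sub-EC50
points — so the wide grid is the only self-consistent choice for the
reported fits.

## Numerical choices and problem sizes

* Per-particle random substreams are spawned from a single seed
  (`numpy` SeedSequence), so ensembles are bit-reproducible and
  independent of chunking. Every stochastic entry point takes an explicit
  seed.
* Truncated normals are sampled by rejection (the bound lies ≥3 SD below
  the mean for all realistic configurations; degenerate SD = 0 returns
  the mean).
* Field placement uses rejection sampling with group anchors ≥3× the
  clustering threshold apart, which guarantees inter-group member
  distances stay above threshold while intra-group members stay below it;
  infeasible packings raise after a bounded retry count.
* Census and recovery tests run at the published dataset sizes (17,000
  and 10,902 particles; 1,020 subunits; 1,207/1,255 holoenzyme fields),
  which take seconds. Monte-Carlo calibration checks (p-uniformity,
  classifier call rates) use 100–1,000 replicates, chosen so that binomial
  or KS bounds at α = 0.01 are meaningful.
* Reported precision follows the conventions of the source figures:
  distances 0.1 nm, fractions 0.1%, envelopes to the nearest nm.

## Known limitations

* The nearest-clockwise separation statistic depends on the (unknown)
  true angular placement model; with independent uniform angles the
  simulated β separation mean is ≈8.8–9.0 nm against the measured 9.4 nm.
  Agreement is ballpark, as expected for a quantity the generator does
  not directly control.
* The measured compact fraction conflates labelled compact states with
  the lower tail of the extended distribution (see above).
* Naive centroid re-picking of rendered blobs is accurate to well under a
  pixel for isolated blobs but biased when blobs overlap; the rendering
  path is a visualization/benchmark aid, not a picker.
* No worm-like-chain or excluded-volume polymer physics: the √N law with
  an effective step length absorbs all chain detail, and the calibrated
  step lengths differ ~1.5× between isoforms (0.49 vs 0.71 nm) — a
  model-adequacy caveat rather than a physical bond length.
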