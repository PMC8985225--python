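"""Synthetic holoenzyme-ensemble generator.

Produces 2D particle coordinate sets (hub vertices + tethered kinase-domain
centers), multi-holoenzyme fields, optional rendered micrographs, and Hill
dose-response datasets, with ground-truth labels for every downstream
classification stage.

Geometry lives in the projection plane of the micrograph: coordinates are in
nm, x to the right, y increasing downward, angles clockwise-positive, hub
pore center at the origin of each particle. A holoenzyme is a ring "hub" of
``k`` vertical association-domain dimers (k in {6, 7, 8}, i.e. 12/14/16
subunits) with two kinase domains anchored per vertex and tethered by a
disordered linker. The generator supports two radial models for the kinase
tether:

* ``gaussian_radius`` (default): the *measured* kinase radius (hub-center to
  kinase-center distance plus the 2.25 nm kinase-domain radius) is drawn
  directly from a truncated normal. This mirrors the apparent Gaussian radius
  histograms that motivate the analysis.
* ``chain``: a freely-jointed-chain end-to-end displacement (3D Gaussian,
  per-axis SD b*sqrt(N/3)) is sampled from the subunit's hub-edge anchor and
  orthographically projected, giving the polymer-null geometry.

Subunit states: ``extended`` (freely tethered), ``dimer`` (paired with an
angularly adjacent subunit at a fixed center-center separation, default
4.5 nm), and ``compact`` (kinase folded back within 10 nm measured radius of
the hub center). Labels are assigned before measurement noise is applied, so
every classifier can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "HoloenzymeParticle",
    "ParticleSet",
    "FieldSet",
    "DoseResponseDataset",
    "ALPHA_LIKE",
    "BETA_LIKE",
    "simulate_particle",
    "simulate_ensemble",
    "simulate_field",
    "render_micrograph",
    "simulate_dose_response",
]

#: subunit count -> hub symmetry order (vertical dimers per ring)
STOICH_TO_ORDER = {12: 6, 14: 7, 16: 8}
ORDER_TO_STOICH = {v: k for k, v in STOICH_TO_ORDER.items()}

#: hub ring radius, nm (outer diameter ~11 nm)
DEFAULT_HUB_RADIUS = 5.5
#: kinase-domain radius, nm (~5 nm diameter density)
DEFAULT_KINASE_RADIUS = 2.25
#: one pixel at the 4.37 A calibration, nm
PIXEL_NM = 0.437


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs.

    ``stoichiometry_mix`` maps subunit counts {12, 14, 16} to population
    fractions; the remainder (1 - sum) is emitted as "ambiguous" particles
    whose hub vertices sit at random angles with 3x positional jitter (no
    coherent ring symmetry), so the census stage has a rejection class.

    ``dimer_fraction`` and ``compact_fraction`` are the expected fractions of
    *subunits* in each labelled state; the remainder is extended.
    """

    stoichiometry_mix: Mapping[int, float] = field(
        default_factory=lambda: {12: 1.0})
    radial_model: str = "gaussian_radius"   # or "chain"
    radius_mean: float = 12.6               # measured kinase radius, nm
    radius_sd: float = 1.6                  # nm
    linker_residues: int = 31               # N, chain model
    step_length_b: float = 0.485            # nm per residue, chain model
    dimer_fraction: float = 0.0
    dimer_separation: float = 4.5           # center-center, nm
    compact_fraction: float = 0.0
    noise_sd: float = PIXEL_NM              # isotropic, nm; 1 pixel default
    hub_radius: float = DEFAULT_HUB_RADIUS
    kinase_radius: float = DEFAULT_KINASE_RADIUS
    pixel_size: float = PIXEL_NM            # nm/px for rendering
    box_px: int = 144
    seed: int = 0

    def validate(self) -> None:
        mix = dict(self.stoichiometry_mix)
        if not mix:
            raise ValueError("stoichiometry_mix is empty")
        for n_sub, frac in mix.items():
            if n_sub not in STOICH_TO_ORDER:
                raise ValueError(
                    f"unsupported stoichiometry {n_sub}; expected one of "
                    f"{sorted(STOICH_TO_ORDER)}")
            if frac < 0:
                raise ValueError(f"negative fraction for {n_sub}-mer")
        total = sum(mix.values())
        if total <= 0:
            raise ValueError("stoichiometry_mix fractions sum to 0")
        if total > 1 + 1e-9:
            raise ValueError("stoichiometry_mix fractions sum above 1")
        for name in ("dimer_fraction", "compact_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dimer_fraction + self.compact_fraction > 1 + 1e-9:
            raise ValueError("dimer_fraction + compact_fraction exceeds 1")
        if self.radial_model not in ("gaussian_radius", "chain"):
            raise ValueError(f"unknown radial_model {self.radial_model!r}")
        if self.radius_mean <= self.hub_radius + self.kinase_radius:
            raise ValueError(
                "radius_mean must exceed hub_radius + kinase_radius")
        if self.radius_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.dimer_separation <= 0:
            raise ValueError("dimer_separation must be positive")
        if self.linker_residues < 1 or self.step_length_b <= 0:
            raise ValueError("invalid chain parameters")

    def with_(self, **changes) -> "SimulationConfig":
        """Return a copy with fields replaced (convenience wrapper)."""
        return replace(self, **changes)


#: CaMKII alpha-like study conditions: short (~31-residue) linker, compact
#: radial envelope, high dimer propensity, 12/14-mer hub mixture.
ALPHA_LIKE = SimulationConfig(
    stoichiometry_mix={12: 0.88, 14: 0.052},
    radius_mean=12.6, radius_sd=1.6,
    linker_residues=31, step_length_b=0.485,
    dimer_fraction=0.19, compact_fraction=0.03,
)

#: CaMKII beta-like study conditions: long (~92-residue) linker, extended
#: radial envelope, rarer dimers/compacts, 12/14/16-mer hub mixture.
BETA_LIKE = SimulationConfig(
    stoichiometry_mix={12: 0.927, 14: 0.055, 16: 0.004},
    radius_mean=16.8, radius_sd=3.3,
    linker_residues=92, step_length_b=0.709,
    dimer_fraction=0.08, compact_fraction=0.01,
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class HoloenzymeParticle:
    """One holoenzyme: hub ring plus 2*symmetry_order tethered kinases."""

    hub_center: np.ndarray            # (2,), nm
    symmetry_order: int               # 6, 7 or 8
    hub_vertices: np.ndarray          # (k, 2), nm
    kinase_centers: np.ndarray        # (2k, 2), nm
    subunit_labels: list[str]         # 'extended' | 'dimer' | 'compact'
    ambiguous: bool = False           # census rejection class

    @property
    def n_subunits(self) -> int:
        return 2 * self.symmetry_order


@dataclass
class ParticleSet:
    particles: list[HoloenzymeParticle]
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)


@dataclass
class FieldSet:
    """Holoenzymes placed in a shared plane, with clustering ground truth."""

    hub_centers: np.ndarray           # (n, 2), nm
    clustered_truth: np.ndarray       # (n,), bool
    diameter: float                   # particle diameter used for spacing, nm
    extent: float                     # square field side, nm
    config: SimulationConfig
    particles: list[HoloenzymeParticle] | None = None

    def __len__(self) -> int:
        return len(self.hub_centers)


@dataclass
class DoseResponseDataset:
    """CaM-activation data: concentrations (M) x replicate activities."""

    cam_concentrations: np.ndarray    # (n_conc,), molar, sorted ascending
    activities: np.ndarray            # (n_conc, n_replicates), fraction Vmax
    generating_params: dict | None = None

    def __post_init__(self):
        self.cam_concentrations = np.asarray(
            self.cam_concentrations, dtype=float)
        self.activities = np.atleast_2d(
            np.asarray(self.activities, dtype=float))
        if np.any(self.cam_concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.cam_concentrations) <= 0):
            raise ValueError("concentrations must be sorted and distinct")
        if self.activities.shape[0] != self.cam_concentrations.size:
            raise ValueError("activities rows must match concentrations")

    @property
    def replicates(self) -> int:
        return self.activities.shape[1]

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """All (concentration, activity) points, replicates unrolled."""
        c = np.repeat(self.cam_concentrations, self.replicates)
        return c, self.activities.ravel()


# ---------------------------------------------------------------------------
# particle simulation
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated below at ``lower``, by rejection.

    The truncation point sits far in the lower tail for realistic
    parameters, so rejection is cheap; degenerate sd returns the mean.
    """
    if sd == 0:
        if mean < lower:
            raise ValueError("degenerate radius below truncation bound")
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out < lower
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lower
    return out


def _assign_labels(rng: np.random.Generator, n_sub: int,
                   cfg: SimulationConfig) -> list[str]:
    """Assign subunit states on disjoint angularly-adjacent pairs.

    Each pair (2i, 2i+1) dimerizes with probability dimer_fraction; members
    of non-dimer pairs are compact with the conditional probability that
    keeps the marginal compact fraction at compact_fraction.
    """
    labels = ["extended"] * n_sub
    p_dimer = cfg.dimer_fraction
    p_compact = (cfg.compact_fraction / (1 - p_dimer)
                 if p_dimer < 1 else 0.0)
    for i in range(n_sub // 2):
        a, b = 2 * i, 2 * i + 1
        if rng.random() < p_dimer:
            labels[a] = labels[b] = "dimer"
        else:
            for j in (a, b):
                if rng.random() < p_compact:
                    labels[j] = "compact"
    return labels


def _draw_symmetry(rng: np.random.Generator,
                   cfg: SimulationConfig) -> tuple[int, bool]:
    """Draw (symmetry_order, ambiguous) from the stoichiometry mixture."""
    items = sorted(cfg.stoichiometry_mix.items())
    stoichs = [s for s, _ in items]
    fracs = np.array([f for _, f in items], dtype=float)
    total = fracs.sum()
    u = rng.random()
    if u < total:
        idx = int(np.searchsorted(np.cumsum(fracs), u, side="right"))
        return STOICH_TO_ORDER[stoichs[idx]], False
    # remainder: ambiguous particle; order drawn from the renormalized mix
    idx = int(np.searchsorted(np.cumsum(fracs / total), rng.random(),
                              side="right"))
    idx = min(idx, len(stoichs) - 1)
    return STOICH_TO_ORDER[stoichs[idx]], True


def simulate_particle(config: SimulationConfig,
                      rng: np.random.Generator) -> HoloenzymeParticle:
    """Simulate one holoenzyme particle in its own hub-centered frame.

    Placement order: draw symmetry and global ring rotation; assign subunit
    state labels; place extended subunits by the configured radial model,
    dimer pairs midway at a shared mean radius with exact center-center
    separation, and compact subunits uniformly inside the <10 nm measured
    window; finally add isotropic Gaussian measurement noise to every vertex
    and kinase coordinate (3x on vertices of ambiguous particles).
    """
    config.validate()
    order, ambiguous = _draw_symmetry(rng, config)
    n_sub = 2 * order
    kr, hr = config.kinase_radius, config.hub_radius

    phase = rng.uniform(0, 2 * np.pi)
    if ambiguous:
        # census rejection class: no coherent ring symmetry to recover
        vert_angles = rng.uniform(0, 2 * np.pi, order)
    else:
        vert_angles = phase + 2 * np.pi * np.arange(order) / order
    vertices = hr * np.column_stack([np.cos(vert_angles),
                                     np.sin(vert_angles)])

    labels = _assign_labels(rng, n_sub, config)
    centers = np.zeros((n_sub, 2))

    # extended subunits
    ext_idx = [i for i, s in enumerate(labels) if s == "extended"]
    if ext_idx:
        if config.radial_model == "gaussian_radius":
            r_meas = _truncated_normal(rng, config.radius_mean,
                                       config.radius_sd, hr + kr,
                                       len(ext_idx))
            theta = rng.uniform(0, 2 * np.pi, len(ext_idx))
            centers[ext_idx] = ((r_meas - kr)[:, None]
                                * np.column_stack([np.cos(theta),
                                                   np.sin(theta)]))
        else:  # chain: projected 3D Gaussian walk from the anchor vertex
            sd = config.step_length_b * np.sqrt(config.linker_residues / 3.0)
            anchors = vertices[[i // 2 for i in ext_idx]]
            disp = rng.normal(0.0, sd, (len(ext_idx), 3))
            centers[ext_idx] = anchors + disp[:, :2]

    # dimer pairs: midway at a shared mean radius, exact separation
    done = set()
    for i, s in enumerate(labels):
        if s != "dimer" or i in done:
            continue
        j = i + 1  # pairs are (2i, 2i+1) by construction
        done.update((i, j))
        r_meas = _truncated_normal(rng, config.radius_mean, config.radius_sd,
                                   hr + kr, 1)[0]
        theta = rng.uniform(0, 2 * np.pi)
        mid = (r_meas - kr) * np.array([np.cos(theta), np.sin(theta)])
        axis = rng.uniform(0, 2 * np.pi)
        half = 0.5 * config.dimer_separation * np.array([np.cos(axis),
                                                         np.sin(axis)])
        centers[i] = mid - half
        centers[j] = mid + half

    # compact subunits: measured radius uniform in (hub+kinase, 10) nm
    comp_idx = [i for i, s in enumerate(labels) if s == "compact"]
    if comp_idx:
        r_meas = rng.uniform(hr + kr, 10.0, len(comp_idx))
        theta = rng.uniform(0, 2 * np.pi, len(comp_idx))
        centers[comp_idx] = ((r_meas - kr)[:, None]
                             * np.column_stack([np.cos(theta),
                                                np.sin(theta)]))

    # measurement noise, applied last; labels were recorded before noise
    if config.noise_sd > 0:
        vert_noise = config.noise_sd * (3.0 if ambiguous else 1.0)
        vertices = vertices + rng.normal(0, vert_noise, vertices.shape)
        centers = centers + rng.normal(0, config.noise_sd, centers.shape)
    elif ambiguous:
        # ambiguity must survive a noiseless configuration
        vertices = vertices + rng.normal(0, 3 * PIXEL_NM, vertices.shape)

    return HoloenzymeParticle(
        hub_center=np.zeros(2), symmetry_order=order,
        hub_vertices=vertices, kinase_centers=centers,
        subunit_labels=labels, ambiguous=ambiguous)


def simulate_ensemble(config: SimulationConfig, n_particles: int,
                      seed: int | None = None) -> ParticleSet:
    """Simulate ``n_particles`` independent holoenzymes.

    A per-particle substream is derived deterministically from the seed, so
    the same (config, seed) pair is bit-reproducible regardless of how the
    ensemble is chunked.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    particles = [simulate_particle(config, np.random.default_rng(child))
                 for child in root.spawn(n_particles)]
    return ParticleSet(particles=particles, config=config)


# ---------------------------------------------------------------------------
# fields of holoenzymes
# ---------------------------------------------------------------------------

def simulate_field(config: SimulationConfig, n_holoenzymes: int,
                   extent: float, cluster_fraction: float,
                   seed: int | None = None, diameter: float | None = None,
                   with_particles: bool = False,
                   max_retries: int = 10_000) -> FieldSet:
    """Place holoenzymes in a square field with a known clustered fraction.

    A fraction ``cluster_fraction`` of holoenzymes is placed in small groups
    (pairs, plus one triple when the count is odd) whose members lie within
    1.5x the particle diameter of each other; all remaining holoenzymes and
    all distinct groups are kept at least that far apart, so the ground-truth
    clustered flags are unambiguous under the 1.5x-diameter rule.
    """
    config.validate()
    if n_holoenzymes < 1:
        raise ValueError("n_holoenzymes must be >= 1")
    if not 0 <= cluster_fraction <= 1:
        raise ValueError("cluster_fraction must be in [0, 1]")
    if diameter is None:
        diameter = 2.0 * config.radius_mean
    threshold = 1.5 * diameter

    n_clustered = int(round(cluster_fraction * n_holoenzymes))
    if n_clustered == 1:
        n_clustered = 2  # a single holoenzyme cannot be clustered
        n_clustered = min(n_clustered, n_holoenzymes)
    n_pairs, odd = divmod(n_clustered, 2)
    group_sizes = [2] * n_pairs
    if odd and group_sizes:
        group_sizes[0] = 3
    elif odd:
        n_clustered = 0  # degenerate: cannot form any group
    group_sizes += [1] * (n_holoenzymes - sum(group_sizes))

    # anchors >= 3x threshold apart guarantee inter-group member distances
    # stay above the threshold (members sit within one threshold of anchor)
    anchor_min = 3.0 * threshold
    if extent < anchor_min:
        raise ValueError("extent too small for the requested spacing")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    anchors: list[np.ndarray] = []
    for _ in group_sizes:
        for attempt in range(max_retries):
            cand = rng.uniform(0, extent, 2)
            if all(np.linalg.norm(cand - a) >= anchor_min for a in anchors):
                anchors.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place {n_holoenzymes} holoenzymes at spacing "
                f"{anchor_min:.1f} nm in a {extent:.0f} nm field after "
                f"{max_retries} retries")

    centers, flags = [], []
    for anchor, size in zip(anchors, group_sizes):
        centers.append(anchor)
        flags.append(size > 1)
        for m in range(size - 1):
            # partner within the clustering threshold but outside hub overlap
            d = rng.uniform(1.1 * config.hub_radius * 2, 0.95 * threshold)
            ang = rng.uniform(0, 2 * np.pi)
            centers.append(anchor + d * np.array([np.cos(ang), np.sin(ang)]))
            flags.append(True)

    hub_centers = np.array(centers)
    clustered = np.array(flags, dtype=bool)

    particles = None
    if with_particles:
        pset = simulate_ensemble(config, n_holoenzymes, seed=seed)
        particles = []
        for p, c in zip(pset.particles, hub_centers):
            particles.append(HoloenzymeParticle(
                hub_center=c, symmetry_order=p.symmetry_order,
                hub_vertices=p.hub_vertices + c,
                kinase_centers=p.kinase_centers + c,
                subunit_labels=p.subunit_labels, ambiguous=p.ambiguous))
    return FieldSet(hub_centers=hub_centers, clustered_truth=clustered,
                    diameter=diameter, extent=extent, config=config,
                    particles=particles)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_micrograph(obj, pixel_size: float = PIXEL_NM,
                      box_px: int = 144, hub_sigma: float = 1.0,
                      kinase_sigma: float = 1.0, hub_weight: float = 1.0,
                      kinase_weight: float = 1.0) -> np.ndarray:
    """Render particles as idealized Gaussian blobs on a pixel grid.

    ``obj`` is a HoloenzymeParticle (centered in the box), a ParticleSet
    (first particle, centered), or a FieldSet with attached particles
    (absolute coordinates). Each hub vertex and kinase center becomes an
    isotropic 2D Gaussian whose integrated intensity equals its weight, so
    the grid sum equals the total blob weight up to edge truncation. No
    electron-optics effects (CTF, stain) are modelled.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if isinstance(obj, ParticleSet):
        if not obj.particles:
            return np.zeros((box_px, box_px), dtype=np.float32)
        obj = obj.particles[0]

    if isinstance(obj, HoloenzymeParticle):
        offset = 0.5 * box_px * pixel_size - obj.hub_center
        points = [(obj.hub_vertices + offset, hub_sigma, hub_weight),
                  (obj.kinase_centers + offset, kinase_sigma, kinase_weight)]
    elif isinstance(obj, FieldSet):
        if obj.particles is None:
            raise ValueError("FieldSet has no attached particles to render")
        verts = np.concatenate([p.hub_vertices for p in obj.particles])
        kins = np.concatenate([p.kinase_centers for p in obj.particles])
        points = [(verts, hub_sigma, hub_weight),
                  (kins, kinase_sigma, kinase_weight)]
    else:
        raise TypeError(f"cannot render {type(obj).__name__}")

    # pixel-center coordinates in nm
    coords = (np.arange(box_px) + 0.5) * pixel_size
    xx, yy = np.meshgrid(coords, coords)  # row=y, col=x
    grid = np.zeros((box_px, box_px), dtype=np.float64)
    for pts, sigma, weight in points:
        amp = weight * pixel_size**2 / (2 * np.pi * sigma**2)
        for x, y in np.atleast_2d(pts):
            grid += amp * np.exp(-((xx - x)**2 + (yy - y)**2)
                                 / (2 * sigma**2))
    return grid.astype(np.float32)


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

def hill_activity(conc, vmax: float, ec50: float, hill_h: float):
    """Variable-slope Hill equation v = Vmax * c^h / (EC50^h + c^h)."""
    conc = np.asarray(conc, dtype=float)
    return vmax * conc**hill_h / (ec50**hill_h + conc**hill_h)


def default_cam_concentrations(n: int = 12) -> np.ndarray:
    """Log-spaced CaM grid from 0.6 nM to 6 uM (molar)."""
    return np.logspace(np.log10(0.6e-9), np.log10(6e-6), n)


def simulate_dose_response(vmax: float, ec50: float, hill_h: float,
                           concentrations: Sequence[float] | None = None,
                           noise_sd: float = 0.0, replicates: int = 1,
                           seed: int | None = None) -> DoseResponseDataset:
    """Hill-model activity with additive Gaussian replicate noise."""
    if ec50 <= 0 or hill_h <= 0:
        raise ValueError("ec50 and hill_h must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    conc = (default_cam_concentrations() if concentrations is None
            else np.asarray(concentrations, dtype=float))
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    mean = hill_activity(conc, vmax, ec50, hill_h)
    rng = np.random.default_rng(seed)
    acts = mean[:, None] + rng.normal(0, noise_sd, (conc.size, replicates)) \
        if noise_sd > 0 else np.tile(mean[:, None], (1, replicates))
    return DoseResponseDataset(
        cam_concentrations=conc, activities=acts,
        generating_params={"vmax": vmax, "ec50": ec50, "hill_h": hill_h,
                           "noise_sd": noise_sd, "seed": seed})
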