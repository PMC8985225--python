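"""File formats, configuration, and the end-to-end pipeline.

Formats (all plain text except optional MRC):

* particle tables: TSV, one row per subunit, columns ``particle_id,
  symmetry_order, hub_x_nm, hub_y_nm, vertex_x_nm, vertex_y_nm, kinase_x_nm,
  kinase_y_nm, label`` (plus ``ambiguous``); '.' marks missing values;
  coordinates round-trip at 0.001 nm; unknown columns are preserved;
* field tables: TSV with ``holoenzyme_id, hub_x_nm, hub_y_nm,
  clustered_truth``;
* dose-response: CSV with ``cam_molar, replicate, activity``;
* configuration and reports: YAML;
* rendered micrographs: MRC 2D float32 (via gemmi), pixel size in header.

Image-frame convention, stated once here and honored everywhere: x right,
y increasing downward, angles clockwise-positive. All lengths are nm; molar
quantities are mol/L with nM/uM/mM suffixes in reports.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activation, measure, polymer, stats
from .synthetic import (DoseResponseDataset, FieldSet, HoloenzymeParticle,
                        ParticleSet, SimulationConfig, simulate_dose_response,
                        simulate_ensemble, simulate_field)

__all__ = [
    "RunConfig", "read_particles", "write_particles", "read_field",
    "write_field", "read_dose_response", "write_dose_response",
    "load_config", "save_config", "write_mrc", "run_pipeline",
]

PARTICLE_COLUMNS = ["particle_id", "symmetry_order", "hub_x_nm", "hub_y_nm",
                    "vertex_x_nm", "vertex_y_nm", "kinase_x_nm",
                    "kinase_y_nm", "label"]
_FMT = "%.4f"  # 0.0001 nm resolution, comfortably inside the 0.001 nm spec


# ---------------------------------------------------------------------------
# particle tables
# ---------------------------------------------------------------------------

def write_particles(particle_set: ParticleSet | list, path) -> None:
    """Write a particle set as the one-row-per-subunit TSV schema."""
    particles = (particle_set.particles
                 if isinstance(particle_set, ParticleSet) else particle_set)
    rows = []
    for pid, p in enumerate(particles):
        for s in range(p.n_subunits):
            v = p.hub_vertices[s // 2]
            k = p.kinase_centers[s]
            rows.append({
                "particle_id": pid,
                "symmetry_order": p.symmetry_order,
                "hub_x_nm": _FMT % p.hub_center[0],
                "hub_y_nm": _FMT % p.hub_center[1],
                "vertex_x_nm": _FMT % v[0],
                "vertex_y_nm": _FMT % v[1],
                "kinase_x_nm": _FMT % k[0],
                "kinase_y_nm": _FMT % k[1],
                "label": (p.subunit_labels[s]
                          if p.subunit_labels is not None else "."),
                "ambiguous": int(p.ambiguous),
            })
    pd.DataFrame(rows, columns=PARTICLE_COLUMNS + ["ambiguous"]).to_csv(
        path, sep="\t", index=False)


def read_particles(path) -> ParticleSet:
    """Read the TSV particle schema back into a ParticleSet.

    Raises a schema error naming any missing mandatory column and a
    record-level error for particles whose subunit count does not match
    their symmetry order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"particle table missing mandatory columns: "
                         f"{missing}")
    if df.empty:
        warnings.warn(f"{path}: particle table has a header but no rows",
                      stacklevel=2)
        return ParticleSet(particles=[], config=SimulationConfig())

    num_cols = [c for c in PARTICLE_COLUMNS
                if c.endswith("_nm") or c in ("particle_id",
                                              "symmetry_order")]
    for col in num_cols:
        cells = df[col].replace(".", np.nan)
        try:
            df[col] = pd.to_numeric(cells)
        except (ValueError, TypeError) as exc:
            bad = cells[pd.to_numeric(cells, errors="coerce").isna()
                        & cells.notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{path}: malformed numeric cell in column {col!r}, "
                f"row {row}") from exc

    particles = []
    for pid, grp in df.groupby("particle_id", sort=True):
        order = int(grp["symmetry_order"].iloc[0])
        if len(grp) != 2 * order:
            raise ValueError(
                f"particle {pid}: {len(grp)} subunit rows but symmetry "
                f"order {order} requires {2 * order}")
        hub = grp[["hub_x_nm", "hub_y_nm"]].iloc[0].to_numpy(float)
        verts = grp[["vertex_x_nm", "vertex_y_nm"]].iloc[::2].to_numpy(float)
        kins = grp[["kinase_x_nm", "kinase_y_nm"]].to_numpy(float)
        labels = grp["label"].tolist()  # '.' marks unknown state
        ambiguous = bool(int(grp["ambiguous"].iloc[0])) \
            if "ambiguous" in grp.columns else False
        particles.append(HoloenzymeParticle(
            hub_center=hub, symmetry_order=order, hub_vertices=verts,
            kinase_centers=kins, subunit_labels=labels,
            ambiguous=ambiguous))
    return ParticleSet(particles=particles, config=SimulationConfig())


# ---------------------------------------------------------------------------
# field / dose-response tables
# ---------------------------------------------------------------------------

def write_field(fieldset: FieldSet, path) -> None:
    pd.DataFrame({
        "holoenzyme_id": np.arange(len(fieldset)),
        "hub_x_nm": [_FMT % v for v in fieldset.hub_centers[:, 0]],
        "hub_y_nm": [_FMT % v for v in fieldset.hub_centers[:, 1]],
        "clustered_truth": fieldset.clustered_truth.astype(int),
    }).to_csv(path, sep="\t", index=False)


def read_field(path, diameter: float, extent: float = 0.0) -> FieldSet:
    df = pd.read_csv(path, sep="\t")
    required = ["holoenzyme_id", "hub_x_nm", "hub_y_nm", "clustered_truth"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"field table missing columns: {missing}")
    return FieldSet(
        hub_centers=df[["hub_x_nm", "hub_y_nm"]].to_numpy(float),
        clustered_truth=df["clustered_truth"].astype(bool).to_numpy(),
        diameter=diameter, extent=extent, config=SimulationConfig())


def write_dose_response(dataset: DoseResponseDataset, path) -> None:
    rows = []
    for i, c in enumerate(dataset.cam_concentrations):
        for r in range(dataset.replicates):
            rows.append({"cam_molar": c, "replicate": r,
                         "activity": dataset.activities[i, r]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dose_response(path) -> DoseResponseDataset:
    df = pd.read_csv(path)
    required = ["cam_molar", "replicate", "activity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dose-response table missing columns: {missing}")
    pivot = df.pivot_table(index="cam_molar", columns="replicate",
                           values="activity")
    return DoseResponseDataset(
        cam_concentrations=pivot.index.to_numpy(float),
        activities=pivot.to_numpy(float))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline run configuration (YAML-mirrored).

    ``simulation`` carries the generator knobs; ``constants`` the analysis
    conventions; ``dose_response`` the Hill-analysis block.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_particles: int = 500
    seed: int = 0
    field_n: int = 0                     # 0 disables the field stage
    field_extent: float = 20_000.0
    cluster_fraction: float = 0.0
    constants: dict = field(default_factory=lambda: {
        "hub_radius": 5.5, "kinase_radius": 2.25, "compact_cutoff": 10.0,
        "dimer_cutoffs": [4.5, 5.0, 6.0], "cluster_factor": 1.5,
        "bin_width": 0.5})
    dose_response: dict | None = None    # {vmax, ec50, hill_h, noise_sd,
    #                                      replicates, n_concentrations}
    mm_km: float = 10e-6                 # molar

    def validate(self) -> None:
        self.simulation.validate()
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        for key in ("hub_radius", "kinase_radius", "compact_cutoff",
                    "cluster_factor", "bin_width"):
            if self.constants.get(key, 0) <= 0:
                raise ValueError(f"constant {key} must be positive")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulation", {})
    if "stoichiometry_mix" in sim_raw:
        sim_raw["stoichiometry_mix"] = {
            int(k): float(v)
            for k, v in sim_raw["stoichiometry_mix"].items()}
    cfg = RunConfig(simulation=SimulationConfig(**sim_raw),
                    **{k: v for k, v in raw.items()
                       if k in RunConfig.__dataclass_fields__})
    cfg.validate()
    return cfg


def save_config(config: RunConfig, path) -> None:
    payload = asdict(config)
    payload["simulation"]["stoichiometry_mix"] = dict(
        config.simulation.stoichiometry_mix)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def write_mrc(grid: np.ndarray, pixel_size_nm: float, path) -> None:
    """Write a 2D intensity grid as an MRC/CCP4 map (float32)."""
    import gemmi

    data = np.ascontiguousarray(grid.astype(np.float32)).reshape(
        grid.shape[0], grid.shape[1], 1)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(data)
    apix = pixel_size_nm * 10.0  # nm -> Angstrom
    m.grid.unit_cell = gemmi.UnitCell(
        grid.shape[1] * apix, grid.shape[0] * apix, apix, 90, 90, 90)
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _round_floats(obj, sig=6):
    """Round floats to significant figures for stable, readable reports."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig, out_dir=None, log=print) -> dict:
    """Run simulate -> measure -> stats/polymer -> activation end to end.

    Returns (and optionally writes as ``report.yaml``) a machine-readable
    report carrying every summary the analysis prints: radius and
    separation statistics with Gaussian fits and envelopes, compact and
    dimer fractions, the stoichiometry census, cluster detection, polymer
    calibration, local concentrations, Hill fit, and the Michaelis-Menten
    fractional velocities. Deterministic for a fixed (config, seed).
    """
    config.validate()
    consts = config.constants
    report: dict = {"config": {
        "seed": config.seed, "n_particles": config.n_particles,
        "simulation": _round_floats(asdict(config.simulation)),
        "constants": _round_floats(dict(consts)),
    }}

    log(f"[simulate] n={config.n_particles} seed={config.seed}")
    pset = simulate_ensemble(config.simulation, config.n_particles,
                             seed=config.seed)

    log("[measure] building measurement table")
    table = measure.measure_particles(
        pset, hub_r=consts["hub_radius"], kinase_r=consts["kinase_radius"],
        compact_cutoff=consts["compact_cutoff"],
        dimer_cutoffs=consts["dimer_cutoffs"])

    log("[stats] radius / separation summaries")
    rad = stats.gaussian_summary(table["kinase_radius_nm"].to_numpy(),
                                 bin_width=consts["bin_width"])
    sep = stats.gaussian_summary(
        table["neighbor_separation_nm"].to_numpy(),
        bin_width=consts["bin_width"])
    report["kinase_radius"] = rad.as_dict()
    report["neighbor_separation"] = sep.as_dict()
    report["linker_extension_nm"] = round(float(
        measure.linker_extension(rad.mean, consts["hub_radius"],
                                 consts["kinase_radius"])), 2)

    compact_frac, _ = measure.classify_compact(
        table["kinase_radius_nm"].to_numpy(), consts["compact_cutoff"])
    dimer_fracs, _ = measure.classify_dimers(
        table["neighbor_separation_nm"].to_numpy(),
        consts["dimer_cutoffs"])
    report["state_fractions"] = {
        "compact_percent": round(100 * compact_frac, 1),
        "dimer_percent_by_cutoff": {
            str(c): round(100 * f, 1) for c, f in dimer_fracs.items()},
    }

    log("[census] hub symmetry census")
    census = measure.stoichiometry_census(pset)
    report["stoichiometry_census"] = {
        "n": census["n"],
        "percent": {str(k): round(v, 2)
                    for k, v in census["percent"].items()}}

    if config.field_n > 0:
        log(f"[field] n={config.field_n} "
            f"cluster_fraction={config.cluster_fraction}")
        fld = simulate_field(config.simulation, config.field_n,
                             config.field_extent, config.cluster_fraction,
                             seed=config.seed + 1)
        frac, _, _ = measure.detect_clusters(
            fld, factor=consts["cluster_factor"])
        report["clustering"] = {
            "n": config.field_n,
            "clustered_percent": round(100 * frac, 1),
            "truth_percent": round(
                100 * float(fld.clustered_truth.mean()), 1)}

    log("[polymer] step-length calibration")
    ext = report["linker_extension_nm"]
    if ext > 0:
        b = polymer.calibrate_step(ext, config.simulation.linker_residues)
        report["polymer"] = {
            "n_residues": config.simulation.linker_residues,
            "step_length_b_nm": round(b, 3),
            "expected_end_to_end_nm": round(polymer.expected_end_to_end(
                config.simulation.linker_residues, b), 2)}

    n_kin = 2 * stats._dominant_order(config.simulation)
    conc_mm = measure.local_concentration(n_kin, rad.mean)
    report["local_concentration_mM"] = round(conc_mm, 2)
    report["mm_fractional_velocity_percent"] = round(
        100 * activation.mm_fractional_velocity(conc_mm * 1e-3,
                                                config.mm_km), 2)

    if config.dose_response:
        dr = dict(config.dose_response)
        log("[activation] Hill fit on synthetic dose-response")
        ds = simulate_dose_response(
            vmax=dr.get("vmax", 1.0), ec50=dr["ec50"],
            hill_h=dr["hill_h"], noise_sd=dr.get("noise_sd", 0.02),
            replicates=dr.get("replicates", 3), seed=config.seed + 2)
        fit = activation.fit_hill(ds)
        report["hill_fit"] = _round_floats(fit.as_dict())

    report = _round_floats(report)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_particles(pset, out_dir / "particles.tsv")
        table.to_csv(out_dir / "measurements.tsv", sep="\t", index=False,
                     float_format="%.4f")
        with open(out_dir / "report.yaml", "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)
        log(f"[report] written to {out_dir}")
    return report


def _null_log(*_args, **_kw):
    pass
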