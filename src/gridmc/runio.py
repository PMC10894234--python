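"""Run orchestration and file I/O: configs, the simulation driver, reports.

``simulate`` is the single entry point that wires the modules together:
parametric source -> (optional) grid collimator transmission -> in-air
fluence plane -> water-phantom transport kernel -> tally set.  Runs are
deterministic for a given (seed, n_histories) and independent of batch
execution order because every history owns a counter-based RNG stream.

JSON run configs are schema-validated (unknown keys rejected) before any
compute by the pydantic schemas in ``load_run_config``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import tallies as T
from .analysis import (AnalysisReport, average_energy, output_factor,
                       pdd_and_dmax, pdf_depth_fluence, spatial_fraction,
                       tpr_20_10)
from .grid import GridSpec, transmit_through_grid
from .source import BeamSpec, PhotonBatch, generate_beam, propagate_to_plane
from .transport import TransportConfig, run_history_batch

DEFAULT_TALLIES = ("cyl_dose", "spectra", "rect", "in_air")


@dataclass
class RunConfig:
    """A single simulation run: beam + optional grid + transport settings."""

    beam: BeamSpec = field(default_factory=BeamSpec)
    grid: GridSpec | None = None
    n_histories: int = 2_000_000
    seed: int = 1
    n_batches: int = 10
    ssd: float = 100.0
    grid_mode: str = "attenuate_and_scatter"
    tallies: tuple = DEFAULT_TALLIES
    phantom: bool = True  # False: collimator + in-air plane only
    roulette: bool = True

    def transport_config(self) -> TransportConfig:
        return TransportConfig(
            n_histories=self.n_histories, seed=self.seed,
            n_batches=self.n_batches, ssd=self.ssd,
            score_spectra="spectra" in self.tallies,
            score_rect="rect" in self.tallies,
            roulette=self.roulette, grid_mode=self.grid_mode,
        )


def _score_in_air(ts: T.TallySet, b: int, pb: PhotonBatch) -> None:
    """Track-length fluence in the 50x50x0.1 cm^3 slab below the grid."""
    dz = pb.direction[:, 2]
    fwd = dz > 1e-9
    above = pb.position[:, 2] <= T.IN_AIR_Z + T.IN_AIR_THICKNESS / 2
    m = fwd & above
    if not np.any(m):
        return
    zmid = T.IN_AIR_Z + T.IN_AIR_THICKNESS / 2
    t = (zmid - pb.position[m, 2]) / dz[m]
    xc = pb.position[m, 0] + t * pb.direction[m, 0]
    yc = pb.position[m, 1] + t * pb.direction[m, 1]
    inside = (np.abs(xc) <= T.IN_AIR_HALF) & (np.abs(yc) <= T.IN_AIR_HALF)
    chord = T.IN_AIR_THICKNESS / dz[m][inside]
    w = pb.weight[m][inside]
    tags = pb.tag[m][inside]
    for tg in (0, 1):
        sel = tags == tg
        ts.in_air.data[b, tg] += float((w[sel] * chord[sel]).sum()) / T.IN_AIR_VOLUME


def simulate(cfg: RunConfig) -> T.TallySet:
    """Run one full simulation and return the populated tally set."""
    tc = cfg.transport_config()
    nb = cfg.n_batches
    per = cfg.n_histories // nb
    ts = T.TallySet(nb, cfg.n_histories, meta={
        "beam": dataclasses.asdict(cfg.beam),
        "grid": dataclasses.asdict(cfg.grid) if cfg.grid else None,
        "ssd": cfg.ssd, "seed": cfg.seed, "n_histories": cfg.n_histories,
        "grid_mode": cfg.grid_mode, "phantom": cfg.phantom,
    })
    gen_plane = cfg.grid.tray_top_z - 1.0 if cfg.grid else T.IN_AIR_Z - 10.0
    for b in range(nb):
        rng = np.random.Generator(np.random.Philox(key=(cfg.seed << 20) + b))
        pb = generate_beam(cfg.beam, per, rng, z_plane=gen_plane)
        pb.history += b * per
        pb.stream += b * per
        if cfg.grid is not None:
            pb = transmit_through_grid(
                pb, cfg.grid, rng, mode=cfg.grid_mode,
                stream_base=(1 << 40) + b * (1 << 32))
        if "in_air" in cfg.tallies:
            _score_in_air(ts, b, pb)
        if not cfg.phantom:
            continue
        propagate_to_plane(pb, cfg.ssd)
        ok = ((pb.direction[:, 2] > 1e-9)
              & (np.abs(pb.position[:, 0]) <= tc.phantom_half)
              & (np.abs(pb.position[:, 1]) <= tc.phantom_half))
        lost = pb.select(~ok)
        ts.counters[b, 7] += float((lost.weight * lost.energy).sum())
        run_history_batch(pb.select(ok), ts, tc)
    return ts


# --------------------------------------------------------------------------
# monitor-unit calibration
# --------------------------------------------------------------------------

def calibrate_histories_per_mu(beam: BeamSpec | None = None,
                               n_histories: int = 2_000_000, seed: int = 1):
    """Histories needed to deliver 1 MU (1 cGy at d_max, open 10x10, SSD 100).

    Returns ``(histories_per_mu, d_max_mm, reference_tallies)``.
    """
    beam = beam or BeamSpec()
    beam = replace(beam, field_size=(10.0, 10.0))
    cfg = RunConfig(beam=beam, grid=None, n_histories=n_histories, seed=seed,
                    tallies=("cyl_dose", "spectra", "rect", "in_air"))
    ts = simulate(cfg)
    curve = ts.cyl_dose_depth_curve()  # cGy per history
    pdd, d_max_mm = pdd_and_dmax(curve)
    from .analysis import fit_buildup_peak
    _, dose_at_dmax = fit_buildup_peak(curve)
    histories_per_mu = 1.0 / dose_at_dmax  # 1 cGy / (cGy per history)
    ts.per_mu_normalize(histories_per_mu)
    return histories_per_mu, d_max_mm, ts


# --------------------------------------------------------------------------
# JSON config schema (strict validation before compute)
# --------------------------------------------------------------------------

def _schema_models():
    from pydantic import BaseModel, ConfigDict

    class _Strict(BaseModel):
        model_config = ConfigDict(extra="forbid")

    class BeamSchema(_Strict):
        nominal_peak_energy: float = 6.02
        focal_spot_fwhm: float = 1.2
        energy_fwhm: float = 1.2
        alpha: float = BeamSpec.alpha
        beta: float = BeamSpec.beta
        source_to_isocenter: float = 100.0
        field_size: tuple[float, float] = (10.0, 10.0)
        penumbra_margin: float = 0.2
        extra_focal_fraction: float = BeamSpec.extra_focal_fraction
        extra_focal_sigma: float = BeamSpec.extra_focal_sigma

    class GridSchema(_Strict):
        material: str = "brass"
        hole_diameter: float = 1.0
        pitch: float = 2.0
        slab_top_z: float = GridSpec.slab_top_z
        slab_bottom_z: float = GridSpec.slab_bottom_z
        max_field: float = 25.0
        sad: float = 100.0
        tray_material: str = "pmma"
        tray_thickness: float = 0.6
        material_density: float | None = None

    class RunSchema(_Strict):
        beam: BeamSchema = BeamSchema()
        grid: GridSchema | None = None
        n_histories: int = 2_000_000
        seed: int = 1
        n_batches: int = 10
        ssd: float = 100.0
        grid_mode: str = "attenuate_and_scatter"
        tallies: tuple[str, ...] = DEFAULT_TALLIES
        phantom: bool = True
        roulette: bool = True
        output_dir: str = "gridmc_out"

    return BeamSchema, GridSchema, RunSchema


def load_run_config(path) -> tuple[RunConfig, str]:
    """Parse and validate a JSON run config; returns (config, output_dir)."""
    _, _, RunSchema = _schema_models()
    raw = json.loads(Path(path).read_text())
    schema = RunSchema.model_validate(raw)
    beam = BeamSpec(**schema.beam.model_dump())
    grid = GridSpec(**schema.grid.model_dump()) if schema.grid else None
    cfg = RunConfig(beam=beam, grid=grid, n_histories=schema.n_histories,
                    seed=schema.seed, n_batches=schema.n_batches,
                    ssd=schema.ssd, grid_mode=schema.grid_mode,
                    tallies=tuple(schema.tallies), phantom=schema.phantom,
                    roulette=schema.roulette)
    return cfg, schema.output_dir


def read_curve(path) -> np.ndarray:
    """Read a two-column delimited curve file ('#' comments) -> (m, 2)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        rows.append((float(parts[0]), float(parts[1])))
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError(f"{path}: not a two-column curve file")
    return arr


def cmd_simulate(config_path, output_dir=None) -> Path:
    """CLI backend: validate config, run, archive tallies, write a log."""
    cfg, out_dir = load_run_config(config_path)
    out = Path(output_dir or out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    ts = simulate(cfg)
    wall = time.time() - t0
    archive = out / "tallies.h5"
    ts.save(archive)
    curve = ts.cyl_dose_depth_curve() if cfg.phantom else None
    max_rel = float(np.nanmax(curve.sigma / np.maximum(curve.value, 1e-300))) \
        if curve is not None else float("nan")
    cfg_text = Path(config_path).read_text()
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": cfg.seed, "n_histories": cfg.n_histories,
        "n_batches": cfg.n_batches, "wall_seconds": round(wall, 2),
        "max_relative_sigma_cyl_dose": max_rel,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "run.log").write_text(
        f"seed={cfg.seed} histories={cfg.n_histories} batches={cfg.n_batches}\n"
        f"wall={wall:.1f}s max_rel_sigma={max_rel:.3g}\n"
        f"archive={archive}\n")
    return archive


# --------------------------------------------------------------------------
# the grid-vs-open benchmark experiment matrix
# --------------------------------------------------------------------------

# Published benchmark values for the modelled 6 MV beam and commercial
# 127-hole grid collimator (dimensionless unless noted).
BENCHMARK = {
    ("tpr", "open"): 0.678,
    ("tpr", "brass"): 0.648,
    ("dmax_mm", "open", 10): 15.5,
    ("dmax_mm", "open", 20): 14.5,
    ("dmax_mm", "brass", 10): 13.5,
    ("output_factor", "open", 20): 1.045,
    ("output_factor", "brass", 10): 0.782,
    ("output_factor", "cerrobend", 10): 0.772,
    ("output_factor", "brass", 20): 0.813,
    ("output_factor", "cerrobend", 20): 0.790,
    ("avg_e_mev", "open", 10, 1.5): 1.47,
    ("avg_e_mev", "brass", 10, 1.5): 1.77,
    ("in_air_ratio",): 0.45,
    ("spatial_fraction", "brass", 10): 0.23,
    ("spatial_fraction", "cerrobend", 10): 0.17,
    ("spatial_fraction", "brass", 20): 0.26,
    ("spatial_fraction", "cerrobend", 20): 0.20,
}

MODALITIES = ("open", "brass", "cerrobend")
FIELDS = (10.0, 20.0)


def _grid_for(modality: str) -> GridSpec | None:
    return None if modality == "open" else GridSpec(material=modality)


def _axial_voxel_per_batch(ts: T.TallySet, depth_cm: float,
                           height_cm: float = 0.4) -> np.ndarray:
    """Per-batch kerma-estimator dose in the 4 mm axial voxel (arb units)."""
    half = height_cm / 2.0
    i0 = int(np.floor((depth_cm - half) / T.CYL_DZ + 1e-9))
    i1 = int(np.ceil((depth_cm + half) / T.CYL_DZ - 1e-9))
    return ts.kerma[:, max(i0, 0):min(i1, T.N_CYL)].mean(axis=1)


def tpr_pair(beam: BeamSpec, grid: GridSpec | None, n_histories: int,
             seed: int, n_batches: int = 10, return_batches: bool = False):
    """Run the two-SSD TPR20/10 procedure; returns (value, sigma).

    Both runs share the seed, so histories are pairwise correlated and
    the ratio variance largely cancels.  The dose is read from the
    track-length kerma estimator in the 4 mm radius x 4 mm height axial
    voxel (collision kerma equals dose at these depths).  With
    ``return_batches`` a per-batch TPR array is appended (for paired
    significance tests between modalities run at the same seed).
    """
    doses = []
    batches = []
    for ssd, depth in ((80.0, 20.0), (90.0, 10.0)):
        cfg = RunConfig(beam=beam, grid=grid, n_histories=n_histories,
                        seed=seed, n_batches=n_batches, ssd=ssd,
                        tallies=("cyl_dose",))
        ts = simulate(cfg)
        doses.append(ts.dose_in_axial_voxel(depth, estimator="kerma"))
        batches.append(_axial_voxel_per_batch(ts, depth))
    (d20, s20), (d10, s10) = doses
    value, sigma = tpr_20_10(d20, d10, s20, s10)
    if return_batches:
        return value, sigma, batches[0] / batches[1]
    return value, sigma


def tpr_open_grid_difference(beam: BeamSpec, grid: GridSpec,
                             n_histories: int, seed: int):
    """Open-minus-grid TPR20/10 with a paired-batch uncertainty.

    Open and grid runs share the seed, so per-history streams coincide
    for photons passing the central hole; forming the difference batch by
    batch removes the correlated part of the variance.  Returns
    ``(tpr_open, sigma_open, tpr_grid, sigma_grid, diff, sigma_diff)``.
    """
    v_o, s_o, b_o = tpr_pair(beam, None, n_histories, seed,
                             return_batches=True)
    v_g, s_g, b_g = tpr_pair(beam, grid, n_histories, seed,
                             return_batches=True)
    d = b_o - b_g
    sigma_diff = float(d.std(ddof=1) / np.sqrt(d.size))
    return v_o, s_o, v_g, s_g, float(v_o - v_g), sigma_diff


def run_benchmark_matrix(scale: float = 1.0, seed: int = 1,
                         output_dir=None, beam: BeamSpec | None = None):
    """Run the full open/brass/cerrobend x 10x10/20x20 experiment matrix.

    ``scale`` multiplies the default number of histories per run.  Writes
    per-experiment analysis reports and a comparison table against the
    benchmark values; returns (AnalysisReport, comparison rows).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    n_phantom = max(int(2_000_000 * scale), 20)
    beam = beam or BeamSpec()
    out = Path(output_dir) if output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    report = AnalysisReport()
    rows = []
    phantom_ts: dict = {}

    def emission_area(fs: float) -> float:
        # photons per MU scale with the collimated emission area, so
        # per-history doses of different field sizes are compared on a
        # fixed-machine-output footing through this factor
        side = fs + 2.0 * beam.penumbra_margin
        return side * side

    hmu, dmax_ref, ref_ts = calibrate_histories_per_mu(
        beam, n_histories=n_phantom, seed=seed)
    phantom_ts[("open", 10.0)] = ref_ts
    ref_curve = ref_ts.cyl_dose_depth_curve()
    from .analysis import fit_buildup_peak
    _, ref_dose = fit_buildup_peak(ref_curve)
    report.d_max_mm[("open", 10.0)] = dmax_ref

    for modality in MODALITIES:
        for fs in FIELDS:
            if (modality, fs) in phantom_ts:
                continue
            cfg = RunConfig(beam=replace(beam, field_size=(fs, fs)),
                            grid=_grid_for(modality),
                            n_histories=n_phantom, seed=seed)
            ts = simulate(cfg)
            ts.per_mu_normalize(hmu * emission_area(fs) / emission_area(10.0))
            phantom_ts[(modality, fs)] = ts

    for (modality, fs), ts in phantom_ts.items():
        curve = ts.cyl_dose_depth_curve()
        pdd, d_max_mm = pdd_and_dmax(curve)
        report.d_max_mm[(modality, fs)] = d_max_mm
        _, dose_peak = fit_buildup_peak(curve)
        of = output_factor(dose_peak * emission_area(fs), ref_dose * emission_area(10.0))
        report.output_factor[(modality, fs)] = of
        key = ("output_factor", modality, int(fs))
        if key in BENCHMARK:
            rows.append({"quantity": f"output_factor {modality} {fs:g}x{fs:g}",
                         "simulated": round(of, 3), "sigma": float("nan"),
                         "benchmark": BENCHMARK[key]})
        for depth in T.SPEC_DEPTHS:
            edges, phi, _ = ts.photon_spectrum(depth, "total")
            report.average_energy_mev[(modality, fs, depth, "total")] = \
                average_energy(phi, edges)
        if modality != "open":
            pitch_at_depth = 2.0 * (100.0 + 10.0) / 100.0  # projected to 10 cm depth
            prof = ts.profile()
            try:
                frac, _ = spatial_fraction(
                    prof, pitch_at_depth,
                    n_peaks=2 * int((fs / 2 * 1.1 - 1.1) / 2.2) + 1)
                report.spatial_fraction[(modality, fs)] = frac
            except ValueError:
                pass
        flu = ts.fluence_depth_curve("total")
        report.pdf_percent[(modality, fs)] = pdf_depth_fluence(
            flu, report.d_max_mm[(modality, fs)])

    # TPR20/10 pairs for every modality and field size
    n_tpr = max(int(2_000_000 * scale), 20)
    for modality in MODALITIES:
        for fs in FIELDS:
            beam_fs = replace(beam, field_size=(fs, fs))
            val, sig = tpr_pair(beam_fs, _grid_for(modality), n_tpr, seed)
            report.tpr_20_10[(modality, fs)] = (val, sig)
            if fs == 10.0 and ("tpr", modality) in BENCHMARK:
                rows.append({"quantity": f"TPR20/10 {modality}",
                             "simulated": round(val, 3),
                             "sigma": round(sig, 3),
                             "benchmark": BENCHMARK[("tpr", modality)]})

    # paired in-air attenuation runs (same seed: correlated ratio)
    air = {}
    for modality in ("open", "brass"):
        cfg = RunConfig(beam=beam, grid=_grid_for(modality),
                        n_histories=max(int(1_000_000 * scale), 20),
                        seed=seed, phantom=False, tallies=("in_air",))
        air[modality] = simulate(cfg).in_air_fluence("total")
    ratio = air["brass"][0] / air["open"][0]
    rows.append({"quantity": "in-air fluence ratio grid/open",
                 "simulated": round(ratio, 3), "sigma": float("nan"),
                 "benchmark": BENCHMARK[("in_air_ratio",)]})

    for (modality, fs), d in report.d_max_mm.items():
        key = ("dmax_mm", modality, int(fs))
        if key in BENCHMARK:
            rows.append({"quantity": f"d_max mm {modality} {fs:g}x{fs:g}",
                         "simulated": round(d, 1), "sigma": 1.0,
                         "benchmark": BENCHMARK[key]})

    if out:
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "benchmark_comparison.csv", index=False)
        (out / "analysis_report.json").write_text(
            json.dumps(_report_to_json(report), indent=2, default=str))
    return report, rows


def _report_to_json(report: AnalysisReport) -> dict:
    out = {}
    for name, d in report.to_dict().items():
        out[name] = {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                     for k, v in d.items()
                     if not hasattr(v, "depth")}
    return out
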