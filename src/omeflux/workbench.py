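"""I/O, configuration, pipeline orchestration and reference experiments.

Stacks travel as plain multi-page TIFF plus a JSON sidecar carrying the
mandatory physical metadata (pixel size, frame interval, channel names,
bleach frame).  ``run_pipeline`` executes requested stages deterministically
— identical config and seed reproduce every output byte for byte, verified
via SHA-256 checksums in the run report.

The module also hosts the reference in-silico experiments that exercise the
whole pipeline end to end (FRAP parameter recovery, contact-dependent focus
formation, population exchange); the test-suite and the reproduction script
both drive these.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import frap as _frap
from . import profiles as _profiles
from .exchange import MixingSummary, homogenization_index, transfer_fraction
from .frap import FrapSeries, FitError
from .simcell import (
    OP_CONTACT, OP_INIT, OP_TRANSFER, CellGeometry, ContactZone, SimConfig,
    Species, allele_compat, field_of_view, init_ensemble, merge_ensembles,
    render_frame, simulate_frap_experiment, step_diffusion, straight_cell,
    substream, transfer_cargo, update_contacts,
)

__version__ = "0.1.0"

log = logging.getLogger("omeflux")

REQUIRED_SIDECAR_FIELDS = ("pixel_size_um", "frame_interval_s", "channels")


def setup_logging(level: str = "INFO", json_lines: bool = False) -> None:
    """Configure stderr logging; ``json_lines`` switches to machine-readable records."""
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        class _J(logging.Formatter):
            def format(self, rec):
                return json.dumps({"level": rec.levelname, "name": rec.name,
                                   "msg": rec.getMessage()})
        handler.setFormatter(_J())
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(getattr(logging, level.upper()))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# Stack I/O: multi-page TIFF + JSON sidecar
# --------------------------------------------------------------------------


def write_stack(path, frames: np.ndarray, meta: dict, sidecar: str | Path | None = None) -> Path:
    """Write a (T, H, W) or (T, C, H, W) stack as multi-page TIFF + sidecar.

    Pages are ordered time-major, channel-minor.  The sidecar must carry
    pixel_size_um, frame_interval_s and channels; a missing field is an error
    at read time, so it is also rejected here.
    """
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim == 3:
        frames = frames[:, None, :, :]
    if frames.ndim != 4:
        raise ValueError("frames must be (T, H, W) or (T, C, H, W)")
    for key in REQUIRED_SIDECAR_FIELDS:
        if key not in meta:
            raise ValueError(f"stack metadata missing mandatory field {key!r}")
    if len(meta["channels"]) != frames.shape[1]:
        raise ValueError("channel names must match the stack's channel axis")
    pages = frames.reshape(-1, *frames.shape[2:])
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    meta = dict(meta)
    meta.setdefault("n_frames", int(frames.shape[0]))
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return sidecar


def load_stack(path, sidecar: str | Path | None = None) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack and its JSON sidecar.

    Returns ``(frames, meta)`` with frames shaped (T, C, H, W), time-major.
    Units are mandatory: a sidecar missing pixel_size_um or frame_interval_s
    is a hard error naming the field.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in REQUIRED_SIDECAR_FIELDS:
        if key not in meta:
            raise ValueError(f"stack sidecar {sidecar.name} missing mandatory field {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_ch = len(meta["channels"])
    if pages.shape[0] % n_ch:
        raise ValueError(f"{pages.shape[0]} pages not divisible by {n_ch} channels")
    frames = pages.reshape(pages.shape[0] // n_ch, n_ch, *pages.shape[1:])
    if np.any(frames < 0):
        raise ValueError("pixel values must be non-negative integers")
    return frames, meta


# --------------------------------------------------------------------------
# FRAP stack analysis (profiles -> normalization -> fits)
# --------------------------------------------------------------------------


def frap_series_from_stack(stack: np.ndarray, times: np.ndarray, prebleach: np.ndarray,
                           geometry: CellGeometry, roi: tuple[float, float],
                           pixel_size: float, origin=(0.0, 0.0), background: float = 0.0,
                           averaging_width: float | None = None):
    """Image-derived FrapSeries plus the per-frame axial profiles."""
    if averaging_width is None:
        averaging_width = geometry.width * 0.8
    lo, hi = roi
    profs, i_frap, i_total = [], [], []
    for i, frame in enumerate(np.asarray(stack, dtype=float)):
        p = _profiles.extract_profile(frame, geometry, averaging_width, pixel_size,
                                      origin=origin, frame_index=i)
        vals = np.clip(p.intensity - background, 0.0, None)
        p = _profiles.IntensityProfile(p.s, vals, frame=i)
        profs.append(p)
        sel = (p.s >= lo) & (p.s < hi)
        i_frap.append(float(vals[sel].sum()))
        i_total.append(float(vals.sum()))
    series = FrapSeries(t=np.asarray(times, float), i_frap=np.asarray(i_frap),
                        i_total=np.asarray(i_total), prebleach=np.asarray(prebleach, bool),
                        roi=roi)
    return series, profs


def analyze_frap_stack(stack: np.ndarray, times: np.ndarray, prebleach: np.ndarray,
                       geometry: CellGeometry, roi: tuple[float, float],
                       pixel_size: float, origin=(0.0, 0.0), background: float = 0.0,
                       averaging_width: float | None = None, fit_d: bool = True,
                       immobile_floor: bool | None = None, d_frames: int | None = None,
                       late_reference: bool = False, n_late: int = 1,
                       n_boot: int = 0, seed: int = 0) -> dict:
    """Full FRAP quantification of one single-channel stack.

    Computes the image-derived intensity series, the double-normalized
    recovery with its exponential fit (mobile fraction A, t_half) and — when
    ``fit_d`` — the diffusion coefficient from the Gaussian difference-profile
    depths.  ``immobile_floor=None`` decides automatically: the constant-floor
    decay model is used when the recovery fit indicates a substantial immobile
    pool (A < 0.9).  ``d_frames`` limits the depth series to the earliest
    frames, where free-diffusion spreading is unaffected by the cell poles.

    With ``late_reference`` the last post-bleach frame is treated as a late
    reference acquired after the mobile pool has equilibrated: its difference
    profile (the frozen immobile bleach pattern plus the uniform mobile
    deficit) is subtracted from every earlier difference profile.  That
    cancels the immobile component exactly, leaving a pure mobile Gaussian
    over a uniform offset, which is fitted with a free baseline; the plain
    depth-decay model then applies without a floor term.
    """
    series, profs = frap_series_from_stack(stack, times, prebleach, geometry, roi,
                                           pixel_size, origin, background, averaging_width)
    i_norm = _frap.double_normalize(series)
    post = series.post_slice
    t_post = series.t[post] - series.t[series.t0_index]
    rec = _frap.fit_recovery(i_norm[post], t_post)
    out = {
        "series": series,
        "i_norm": i_norm,
        "relative_recovery": _frap.relative_recovery(series),
        "recovery": rec,
        "diffusion": None,
        "excluded_frames": [],
    }
    if not fit_d:
        return out

    # kymograph-style normalization (each profile / its mean), then pre - post
    norm = [_profiles.IntensityProfile(p.s, p.intensity / p.intensity.mean(), frame=p.frame)
            for p in profs]
    pre = norm[series.pre_index]
    posts = norm[series.t0_index:]
    dps = _frap.difference_profiles(pre, posts, t_post)
    use_baseline = False
    if late_reference:
        if len(dps) < n_late + 3:
            raise ValueError("late-reference correction needs >= 4 post-bleach frames")
        ref = np.mean([dp.delta for dp in dps[-n_late:]], axis=0)
        dps = [_frap.DifferenceProfile(dp.s, dp.delta - ref, dp.t)
               for dp in dps[:-n_late]]
        use_baseline = True
        immobile_floor = False
    if d_frames is not None:
        dps = dps[:d_frames]
    cs, ts, excluded = [], [], []
    g0 = None
    for dp in dps:
        try:
            g = _frap.fit_gaussian(dp, baseline=use_baseline)
        except FitError:
            excluded.append(dp.t)
            continue
        if g0 is None:
            g0 = g
        cs.append(g.c)
        ts.append(dp.t)
    out["excluded_frames"] = excluded
    if g0 is None or len(cs) < 3:
        warnings.warn("too few valid difference-profile fits; diffusion not estimated",
                      stacklevel=2)
        return out
    if immobile_floor is None:
        immobile_floor = rec.a < 0.9
    try:
        out["diffusion"] = _frap.estimate_D(np.asarray(cs), np.asarray(ts), g0.c, g0.r,
                                            immobile_floor=immobile_floor,
                                            n_boot=n_boot, seed=seed)
    except (FitError, ValueError) as exc:
        warnings.warn(f"diffusion estimate failed: {exc}", stacklevel=2)
    return out


# --------------------------------------------------------------------------
# Reference experiment: FRAP parameter recovery
# --------------------------------------------------------------------------

#: Geometry and optics of the reference single-cell FRAP experiment.
FRAP_CELL_LENGTH = 4.0      # um
FRAP_CELL_WIDTH = 0.5       # um
FRAP_ROI = (1.7, 2.3)       # um, centred bleach interval for recovery series
#: Narrow (near diffraction-limited) bleach spot for the spreading series: the
#: pre-minus-post profile is then Gaussian from the first frame, the validity
#: regime of the C(t) = C0*R0*(R0^2+8Dt)^{-1/2} decay model.
FRAP_SPOT_ROI = (1.87, 2.13)
FRAP_R0_NOMINAL = 0.17      # um, nominal initial spot half-width (sets cadence)


def _frap_config(d_true: float, immobile_fraction: float, seed: int, *,
                 dt: float, n_steps: int, n_particles: int) -> SimConfig:
    return SimConfig(dt=dt, n_steps=n_steps, steps_per_frame=1,
                     n_particles=n_particles, immobile_fraction=immobile_fraction,
                     rng_seed=seed)


def frap_parameter_recovery(d_true: float, immobile_fraction: float, seed: int,
                            n_particles: int = 6000) -> dict:
    """Simulate-and-refit one FRAP replicate; returns estimates and truth.

    Two acquisitions of the same cell/condition are simulated, as a
    microscopist would schedule them:

    * a *recovery* series spanning ~6 diffusive equilibration times of the
      cell (48 frames) for the mobile fraction and t_half;
    * a *spreading* series with a narrow bleach spot, cadenced at
      2*R0^2/(8 D) (15 frames) for the diffusion estimate — short and narrow
      enough that the spreading Gaussian stays clear of the cell poles.
    """
    geometry = straight_cell(FRAP_CELL_LENGTH, FRAP_CELL_WIDTH)
    species = Species("reporter", d_free=d_true)

    # recovery series
    tau = FRAP_CELL_LENGTH**2 / (np.pi**2 * d_true)
    cfg_a = _frap_config(d_true, immobile_fraction, seed,
                         dt=6.0 * tau / 48, n_steps=48, n_particles=n_particles)
    stack_a, series_a, truth = simulate_frap_experiment(cfg_a, geometry, species, FRAP_ROI)
    res_a = analyze_frap_stack(stack_a, series_a.t, series_a.prebleach, geometry, FRAP_ROI,
                               cfg_a.pixel_size, origin=field_of_view([geometry], cfg_a)[0],
                               background=cfg_a.background, fit_d=False)

    # spreading series (independent replicate of the same condition) with a
    # late reference frame to cancel the immobile bleach pattern
    cfg_d = _frap_config(d_true, immobile_fraction, seed + 1_000_003,
                         dt=2.0 * FRAP_R0_NOMINAL**2 / (8.0 * d_true), n_steps=20,
                         n_particles=2 * n_particles)
    cfg_d.late_frame_time = 6.0 * tau
    cfg_d.n_late_frames = 3
    stack_d, series_d, _ = simulate_frap_experiment(cfg_d, geometry, species, FRAP_SPOT_ROI)
    res_d = analyze_frap_stack(stack_d, series_d.t, series_d.prebleach, geometry, FRAP_SPOT_ROI,
                               cfg_d.pixel_size, origin=field_of_view([geometry], cfg_d)[0],
                               background=cfg_d.background, fit_d=True,
                               late_reference=True, n_late=3, d_frames=12)

    diff = res_d["diffusion"]
    return {
        "a_hat": res_a["recovery"].a,
        "t_half_hat": res_a["recovery"].t_half,
        "d_hat": diff.d if diff is not None else np.nan,
        "a_true": 1.0 - immobile_fraction,
        "d_true": d_true,
        "truth": truth,
    }


def frap_recovery_grid(d_values: Sequence[float], immobile_fractions: Sequence[float],
                       n_replicates: int, seed: int, n_particles: int = 6000) -> pd.DataFrame:
    """Parameter-recovery study over a (D, immobile fraction) grid."""
    rows = []
    base = int(seed) & 0x3FFFFFFF
    for d_true in d_values:
        for imm in immobile_fractions:
            for rep in range(n_replicates):
                rep_seed = base + 7919 * rep + hash((round(d_true * 1e6), round(imm * 100))) % 100_000
                r = frap_parameter_recovery(d_true, imm, rep_seed & 0x7FFFFFFF,
                                            n_particles=n_particles)
                rows.append({"d_true": d_true, "immobile_fraction": imm, "replicate": rep,
                             "a_hat": r["a_hat"], "d_hat": r["d_hat"],
                             "t_half_hat": r["t_half_hat"]})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Reference experiment: contact-dependent receptor trapping (foci)
# --------------------------------------------------------------------------


def make_cell_pair(allele_a: str = "DK1622", allele_b: str = "DK1622", *,
                   n_receptors: int = 400, n_cargo_a: int = 0, n_cargo_b: int = 0,
                   cargo_d: float = 0.1, receptor_d: float = 0.005,
                   seed: int = 0, pair_id: str = "p0", gap: float = 0.55,
                   zone: tuple[float, float] = (1.7, 2.3)):
    """Two parallel rod cells with a shared contact zone and optional cargo.

    Cargo on cell A is the 'gfp' species, on cell B the 'mch' species, so the
    two labels identify the cell of origin (donor/recipient bookkeeping).
    """
    ga = straight_cell(FRAP_CELL_LENGTH, FRAP_CELL_WIDTH, cell_id=f"{pair_id}a")
    gb = straight_cell(FRAP_CELL_LENGTH, FRAP_CELL_WIDTH, y=gap, cell_id=f"{pair_id}b")
    rec_a = Species(f"receptor_{allele_a}", receptor_d, tra_allele=allele_a)
    rec_b = Species(f"receptor_{allele_b}", receptor_d, tra_allele=allele_b)
    parts = [init_ensemble(ga, rec_a, n_receptors, seed=substream(seed, OP_INIT, 0)),
             init_ensemble(gb, rec_b, n_receptors, seed=substream(seed, OP_INIT, 1))]
    if n_cargo_a:
        parts.append(init_ensemble(ga, Species("gfp", cargo_d, transferable=True),
                                   n_cargo_a, seed=substream(seed, OP_INIT, 2)))
    if n_cargo_b:
        parts.append(init_ensemble(gb, Species("mch", cargo_d, transferable=True),
                                   n_cargo_b, seed=substream(seed, OP_INIT, 3)))
    ens = merge_ensembles(*parts)
    z = ContactZone(ga.cell_id, gb.cell_id, zone, zone)
    return ens, (ga, gb), z


def contact_experiment(compatible: bool, seed: int, *, n_steps: int = 150,
                       dt: float = 0.1, n_receptors: int = 400,
                       k_on: float = 1.0, k_off: float = 0.1,
                       deactivate_at: int | None = None) -> dict:
    """Receptor trapping at one cell-cell contact, compatible or not.

    Returns the bound-receptor count over time, the final ensemble and the
    zone.  ``deactivate_at`` separates the cells at that step (the zone is
    switched off), mirroring focus dissolution on cell separation.
    """
    allele_b = "DK1622" if compatible else "Mf"
    ens, (ga, gb), zone = make_cell_pair("DK1622", allele_b,
                                         n_receptors=n_receptors, seed=seed)
    cfg = SimConfig(dt=dt, k_on=k_on, k_off=k_off, rng_seed=seed)
    diff_rng = substream(seed, 20)
    bind_rng = substream(seed, OP_CONTACT)
    bound_counts = []
    for step in range(n_steps):
        if deactivate_at is not None and step == deactivate_at:
            zone.active = False
        ens = step_diffusion(ens, dt, rng=diff_rng, d_bound=cfg.d_bound)
        ens = update_contacts(ens, [zone], allele_compat, dt, cfg, rng=bind_rng)
        bound_counts.append(int(ens.bound.sum()))
    return {"bound_counts": np.asarray(bound_counts), "ensemble": ens,
            "zone": zone, "geometries": (ga, gb), "config": cfg}


def zone_enrichment(ensemble, geometry, zone_interval, config, rng) -> float:
    """In-zone vs elsewhere mean-intensity ratio of a rendered receptor image."""
    fov = field_of_view(ensemble.geometries, config)
    img = render_frame(ensemble, config, rng=rng, fov=fov).astype(float) - config.background
    origin, _ = fov
    prof = _profiles.extract_profile(img, geometry, geometry.width * 0.8,
                                     config.pixel_size, origin=origin)
    in_zone = (prof.s >= zone_interval[0]) & (prof.s < zone_interval[1])
    inside = prof.intensity[in_zone].mean()
    outside = prof.intensity[~in_zone].mean()
    return float(inside / outside) if outside > 0 else np.inf


# --------------------------------------------------------------------------
# Reference experiment: population exchange and homogenization
# --------------------------------------------------------------------------


def exchange_population(compatible: bool, seed: int, *, n_pairs: int = 8,
                        t_total: float = 600.0, dt: float = 0.1,
                        n_receptors: int = 200, n_cargo: int = 300,
                        k_on: float = 1.0, k_off: float = 0.1,
                        k_transfer: float = 0.2, cargo_d: float = 0.1,
                        record_every: int = 50) -> dict:
    """Simulate a mixed population of labelled cell pairs exchanging cargo.

    Each pair starts fully bimodal (cell A carries only 'gfp' cargo, cell B
    only 'mch').  With compatible receptor alleles, zones engage and cargo
    equilibrates toward a 50:50 per-cell balance; with incompatible alleles no
    receptor pair ever binds, so transfer is gated off and the population
    stays bimodal.  Returns the homogenization index, per-cell channel counts
    and the donor/recipient time series of the first pair.
    """
    allele_b = "DK1622" if compatible else "Mf"
    parts, zones = [], []
    for p in range(n_pairs):
        ens, _, zone = make_cell_pair("DK1622", allele_b, n_receptors=n_receptors,
                                      n_cargo_a=n_cargo, n_cargo_b=n_cargo,
                                      cargo_d=cargo_d, seed=seed + 31 * p,
                                      pair_id=f"p{p}")
        parts.append(ens)
        zones.append(zone)
    ens = merge_ensembles(*parts)
    # re-index zones against the merged registry order (ids are unique per pair)
    cfg = SimConfig(dt=dt, k_on=k_on, k_off=k_off, k_transfer=k_transfer, rng_seed=seed)
    cfg.check_step_resolution(cargo_d, length_scale=(zones[0].interval_a[1]
                                                     - zones[0].interval_a[0]) / 2)
    diff_rng = substream(seed, 21)
    bind_rng = substream(seed, OP_CONTACT)
    tr_rng = substream(seed, OP_TRANSFER)

    gfp = ens.species_index("gfp")
    cell_a0 = ens.cell_index("p0a")
    cell_b0 = ens.cell_index("p0b")
    ts, f_donor, f_recipient = [], [], []
    n_steps = int(round(t_total / dt))
    for step in range(n_steps):
        ens = step_diffusion(ens, dt, rng=diff_rng, d_bound=cfg.d_bound)
        ens = update_contacts(ens, zones, allele_compat, dt, cfg, rng=bind_rng)
        ens = transfer_cargo(ens, zones, dt, cfg, rng=tr_rng)
        if step % record_every == 0 or step == n_steps - 1:
            ts.append((step + 1) * dt)
            sel = ens.species == gfp
            f_donor.append(float(np.sum(sel & (ens.cell == cell_a0))))
            f_recipient.append(float(np.sum(sel & (ens.cell == cell_b0))))

    # per-cell two-channel counts
    mch = ens.species_index("mch")
    ch1, ch2 = [], []
    for ci in range(len(ens.geometries)):
        ch1.append(float(np.sum((ens.cell == ci) & (ens.species == gfp))))
        ch2.append(float(np.sum((ens.cell == ci) & (ens.species == mch))))
    mix = homogenization_index(np.array(ch1), np.array(ch2))
    return {"mixing": mix, "ch1": np.array(ch1), "ch2": np.array(ch2),
            "t": np.array(ts), "f_donor": np.array(f_donor),
            "f_recipient": np.array(f_recipient), "ensemble": ens,
            "bound_total": int(ens.bound.sum())}


# --------------------------------------------------------------------------
# Run configuration and pipeline
# --------------------------------------------------------------------------


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative description of one reproducible pipeline run."""

    stages: list[str] = field(default_factory=list)
    outdir: str = "omeflux_out"
    rng_seed: int = 0
    pixel_size_um: float = 0.065
    frame_interval_s: float = 5.0
    cell_length_um: float = 4.0
    cell_width_um: float = 0.5
    d_free_um2_s: float = 0.02
    immobile_fraction: float = 0.3
    n_particles: int = 4000
    n_frames: int = 45
    bleach_roi_um: tuple[float, float] = (1.7, 2.3)
    stack_path: str | None = None      # analyse an existing stack instead of simulating
    sidecar_path: str | None = None
    roi_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "bleach_roi_um" in raw:
            raw["bleach_roi_um"] = tuple(raw["bleach_roi_um"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bleach_roi_um"] = list(d["bleach_roi_um"])
        return d


@dataclass
class RunReport:
    version: str
    config: dict
    stages: dict
    files: dict              # path -> sha256
    warnings: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the requested stages in dependency order.

    Stages: ``simulate`` (synthetic FRAP stack + sidecar + truth), ``frap``
    (normalization + fits -> JSON report and curve CSV), ``kymo`` (kymograph
    CSV + PNG heatmap).  Identical config + seed reproduce identical bytes.
    A stage failure aborts the run, removes that stage's partial outputs and
    raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=config.to_dict(), stages={},
                       files={}, warnings=[])
    if not config.stages:
        report.warnings.append("no stages requested; nothing to do")
        report.to_json(outdir / "run_report.json")
        return report

    order = [s for s in ("simulate", "frap", "kymo") if s in config.stages]
    unknown = set(config.stages) - set(order)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    geometry = straight_cell(config.cell_length_um, config.cell_width_um)
    state: dict = {}

    def _load_inputs():
        if "stack" in state:
            return
        if config.stack_path is None:
            raise ValueError("no stack available: run the simulate stage or set stack_path")
        frames, meta = load_stack(config.stack_path, config.sidecar_path)
        state.update(stack=frames[:, 0], meta=meta,
                     times=np.asarray(meta["times_s"], float),
                     prebleach=np.asarray(meta["prebleach"], bool),
                     origin=np.asarray(meta.get("origin_um", (0.0, 0.0)), float),
                     background=float(meta.get("background", 0.0)))

    for stage in order:
        written: list[Path] = []
        try:
            if stage == "simulate":
                sim_cfg = SimConfig(dt=config.frame_interval_s, n_steps=config.n_frames,
                                    n_particles=config.n_particles,
                                    immobile_fraction=config.immobile_fraction,
                                    rng_seed=config.rng_seed)
                species = Species("reporter", config.d_free_um2_s)
                stack, series, truth = simulate_frap_experiment(
                    sim_cfg, geometry, species, config.bleach_roi_um)
                origin, _ = field_of_view([geometry], sim_cfg)
                times = series.t
                meta = {
                    "pixel_size_um": sim_cfg.pixel_size,
                    "frame_interval_s": sim_cfg.frame_interval,
                    "channels": ["reporter"],
                    "bleach_frame": 1,
                    "times_s": times.tolist(),
                    "prebleach": series.prebleach.tolist(),
                    "origin_um": origin.tolist(),
                    "background": sim_cfg.background,
                    "rng_seed": config.rng_seed,
                }
                stack_path = outdir / "frap_stack.tif"
                sidecar = write_stack(stack_path, stack, meta)
                truth_path = outdir / "ground_truth.json"
                with open(truth_path, "w") as fh:
                    json.dump({**truth, "rng_seed": config.rng_seed}, fh,
                              indent=2, sort_keys=True)
                roi_path = outdir / "geometry.json"
                with open(roi_path, "w") as fh:
                    json.dump(geometry.to_dict({"bleach": config.bleach_roi_um}),
                              fh, indent=2, sort_keys=True)
                written += [stack_path, sidecar, truth_path, roi_path]
                state.update(stack=stack, meta=meta, times=times,
                             prebleach=series.prebleach, origin=origin,
                             background=sim_cfg.background)
                config.stack_path = str(stack_path)
                report.stages["simulate"] = {"n_frames": int(stack.shape[0]),
                                             "truth": truth}
            elif stage == "frap":
                _load_inputs()
                res = analyze_frap_stack(state["stack"], state["times"], state["prebleach"],
                                         geometry, config.bleach_roi_um,
                                         config.pixel_size_um, origin=state["origin"],
                                         background=state["background"])
                rec, diff = res["recovery"], res["diffusion"]
                fit_report = {
                    "mobile_fraction_A": rec.a,
                    "t_half_s": rec.t_half,
                    "recovery_residual_norm": rec.residual_norm,
                    "seed_recorded": config.rng_seed,
                }
                if diff is not None:
                    fit_report.update(D_um2_per_s=diff.d, C0=diff.c0, R0_um=diff.r0,
                                      C_inf=diff.c_inf, n_depth_frames=diff.n_frames)
                p_json = outdir / "frap_fit.json"
                with open(p_json, "w") as fh:
                    json.dump(fit_report, fh, indent=2, sort_keys=True)
                curves = pd.DataFrame({"t_s": state["times"],
                                       "i_frap": res["series"].i_frap,
                                       "i_total": res["series"].i_total,
                                       "relative_recovery": res["relative_recovery"],
                                       "i_norm": res["i_norm"],
                                       "is_prebleach": res["series"].prebleach})
                p_csv = outdir / "frap_curves.csv"
                curves.to_csv(p_csv, index=False)
                written += [p_json, p_csv]
                report.stages["frap"] = fit_report
            elif stage == "kymo":
                _load_inputs()
                kym = _profiles.kymograph(state["stack"], geometry, config.pixel_size_um,
                                          frame_interval=config.frame_interval_s,
                                          origin=state["origin"])
                p_csv = outdir / "kymograph.csv"
                pd.DataFrame(kym.data, index=kym.s).to_csv(p_csv, header=False)
                p_png = outdir / "kymograph.png"
                _save_heatmap(kym.data, p_png, xlabel="frame", ylabel="position (um)")
                written += [p_csv, p_png]
                report.stages["kymo"] = {"shape": list(kym.data.shape)}
        except Exception as exc:  # abort: remove partial outputs, name the stage
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineError(stage, exc) from exc
        for p in written:
            report.files[p.name] = sha256_file(p)
        log.info("stage %s done (%d files)", stage, len(written))

    report.to_json(outdir / "run_report.json")
    return report


def _save_heatmap(matrix: np.ndarray, path, xlabel: str = "", ylabel: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3), dpi=120)
    im = ax.imshow(matrix, aspect="auto", origin="lower", cmap="viridis",
                   interpolation="nearest")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": None})
    plt.close(fig)


# --------------------------------------------------------------------------
# Deterministic fixture bundle
# --------------------------------------------------------------------------


def make_fixtures(outdir, seed: int = 0) -> dict:
    """Write the small deterministic dataset used by the test-suite.

    Contents: one FRAP stack with known D and immobile fraction, one
    compatible-allele contact stack, one incompatible-allele contact stack
    (zero bound receptors in ground truth by construction), one transfer time
    series and one protease-accessibility table.  Returns the manifest (also
    written as manifest.json) listing every file with its SHA-256 checksum.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    # 1) FRAP stack
    cfg = SimConfig(dt=5.0, n_steps=20, n_particles=2000, immobile_fraction=0.3,
                    rng_seed=seed)
    geometry = straight_cell(FRAP_CELL_LENGTH, FRAP_CELL_WIDTH)
    stack, series, truth = simulate_frap_experiment(cfg, geometry,
                                                    Species("reporter", 0.02), FRAP_ROI)
    origin, _ = field_of_view([geometry], cfg)
    meta = {"pixel_size_um": cfg.pixel_size, "frame_interval_s": cfg.frame_interval,
            "channels": ["reporter"], "bleach_frame": 1,
            "times_s": series.t.tolist(), "prebleach": series.prebleach.tolist(),
            "origin_um": origin.tolist(), "background": cfg.background,
            "rng_seed": seed}
    write_stack(outdir / "frap_stack.tif", stack, meta)
    with open(outdir / "frap_truth.json", "w") as fh:
        json.dump({**truth, "rng_seed": seed}, fh, indent=2, sort_keys=True)
    with open(outdir / "frap_geometry.json", "w") as fh:
        json.dump(geometry.to_dict({"bleach": FRAP_ROI}), fh, indent=2, sort_keys=True)

    # 2+3) contact stacks, compatible and incompatible
    for name, compatible in (("contact_compatible", True), ("contact_incompatible", False)):
        res = contact_experiment(compatible, seed + 17, n_steps=100)
        ccfg = res["config"]
        rng = substream(seed + 17, 6)
        fov = field_of_view(res["geometries"], ccfg)
        img = render_frame(res["ensemble"], ccfg, rng=rng, fov=fov)
        meta = {"pixel_size_um": ccfg.pixel_size, "frame_interval_s": ccfg.dt,
                "channels": ["receptor"], "bleach_frame": None,
                "origin_um": fov[0].tolist(), "background": ccfg.background,
                "rng_seed": seed + 17}
        write_stack(outdir / f"{name}.tif", img[None], meta)
        with open(outdir / f"{name}_truth.json", "w") as fh:
            json.dump({"compatible": compatible,
                       "final_bound_receptors": int(res["bound_counts"][-1]),
                       "bound_counts": res["bound_counts"].tolist(),
                       "rng_seed": seed + 17}, fh, indent=2, sort_keys=True)

    # 4) transfer time series
    ex = exchange_population(True, seed + 23, n_pairs=2, t_total=200.0, record_every=100)
    pd.DataFrame({"t_s": ex["t"], "F_donor": ex["f_donor"],
                  "F_recipient": ex["f_recipient"]}).to_csv(
        outdir / "transfer_series.csv", index=False)

    # 5) protease-accessibility table (synthetic per-cell measurements)
    rng = np.random.default_rng(seed + 29)
    n = 20
    f0 = rng.normal(1000, 80, size=2 * n).clip(min=1)
    ratio = np.concatenate([rng.normal(0.1, 0.05, n).clip(0, 1),     # surface-exposed
                            rng.normal(0.95, 0.05, n).clip(0, 1.2)])  # protected
    pd.DataFrame({"cell_id": np.arange(2 * n),
                  "group": ["surface_exposed"] * n + ["protected"] * n,
                  "F_0": f0, "F_PK": f0 * ratio}).to_csv(outdir / "pk_table.csv",
                                                         index=False)

    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json":
            files[p.name] = sha256_file(p)
    manifest = {"seed": seed, "files": files}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
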