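"""Particle-based simulation of outer-membrane protein dynamics on rod cells.

Surface proteins (slow TraA-like receptors, fast lipoprotein-like cargo) are
modelled as point particles diffusing along the 1-D arc-length axis of a rod
cell with reflecting poles.  Cell-cell contact zones trap compatible receptors
(focus formation), and cargo crosses between cells through zones that hold
bound receptor pairs (outer-membrane exchange).  A rendering step turns an
ensemble into a realistic fluorescence image: Gaussian PSF, Poisson shot
noise, Gaussian read noise.

Everything downstream (profiles, FRAP quantification, exchange statistics)
can therefore be validated against known ground truth.

All positions are in micrometres, times in seconds, diffusivities in um^2/s.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CellGeometry",
    "Species",
    "ParticleEnsemble",
    "ContactZone",
    "SimConfig",
    "straight_cell",
    "init_ensemble",
    "merge_ensembles",
    "step_diffusion",
    "analytic_profile",
    "apply_bleach",
    "update_contacts",
    "transfer_cargo",
    "render_frame",
    "field_of_view",
    "simulate_frap_experiment",
    "allele_compat",
]


# --------------------------------------------------------------------------
# RNG plumbing: one root seed per simulation; sub-streams are derived
# deterministically from (seed, operation code, call index) so that the order
# in which independent operations consume randomness cannot change results.
# --------------------------------------------------------------------------

OP_INIT, OP_DIFFUSE, OP_BLEACH, OP_CONTACT, OP_TRANSFER, OP_RENDER = range(1, 7)


def substream(seed: int, op: int, call: int = 0) -> np.random.Generator:
    """Deterministic child generator for operation ``op``, invocation ``call``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, op, call]))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGeometry:
    """A rod cell: centerline polyline (um) plus width; arc length s in [0, L].

    The arc origin (s = 0) is the first centerline point.
    """

    centerline: np.ndarray
    width: float
    cell_id: str = "cell"

    def __post_init__(self):
        pts = np.asarray(self.centerline, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("centerline must be an (N>=2, 2) array of 2-D points")
        if not self.width > 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline arc length must be strictly increasing (repeated vertex)")
        object.__setattr__(self, "centerline", pts)
        object.__setattr__(self, "_cum", np.concatenate([[0.0], np.cumsum(seg)]))

    @property
    def length(self) -> float:
        return float(self._cum[-1])

    def point_at(self, s) -> np.ndarray:
        """Interpolate 2-D position(s) at arc length(s) ``s``."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        x = np.interp(s, self._cum, self.centerline[:, 0])
        y = np.interp(s, self._cum, self.centerline[:, 1])
        return np.stack([x, y], axis=-1)

    def normal_at(self, s) -> np.ndarray:
        """Unit normal(s) to the centerline at arc length(s) ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        idx = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0, len(self._cum) - 2)
        tang = self.centerline[idx + 1] - self.centerline[idx]
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        return np.stack([-tang[:, 1], tang[:, 0]], axis=-1)

    def to_dict(self, rois: dict[str, tuple[float, float]] | None = None) -> dict:
        d = {
            "cell_id": self.cell_id,
            "centerline": self.centerline.tolist(),
            "width_um": self.width,
        }
        if rois is not None:
            d["rois"] = [{"name": k, "lo_um": lo, "hi_um": hi} for k, (lo, hi) in rois.items()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CellGeometry":
        return cls(np.asarray(d["centerline"], float), float(d["width_um"]), str(d["cell_id"]))


def straight_cell(length: float, width: float = 0.5, *, x0: float = 0.0,
                  y: float = 0.0, cell_id: str = "cell") -> CellGeometry:
    """Convenience: a straight horizontal rod from (x0, y) to (x0+length, y)."""
    return CellGeometry(np.array([[x0, y], [x0 + length, y]]), width, cell_id)


# --------------------------------------------------------------------------
# Species and configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Species:
    """A surface-protein species.

    Receptors (TraA-like) carry an allele label and are never transferred;
    cargo (lipoprotein-like) has no allele and may be transferable.
    """

    name: str
    d_free: float
    tra_allele: str | None = None
    transferable: bool = False

    def __post_init__(self):
        if self.d_free < 0:
            raise ValueError("d_free must be >= 0")
        if self.tra_allele is not None and self.transferable:
            raise ValueError("receptor species (with an allele) cannot be transferable")

    @property
    def is_receptor(self) -> bool:
        return self.tra_allele is not None


@dataclass
class SimConfig:
    """Simulation parameters: kinetics, optics and acquisition schedule.

    ``dt`` is the integration step used when contact/transfer kinetics run;
    pure diffusion is sampled exactly at any step size (reflected Brownian
    motion has a closed-form transition kernel), so FRAP acquisitions may use
    one step per frame.
    """

    dt: float = 0.1                     # s
    n_steps: int = 100                  # diffusion steps after the bleach/contact event
    steps_per_frame: int = 1            # frames rendered every this many steps
    pixel_size: float = 0.065           # um
    psf_sigma: float = 0.10             # um (Gaussian PSF sd)
    background: float = 100.0           # camera counts per pixel
    photons_per_particle: float = 50.0  # counts deposited per fluorescent particle
    read_noise_sd: float = 2.0          # counts
    k_on: float = 0.0                   # 1/s, receptor trapping rate in compatible zones
    k_off: float = 0.1                  # 1/s, receptor release rate
    k_transfer: float = 0.0             # 1/s, cargo transfer rate through engaged zones
    d_bound: float = 5e-4               # um^2/s, diffusivity of zone-bound receptors
    bleach_prob: float = 0.6            # per-pulse dark conversion probability
    n_pulses: int = 4                   # laser pulses per bleach event
    rng_seed: int = 0
    n_particles: int = 6000
    immobile_fraction: float = 0.0
    n_prebleach: int = 1
    late_frame_time: float | None = None  # s; extra reference frames long after the bleach
    n_late_frames: int = 1                # reference frames acquired from late_frame_time on
    fov_pad: float = 0.5                # um of clearance around geometry in rendered frames

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for name in ("pixel_size", "psf_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("background", "photons_per_particle", "read_noise_sd", "k_on",
                     "k_off", "k_transfer", "d_bound", "fov_pad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.bleach_prob <= 1:
            raise ValueError("bleach_prob must be in [0, 1]")
        if not 0 <= self.immobile_fraction <= 1:
            raise ValueError("immobile_fraction must be in [0, 1]")
        if self.n_pulses < 0 or self.n_steps < 0 or self.n_particles < 0:
            raise ValueError("counts must be >= 0")

    @property
    def frame_interval(self) -> float:
        return self.dt * self.steps_per_frame

    def check_step_resolution(self, d_max: float, length_scale: float | None = None) -> None:
        """Warn when dt under-resolves motion relative to ``length_scale``.

        Only relevant when reaction kinetics (binding/transfer) are active:
        their per-step probabilities assume positions change little within dt
        relative to the capture region.  ``length_scale`` defaults to half a
        pixel; pass half the contact-zone length when zones are the relevant
        capture scale.
        """
        if length_scale is None:
            length_scale = self.pixel_size / 2
        if (self.k_on > 0 or self.k_transfer > 0) and d_max > 0:
            if math.sqrt(2 * d_max * self.dt) > length_scale:
                warnings.warn(
                    f"sqrt(2*D*dt)={math.sqrt(2 * d_max * self.dt):.3g} um exceeds "
                    f"{length_scale:.3g} um; reaction kinetics may be "
                    "under-resolved — reduce dt",
                    stacklevel=2,
                )


# --------------------------------------------------------------------------
# Particle ensemble
# --------------------------------------------------------------------------


@dataclass
class ParticleEnsemble:
    """Flat arrays describing every simulated particle, possibly across cells.

    ``cell`` and ``species`` index into the ``geometries`` / ``species_table``
    registries.  ``lateral`` is a per-particle fixed fractional offset across
    the cell width, used only by the renderer (drawn once at creation so that
    rendering is deterministic given the ensemble).
    """

    s: np.ndarray              # float, arc position (um)
    cell: np.ndarray           # int index into geometries
    species: np.ndarray        # int index into species_table
    fluorescent: np.ndarray    # bool
    immobile: np.ndarray       # bool, permanently immobile subpopulation
    bound: np.ndarray          # bool, trapped in a contact zone
    bound_zone: np.ndarray     # int, zone index or -1
    lateral: np.ndarray        # float in [-0.5, 0.5]
    geometries: tuple[CellGeometry, ...]
    species_table: tuple[Species, ...]

    def __post_init__(self):
        n = len(self.s)
        for name in ("cell", "species", "fluorescent", "immobile", "bound", "bound_zone", "lateral"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        lengths = np.array([g.length for g in self.geometries])
        if n and (np.any(self.s < 0) or np.any(self.s > lengths[self.cell])):
            raise ValueError("particle arc positions must lie within their cell: 0 <= s <= L")

    @property
    def n(self) -> int:
        return len(self.s)

    def copy(self) -> "ParticleEnsemble":
        return ParticleEnsemble(
            self.s.copy(), self.cell.copy(), self.species.copy(),
            self.fluorescent.copy(), self.immobile.copy(), self.bound.copy(),
            self.bound_zone.copy(), self.lateral.copy(),
            self.geometries, self.species_table,
        )

    def species_index(self, name: str) -> int:
        for i, sp in enumerate(self.species_table):
            if sp.name == name:
                return i
        raise KeyError(f"unknown species {name!r}")

    def cell_index(self, cell_id: str) -> int:
        for i, g in enumerate(self.geometries):
            if g.cell_id == cell_id:
                return i
        raise KeyError(f"unknown cell {cell_id!r}")

    def counts(self) -> dict[tuple[str, str], int]:
        """Particle count per (cell_id, species name) — conservation bookkeeping."""
        out: dict[tuple[str, str], int] = {}
        for ci, g in enumerate(self.geometries):
            for si, sp in enumerate(self.species_table):
                out[(g.cell_id, sp.name)] = int(np.sum((self.cell == ci) & (self.species == si)))
        return out


def init_ensemble(geometry: CellGeometry, species: Species, n: int,
                  immobile_fraction: float = 0.0, seed=0) -> ParticleEnsemble:
    """Uniformly seed ``n`` fluorescent particles of one species on one cell.

    ``round(n * immobile_fraction)`` particles are flagged permanently
    immobile (they never diffuse, bind or transfer).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0 <= immobile_fraction <= 1:
        raise ValueError("immobile_fraction must be in [0, 1]")
    rng = _as_rng(seed)
    s = rng.uniform(0.0, geometry.length, size=n)
    immobile = np.zeros(n, dtype=bool)
    n_imm = int(round(n * immobile_fraction))
    if n_imm:
        immobile[rng.choice(n, size=n_imm, replace=False)] = True
    return ParticleEnsemble(
        s=s,
        cell=np.zeros(n, dtype=np.intp),
        species=np.zeros(n, dtype=np.intp),
        fluorescent=np.ones(n, dtype=bool),
        immobile=immobile,
        bound=np.zeros(n, dtype=bool),
        bound_zone=np.full(n, -1, dtype=np.intp),
        lateral=rng.uniform(-0.5, 0.5, size=n),
        geometries=(geometry,),
        species_table=(species,),
    )


def merge_ensembles(*ensembles: ParticleEnsemble) -> ParticleEnsemble:
    """Concatenate ensembles, de-duplicating cell and species registries by id."""
    geoms: list[CellGeometry] = []
    specs: list[Species] = []
    for e in ensembles:
        for g in e.geometries:
            if not any(h.cell_id == g.cell_id for h in geoms):
                geoms.append(g)
        for sp in e.species_table:
            if not any(t.name == sp.name for t in specs):
                specs.append(sp)
    gmap = {g.cell_id: i for i, g in enumerate(geoms)}
    smap = {sp.name: i for i, sp in enumerate(specs)}
    parts = {k: [] for k in ("s", "cell", "species", "fluorescent", "immobile",
                             "bound", "bound_zone", "lateral")}
    for e in ensembles:
        parts["s"].append(e.s)
        parts["cell"].append(np.array([gmap[e.geometries[c].cell_id] for c in e.cell], dtype=np.intp))
        parts["species"].append(np.array([smap[e.species_table[i].name] for i in e.species], dtype=np.intp))
        for k in ("fluorescent", "immobile", "bound", "bound_zone", "lateral"):
            parts[k].append(getattr(e, k))
    cat = {k: (np.concatenate(v) if v else np.empty(0)) for k, v in parts.items()}
    return ParticleEnsemble(geometries=tuple(geoms), species_table=tuple(specs), **cat)


# --------------------------------------------------------------------------
# Diffusion
# --------------------------------------------------------------------------


def _reflect(s: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Fold positions into [0, L] (exact reflected-Brownian transition)."""
    s = np.mod(s, 2.0 * L)
    return np.where(s > L, 2.0 * L - s, s)


def step_diffusion(ensemble: ParticleEnsemble, dt: float,
                   rng=0, d_bound: float = 0.0) -> ParticleEnsemble:
    """Advance every particle by one Brownian step of duration ``dt``.

    Mobile unbound particles move with their species d_free, zone-bound
    particles with ``d_bound``, immobile particles not at all.  Poles reflect.
    Fluorescence states are untouched.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = _as_rng(rng)
    out = ensemble.copy()
    if out.n == 0:
        return out
    d_free = np.array([sp.d_free for sp in out.species_table])[out.species]
    d_eff = np.where(out.bound, d_bound, d_free)
    d_eff = np.where(out.immobile, 0.0, d_eff)
    sd = np.sqrt(2.0 * d_eff * dt)
    steps = rng.standard_normal(out.n) * sd
    L = np.array([g.length for g in out.geometries])[out.cell]
    out.s = _reflect(out.s + steps, L)
    return out


def analytic_profile(d: float, t: float, length: float,
                     bleach_interval: tuple[float, float], depth: float,
                     n_terms: int = 200, s: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form concentration profile for 1-D diffusion with reflecting ends.

    Initial condition: c = 1 outside ``bleach_interval`` = [a, b), 1 - depth
    inside.  Solution is the truncated cosine series (Neumann eigenbasis):

        c(s, t) = 1 - depth*(b-a)/L
                  - depth * sum_n (2/(n*pi)) (sin(n*pi*b/L) - sin(n*pi*a/L))
                          * cos(n*pi*s/L) * exp(-D (n*pi/L)^2 t)

    Mass is conserved for every t.  Returns (s, c).
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if not 0 <= depth <= 1:
        raise ValueError("depth must be in [0, 1]")
    a, b = bleach_interval
    if not (0 <= a < b <= length):
        raise ValueError(f"bleach_interval {bleach_interval} outside [0, {length}]")
    if s is None:
        s = np.linspace(0.0, length, 512)
    s = np.asarray(s, dtype=float)
    n = np.arange(1, n_terms + 1)
    k = n * np.pi / length
    coef = (2.0 / (n * np.pi)) * (np.sin(k * b) - np.sin(k * a)) * np.exp(-d * k**2 * t)
    c = 1.0 - depth * (b - a) / length - depth * (np.cos(np.outer(s, k)) @ coef)
    return s, c


# --------------------------------------------------------------------------
# Photobleaching
# --------------------------------------------------------------------------


def apply_bleach(ensemble: ParticleEnsemble, roi: tuple[float, float],
                 bleach_prob: float, n_pulses: int, seed=0,
                 cell: int | str | None = None) -> ParticleEnsemble:
    """Dark-convert fluorophores inside the arc interval ``roi`` = [lo, hi).

    Each fluorescent particle in the ROI goes dark independently with
    probability 1 - (1 - bleach_prob)**n_pulses (the pulse train is fast:
    positions are frozen during bleaching).  ``cell`` restricts the ROI to one
    cell of a multi-cell ensemble.
    """
    if not 0 <= bleach_prob <= 1:
        raise ValueError("bleach_prob must be in [0, 1]")
    lo, hi = roi
    out = ensemble.copy()
    if hi <= lo:
        warnings.warn("empty bleach ROI: no particles bleached", stacklevel=2)
        return out
    rng = _as_rng(seed)
    in_roi = (out.s >= lo) & (out.s < hi) & out.fluorescent
    if cell is not None:
        ci = cell if isinstance(cell, (int, np.integer)) else out.cell_index(cell)
        in_roi &= out.cell == ci
    p_dark = 1.0 - (1.0 - bleach_prob) ** n_pulses
    dark = in_roi & (rng.random(out.n) < p_dark)
    out.fluorescent[dark] = False
    return out


# --------------------------------------------------------------------------
# Contact-dependent receptor trapping and cargo transfer
# --------------------------------------------------------------------------


@dataclass
class ContactZone:
    """An apposed membrane interval between two cells (or one cell touching
    itself).  Intervals are half-open arc ranges [lo, hi) of equal length."""

    cell_a: str
    cell_b: str
    interval_a: tuple[float, float]
    interval_b: tuple[float, float]
    active: bool = True

    def __post_init__(self):
        la = self.interval_a[1] - self.interval_a[0]
        lb = self.interval_b[1] - self.interval_b[0]
        if la <= 0 or lb <= 0:
            raise ValueError("contact intervals must have positive length")
        if abs(la - lb) > 1e-9:
            raise ValueError("contact intervals must have equal length")
        if self.cell_a == self.cell_b:
            a0, a1 = self.interval_a
            b0, b1 = self.interval_b
            if max(a0, b0) < min(a1, b1):
                raise ValueError("self-contact requires disjoint intervals on the same cell")

    def validate_against(self, geometries: Sequence[CellGeometry]) -> tuple[int, int]:
        ids = {g.cell_id: i for i, g in enumerate(geometries)}
        for cid in (self.cell_a, self.cell_b):
            if cid not in ids:
                raise ValueError(f"contact zone references unknown cell {cid!r}")
        for cid, (lo, hi) in ((self.cell_a, self.interval_a), (self.cell_b, self.interval_b)):
            L = geometries[ids[cid]].length
            if not (0 <= lo < hi <= L):
                raise ValueError(f"contact interval [{lo}, {hi}) outside cell {cid!r} (L={L})")
        return ids[self.cell_a], ids[self.cell_b]


def allele_compat(a: str, b: str) -> bool:
    """Default allele compatibility: the homotypic handshake (equal alleles)."""
    return a == b


def _in_interval(s: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    return (s >= lo) & (s < hi)


def _cell_alleles(ensemble: ParticleEnsemble, cell_idx: int) -> set[str]:
    mask = ensemble.cell == cell_idx
    out = set()
    for si in np.unique(ensemble.species[mask]):
        allele = ensemble.species_table[si].tra_allele
        if allele is not None:
            out.add(allele)
    return out


def update_contacts(ensemble: ParticleEnsemble, zones: Sequence[ContactZone],
                    compat: Callable[[str, str], bool], dt: float,
                    config: SimConfig, rng=0) -> ParticleEnsemble:
    """One binding/unbinding step for receptor particles in contact zones.

    In an active zone whose opposing cell carries a compatible allele, free
    receptors inside the zone bind with probability 1 - exp(-k_on*dt); bound
    receptors release with probability 1 - exp(-k_off*dt).  Deactivating a
    zone releases all of its bonds immediately (foci dissolve on separation).
    Incompatible zones never bind.
    """
    rng = _as_rng(rng)
    out = ensemble.copy()
    p_on = 1.0 - math.exp(-config.k_on * dt)
    p_off = 1.0 - math.exp(-config.k_off * dt)

    # release bonds whose zone is gone or inactive
    active_ids = {zi for zi, z in enumerate(zones) if z.active}
    stale = out.bound & ~np.isin(out.bound_zone, list(active_ids) or [-2])
    out.bound[stale] = False
    out.bound_zone[stale] = -1

    # spontaneous release
    if p_off > 0:
        rel = out.bound & (rng.random(out.n) < p_off)
        out.bound[rel] = False
        out.bound_zone[rel] = -1

    is_receptor = np.array([sp.is_receptor for sp in out.species_table])[out.species]
    alleles = np.array([sp.tra_allele or "" for sp in out.species_table], dtype=object)[out.species]

    for zi, zone in enumerate(zones):
        ia, ib = zone.validate_against(out.geometries)
        if not zone.active:
            continue
        for side_cell, side_int, other_cell in ((ia, zone.interval_a, ib), (ib, zone.interval_b, ia)):
            opposing = _cell_alleles(out, other_cell)
            cand = (is_receptor & ~out.bound & ~out.immobile
                    & (out.cell == side_cell) & _in_interval(out.s, side_int))
            if not np.any(cand):
                continue
            idx = np.flatnonzero(cand)
            cand_alleles = alleles[idx]
            ok = np.zeros(len(idx), dtype=bool)
            for a in set(cand_alleles.tolist()):
                try:
                    good = any(compat(a, b) for b in opposing)
                except KeyError as exc:
                    raise ValueError(f"unknown allele label: {exc}") from exc
                if good:
                    ok |= cand_alleles == a
            idx = idx[ok]
            if len(idx) and p_on > 0:
                hit = idx[rng.random(len(idx)) < p_on]
                out.bound[hit] = True
                out.bound_zone[hit] = zi
    return out


def transfer_cargo(ensemble: ParticleEnsemble, zones: Sequence[ContactZone],
                   dt: float, config: SimConfig, rng=0) -> ParticleEnsemble:
    """One cargo-exchange step through engaged contact zones.

    A zone is engaged when it holds at least one bound receptor pair (bound
    receptors on both apposed intervals).  Transferable cargo inside either
    interval of an engaged zone switches cell with probability
    1 - exp(-k_transfer*dt); its arc position is mapped interval-to-interval.
    Receptors never switch cells; global per-species counts are conserved.
    """
    rng = _as_rng(rng)
    out = ensemble.copy()
    p_tr = 1.0 - math.exp(-config.k_transfer * dt)
    if p_tr == 0:
        return out
    transferable = np.array([sp.transferable for sp in out.species_table])[out.species]
    for zi, zone in enumerate(zones):
        if not zone.active:
            continue
        ia, ib = zone.validate_against(out.geometries)
        bound_here = out.bound & (out.bound_zone == zi)
        n_a = np.sum(bound_here & (out.cell == ia) & _in_interval(out.s, zone.interval_a))
        n_b = np.sum(bound_here & (out.cell == ib) & _in_interval(out.s, zone.interval_b))
        if min(n_a, n_b) < 1:
            continue
        for src, src_int, dst, dst_int in (
            (ia, zone.interval_a, ib, zone.interval_b),
            (ib, zone.interval_b, ia, zone.interval_a),
        ):
            cand = (transferable & ~out.immobile & (out.cell == src)
                    & _in_interval(out.s, src_int))
            idx = np.flatnonzero(cand)
            if not len(idx):
                continue
            move = idx[rng.random(len(idx)) < p_tr]
            if not len(move):
                continue
            frac = (out.s[move] - src_int[0]) / (src_int[1] - src_int[0])
            out.s[move] = dst_int[0] + frac * (dst_int[1] - dst_int[0])
            out.cell[move] = dst
    return out


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def field_of_view(geometries: Sequence[CellGeometry], config: SimConfig,
                  ) -> tuple[np.ndarray, tuple[int, int]]:
    """(origin_xy um, (ny, nx) pixels) covering all cells plus padding."""
    pts = np.concatenate([g.centerline for g in geometries])
    wmax = max(g.width for g in geometries)
    pad = config.fov_pad + wmax / 2 + 3 * config.psf_sigma
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    shape_xy = np.ceil((hi - lo) / config.pixel_size).astype(int) + 1
    return lo, (int(shape_xy[1]), int(shape_xy[0]))


def render_frame(ensemble: ParticleEnsemble, config: SimConfig, rng=None,
                 noise: bool = True, fov=None,
                 species: str | None = None) -> np.ndarray:
    """Render one fluorescence frame (integer camera counts, row = y).

    Each fluorescent particle deposits ``photons_per_particle`` counts at its
    2-D membrane position (arc position on the centerline plus its fixed
    lateral offset across the width), split bilinearly over the four
    neighbouring pixels so that total deposited signal is exact.  The image is
    then blurred with a Gaussian PSF; with ``noise`` the blurred signal plus
    background passes through Poisson shot noise and additive Gaussian read
    noise.  ``species`` restricts rendering to one channel.
    """
    if fov is None:
        fov = field_of_view(ensemble.geometries, config)
    origin, (ny, nx) = fov
    img = np.zeros((ny, nx), dtype=float)

    mask = ensemble.fluorescent.copy()
    if species is not None:
        mask &= ensemble.species == ensemble.species_index(species)
    idx = np.flatnonzero(mask)
    if len(idx):
        pos = np.empty((len(idx), 2))
        for ci, g in enumerate(ensemble.geometries):
            sub = ensemble.cell[idx] == ci
            if not np.any(sub):
                continue
            s = ensemble.s[idx[sub]]
            p = g.point_at(s) + g.normal_at(s) * (ensemble.lateral[idx[sub], None] * g.width)
            pos[sub] = p
        px = (pos - origin) / config.pixel_size
        if np.any(px < -0.5) or np.any(px[:, 0] > nx - 0.5) or np.any(px[:, 1] > ny - 0.5):
            raise ValueError("geometry places particles outside the field of view")
        x0 = np.floor(px[:, 0]).astype(int)
        y0 = np.floor(px[:, 1]).astype(int)
        fx = px[:, 0] - x0
        fy = px[:, 1] - y0
        w = config.photons_per_particle
        for dy, dx, wt in ((0, 0, (1 - fx) * (1 - fy)), (0, 1, fx * (1 - fy)),
                           (1, 0, (1 - fx) * fy), (1, 1, fx * fy)):
            yy = np.clip(y0 + dy, 0, ny - 1)
            xx = np.clip(x0 + dx, 0, nx - 1)
            np.add.at(img, (yy, xx), w * wt)

    if config.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=config.psf_sigma / config.pixel_size,
                                      mode="constant", truncate=6.0)
    if not noise:
        return img  # noiseless float image: photon deposition is exact
    rng = _as_rng(rng if rng is not None else config.rng_seed)
    img = rng.poisson(np.clip(img + config.background, 0, None)).astype(float)
    img += rng.normal(0.0, config.read_noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, None).astype(np.int32)


# --------------------------------------------------------------------------
# FRAP experiment driver
# --------------------------------------------------------------------------


def simulate_frap_experiment(config: SimConfig, geometry: CellGeometry,
                             species: Species, roi: tuple[float, float]):
    """Run a complete in-silico FRAP acquisition on a single cell.

    Acquires ``config.n_prebleach`` frames, applies the bleach pulse train to
    ``roi``, then renders a post-bleach frame every ``steps_per_frame``
    diffusion steps for ``config.n_steps`` steps (the first post-bleach frame
    is captured immediately after the bleach, at t0).

    Returns ``(stack, series, truth)``: the noisy image stack (T, H, W), the
    ground-truth :class:`~omeflux.frap.FrapSeries` built from fluorescent
    particle counts, and a dict of true parameters.
    """
    from .frap import FrapSeries  # local import to avoid a module cycle

    lo, hi = roi
    if not (0 <= lo < hi <= geometry.length):
        raise ValueError(f"bleach ROI {roi} outside cell (L={geometry.length})")
    config.check_step_resolution(species.d_free)

    seed = config.rng_seed
    ens = init_ensemble(geometry, species, config.n_particles,
                        config.immobile_fraction, seed=substream(seed, OP_INIT))
    diff_rng = substream(seed, OP_DIFFUSE)
    render_rng = substream(seed, OP_RENDER)
    fov = field_of_view([geometry], config)

    frames, times, i_frap, i_total, prebleach = [], [], [], [], []

    def record(t, is_pre):
        frames.append(render_frame(ens, config, rng=render_rng, fov=fov))
        times.append(t)
        in_roi = (ens.s >= lo) & (ens.s < hi) & ens.fluorescent
        i_frap.append(float(np.sum(in_roi)))
        i_total.append(float(np.sum(ens.fluorescent)))
        prebleach.append(is_pre)

    t = -config.frame_interval * config.n_prebleach
    for _ in range(config.n_prebleach):
        record(t, True)
        t += config.frame_interval

    ens = apply_bleach(ens, roi, config.bleach_prob, config.n_pulses,
                       seed=substream(seed, OP_BLEACH))
    still_bright = float(np.sum((ens.s >= lo) & (ens.s < hi) & ens.fluorescent))
    realized_depth = 1.0 - still_bright / i_frap[-1] if i_frap[-1] else 0.0

    record(0.0, False)  # t0: immediately after photobleaching
    n_frames = config.n_steps // config.steps_per_frame
    for f in range(n_frames):
        for _ in range(config.steps_per_frame):
            ens = step_diffusion(ens, config.dt, rng=diff_rng, d_bound=config.d_bound)
        record((f + 1) * config.frame_interval, False)
    if config.late_frame_time is not None:
        # extra reference frames long after the bleach; a single folded step
        # is the exact reflected-Brownian transition, so jump there directly
        gap = config.late_frame_time - n_frames * config.frame_interval
        if gap <= 0:
            raise ValueError("late_frame_time must exceed the regular series span")
        for k in range(config.n_late_frames):
            ens = step_diffusion(ens, gap if k == 0 else config.frame_interval,
                                 rng=diff_rng, d_bound=config.d_bound)
            record(config.late_frame_time + k * config.frame_interval, False)

    # series flags exactly one pre-bleach point: the last pre-bleach frame
    pre_flags = np.zeros(len(times), dtype=bool)
    pre_flags[config.n_prebleach - 1] = True
    keep = np.ones(len(times), dtype=bool)
    keep[:config.n_prebleach - 1] = False
    times_a = np.asarray(times)[keep]
    series = FrapSeries(
        t=times_a,
        i_frap=np.asarray(i_frap)[keep],
        i_total=np.asarray(i_total)[keep],
        prebleach=pre_flags[keep],
        roi=roi,
    )
    truth = {
        "d_free_um2_per_s": species.d_free,
        "immobile_fraction": config.immobile_fraction,
        "bleach_depth": float(realized_depth),
        "expected_bleach_depth": 1.0 - (1.0 - config.bleach_prob) ** config.n_pulses,
        "seed": seed,
    }
    return np.stack(frames), series, truth


# --------------------------------------------------------------------------
# Stack serialization (TIFF + JSON sidecar) lives in workbench; simcell only
# provides ground-truth serialization helpers.
# --------------------------------------------------------------------------


def truth_to_json(path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
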