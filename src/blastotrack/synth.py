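"""Seeded generator of ground-truth blastocyst-like nuclei dynamics and
rendered anisotropic 3D time-lapse movies.

The generator emulates chromatin-labelled (H2B-reporter) nuclei at the
blastocyst stage: an outer shell of tangentially elongated ellipsoidal
nuclei (trophectoderm-like), an inner cluster (ICM-like), scheduled cell
divisions, optional micronuclei riding along a daughter track, slow embryo
expansion/collapse oscillation, anisotropic Gaussian blur and
Poisson+Gaussian noise.  Everything is deterministic given a seed, so the
downstream segmentation, tracking and morphometry modules are testable
without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import ConfigError, LabelVolume, VolumetricFrame, orthonormal_frame, unit
from .lineage import LineageForest


@dataclass
class TruthNucleus:
    """Ground-truth trajectory of one ellipsoidal nucleus.

    Per-frame arrays cover the whole movie; entries outside
    ``[birth_frame, death_frame]`` are NaN.
    """

    id: int
    parent_id: int | None
    birth_frame: int
    death_frame: int
    centroids: np.ndarray      # (n_frames, 3) μm, (z, y, x)
    semi_axes: np.ndarray      # (n_frames, 3) μm, a >= b >= c
    orientations: np.ndarray   # (n_frames, 3) unit long-axis vectors
    is_micronucleus: bool = False

    def alive(self, frame: int) -> bool:
        return self.birth_frame <= frame <= self.death_frame

    def volume(self, frame: int) -> float:
        a, b, c = self.semi_axes[frame]
        return float(4.0 / 3.0 * np.pi * a * b * c)


@dataclass
class DivisionEvent:
    parent: int
    daughter1: int
    daughter2: int
    frame: int           # first frame at which the daughters exist
    axis: np.ndarray     # unit division axis


@dataclass
class TruthEmbryo:
    """Ground truth for a whole synthetic movie."""

    centers: np.ndarray        # (n_frames, 3) μm
    shell_radius: np.ndarray   # (n_frames,) μm
    nuclei: list[TruthNucleus]
    divisions: list[DivisionEvent]
    kappa: float
    frame_interval_min: float = 15.0

    @property
    def n_frames(self) -> int:
        return len(self.shell_radius)

    def alive_at(self, frame: int) -> list[TruthNucleus]:
        return [n for n in self.nuclei if n.alive(frame)]

    def live_counts(self) -> np.ndarray:
        """Number of live nuclei per frame (micronuclei included)."""
        return np.array(
            [sum(n.alive(t) for n in self.nuclei) for t in range(self.n_frames)]
        )


def sample_axis(rng: np.random.Generator, radial: np.ndarray | None, kappa: float,
                size: int | None = None) -> np.ndarray:
    """Sample sign-free unit axes with tangential bias ``kappa``.

    An isotropic axis v is decomposed against the radial unit vector r̂ into
    radial and tangential parts; the radial component is shrunk by
    (1 - kappa) and the result renormalised:

        v' = normalize((1 - kappa) (v·r̂) r̂ + (v - (v·r̂) r̂))

    kappa = 0 returns v unchanged (isotropic); kappa = 1 projects exactly
    onto the tangent plane.  The angle to the radial direction is monotone
    increasing in kappa for every sample, so the mean angle is monotone too.
    """
    scalar = size is None
    n = 1 if scalar else size
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if radial is not None and kappa > 0:
        r = unit(radial)
        c = v @ r
        tang = v - np.outer(c, r)
        # resample nearly-radial draws whose tangential part would vanish
        bad = np.linalg.norm(tang, axis=1) < 1e-9
        while kappa == 1.0 and bad.any():
            v[bad] = rng.normal(size=(int(bad.sum()), 3))
            v[bad] /= np.linalg.norm(v[bad], axis=1, keepdims=True)
            c = v @ r
            tang = v - np.outer(c, r)
            bad = np.linalg.norm(tang, axis=1) < 1e-9
        v = (1.0 - kappa) * np.outer(c, r) + tang
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v[0] if scalar else v


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (z, y, x)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([z, s * np.sin(phi), s * np.cos(phi)], axis=1)


def make_blastocyst(
    n_outer: int = 12,
    n_inner: int = 4,
    n_frames: int = 40,
    division_schedule: list | None = None,
    kappa: float = 0.8,
    oscillation: tuple[float, float] = (0.06, 24.0),
    seed: int = 0,
    radius: float = 30.0,
    drift: float = 1.0,
    mean_semi_axes: tuple[float, float, float] = (6.5, 4.5, 3.5),
    size_jitter: float = 0.10,
    n_micronuclei: int = 0,
    micro_semi_axes: tuple[float, float, float] = (1.6, 1.4, 1.2),
    frame_interval_min: float = 15.0,
) -> TruthEmbryo:
    """Build a ground-truth blastocyst-like movie.

    Parameters
    ----------
    n_outer, n_inner : int
        Founder nuclei on the shell and in the inner cluster.
    n_frames : int
        Movie length; frames are ``frame_interval_min`` apart (default 15 min).
    division_schedule : list
        Frames at which a division occurs, either plain ints (parents picked
        round-robin among live outer nuclei) or ``(frame, parent_id)`` pairs.
    kappa : float in [0, 1]
        Tangential bias of nuclear long axes and division axes; 0 isotropic,
        1 exactly tangential.
    oscillation : (amplitude, period_frames)
        Relative sinusoidal modulation of the shell radius emulating
        expansion/collapse cycles.
    radius : float
        Baseline shell radius R₀ in μm.
    drift : float
        RMS per-frame centroid displacement in μm (free parameter; real
        inter-frame motion at a 15-min cadence is of order a micrometre).
    n_micronuclei : int
        Number of division events that shed a micronucleus (< 30 μm³)
        passively inherited by daughter 1.
    """
    if n_frames < 1:
        raise ConfigError("n_frames must be >= 1")
    if not 0.0 <= kappa <= 1.0:
        raise ConfigError("kappa must lie in [0, 1]")
    if radius <= 0:
        raise ConfigError("radius must be positive")
    amp, period = oscillation
    if abs(amp) >= 1.0:
        raise ConfigError("oscillation amplitude must be < 1 (radius stays positive)")
    a0, b0, c0 = mean_semi_axes
    if not (a0 >= b0 >= c0 > 0):
        raise ConfigError("mean_semi_axes must satisfy a >= b >= c > 0")
    # crude surface-packing feasibility: ellipse footprints must fit the shell
    if n_outer * np.pi * a0 * b0 > 0.7 * 4.0 * np.pi * radius**2:
        raise ConfigError(
            f"cannot place {n_outer} nuclei of footprint ~{np.pi*a0*b0:.0f} μm² "
            f"on a shell of radius {radius} μm"
        )

    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    shell_radius = radius * (1.0 + amp * np.sin(2.0 * np.pi * t / period))
    centers = np.zeros((n_frames, 3))

    schedule: list[tuple[int, int | None]] = []
    for item in division_schedule or []:
        if isinstance(item, (tuple, list)):
            f, p = int(item[0]), int(item[1])
        else:
            f, p = int(item), None
        if not 1 <= f < n_frames:
            raise ConfigError(f"division frame {f} outside (0, n_frames)")
        schedule.append((f, p))
    schedule.sort(key=lambda fp: fp[0])

    nuclei: list[TruthNucleus] = []
    nan = np.full((n_frames, 3), np.nan)

    def new_nucleus(nid, parent, birth, semi, is_micro=False):
        n = TruthNucleus(
            id=nid, parent_id=parent, birth_frame=birth, death_frame=n_frames - 1,
            centroids=nan.copy(), semi_axes=nan.copy(), orientations=nan.copy(),
            is_micronucleus=is_micro,
        )
        n.semi_axes[birth:] = semi
        nuclei.append(n)
        return n

    def jittered_axes(base):
        s = np.sort(np.asarray(base) * rng.lognormal(0.0, size_jitter, 3))[::-1]
        return s

    # founders: outer on the shell, inner in a cluster
    outer_dirs = _fibonacci_sphere(max(n_outer, 1))[:n_outer]
    # random rotation so seeds differ in placement, not just jitter
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    outer_dirs = outer_dirs @ q.T
    next_id = 1
    outer_pos = {}
    for d in outer_dirs:
        nuc = new_nucleus(next_id, None, 0, jittered_axes(mean_semi_axes))
        outer_pos[nuc.id] = unit(d)
        next_id += 1
    inner_ids = []
    if n_inner:
        inner_dirs = _fibonacci_sphere(max(n_inner, 1))[:n_inner] @ q.T
        for d in inner_dirs:
            nuc = new_nucleus(next_id, None, 0, jittered_axes(mean_semi_axes))
            inner_ids.append(nuc.id)
            nuc._inner_dir = unit(d)  # type: ignore[attr-defined]
            next_id += 1

    by_id = {n.id: n for n in nuclei}
    inner_radius_frac = 0.35
    divisions: list[DivisionEvent] = []
    micro_follow: dict[int, tuple[int, np.ndarray]] = {}  # micro id -> (host id, offset)
    micro_budget = n_micronuclei
    sched_idx = 0
    divided: set[int] = set()

    for f in range(n_frames):
        R = shell_radius[f]
        # ---- positions ----
        for n in nuclei:
            if not n.alive(f) or n.is_micronucleus:
                continue
            if f == n.birth_frame and not np.isnan(n.centroids[f]).all():
                continue  # placed by a division event below
            if n.id in outer_pos:
                d = outer_pos[n.id]
                if f > n.birth_frame:
                    step = drift / R  # tangential random walk on the unit sphere
                    d = unit(d + step * sample_axis(rng, d, 1.0))
                    outer_pos[n.id] = d
                n.centroids[f] = centers[f] + R * d
            else:
                if f == n.birth_frame:
                    p = getattr(n, "_inner_dir", None)
                    if p is None:
                        p = sample_axis(rng, None, 0.0)
                    n.centroids[f] = centers[f] + inner_radius_frac * R * 0.8 * p
                else:
                    pos = n.centroids[f - 1] + drift * sample_axis(rng, None, 0.0)
                    rel = pos - centers[f]
                    rmax = inner_radius_frac * R
                    if np.linalg.norm(rel) > rmax:
                        rel = unit(rel) * rmax
                    n.centroids[f] = centers[f] + rel
        # micronuclei ride along their host daughter at a fixed offset
        for mid, (host, off) in micro_follow.items():
            m = by_id[mid]
            if m.alive(f) and by_id[host].alive(f):
                m.centroids[f] = by_id[host].centroids[f] + off

        # ---- orientations: resampled each frame with tangential bias ----
        for n in nuclei:
            if not n.alive(f):
                continue
            if not np.isnan(n.orientations[f]).all():
                continue  # set at division
            radial = n.centroids[f] - centers[f]
            if n.id in outer_pos and np.linalg.norm(radial) > 1e-9:
                n.orientations[f] = sample_axis(rng, radial, kappa)
            else:
                n.orientations[f] = sample_axis(rng, None, 0.0)

        # ---- divisions happening at the *next* frame are resolved there; ----
        # events scheduled at frame f replace the parent now.
        while sched_idx < len(schedule) and schedule[sched_idx][0] == f:
            _, pid = schedule[sched_idx]
            sched_idx += 1
            live_outer = [n.id for n in nuclei
                          if n.alive(f) and n.id in outer_pos and not n.is_micronucleus]
            if pid is None:
                candidates = [i for i in live_outer if i not in divided] or live_outer
                if not candidates:
                    raise ConfigError("no live outer nucleus available to divide")
                pid = min(candidates)
            if pid not in by_id or not by_id[pid].alive(f):
                raise ConfigError(f"scheduled parent {pid} is not alive at frame {f}")
            parent = by_id[pid]
            divided.add(pid)
            radial = parent.centroids[f - 1] - centers[f - 1]
            axis = sample_axis(rng, radial, kappa)
            a_par = parent.semi_axes[f - 1][0]
            # parent dies at f-1; daughters appear at f, symmetric about the
            # parent's last position along the division axis (±0.8·a)
            base = np.array(parent.centroids[f - 1] if np.isnan(parent.centroids[f]).all()
                            else parent.centroids[f])
            parent.death_frame = f - 1
            parent.centroids[f:] = np.nan
            parent.orientations[f:] = np.nan
            d_axes = np.sort(parent.semi_axes[f - 1] / 2.0 ** (1.0 / 3.0))[::-1]
            kids = []
            for sgn in (+1.0, -1.0):
                kid = new_nucleus(next_id, pid, f, d_axes)
                next_id += 1
                kid.centroids[f] = base + sgn * 0.8 * a_par * axis
                kid.orientations[f] = sample_axis(
                    rng, kid.centroids[f] - centers[f], kappa)
                if pid in outer_pos:
                    outer_pos[kid.id] = unit(kid.centroids[f] - centers[f])
                kids.append(kid)
            outer_pos.pop(pid, None)
            divisions.append(DivisionEvent(pid, kids[0].id, kids[1].id, f, axis))
            by_id.update({k.id: k for k in kids})
            if micro_budget > 0:
                micro_budget -= 1
                host = kids[0]
                off = 1.3 * a_par * sample_axis(rng, None, 0.0)
                m = new_nucleus(next_id, host.id, f,
                                jittered_axes(micro_semi_axes), is_micro=True)
                next_id += 1
                m.centroids[f] = host.centroids[f] + off
                m.orientations[f] = sample_axis(rng, None, 0.0)
                micro_follow[m.id] = (host.id, off)
                by_id[m.id] = m
        # micronuclei created this frame already have orientation; others keep NaN-free state

    # fill micronuclei orientations for all alive frames
    for mid in micro_follow:
        m = by_id[mid]
        for f in range(m.birth_frame, m.death_frame + 1):
            if np.isnan(m.orientations[f]).all():
                m.orientations[f] = sample_axis(rng, None, 0.0)

    return TruthEmbryo(centers=centers, shell_radius=shell_radius, nuclei=nuclei,
                       divisions=divisions, kappa=kappa,
                       frame_interval_min=frame_interval_min)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _movie_geometry(truth: TruthEmbryo, spacing: np.ndarray, margin: float):
    rmax = float(truth.shell_radius.max())
    amax = max(float(np.nanmax(n.semi_axes)) for n in truth.nuclei) if truth.nuclei else 5.0
    half = rmax + amax + margin
    origin = truth.centers[0] - half
    shape = np.ceil(2 * half / spacing).astype(int) + 1
    return origin, tuple(int(s) for s in shape)


def rasterize_labels(
    truth: TruthEmbryo,
    spacing=(2.0, 1.0, 1.0),
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
    margin: float = 4.0,
) -> list[LabelVolume]:
    """Noise-free rasterization of the truth ellipsoids, one LabelVolume per
    frame.  Voxels claimed by several ellipsoids go to the instance with the
    smaller Euclidean distance-to-centroid, ties to the lower id.
    """
    spacing = np.asarray(spacing, dtype=float)
    if origin is None or shape is None:
        origin, shape = _movie_geometry(truth, spacing, margin)
    out = []
    warned = False
    for f in range(truth.n_frames):
        labels = np.zeros(shape, dtype=np.int32)
        best = np.full(shape, np.inf, dtype=np.float32)
        for n in sorted(truth.alive_at(f), key=lambda n: n.id):
            c = n.centroids[f]
            a = n.semi_axes[f]
            frame_basis = orthonormal_frame(n.orientations[f])
            amax = a[0]
            lo = np.floor((c - origin - amax) / spacing).astype(int)
            hi = np.ceil((c - origin + amax) / spacing).astype(int) + 1
            if np.any(hi <= 0) or np.any(lo >= shape):
                if not warned:
                    warnings.warn("truth nuclei outside the field of view; clipping")
                    warned = True
                continue
            if np.any(lo < 0) or np.any(hi > shape):
                if not warned:
                    warnings.warn("truth nuclei outside the field of view; clipping")
                    warned = True
            lo = np.clip(lo, 0, shape)
            hi = np.clip(hi, 0, shape)
            grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                                indexing="ij")
            pos = np.stack(grids, axis=-1) * spacing + origin  # physical coords
            q = pos - c
            local = q @ frame_basis.T          # coords in ellipsoid axes
            m = np.sum((local / a) ** 2, axis=-1)
            inside = m <= 1.0
            if not inside.any():
                continue
            d = np.linalg.norm(q, axis=-1)
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            take = inside & (d < best[sl])
            labels[sl][take] = n.id
            best[sl][take] = d[take]
        out.append(LabelVolume(labels=labels, spacing=spacing, frame_index=f))
    return out


def render(
    truth: TruthEmbryo,
    spacing=(2.0, 1.0, 1.0),
    blur_sigma=(1.6, 0.8, 0.8),
    noise=(50.0, 0.05),
    seed: int = 0,
    margin: float = 4.0,
) -> tuple[list[VolumetricFrame], list[LabelVolume]]:
    """Render intensity movie + ground-truth label movie.

    intensity = anisotropic-Gaussian-blurred indicator of the nuclei, then
    Poisson noise on the scaled signal plus additive Gaussian noise.  With the
    defaults (photon scale 50, Gaussian sd 0.05) in-nucleus SNR is ~10.
    """
    spacing = np.asarray(spacing, dtype=float)
    blur_sigma = np.asarray(blur_sigma, dtype=float)
    if np.any(blur_sigma < 0):
        raise ConfigError("blur_sigma must be non-negative")
    poisson_scale, gauss_sd = noise
    rng = np.random.default_rng(seed)
    labels = rasterize_labels(truth, spacing, margin=margin)
    frames = []
    for f, lv in enumerate(labels):
        signal = (lv.labels > 0).astype(np.float32)
        sig_vox = blur_sigma / spacing
        if np.any(sig_vox > 0):
            signal = gaussian_filter(signal, sigma=sig_vox)
        if poisson_scale > 0:
            signal = rng.poisson(signal * poisson_scale).astype(np.float32) / poisson_scale
        if gauss_sd > 0:
            signal = signal + rng.normal(0.0, gauss_sd, signal.shape).astype(np.float32)
        frames.append(VolumetricFrame(intensity=signal, spacing=spacing,
                                      time_index=f,
                                      time_minutes=f * truth.frame_interval_min))
    return frames, labels


def truth_lineage(truth: TruthEmbryo) -> LineageForest:
    """Ground-truth lineage forest: continuation edges along each life span,
    division edges from a parent's last frame to each daughter's first frame.
    Micronuclei appear as independent single chains (they carry a parent_id
    association but are not lineage daughters)."""
    forest = LineageForest(n_frames=truth.n_frames)
    for n in truth.nuclei:
        for f in range(n.birth_frame, n.death_frame + 1):
            forest.add_node(f, n.id)
            if f > n.birth_frame:
                forest.add_edge((f - 1, n.id), (f, n.id), kind="continuation")
    for ev in truth.divisions:
        parent = next(n for n in truth.nuclei if n.id == ev.parent)
        src = (parent.death_frame, ev.parent)
        forest.add_edge(src, (ev.frame, ev.daughter1), kind="division")
        forest.add_edge(src, (ev.frame, ev.daughter2), kind="division")
    return forest


def truth_table(truth: TruthEmbryo) -> pd.DataFrame:
    """One row per nucleus-frame: id, parent_id, frame, z, y, x, a, b, c,
    orientation vector, micronucleus flag."""
    rows = []
    for n in truth.nuclei:
        for f in range(n.birth_frame, n.death_frame + 1):
            z, y, x = n.centroids[f]
            a, b, c = n.semi_axes[f]
            oz, oy, ox = n.orientations[f]
            rows.append(dict(id=n.id, parent_id=-1 if n.parent_id is None else n.parent_id,
                             frame=f, z=z, y=y, x=x, a=a, b=b, c=c,
                             orient_z=oz, orient_y=oy, orient_x=ox,
                             is_micronucleus=int(n.is_micronucleus)))
    return pd.DataFrame(rows)


def write_truth_csv(truth: TruthEmbryo, path: str | Path) -> None:
    truth_table(truth).to_csv(path, index=False, float_format="%.6f")


# default preset used across tests and the pipeline smoke runs:
# 12 shell founders, 4 inner, 6 scheduled divisions, 40 frames, ~1 μm/frame
# drift (well below the ~4 μm short nuclear semi-axis).
DEFAULT_PRESET = dict(
    n_outer=12, n_inner=4, n_frames=40,
    division_schedule=[6, 12, 18, 24, 30, 36],
    kappa=0.8, oscillation=(0.06, 24.0), radius=30.0, drift=1.0,
)


def make_preset(name: str = "blastocyst", seed: int = 0, **overrides) -> TruthEmbryo:
    if name != "blastocyst":
        raise ConfigError(f"unknown preset {name!r}")
    params = dict(DEFAULT_PRESET)
    params.update(overrides)
    if "division_schedule" not in overrides:
        # keep the preset schedule consistent with a shortened movie
        nf = params["n_frames"]
        params["division_schedule"] = [
            f for f in params["division_schedule"]
            if (f[0] if isinstance(f, (tuple, list)) else f) < nf]
    return make_blastocyst(seed=seed, **params)
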