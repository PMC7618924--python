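"""Nuclear and embryo-level morphometrics and orientation statistics.

For each segmented nucleus the best-fitting ellipsoid is obtained from the
second central moments of its voxel coordinates: the axis diameter along
eigenvector k is 2·sqrt(5·λ_k) (the moment inversion of a solid uniform
ellipsoid), anisotropy is d_max/d_min and the orientation is the sign-free
long-axis eigenvector.  The same construction applied to the convex hull of
all nuclei gives the embryo-level shape; the average shell thickness is the
standard deviation of nucleus-to-embryo-centre distances (zero for a
perfect single-layer shell).

Orientation statistics use three sign-free angles in [0°, 90°]:

* α — nucleus long axis vs embryo long axis,
* β — nucleus long axis vs the radial direction from the embryo centre
  (0° radial, 90° tangential),
* ϑ — division axis (line through the two daughters at their first shared
  frame) vs the radial direction at the parent.

Deviations from isotropy are assessed with a one-sample Kolmogorov–Smirnov
test: for an isotropic 3D axis the cosine of the angle to any fixed
direction is Uniform(0, 1), so u = cos(angle) is tested against U(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull

from .core import DataFormatError, LabelVolume, unit
from .lineage import LineageForest

_EIG_FLOOR = 0.5**2  # μm², degenerate-instance covariance floor


@dataclass
class NucleusRecord:
    frame: int
    label: int
    centroid: np.ndarray        # (3,) μm
    volume: float               # μm³
    covariance: np.ndarray      # (3, 3) μm²
    axis_diameters: np.ndarray  # (3,) μm, d_max >= d_mid >= d_min
    orientation: np.ndarray     # (3,) unit long-axis vector (sign-free)
    anisotropy: float           # d_max / d_min
    degenerate: bool = False


@dataclass
class EmbryoShape:
    frame: int
    center: np.ndarray
    hull_volume: float
    axis_diameters: np.ndarray
    orientation: np.ndarray
    anisotropy: float
    shell_thickness: float


def _moment_shape(coords_um: np.ndarray, box_correction=None):
    """Centroid, covariance, diameters (2√(5λ)), orientation, anisotropy.

    ``box_correction`` (a voxel spacing) adds Sheppard's + spacing²/12 term
    for grid-sampled masses; leave None for true point samples.
    """
    center = coords_um.mean(axis=0)
    q = coords_um - center
    cov = (q.T @ q) / len(coords_um)
    if box_correction is not None:
        cov = cov + np.diag(np.asarray(box_correction, float) ** 2 / 12.0)
    w, v = np.linalg.eigh(cov)
    degenerate = bool(w.min() <= 1e-12)
    w = np.maximum(w, _EIG_FLOOR if degenerate else w.min())
    diam = 2.0 * np.sqrt(5.0 * w)[::-1]          # descending
    orientation = v[:, -1]                       # eigenvector of λ_max
    if degenerate:
        diam = np.full(3, diam.max())            # flagged, anisotropy 1
    aniso = float(diam[0] / diam[-1])
    return center, cov, diam, orientation, max(aniso, 1.0), degenerate


def nucleus_shape(lv: LabelVolume, label: int) -> NucleusRecord:
    """Moments-based ellipsoid fit of one instance.

    The voxel covariance carries Sheppard's correction (+ spacing²/12 per
    axis): a voxel's mass fills its box, and point-sampling alone biases the
    moments low on coarse axes.
    """
    idx = np.argwhere(lv.labels == label)
    if len(idx) == 0:
        raise KeyError(f"label {label} not present")
    coords = idx.astype(float) * lv.spacing
    volume = len(idx) * lv.voxel_volume
    if len(idx) <= 2:
        center = coords.mean(axis=0)
        return NucleusRecord(frame=lv.frame_index, label=int(label),
                             centroid=center, volume=volume,
                             covariance=np.eye(3) * _EIG_FLOOR,
                             axis_diameters=np.full(3, 2 * np.sqrt(5 * _EIG_FLOOR)),
                             orientation=np.array([0.0, 0.0, 1.0]),
                             anisotropy=1.0, degenerate=True)
    center, cov, diam, ori, aniso, degen = _moment_shape(
        coords, box_correction=lv.spacing)
    return NucleusRecord(frame=lv.frame_index, label=int(label), centroid=center,
                         volume=volume, covariance=cov, axis_diameters=diam,
                         orientation=ori, anisotropy=aniso, degenerate=degen)


def frame_records(lv: LabelVolume) -> list[NucleusRecord]:
    return [nucleus_shape(lv, int(label)) for label in lv.ids()]


def _hull_centroid_volume(hull: ConvexHull):
    """Exact solid-hull volume and centroid via tetrahedral decomposition."""
    pts = hull.points
    ref = pts[hull.vertices].mean(axis=0)
    vol = 0.0
    cent = np.zeros(3)
    for simplex in hull.simplices:
        a, b, c = pts[simplex]
        v = abs(np.linalg.det(np.stack([a - ref, b - ref, c - ref]))) / 6.0
        vol += v
        cent += v * (a + b + c + ref) / 4.0
    return vol, cent / vol


def embryo_hull(points_um: np.ndarray, nucleus_centroids: np.ndarray | None = None,
                frame: int = 0, n_samples: int = 20000, seed: int = 0
                ) -> EmbryoShape:
    """Embryo shape from the convex hull of all nucleus voxel coordinates.

    The embryo ellipsoid (diameters/orientation/anisotropy) is fitted to
    uniform samples of the hull *interior* (fixed-seed rejection sampling) so
    vertex-density bias cannot tilt the axes.  ``shell_thickness`` is the
    standard deviation of |centroid − centre| over ``nucleus_centroids``.
    """
    points_um = np.asarray(points_um, dtype=float)
    if len(points_um) < 4:
        raise DataFormatError("need >= 4 points for a 3D hull")
    try:
        hull = ConvexHull(points_um)
    except Exception as exc:  # qhull degeneracy (coplanar input)
        raise DataFormatError(f"degenerate geometry for convex hull: {exc}") from exc
    vol, center = _hull_centroid_volume(hull)
    rng = np.random.default_rng(seed)
    lo, hi = points_um.min(axis=0), points_um.max(axis=0)
    A, b = hull.equations[:, :3], hull.equations[:, 3]
    samples = []
    need = n_samples
    for _ in range(200):
        cand = rng.uniform(lo, hi, size=(4 * need, 3))
        inside = np.all(cand @ A.T + b <= 1e-9, axis=1)
        samples.append(cand[inside])
        if sum(len(s) for s in samples) >= n_samples:
            break
    interior = np.concatenate(samples)[:n_samples]
    _, _, diam, ori, aniso, _ = _moment_shape(interior)
    if nucleus_centroids is not None and len(nucleus_centroids):
        d = np.linalg.norm(np.asarray(nucleus_centroids) - center, axis=1)
        shell = float(d.std())
    else:
        shell = float("nan")
    return EmbryoShape(frame=frame, center=center, hull_volume=float(vol),
                       axis_diameters=diam, orientation=ori, anisotropy=aniso,
                       shell_thickness=shell)


def embryo_shape_from_labels(lv: LabelVolume, records=None, seed: int = 0) -> EmbryoShape:
    pts = np.argwhere(lv.labels > 0).astype(float) * lv.spacing
    if records is None:
        records = frame_records(lv)
    cents = np.array([r.centroid for r in records]) if records else None
    return embryo_hull(pts, cents, frame=lv.frame_index, seed=seed)


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def _axis_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two sign-free axes, folded to [0, 90] degrees."""
    c = abs(float(unit(u) @ unit(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def angle_alpha(nucleus_orientation, embryo_orientation) -> float:
    """Nucleus long axis vs embryo long axis, degrees in [0, 90]."""
    return _axis_angle_deg(nucleus_orientation, embryo_orientation)


def angle_beta(nucleus_orientation, centroid, embryo_center) -> float:
    """Nucleus long axis vs the radial direction; 0° radial, 90° tangential."""
    radial = np.asarray(centroid, float) - np.asarray(embryo_center, float)
    if np.linalg.norm(radial) < 1e-12:
        raise ValueError("centroid coincides with the embryo centre; "
                         "radial direction undefined")
    return _axis_angle_deg(nucleus_orientation, radial)


def division_angle_theta(daughter1_centroid, daughter2_centroid,
                         parent_centroid, embryo_center) -> float:
    """Division axis (through the daughters) vs the radial direction at the
    parent; 0° radial, 90° tangential."""
    d1 = np.asarray(daughter1_centroid, float)
    d2 = np.asarray(daughter2_centroid, float)
    if np.linalg.norm(d1 - d2) < 1e-12:
        raise ValueError("coincident daughter centroids")
    radial = np.asarray(parent_centroid, float) - np.asarray(embryo_center, float)
    if np.linalg.norm(radial) < 1e-12:
        raise ValueError("parent at the embryo centre; radial direction undefined")
    return _axis_angle_deg(d1 - d2, radial)


def ks_isotropy_test(degrees, null: str = "isotropic-axis") -> tuple[float, float]:
    """One-sample K–S test of sign-free axis angles against isotropy.

    ``null='isotropic-axis'`` (default) tests u = cos(angle) against
    Uniform(0, 1) — the exact null for an isotropic 3D axis.
    ``null='uniform-angle'`` tests angle/90° against Uniform(0, 1) instead.
    Returns (D, p).
    """
    deg = np.asarray(degrees, dtype=float)
    if len(deg) < 5:
        raise ValueError("need at least 5 angle samples")
    if np.any(deg < 0) or np.any(deg > 90) or not np.all(np.isfinite(deg)):
        raise ValueError("angles must lie in [0, 90] degrees")
    if null == "isotropic-axis":
        u = np.cos(np.radians(deg))
    elif null == "uniform-angle":
        u = deg / 90.0
    else:
        raise ValueError(f"unknown null {null!r}")
    res = stats.kstest(u, "uniform")
    return float(res.statistic), float(res.pvalue)


def regress(x, y) -> tuple[float, float, float]:
    """Ordinary least squares y = slope·x + intercept; returns (slope,
    intercept, r²)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length series of at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# movie-level tables
# ---------------------------------------------------------------------------

def nuclei_table(records: list[NucleusRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(dict(frame=r.frame, label=r.label,
                         z=r.centroid[0], y=r.centroid[1], x=r.centroid[2],
                         volume_um3=r.volume,
                         d_max=r.axis_diameters[0], d_mid=r.axis_diameters[1],
                         d_min=r.axis_diameters[2],
                         orient_z=r.orientation[0], orient_y=r.orientation[1],
                         orient_x=r.orientation[2],
                         anisotropy=r.anisotropy, degenerate=int(r.degenerate)))
    return pd.DataFrame(rows)


def embryo_table(shapes: list[EmbryoShape]) -> pd.DataFrame:
    rows = []
    for s in shapes:
        rows.append(dict(frame=s.frame,
                         center_z=s.center[0], center_y=s.center[1],
                         center_x=s.center[2],
                         hull_volume_um3=s.hull_volume,
                         d_max=s.axis_diameters[0], d_mid=s.axis_diameters[1],
                         d_min=s.axis_diameters[2],
                         orient_z=s.orientation[0], orient_y=s.orientation[1],
                         orient_x=s.orientation[2],
                         anisotropy=s.anisotropy,
                         shell_thickness_um=s.shell_thickness))
    return pd.DataFrame(rows)


def angle_table(records_by_frame: dict[int, list[NucleusRecord]],
                embryos: dict[int, EmbryoShape],
                forest: LineageForest | None = None) -> pd.DataFrame:
    """All α and β samples (per nucleus-frame) plus ϑ samples (per division)."""
    rows = []
    for f, recs in sorted(records_by_frame.items()):
        emb = embryos.get(f)
        if emb is None:
            continue
        for r in recs:
            if r.degenerate:
                continue
            rows.append(dict(kind="alpha", degrees=angle_alpha(r.orientation,
                                                               emb.orientation),
                             frame=f, label=r.label, label2=-1))
            if np.linalg.norm(r.centroid - emb.center) > 1e-9:
                rows.append(dict(kind="beta",
                                 degrees=angle_beta(r.orientation, r.centroid,
                                                    emb.center),
                                 frame=f, label=r.label, label2=-1))
    if forest is not None:
        index = {(r.frame, r.label): r
                 for recs in records_by_frame.values() for r in recs}
        for node in forest.division_nodes():
            kids = sorted(forest.graph.successors(node))
            if len(kids) != 2:
                continue
            f_kid = kids[0][0]
            emb = embryos.get(node[0])
            parent = index.get(node)
            k1, k2 = index.get(kids[0]), index.get(kids[1])
            if None in (emb, parent, k1, k2):
                continue
            try:
                theta = division_angle_theta(k1.centroid, k2.centroid,
                                             parent.centroid, emb.center)
            except ValueError:
                continue
            rows.append(dict(kind="theta", degrees=theta, frame=f_kid,
                             label=kids[0][1], label2=kids[1][1]))
    return pd.DataFrame(rows, columns=["kind", "degrees", "frame", "label", "label2"])
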