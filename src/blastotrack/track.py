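"""Frame-to-frame nucleus linking by regularized Gaussian-mixture optimal
transport (GMMOT).

Each segmented frame is summarised as a Gaussian mixture: one component per
instance with weight ∝ volume, mean = centroid and covariance = second
central voxel moment.  Consecutive frames are coupled by discrete optimal
transport between the component weights under the squared Bures–Wasserstein
cost, optionally scaled by a displacement penalty (the regularization term
that discourages long-range mass teleportation) and smoothed entropically
(Sinkhorn).  Mass splits in the coupling are read out as continuation,
division, appearance and disappearance events, which are assembled into a
:class:`~blastotrack.lineage.LineageForest`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .core import ConfigError, DataFormatError, LabelVolume, NumericalError
from .lineage import LineageForest

#: eigenvalue floor applied to component covariances, μm²
COV_EIGENVALUE_FLOOR = 0.5**2


@dataclass
class GaussianComponent:
    """One mixture component summarising a segmented nucleus."""

    weight: float          # mass fraction within its frame, sums to 1
    mean: np.ndarray       # (3,) centroid, μm
    covariance: np.ndarray # (3, 3) SPD second central moment, μm²
    source_label: int      # instance id in the LabelVolume

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)


@dataclass
class TransportPlan:
    """Mass coupling between the mixtures of two consecutive frames."""

    coupling: np.ndarray     # (n, m) >= 0; rows sum to source weights
    cost_matrix: np.ndarray  # (n, m) regularized pairwise costs, μm²
    total_cost: float
    src_labels: np.ndarray   # (n,) instance ids at t
    dst_labels: np.ndarray   # (m,) instance ids at t+1


def fit_gaussian_mixture(lv: LabelVolume) -> list[GaussianComponent]:
    """One Gaussian per instance: weight ∝ voxel volume (normalized over the
    frame), mean = centroid in μm, covariance = second central moment of the
    voxel coordinates (Sheppard-corrected: + spacing²/12 per axis, since a
    voxel's mass fills its box) with eigenvalues floored at (0.5 μm)²."""
    comps: list[GaussianComponent] = []
    ids = lv.ids()
    if len(ids) == 0:
        return comps
    counts = np.bincount(lv.labels.ravel())
    total = float(counts[ids].sum())
    for label in ids:
        idx = np.argwhere(lv.labels == label).astype(float) * lv.spacing
        mean = idx.mean(axis=0)
        q = idx - mean
        cov = (q.T @ q) / len(idx) + np.diag(lv.spacing**2 / 12.0)
        w, v = np.linalg.eigh(cov)
        cov = (v * np.maximum(w, COV_EIGENVALUE_FLOOR)) @ v.T
        comps.append(GaussianComponent(weight=float(counts[label]) / total,
                                       mean=mean, covariance=cov,
                                       source_label=int(label)))
    return comps


def _spd_sqrt(a: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(a)
    if w.min() < -1e-8 * max(abs(w.max()), 1.0):
        raise NumericalError("matrix is not positive semi-definite")
    return (v * np.sqrt(np.maximum(w, 0.0))) @ v.T


def w2_gaussian(g1: GaussianComponent, g2: GaussianComponent) -> float:
    """Squared Bures–Wasserstein distance between two Gaussians:

        |m₁ − m₂|² + tr(Σ₁ + Σ₂ − 2 (Σ₁^{1/2} Σ₂ Σ₁^{1/2})^{1/2})

    Symmetric, zero iff the components coincide.
    """
    dm = g1.mean - g2.mean
    s1h = _spd_sqrt(g1.covariance)
    cross = _spd_sqrt(s1h @ g2.covariance @ s1h)
    bures = np.trace(g1.covariance) + np.trace(g2.covariance) - 2.0 * np.trace(cross)
    return float(dm @ dm + max(bures, 0.0))


def cost_matrix(src: list[GaussianComponent], dst: list[GaussianComponent],
                lambda_disp: float = 0.01) -> np.ndarray:
    """Pairwise regularized costs c_ij = W₂²(i, j)·(1 + λ·|Δm|²).

    ``lambda_disp`` (μm⁻²) inflates the cost of long displacements
    superlinearly, discouraging long-range mass teleportation.
    """
    n, m = len(src), len(dst)
    c = np.empty((n, m))
    for i, gi in enumerate(src):
        for j, gj in enumerate(dst):
            d2 = float(np.sum((gi.mean - gj.mean) ** 2))
            c[i, j] = w2_gaussian(gi, gj) * (1.0 + lambda_disp * d2)
    return c


def _solve_lp(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Exact balanced transport by linear programming (HiGHS)."""
    n, m = c.shape
    # equality constraints: row sums = a, column sums = b (drop one redundant)
    rows = np.zeros((n, n * m))
    for i in range(n):
        rows[i, i * m:(i + 1) * m] = 1.0
    cols = np.zeros((m, n * m))
    for j in range(m):
        cols[j, j::m] = 1.0
    A = np.vstack([rows, cols[:-1]])
    rhs = np.concatenate([a, b[:-1]])
    res = linprog(c.ravel(), A_eq=A, b_eq=rhs, bounds=(0, None), method="highs")
    if not res.success:
        raise NumericalError(f"transport LP failed: {res.message}")
    return res.x.reshape(n, m)


def _sinkhorn(a: np.ndarray, b: np.ndarray, c: np.ndarray, epsilon: float,
              tol: float = 1e-6, max_iter: int = 2000) -> np.ndarray:
    """Log-domain Sinkhorn with ε-scaling to marginal tolerance ``tol``.

    The regularization is annealed from max(cost) down to ``epsilon``
    (halving each stage, warm-starting the dual potentials), which keeps the
    iteration count manageable when ``epsilon`` is far below the cost scale.
    """
    from scipy.special import logsumexp

    loga, logb = np.log(a), np.log(b)
    f = np.zeros(len(a))
    g = np.zeros(len(b))
    ladder = []
    e = max(float(c.max()), epsilon)
    while e > epsilon * 1.5:
        ladder.append(e)
        e /= 2.0
    ladder.append(epsilon)
    err = np.inf
    total = 0
    plan = np.outer(a, b)
    for stage, eps in enumerate(ladder):
        K = -c / eps
        stage_tol = tol if stage == len(ladder) - 1 else 1e-3
        for _ in range(max_iter):
            total += 1
            f = eps * (loga - logsumexp(K + g[None, :] / eps, axis=1))
            g = eps * (logb - logsumexp(K + f[:, None] / eps, axis=0))
            plan = np.exp(K + f[:, None] / eps + g[None, :] / eps)
            err = max(np.abs(plan.sum(axis=1) - a).max(),
                      np.abs(plan.sum(axis=0) - b).max())
            if err < stage_tol:
                break
    if err >= tol:
        # project the nearly-converged plan exactly onto the marginal
        # polytope (scale rows, then columns, then spread the residual as
        # a rank-one correction); a large correction means non-convergence
        plan, moved = _round_to_marginals(plan, a, b)
        if moved > 0.01:
            raise NumericalError(
                f"Sinkhorn did not reach marginal tolerance {tol} after "
                f"{total} iterations (marginal error {err:.3e}, residual mass "
                f"{moved:.3e}, epsilon={epsilon})")
    return plan


def _round_to_marginals(plan: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Exact-feasibility rounding of an approximate transport plan.

    Rows with excess mass are scaled down, then columns, and the remaining
    deficit is filled by the rank-one plan on the residual marginals.
    Returns the feasible plan and the total mass adjusted.
    """
    p = plan.copy()
    rs = p.sum(axis=1)
    scale = np.minimum(1.0, np.divide(a, rs, out=np.ones_like(a), where=rs > 0))
    p *= scale[:, None]
    cs = p.sum(axis=0)
    scale = np.minimum(1.0, np.divide(b, cs, out=np.ones_like(b), where=cs > 0))
    p *= scale[None, :]
    ra = a - p.sum(axis=1)
    rb = b - p.sum(axis=0)
    moved = float(ra.sum())
    if moved > 0:
        p += np.outer(ra, rb) / moved
    return p, moved


def gmmot_plan(src: list[GaussianComponent], dst: list[GaussianComponent],
               epsilon: float | str = 0.0, lambda_disp: float = 0.01
               ) -> TransportPlan:
    """Balanced optimal transport between two frame mixtures.

    ``epsilon`` = 0 solves the exact linear program; ``epsilon`` > 0 runs
    entropic Sinkhorn iterations (marginal tolerance 1e-6).  ``epsilon`` may
    be the string ``"auto"`` for 0.05 × median pairwise cost.
    """
    if not src or not dst:
        raise ConfigError("both mixtures must be non-empty")
    a = np.array([g.weight for g in src], dtype=float)
    b = np.array([g.weight for g in dst], dtype=float)
    a = a / a.sum()
    b = b / b.sum()
    c = cost_matrix(src, dst, lambda_disp)
    if epsilon == "auto":
        # scale to the typical matched-pair cost: the median over all pairs
        # is dominated by far-apart components and would wash the plan out
        med = float(np.median(c.min(axis=1)))
        epsilon = 0.05 * med if med > 0 else 0.0
    epsilon = float(epsilon)
    if epsilon < 0:
        raise ConfigError("epsilon must be >= 0")
    if epsilon == 0.0:
        plan = _solve_lp(a, b, c)
    else:
        plan = _sinkhorn(a, b, c, epsilon)
    return TransportPlan(coupling=plan, cost_matrix=c,
                         total_cost=float(np.sum(plan * c)),
                         src_labels=np.array([g.source_label for g in src]),
                         dst_labels=np.array([g.source_label for g in dst]))


def link_frames(plan: TransportPlan, min_daughter_fraction: float = 0.2):
    """Read typed links out of a transport plan.

    For each source, daughters are the targets receiving at least
    ``min_daughter_fraction`` of its mass: one daughter → continuation, two →
    division, zero → disappearance.  A target claimed by several sources goes
    to the source sending the most mass (merges are suppressed; a runner-up
    losing its only daughter becomes a disappearance).  Unclaimed targets are
    appearances.

    Returns ``(edges, events)`` with edges ``(src_label, dst_label, kind)``
    and events ``{"appearance": [...], "disappearance": [...]}``.
    """
    coupling = plan.coupling
    n, m = coupling.shape
    row_mass = coupling.sum(axis=1, keepdims=True)
    frac = np.divide(coupling, row_mass, out=np.zeros_like(coupling),
                     where=row_mass > 0)
    claims = frac >= min_daughter_fraction
    # resolve competing claims: target j goes to the source sending most mass
    for j in range(m):
        who = np.nonzero(claims[:, j])[0]
        if len(who) > 1:
            winner = who[np.argmax(coupling[who, j])]
            for i in who:
                if i != winner:
                    claims[i, j] = False
    edges = []
    events = {"appearance": [], "disappearance": [], "residual": []}
    for i in range(n):
        targets = np.nonzero(claims[i])[0]
        if len(targets) == 0:
            events["disappearance"].append(int(plan.src_labels[i]))
            continue
        if len(targets) > 2:
            # cap at 2: keep the top-2 mass receivers, flag the rest
            order = targets[np.argsort(-coupling[i, targets], kind="stable")]
            for j in order[2:]:
                events["residual"].append((int(plan.src_labels[i]),
                                           int(plan.dst_labels[j])))
            targets = np.sort(order[:2])
        kind = "continuation" if len(targets) == 1 else "division"
        for j in targets:
            edges.append((int(plan.src_labels[i]), int(plan.dst_labels[j]), kind))
    claimed = claims.any(axis=0)
    for j in range(m):
        if not claimed[j]:
            events["appearance"].append(int(plan.dst_labels[j]))
    return edges, events


def build_lineage(edge_sets: list[list[tuple[int, int, str]]],
                  labels_per_frame: list[np.ndarray] | None = None,
                  n_frames: int | None = None) -> LineageForest:
    """Assemble per-frame-pair edges into a lineage forest.

    ``edge_sets[t]`` links frame t to t+1.  ``labels_per_frame`` (optional)
    lists all instance ids per frame so isolated nuclei become nodes too.
    """
    nf = n_frames if n_frames is not None else len(edge_sets) + 1
    forest = LineageForest(n_frames=nf)
    if labels_per_frame is not None:
        for f, ids in enumerate(labels_per_frame):
            for label in ids:
                forest.add_node(f, int(label))
    for t, edges in enumerate(edge_sets):
        for src, dst, kind in edges:
            forest.add_edge((t, src), (t + 1, dst), kind=kind)
    forest.validate()
    return forest


def track_movie(label_volumes: list[LabelVolume], epsilon: float | str = 0.0,
                lambda_disp: float = 0.01, min_daughter_fraction: float = 0.2
                ) -> LineageForest:
    """Track a whole movie of label volumes into a lineage forest."""
    if not label_volumes:
        raise ConfigError("no label volumes to track")
    mixtures = [fit_gaussian_mixture(lv) for lv in label_volumes]
    edge_sets = []
    for t in range(len(mixtures) - 1):
        if not mixtures[t] or not mixtures[t + 1]:
            edge_sets.append([])
            continue
        plan = gmmot_plan(mixtures[t], mixtures[t + 1], epsilon=epsilon,
                          lambda_disp=lambda_disp)
        edges, _ = link_frames(plan, min_daughter_fraction)
        edge_sets.append(edges)
    ids = [[g.source_label for g in mix] for mix in mixtures]
    return build_lineage(edge_sets, labels_per_frame=ids,
                         n_frames=len(label_volumes))


def nuclei_counts(forest: LineageForest):
    """Per-frame live-nucleus counts (pandas Series indexed by frame)."""
    return forest.counts()
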