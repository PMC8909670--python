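"""Single-lineage trajectory inference in the embedding space.

A minimum spanning tree over GMM cluster centers seeds a polyline, which is
refined by a project-then-smooth principal-curve iteration; pseudotime is the
arc length from the start of the curve to each sample's orthogonal projection
onto it.  Branching topologies are rejected explicitly rather than silently
collapsed onto one lineage.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datasets import InputError, MethylationDataset
from .reduce_cluster import EmbeddingModel, GMMModel, embed

logger = logging.getLogger(__name__)


class UnsupportedTopologyError(RuntimeError):
    """The cluster tree branches beyond a single lineage."""


@dataclasses.dataclass
class ClusterGraph:
    centers: np.ndarray                      # (k, d)
    edges: List[Tuple[int, int]]             # spanning-tree edges, i < j
    start_cluster: int = 0

    def __post_init__(self) -> None:
        k = self.centers.shape[0]
        if len(self.edges) != max(k - 1, 0):
            raise InputError("edges do not form a spanning tree (count)")
        if k > 1 and not _is_connected(k, self.edges):
            raise InputError("edges do not form a spanning tree (connectivity)")


@dataclasses.dataclass
class PrincipalCurve:
    """Polyline through the middle of the point cloud.

    ``cumulative_arc_length[i]`` is the arc length from the first control
    point to control point i; pseudotime lives on [0, total_length].
    """

    control_points: np.ndarray               # (m, d), consecutive points distinct
    cumulative_arc_length: np.ndarray
    total_length: float
    mse_history: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        seg = np.linalg.norm(np.diff(self.control_points, axis=0), axis=1)
        if (seg == 0).any():
            raise InputError("consecutive control points must be distinct")
        if (np.diff(self.cumulative_arc_length) < 0).any():
            raise InputError("cumulative arc length must be non-decreasing")
        if abs(self.cumulative_arc_length[-1] - self.total_length) > 1e-9:
            raise InputError("total_length inconsistent with arc lengths")


@dataclasses.dataclass
class TrajectoryModel:
    """Everything needed to map a methylation profile to a pseudotime value."""

    embedding: EmbeddingModel
    gmm: GMMModel
    graph: ClusterGraph
    curve: PrincipalCurve
    probe_ids: list


def _is_connected(k: int, edges: Sequence[Tuple[int, int]]) -> bool:
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent[find(i)] = find(j)
    return len({find(i) for i in range(k)}) == 1


def minimum_spanning_tree(centers: np.ndarray) -> List[Tuple[int, int]]:
    """Kruskal MST under Euclidean distance; ties broken lexicographically.

    Duplicate centers are allowed (zero-weight edges) and logged.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    k = centers.shape[0]
    if k < 1:
        raise InputError("need at least one center")
    if k == 1:
        return []
    cand = []
    for i, j in itertools.combinations(range(k), 2):
        w = float(np.linalg.norm(centers[i] - centers[j]))
        if w == 0.0:
            logger.warning("duplicate cluster centers %d and %d", i, j)
        cand.append((w, i, j))
    cand.sort()
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: List[Tuple[int, int]] = []
    for w, i, j in cand:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j))
            if len(edges) == k - 1:
                break
    return edges


def choose_start_cluster(gmm: GMMModel, coords: np.ndarray, ages: np.ndarray) -> int:
    """Cluster with the lowest mean training age (ties: smaller index)."""
    labels = gmm.predict(coords)
    ages = np.asarray(ages, dtype=float)
    mean_ages = np.full(gmm.k, np.inf)
    for c in range(gmm.k):
        mask = labels == c
        if mask.any():
            mean_ages[c] = ages[mask].mean()
    return int(np.argmin(mean_ages))


def initial_path(graph: ClusterGraph) -> List[int]:
    """Ordered center sequence for a single lineage.

    The tree must be a simple path with the start cluster at one endpoint;
    any other topology (a node of degree >= 3, or a start in the interior)
    raises :class:`UnsupportedTopologyError`.
    """
    k = graph.centers.shape[0]
    if k == 1:
        return [0]
    degree = np.zeros(k, dtype=int)
    adjacency: List[List[int]] = [[] for _ in range(k)]
    for i, j in graph.edges:
        degree[i] += 1
        degree[j] += 1
        adjacency[i].append(j)
        adjacency[j].append(i)
    if degree.max() > 2:
        raise UnsupportedTopologyError(
            "cluster tree branches (a center has degree > 2)")
    if degree[graph.start_cluster] > 1:
        raise UnsupportedTopologyError(
            "start cluster lies in the interior of the path")
    path = [graph.start_cluster]
    prev = -1
    while True:
        nxt = [n for n in adjacency[path[-1]] if n != prev]
        if not nxt:
            break
        prev = path[-1]
        path.append(nxt[0])
    if len(path) != k:
        raise UnsupportedTopologyError("tree path does not cover all clusters")
    return path


def _project_onto_polyline(points: np.ndarray, ctrl: np.ndarray):
    """Arc-length positions and squared distances of orthogonal projections.

    Nearest segment chosen by minimum Euclidean distance, ties by smaller
    segment index; positions are clamped to [0, total length].
    """
    points = np.atleast_2d(points)
    seg = ctrl[1:] - ctrl[:-1]
    seglen = np.linalg.norm(seg, axis=1)
    seglen2 = np.maximum(seglen ** 2, 1e-300)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    diff = points[:, None, :] - ctrl[None, :-1, :]
    tpar = np.clip((diff * seg[None]).sum(-1) / seglen2, 0.0, 1.0)
    proj = ctrl[None, :-1, :] + tpar[..., None] * seg[None]
    d2 = ((points[:, None, :] - proj) ** 2).sum(-1)
    idx = np.argmin(d2, axis=1)                      # first minimum
    rows = np.arange(points.shape[0])
    t = cum[idx] + tpar[rows, idx] * seglen[idx]
    return t, d2[rows, idx]


def _dedupe(points: np.ndarray) -> np.ndarray:
    keep = [0]
    for i in range(1, len(points)):
        if not np.array_equal(points[i], points[keep[-1]]):
            keep.append(i)
    return points[keep]


def _make_curve(ctrl: np.ndarray, mse_history=None) -> PrincipalCurve:
    ctrl = _dedupe(np.atleast_2d(ctrl))
    if len(ctrl) < 2:
        raise InputError("curve needs at least two distinct control points")
    seglen = np.linalg.norm(np.diff(ctrl, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    return PrincipalCurve(control_points=ctrl, cumulative_arc_length=cum,
                          total_length=float(cum[-1]),
                          mse_history=list(mse_history or []))


def _smooth_against_arclength(coords: np.ndarray, t: np.ndarray,
                              span: float) -> np.ndarray:
    """Local-linear smoother of each coordinate against arc-length position.

    Each sample's coordinates are replaced by the value at its own position
    of a straight line fitted to the ``span`` fraction of neighbours in
    arc-length order (uniform weights).  Degree-1 local averaging avoids the
    endpoint shrinkage of a plain running mean: exactly collinear data is a
    fixed point.  Windows with degenerate positions fall back to the mean.
    """
    order = np.argsort(t, kind="stable")
    n = len(t)
    h = max(1, int(round(0.5 * span * n)))
    ts = t[order]
    xs = coords[order]
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)

    def winsum(values):
        c = np.concatenate([np.zeros((1,) + values.shape[1:]),
                            np.cumsum(values, axis=0)])
        return c[hi] - c[lo]

    nw = (hi - lo).astype(float)
    st = winsum(ts)
    stt = winsum(ts ** 2)
    sx = winsum(xs)
    stx = winsum(ts[:, None] * xs)
    denom = nw * stt - st ** 2
    mean = sx / nw[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (nw[:, None] * stx - st[:, None] * sx) / denom[:, None]
        intercept = (sx - slope * st[:, None]) / nw[:, None]
        fitted = intercept + slope * ts[:, None]
    degenerate = denom <= 1e-12 * np.maximum(stt, 1.0)
    fitted[degenerate] = mean[degenerate]
    return fitted         # ordered by arc-length position


def _resample(points: np.ndarray, n_control: int) -> np.ndarray:
    pts = _dedupe(points)
    if len(pts) < 2:
        return pts
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    grid = np.linspace(0.0, cum[-1], n_control)
    return np.column_stack([np.interp(grid, cum, pts[:, d])
                            for d in range(pts.shape[1])])


def fit_principal_curve(coords: np.ndarray, path_centers: np.ndarray,
                        max_iter: int = 50, tol: float = 1e-6,
                        span: float = 0.3, n_control: int = 100) -> PrincipalCurve:
    """Project-then-smooth principal-curve iteration seeded by the MST path.

    Each round projects every sample onto the current polyline, orders the
    samples by arc-length position, smooths each coordinate with a running
    mean over a ``span`` fraction of samples, and re-discretizes into
    ``n_control`` control points.  Stops when the mean squared projection
    distance changes by less than ``tol`` (relative) or after ``max_iter``
    rounds; the distance trace is recorded on the returned curve.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(np.unique(coords, axis=0)) < 2:
        raise InputError("need at least two distinct coordinates")
    path_centers = np.atleast_2d(np.asarray(path_centers, dtype=float))
    if len(_dedupe(path_centers)) < 2:
        ctrl = _principal_axis_segment(coords)
    else:
        ctrl = _dedupe(path_centers)
    ctrl = _resample(ctrl, n_control)
    if max_iter == 0:
        return _make_curve(ctrl)

    history = []
    prev_mse = None
    for _ in range(max_iter):
        t, d2 = _project_onto_polyline(coords, ctrl)
        mse = float(d2.mean())
        history.append(mse)
        if prev_mse is not None and abs(prev_mse - mse) <= tol * max(prev_mse, 1e-300):
            break
        prev_mse = mse
        smoothed = _smooth_against_arclength(coords, t, span)
        new_ctrl = _resample(smoothed, n_control)
        if len(new_ctrl) < 2:
            break
        ctrl = new_ctrl
    # keep the start of the curve anchored at the young end: the smoother
    # preserves sample order along t, so orientation is retained
    _, d2 = _project_onto_polyline(coords, ctrl)
    history.append(float(d2.mean()))
    return _make_curve(ctrl, history)


def _principal_axis_segment(coords: np.ndarray) -> np.ndarray:
    """Fallback initial polyline for a single-cluster tree: the first
    principal axis of the coordinates, oriented along increasing first axis
    (the embedding's age-oriented component)."""
    center = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - center, full_matrices=False)
    direction = vt[0]
    if direction[0] < 0:
        direction = -direction
    proj = (coords - center) @ direction
    return np.vstack([center + proj.min() * direction,
                      center + proj.max() * direction])


def assign_pseudotime(curve: PrincipalCurve, coords: np.ndarray) -> np.ndarray:
    """Arc length from the curve start to each sample's projection."""
    t, _ = _project_onto_polyline(np.atleast_2d(coords), curve.control_points)
    return np.clip(t, 0.0, curve.total_length)


def fit_trajectory(coords: np.ndarray, gmm: GMMModel, ages: np.ndarray,
                   embedding: EmbeddingModel, probe_ids: Sequence[str],
                   max_iter: int = 50, tol: float = 1e-6,
                   span: float = 0.3, n_control: int = 100) -> TrajectoryModel:
    """Compose MST, start-cluster choice, path, and principal curve."""
    edges = minimum_spanning_tree(gmm.means)
    start = choose_start_cluster(gmm, coords, ages)
    graph = ClusterGraph(centers=gmm.means.copy(), edges=edges, start_cluster=start)
    path = initial_path(graph)
    curve = fit_principal_curve(coords, gmm.means[path], max_iter=max_iter,
                                tol=tol, span=span, n_control=n_control)
    curve = _orient_curve(curve, coords, ages)
    return TrajectoryModel(embedding=embedding, gmm=gmm, graph=graph,
                           curve=curve, probe_ids=list(probe_ids))


def _orient_curve(curve: PrincipalCurve, coords: np.ndarray,
                  ages: np.ndarray) -> PrincipalCurve:
    """Flip the curve if pseudotime decreases with age, so the trajectory
    start is the young end regardless of how the smoother ordered points."""
    t = assign_pseudotime(curve, coords)
    ages = np.asarray(ages, dtype=float)
    if np.ptp(t) > 0 and np.ptp(ages) > 0 and np.corrcoef(t, ages)[0, 1] < 0:
        ctrl = curve.control_points[::-1].copy()
        return _make_curve(ctrl, curve.mse_history)
    return curve


def predict_pseudotime(model: TrajectoryModel, dataset: MethylationDataset) -> np.ndarray:
    """Embed a (normalized, site-matched) dataset and assign pseudotime.

    No component is refitted.  The dataset must carry exactly the model's
    selected probes in order; missing probes are named in the error.
    """
    if list(dataset.probe_ids) != list(model.probe_ids):
        missing = [p for p in model.probe_ids if p not in set(dataset.probe_ids)]
        if missing:
            shown = ", ".join(missing[:10])
            raise InputError(f"dataset lacks model probes: {shown}")
        dataset = dataset.select_probes(model.probe_ids)
    coords = embed(model.embedding, dataset.betas)
    return assign_pseudotime(model.curve, coords)
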