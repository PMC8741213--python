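"""Mutual-information generalized correlations and the dynamic network.

The coupling between two residues i and j is quantified by the mutual
information between their 3-D fluctuation vectors,

    MI(x_i, x_j) = H(x_i) + H(x_j) - H(x_i, x_j)      [nats]

mapped onto a normalized generalized correlation

    GC_ij = (1 - exp(-2 MI / d))^(1/2),   d = 3,

which ranges from 0 (independent) to 1 (fully correlated) and, unlike a
Pearson coefficient, captures nonlinear and non-collinear coupling.  Edges of
the dynamic network connect residue pairs that stay in geometric contact for
at least a fraction of the simulation (default 75% within 5 A) and carry
weights w_ij = -log GC_ij, so highly correlated pairs are short, efficient
links for information transfer.

MI is estimated with the Kraskov k-nearest-neighbour estimator by default
(k = 6); a plug-in histogram estimator and the Gaussian closed form (exact
for the isotropic Gaussian fluctuations of the synthetic generator, and a
fast approximation otherwise) are available as cross-checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .contacts import ContactFrequencyMatrix
from .errors import InputError
from .trajio import ResidueTrajectory

log = logging.getLogger(__name__)

GC_CLAMP_EPS = 1e-6  # GC clipped to [eps, 1-eps] before -log so weights stay finite


@dataclass
class CorrelationMatrix:
    """Pairwise generalized correlations plus the underlying MI estimates."""

    residue_ids: np.ndarray
    gc: np.ndarray  # (N, N), in [0, 1], symmetric, unit diagonal
    mi: np.ndarray  # (N, N), nats
    d: int = 3
    method: str = "ksg"
    k: int | None = 6
    n_samples: int = 0

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.gc, index=self.residue_ids,
                     columns=self.residue_ids).to_csv(path)


@dataclass
class DynamicNetwork:
    """Contact-filtered residue graph with information-transfer weights."""

    graph: nx.Graph
    residue_ids: np.ndarray
    contact_fraction: float
    rt: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self):
        import pandas as pd
        rows = [(u, v, d["weight"], d.get("gc", np.nan), d.get("contact", np.nan))
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["i", "j", "weight", "gc", "contact"])

    def to_edge_list(self, path) -> None:
        self.edge_table().to_csv(path, index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def residue_fluctuations(traj: ResidueTrajectory, selection: str = "ca") -> np.ndarray:
    """Per-frame displacement of each residue from its mean position.

    Returns an array of shape ``(n_frames, n_residues, 3)``; each residue's
    position is the centroid of its selected atoms.  Assumes global motion has
    been removed -- a warning is logged otherwise.
    """
    if not traj.superposed:
        log.warning("trajectory is not flagged as superposed; correlations may "
                    "conflate global tumbling with internal motion")
    sub = traj.select(selection)
    groups = sub.residue_atom_groups()
    centers = np.stack([sub.coords[:, g, :].mean(axis=1) for g in groups], axis=1)
    return centers - centers.mean(axis=0, keepdims=True)


# --------------------------------------------------------------------------
# MI estimators
# --------------------------------------------------------------------------

def _mi_ksg(x: np.ndarray, y: np.ndarray, k: int,
            x_tree: cKDTree | None = None, y_tree: cKDTree | None = None) -> float:
    """Kraskov-Stoegbauer-Grassberger estimator (algorithm 1), max-norm."""
    n = len(x)
    joint = np.hstack([x, y])
    eps = cKDTree(joint).query(joint, k=k + 1, p=np.inf)[0][:, -1]
    # strictly-inside counts (exclude the point itself)
    r = np.nextafter(eps, 0.0)
    x_tree = x_tree if x_tree is not None else cKDTree(x)
    y_tree = y_tree if y_tree is not None else cKDTree(y)
    nx_ = x_tree.query_ball_point(x, r, p=np.inf, return_length=True) - 1
    ny_ = y_tree.query_ball_point(y, r, p=np.inf, return_length=True) - 1
    mi = (digamma(k) + digamma(n)
          - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1)))
    return float(mi)


def _mi_gaussian(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form MI of a jointly Gaussian pair from sample covariances."""
    joint = np.hstack([x, y])
    cov = np.cov(joint, rowvar=False)
    dx = x.shape[1]
    sign, logdet_joint = np.linalg.slogdet(cov)
    if sign <= 0:  # degenerate (e.g. y identical to x): MI diverges
        return float("inf")
    _, logdet_x = np.linalg.slogdet(cov[:dx, :dx])
    _, logdet_y = np.linalg.slogdet(cov[dx:, dx:])
    return float(0.5 * (logdet_x + logdet_y - logdet_joint))


def _mi_histogram(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Plug-in estimate from a joint d_x+d_y-dimensional histogram.

    Coarse cross-check only: binning discards information (underestimates)
    while undersampling of the bins**(dx+dy) joint cells inflates the
    estimate, so accuracy is limited for 3-D variables.
    """
    joint = np.hstack([x, y])
    counts, _ = np.histogramdd(joint, bins=bins)
    p = counts / counts.sum()
    dx = x.shape[1]
    px = p.sum(axis=tuple(range(dx, p.ndim)))
    py = p.sum(axis=tuple(range(dx)))
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    hxy = -np.sum(p[p > 0] * np.log(p[p > 0]))
    return float(hx + hy - hxy)


def estimate_mi(x_series: np.ndarray, y_series: np.ndarray, k: int = 6,
                method: str = "ksg", bins: int = 6, **kwargs) -> float:
    """Mutual information between two (n, d) series, in nats.

    ``method`` is one of ``ksg`` (Kraskov k-NN, default), ``gaussian``
    (closed form from sample covariance) or ``histogram`` (plug-in).
    Negative estimates, an artefact of finite-sample k-NN noise under
    independence, are clamped to 0.
    """
    x = np.atleast_2d(np.asarray(x_series, dtype=float))
    y = np.atleast_2d(np.asarray(y_series, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    if y.shape[0] == 1:
        y = y.T
    if x.shape[0] != y.shape[0]:
        raise InputError(f"series lengths differ: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if method == "ksg":
        if n < k + 2:
            raise InputError(f"KSG with k={k} needs at least {k + 2} samples, got {n}")
        mi = _mi_ksg(x, y, k, kwargs.get("x_tree"), kwargs.get("y_tree"))
    elif method == "gaussian":
        mi = _mi_gaussian(x, y)
    elif method == "histogram":
        mi = _mi_histogram(x, y, bins)
    else:
        raise InputError(f"unknown MI estimator {method!r}")
    if mi < 0:
        log.debug("negative MI estimate %.4g clamped to 0", mi)
        mi = 0.0
    return mi


def gc_transform(mi, d: int = 3) -> np.ndarray | float:
    """Map MI (nats) to the normalized generalized correlation in [0, 1]."""
    if d <= 0:
        raise InputError(f"dimensionality d must be positive, got {d}")
    mi_arr = np.asarray(mi, dtype=float)
    neg = mi_arr < 0
    if np.any(neg):
        log.debug("clamping %d negative MI value(s) to 0 before GC transform",
                  int(np.count_nonzero(neg)))
        mi_arr = np.where(neg, 0.0, mi_arr)
    gc = np.sqrt(1.0 - np.exp(-2.0 * mi_arr / d))
    return float(gc) if np.isscalar(mi) or np.ndim(mi) == 0 else gc


def gc_matrix(traj: ResidueTrajectory, selection: str = "ca", k: int = 6,
              method: str = "ksg", bins: int = 6) -> CorrelationMatrix:
    """All-pairs generalized correlations from residue fluctuations.

    The KSG estimate is symmetric in its arguments by construction; symmetry
    of the matrix is nevertheless enforced by averaging (i,j) and (j,i).
    Diagonal GC is set to 1 by convention.
    """
    disp = residue_fluctuations(traj, selection)
    n_frames, n_res, _ = disp.shape
    if n_res < 2:
        raise InputError("GC matrix needs at least 2 residues")
    mi = np.zeros((n_res, n_res))
    if method == "gaussian":
        # one covariance factorization instead of per-pair estimates
        flat = disp.reshape(n_frames, -1)
        cov = np.cov(flat, rowvar=False)
        for i in range(n_res):
            for j in range(i + 1, n_res):
                idx = np.r_[3 * i:3 * i + 3, 3 * j:3 * j + 3]
                sub = cov[np.ix_(idx, idx)]
                sign, logdet = np.linalg.slogdet(sub)
                _, ldx = np.linalg.slogdet(sub[:3, :3])
                _, ldy = np.linalg.slogdet(sub[3:, 3:])
                mi[i, j] = np.inf if sign <= 0 else max(0.0, 0.5 * (ldx + ldy - logdet))
    else:
        trees = ([cKDTree(disp[:, i, :]) for i in range(n_res)]
                 if method == "ksg" else [None] * n_res)
        for i in range(n_res):
            for j in range(i + 1, n_res):
                mi[i, j] = estimate_mi(disp[:, i, :], disp[:, j, :], k=k,
                                       method=method, bins=bins,
                                       x_tree=trees[i], y_tree=trees[j])
    mi = mi + mi.T
    mi = 0.5 * (mi + mi.T)  # exact symmetry even after future estimator changes
    gc = gc_transform(mi)
    np.fill_diagonal(gc, 1.0)
    np.fill_diagonal(mi, np.inf)
    return CorrelationMatrix(residue_ids=traj.residue_ids.copy(), gc=gc, mi=mi,
                             method=method, k=(k if method == "ksg" else None),
                             n_samples=n_frames)


def weight_from_gc(gc, eps: float = GC_CLAMP_EPS):
    """Edge weight w = -log GC with GC clamped to [eps, 1-eps]."""
    gc_arr = np.clip(np.asarray(gc, dtype=float), eps, 1.0 - eps)
    w = -np.log(gc_arr)
    return float(w) if np.ndim(gc) == 0 else w


def build_network(gcm: CorrelationMatrix, M: ContactFrequencyMatrix,
                  contact_fraction: float = 0.75,
                  clamp_eps: float = GC_CLAMP_EPS) -> DynamicNetwork:
    """Contact-filtered weighted graph: edge (i,j) iff M_ij >= contact_fraction,
    weight -log GC_ij (GC clamped so weights are finite and positive)."""
    if (len(gcm.residue_ids) != len(M.residue_ids)
            or not np.array_equal(gcm.residue_ids, M.residue_ids)):
        raise InputError(
            "GC and contact matrices cover different residue sets: "
            f"{sorted(set(gcm.residue_ids.tolist()) ^ set(M.residue_ids.tolist()))}"
        )
    n_clamped = int(np.count_nonzero(
        (gcm.gc < clamp_eps) | (gcm.gc > 1 - clamp_eps)))
    if n_clamped:
        log.info("clamped %d GC value(s) to [%g, %g] for finite weights",
                 n_clamped, clamp_eps, 1 - clamp_eps)
    G = nx.Graph()
    G.add_nodes_from(int(r) for r in gcm.residue_ids)
    n = len(gcm.residue_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if M.matrix[i, j] >= contact_fraction:
                gc = float(np.clip(gcm.gc[i, j], clamp_eps, 1.0 - clamp_eps))
                G.add_edge(int(gcm.residue_ids[i]), int(gcm.residue_ids[j]),
                           weight=-float(np.log(gc)), gc=gc,
                           contact=float(M.matrix[i, j]))
    return DynamicNetwork(graph=G, residue_ids=gcm.residue_ids.copy(),
                          contact_fraction=contact_fraction, rt=M.rt)
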