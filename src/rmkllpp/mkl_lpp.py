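"""Regularized multiple-kernel learning with locality preserving projections.

The model embeds N samples described by M kernel matrices into P dimensions
by jointly optimizing a sample-coefficient matrix A (N x P) and a simplex-
constrained kernel weight vector beta (length M). Writing
``kappa_i`` for the N x M matrix whose column m is column i of kernel m,
the embedding of sample i is ``A^T kappa_i beta`` and the objective is the
locality preserving criterion

    min_{A, beta}  sum_ij w_ij || A^T kappa_i beta - A^T kappa_j beta ||^2
    subject to     sum_i d_ii || A^T kappa_i beta ||^2 = 1,
                   ||beta||_1 = 1, beta >= 0,

where W is the symmetrized k-nearest-neighbor adjacency of the samples and
D its degree matrix. With U(beta) = sum_m beta_m K_m and L = D - W the
numerator is 2 tr(A^T U L U A) and the constraint is tr(A^T U D U A) = 1,
so the A-step is a generalized eigenproblem and the beta-step a quadratic
ratio over the simplex; the two are alternated (coordinate descent).

Overfitting is controlled by ridge inflation of the constraint matrix,
S_D + ridge * (tr(S_D)/N) * I (the ridge parameter is relative to the mean
diagonal so its meaning is independent of cohort size and kernel scale).
The ridge does double duty: it makes the constraint matrix positive
definite, and it shrinks embedding directions that live in the composite
kernel's near-null space — without it, "anti-locality" directions with
negligible support can enter the bottom eigenpairs at full amplitude and
swamp the cluster structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .kernels import KernelSet, KernelWeights, combine_kernels

__all__ = [
    "NeighborGraph",
    "ProjectionModel",
    "build_neighbor_graph",
    "projected_scatter",
    "optimize_projection",
    "optimize_weights",
    "fit_mkl_lpp",
    "project",
    "MKLLPP",
]

logger = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Symmetrized k-nearest-neighbor graph.

    W is binary and symmetric with zero diagonal (an edge exists when either
    endpoint lists the other among its k nearest); degrees holds the
    diagonal of D.
    """

    W: np.ndarray
    degrees: np.ndarray
    k_neighbors: int

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.degrees) - self.W


@dataclass
class ProjectionModel:
    """Fitted rMKL-LPP state: projection A, kernel weights beta, and the
    objective trajectory of the alternating optimization."""

    A: np.ndarray
    beta: KernelWeights
    n_components: int
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    graph: NeighborGraph
    sample_ids: np.ndarray


def _kernel_distances(k: np.ndarray) -> np.ndarray:
    """Squared kernel-induced distances d2(i,j) = K(i,i)+K(j,j)-2K(i,j)."""
    diag = np.diag(k)
    d2 = diag[:, None] + diag[None, :] - 2.0 * k
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def build_neighbor_graph(
    ks: KernelSet, k_neighbors: int = 9, weights: KernelWeights | None = None
) -> NeighborGraph:
    """k-NN graph under the (by default uniform-weight) composite kernel.

    Edge rule: w_ij = 1 iff i is among the k nearest of j OR j among the k
    nearest of i; ties in distance broken by sample index.
    """
    n = ks.n_samples
    if not 0 < k_neighbors < n:
        raise ValueError(f"k_neighbors must be in (0, {n}) for {n} samples")
    if weights is None:
        weights = KernelWeights.uniform(ks.n_kernels)
    d2 = _kernel_distances(combine_kernels(ks, weights))
    # stable argsort: self (distance 0) sorts first, skip it
    order = np.argsort(d2, axis=1, kind="stable")
    w = np.zeros((n, n), dtype=float)
    rows = np.repeat(np.arange(n), k_neighbors)
    cols = np.empty(n * k_neighbors, dtype=int)
    for i in range(n):
        neigh = order[i][order[i] != i][:k_neighbors]
        cols[i * k_neighbors : (i + 1) * k_neighbors] = neigh
    w[rows, cols] = 1.0
    w = np.maximum(w, w.T)  # OR rule
    np.fill_diagonal(w, 0.0)
    return NeighborGraph(W=w, degrees=w.sum(axis=1), k_neighbors=k_neighbors)


def projected_scatter(
    ks: KernelSet, g: NeighborGraph, w: KernelWeights
) -> tuple[np.ndarray, np.ndarray]:
    """Graph scatter matrices in kernel coordinates for fixed beta.

    With u_i the i-th column of the composite kernel U,
    S_W = sum_ij w_ij (u_i - u_j)(u_i - u_j)^T = 2 U L U^T and
    S_D = sum_i d_ii u_i u_i^T = U D U^T.
    """
    u = combine_kernels(ks, w)
    s_w = 2.0 * u @ g.laplacian @ u.T
    s_d = (u * g.degrees[None, :]) @ u.T
    return (s_w + s_w.T) / 2.0, (s_d + s_d.T) / 2.0


def _relative_ridge(s_d: np.ndarray, ridge: float) -> float:
    """Absolute ridge from the relative parameter: ridge * tr(S_D) / N."""
    n = s_d.shape[0]
    scale = np.trace(s_d) / n
    return ridge * (scale if scale > 0 else 1.0)


def _solve_projection(
    s_w: np.ndarray, s_d: np.ndarray, n_components: int, ridge_abs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bottom eigenpairs of S_W a = lam (S_D + ridge_abs I) a, with x10
    ridge escalation on solver failure and a deterministic sign convention."""
    n = s_w.shape[0]
    if not 1 <= n_components <= n - 1:
        raise ValueError(f"n_components must be in [1, {n - 1}]")
    r = ridge_abs if ridge_abs > 0 else 1e-12
    last_err: Exception | None = None
    for _ in range(8):
        try:
            b = s_d + r * np.eye(n)
            vals, vecs = linalg.eigh(s_w, b, subset_by_index=[0, n_components - 1])
            break
        except linalg.LinAlgError as err:  # indefinite constraint: inflate
            last_err = err
            r *= 10.0
    else:
        raise linalg.LinAlgError(f"generalized eigensolver failed up to ridge {r}") from last_err
    # eigh returns B-orthonormal columns sorted ascending; fix signs
    for j in range(vecs.shape[1]):
        idx = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[idx, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs, vals


def optimize_projection(
    ks: KernelSet,
    g: NeighborGraph,
    w: KernelWeights,
    n_components: int,
    ridge: float = 1e-3,
) -> np.ndarray:
    """A-step: generalized eigenvectors of (S_W, S_D + r I) with the
    n_components smallest eigenvalues, normalized so A^T (S_D + rI) A = I;
    r = ridge * tr(S_D)/N."""
    s_w, s_d = projected_scatter(ks, g, w)
    a, _ = _solve_projection(s_w, s_d, n_components, _relative_ridge(s_d, ridge))
    return a


def _weight_step_matrices(
    ks: KernelSet, g: NeighborGraph, a: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """M x M quadratic forms of the beta-step for fixed projection A.

    S_W^A[m, m'] = 2 tr(B_m^T L B_m') and S_D^A[m, m'] = sum_i d_i B_m[i].B_m'[i]
    with B_m = K_m A; for the A A^T = I initialization pass a = None, which
    uses B_m = K_m.
    """
    if a is None:
        bs = [k for k in ks.kernels]
    else:
        bs = [k @ a for k in ks.kernels]
    m = ks.n_kernels
    lap = g.laplacian
    s_w = np.empty((m, m))
    s_d = np.empty((m, m))
    lbs = [lap @ b for b in bs]
    dbs = [g.degrees[:, None] * b for b in bs]
    for i in range(m):
        for j in range(i, m):
            s_w[i, j] = s_w[j, i] = 2.0 * float(np.sum(lbs[i] * bs[j]))
            s_d[i, j] = s_d[j, i] = float(np.sum(dbs[i] * bs[j]))
    return s_w, s_d


def _ratio(beta: np.ndarray, s_w: np.ndarray, s_d: np.ndarray) -> float:
    den = float(beta @ s_d @ beta)
    if den <= 0:
        return np.inf
    return float(beta @ s_w @ beta) / den


def _minimize_simplex_ratio(
    s_w: np.ndarray, s_d: np.ndarray, beta0: np.ndarray
) -> np.ndarray:
    """Minimize beta' S_W beta / beta' S_D beta over the probability simplex.

    The ratio is scale-invariant, so the simplex parameterization loses no
    generality. The subproblem is nonconvex; we polish several starts
    (previous beta, uniform, vertices, and a dense grid for M <= 3) with
    SLSQP and keep the best, falling back to the incumbent if no candidate
    improves it.
    """
    m = s_w.shape[0]
    if m == 1:
        return np.array([1.0])
    starts = [np.asarray(beta0, dtype=float), np.full(m, 1.0 / m)]
    starts += [np.eye(m)[i] * 0.94 + 0.06 / m for i in range(m)]
    if m == 2:
        t = np.linspace(0.0, 1.0, 1001)
        grid = np.column_stack([t, 1.0 - t])
        vals = np.einsum("gi,ij,gj->g", grid, s_w, grid) / np.maximum(
            np.einsum("gi,ij,gj->g", grid, s_d, grid), 1e-300
        )
        starts.append(grid[int(np.argmin(vals))])
    elif m == 3:
        step = 0.02
        t = np.arange(0.0, 1.0 + step / 2, step)
        pts = [
            np.array([a, b, 1.0 - a - b])
            for a in t
            for b in t
            if a + b <= 1.0 + 1e-12
        ]
        grid = np.clip(np.array(pts), 0.0, 1.0)
        vals = np.einsum("gi,ij,gj->g", grid, s_w, grid) / np.maximum(
            np.einsum("gi,ij,gj->g", grid, s_d, grid), 1e-300
        )
        starts.append(grid[int(np.argmin(vals))])

    def fun(b):
        return _ratio(b, s_w, s_d)

    def jac(b):
        den = float(b @ s_d @ b)
        num = float(b @ s_w @ b)
        return (2.0 * (s_w @ b) * den - 2.0 * num * (s_d @ b)) / den**2

    cons = ({"type": "eq", "fun": lambda b: b.sum() - 1.0, "jac": lambda b: np.ones(m)},)
    bounds = [(0.0, 1.0)] * m
    best, best_val = np.asarray(beta0, float), fun(np.asarray(beta0, float))
    for x0 in starts:
        x0 = np.clip(x0, 0.0, 1.0)
        x0 = x0 / x0.sum()
        res = optimize.minimize(
            fun, x0, jac=jac, bounds=bounds, constraints=cons, method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-14},
        )
        for cand in (res.x, x0):
            cand = np.clip(cand, 0.0, None)
            if cand.sum() <= 0:
                continue
            cand = cand / cand.sum()
            v = fun(cand)
            if v < best_val - 1e-15:
                best, best_val = cand, v
    return best


def optimize_weights(
    ks: KernelSet,
    g: NeighborGraph,
    a: np.ndarray,
    beta0: np.ndarray | None = None,
) -> KernelWeights:
    """beta-step: minimize the locality ratio over the simplex for fixed A.

    Minimizes beta' S_W^A beta subject to beta' S_D^A beta = 1, beta >= 0,
    rescaled to ||beta||_1 = 1 (the objective/constraint pair is scale
    consistent, so the rescaling preserves the argmin direction).
    """
    s_w, s_d = _weight_step_matrices(ks, g, a)
    if np.all(np.abs(s_d) < 1e-300):
        raise ValueError("degenerate beta-step: S_D^A is zero")
    if beta0 is None:
        beta0 = np.full(ks.n_kernels, 1.0 / ks.n_kernels)
    beta = _minimize_simplex_ratio(s_w, s_d, np.asarray(beta0, float))
    return KernelWeights(beta)


def _objective(ks: KernelSet, g: NeighborGraph, a: np.ndarray, w: KernelWeights) -> float:
    """Normalized locality objective 2 tr(Y' L Y) / tr(Y' D Y) with Y = U A."""
    y = combine_kernels(ks, w) @ a
    num = 2.0 * float(np.sum((g.laplacian @ y) * y))
    den = float(np.sum((g.degrees[:, None] * y) * y))
    if den <= 0:
        raise FloatingPointError("non-positive embedding norm in objective")
    return num / den


def fit_mkl_lpp(
    ks: KernelSet,
    g: NeighborGraph | None = None,
    n_components: int = 5,
    k_neighbors: int = 9,
    max_iter: int = 30,
    tol: float = 1e-6,
    init: str = "A_first",
    ridge: float = 1e-3,
    rebuild_graph: bool = False,
) -> ProjectionModel:
    """Alternating optimization of A and beta (functional façade over
    :class:`MKLLPP`; see the class for the algorithm)."""
    est = MKLLPP(
        n_components=n_components,
        k_neighbors=k_neighbors,
        max_iter=max_iter,
        tol=tol,
        init=init,
        ridge=ridge,
        rebuild_graph=rebuild_graph,
    )
    est.fit(ks, graph=g)
    return est.model_


def project(model: ProjectionModel, ks: KernelSet) -> np.ndarray:
    """Embed samples: row i of the output is (A^T kappa_i beta)^T, i.e.
    the i-th column of the composite kernel projected through A."""
    if ks.n_samples != model.A.shape[0]:
        raise ValueError("kernel set does not match the trained sample count")
    if ks.n_kernels != len(model.beta):
        raise ValueError("kernel count does not match the trained weights")
    return combine_kernels(ks, model.beta) @ model.A


class MKLLPP(TransformerMixin, BaseEstimator):
    """Multiple-kernel locality preserving projections (scikit-learn style).

    Parameters
    ----------
    n_components : int, default=5
        Embedding dimension P.
    k_neighbors : int, default=9
        Neighbors for the locality graph.
    max_iter : int, default=30
        Maximum outer alternations of the A-step and beta-step.
    tol : float, default=1e-6
        Relative change of the normalized objective below which the
        alternation stops.
    init : {"A_first", "beta_first"}, default="A_first"
        "A_first" starts from uniform kernel weights and solves for A;
        "beta_first" first optimizes beta under A A^T = I.
    ridge : float, default=1e-3
        Ridge strength relative to the mean diagonal of S_D: the
        constraint matrix is S_D + ridge * (tr(S_D)/N) * I (escalated x10
        on eigensolver failure). Larger values shrink weakly supported
        embedding directions harder.
    rebuild_graph : bool, default=False
        Rebuild the neighbor graph from the current composite kernel after
        each beta-step instead of holding the uniform-weight graph fixed.

    Attributes
    ----------
    projection_ : ndarray of shape (n_samples, n_components)
        Sample-coefficient matrix A.
    kernel_weights_ : ndarray of shape (n_kernels,)
        Simplex weights beta.
    embedding_ : ndarray of shape (n_samples, n_components)
        Training-set embedding U(beta) A.
    objective_trace_ : ndarray
        Normalized objective after each full alternation (non-increasing).
    n_iter_ : int
    converged_ : bool

    Examples
    --------
    >>> import numpy as np
    >>> from rmkllpp.mkl_lpp import MKLLPP
    >>> rng = np.random.default_rng(0)
    >>> x = rng.normal(size=(30, 4))
    >>> k = np.exp(-0.1 * ((x[:, None] - x[None]) ** 2).sum(-1))
    >>> emb = MKLLPP(n_components=2, k_neighbors=5).fit_transform([k])
    >>> emb.shape
    (30, 2)
    """

    def __init__(
        self,
        n_components: int = 5,
        k_neighbors: int = 9,
        max_iter: int = 30,
        tol: float = 1e-6,
        init: str = "A_first",
        ridge: float = 1e-3,
        rebuild_graph: bool = False,
    ):
        self.n_components = n_components
        self.k_neighbors = k_neighbors
        self.max_iter = max_iter
        self.tol = tol
        self.init = init
        self.ridge = ridge
        self.rebuild_graph = rebuild_graph

    @staticmethod
    def _as_kernel_set(X) -> KernelSet:
        if isinstance(X, KernelSet):
            return X
        ks = [np.asarray(k, dtype=float) for k in X]
        n = ks[0].shape[0]
        return KernelSet(ks, sample_ids=np.array([f"S{i:04d}" for i in range(n)], dtype=object))

    def fit(self, X, y=None, graph: NeighborGraph | None = None):
        """Fit on a stack of precomputed kernels.

        Parameters
        ----------
        X : KernelSet, sequence of (n, n) arrays, or (m, n, n) array
        graph : NeighborGraph, optional
            Precomputed locality graph; built from the uniform-weight
            composite kernel when omitted.
        """
        if self.init not in ("A_first", "beta_first"):
            raise ValueError("init must be 'A_first' or 'beta_first'")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        ks = self._as_kernel_set(X)
        m = ks.n_kernels
        g = graph if graph is not None else build_neighbor_graph(ks, self.k_neighbors)

        if self.init == "beta_first":
            # A A^T = I: run a weight step in the identity gram
            s_w0, s_d0 = _weight_step_matrices(ks, g, None)
            beta = KernelWeights(
                _minimize_simplex_ratio(s_w0, s_d0, np.full(m, 1.0 / m))
            )
        else:
            beta = KernelWeights.uniform(m)

        def eig_step(w: KernelWeights):
            """A-step at fixed weights; returns A and the normalized
            objective tr(A'S_W A)/tr(A'(S_D+rI)A) = mean bottom eigenvalue."""
            s_w, s_d = projected_scatter(ks, g, w)
            a, vals = _solve_projection(
                s_w, s_d, self.n_components, _relative_ridge(s_d, self.ridge)
            )
            return a, float(vals.mean())

        # each alternation: A-step at the incumbent beta, then a beta-step;
        # the new beta is accepted only if the next A-step's objective does
        # not increase (backtracking toward the incumbent when the full step
        # overshoots), so the recorded trace is non-increasing by
        # construction; when no damped step decreases, the alternation has
        # reached a stationary point and stops
        a, obj = eig_step(beta)
        trace: list[float] = [obj]
        converged = False
        n_iter = 1
        for it in range(1, self.max_iter):
            if not np.isfinite(obj):
                raise FloatingPointError(f"non-finite objective at iteration {n_iter}")
            if m > 1:
                beta_prop = optimize_weights(ks, g, a, beta0=beta.beta).beta
            else:
                beta_prop = beta.beta
            accepted = False
            for step in (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125):
                mix = (1.0 - step) * beta.beta + step * beta_prop
                beta_new = KernelWeights(mix / mix.sum())
                a_new, obj_new = eig_step(beta_new)
                if obj_new <= obj * (1.0 + 1e-12) + 1e-300:
                    accepted = True
                    break
            if not accepted:
                # the objective is multimodal in beta and mixture weights can
                # sit at a ridge between single-kernel basins; probe the
                # simplex vertices and accept the best strict decrease
                best_v, best_obj = None, obj
                for v in range(m):
                    beta_v = KernelWeights(np.eye(m)[v])
                    a_v, obj_v = eig_step(beta_v)
                    if obj_v < best_obj * (1.0 - 1e-9):
                        best_v, best_obj, a_best = beta_v, obj_v, a_v
                if best_v is None:
                    converged = True  # stationary: no non-increasing move found
                    break
                beta_new, a_new, obj_new = best_v, a_best, best_obj
                accepted = True
            if self.rebuild_graph:
                # objectives under different graphs are not comparable, so
                # monotonicity of the trace is only guaranteed with the
                # default fixed graph
                g = build_neighbor_graph(ks, self.k_neighbors, weights=beta_new)
                a_new, obj_new = eig_step(beta_new)
            n_iter = it + 1
            a, beta, prev = a_new, beta_new, obj
            trace.append(obj_new)
            obj = obj_new
            if abs(prev - obj) / max(abs(prev), np.finfo(float).tiny) < self.tol:
                converged = True
                break

        self.projection_ = a
        self.kernel_weights_ = beta.beta
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.graph_ = g
        self.embedding_ = combine_kernels(ks, beta) @ a
        self.n_kernels_ = m
        self.sample_ids_ = ks.sample_ids
        self.model_ = ProjectionModel(
            A=a,
            beta=beta,
            n_components=self.n_components,
            objective_trace=self.objective_trace_,
            n_iter=n_iter,
            converged=converged,
            graph=g,
            sample_ids=ks.sample_ids,
        )
        return self

    def transform(self, X) -> np.ndarray:
        """Embedding of the training samples described by kernel stack X
        (sample ordering must match fit)."""
        if not hasattr(self, "projection_"):
            raise RuntimeError("MKLLPP instance is not fitted")
        ks = self._as_kernel_set(X)
        return project(self.model_, ks)

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        self.fit(X, y, **kwargs)
        return self.embedding_
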