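"""Gaussian Markov random field precision structures.

The latent components of the risk model are all zero-mean Gaussians
specified through sparse precision matrices:

* intrinsic CAR (Besag) on the region graph, ``Q = tau * (D - A)``,
  improper with a one-dimensional null space (the constant vector) on a
  connected graph, handled through a sum-to-zero constraint;
* stationary AR(1) in time, tridiagonal and full rank;
* chain priors over ordered covariate categories (AR or independent);
* a 2-D ICAR on the category lattice for covariate interactions;
* separable space-time fields via Kronecker products.

:func:`sample_gmrf` draws exact constrained samples through the spectral
decomposition (intrinsic directions carry no variance), and
:func:`gmrf_logdensity` evaluates the density with the generalized
determinant over the non-null eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
import json

import numpy as np
import scipy.sparse as sp

from .regions import RegionGraph

__all__ = [
    "Precision",
    "icar_precision",
    "ar1_precision",
    "chain_precision",
    "iid_precision",
    "grid2d_icar_precision",
    "spacetime_precision",
    "sample_gmrf",
    "gmrf_logdensity",
]

# eigenvalues below _NULL_TOL * max(eig) are treated as the null space
_NULL_TOL = 1e-9


@dataclass
class Precision:
    """A (possibly intrinsic) GMRF precision.

    Attributes
    ----------
    Q
        Symmetric PSD sparse matrix, already scaled by ``tau``.
    tau
        The scale multiplier that was applied (kept for bookkeeping).
    constraints
        ``(k, n)`` array of linear constraint vectors spanning the null
        space of intrinsic structures (``C x = 0``), or None.
    rank_deficiency
        ``n - rank(Q)``.
    kron
        For separable structures, the ``(spatial, temporal)`` factor pair;
        lets sampling and determinants work on the small factors.
    """

    Q: sp.csr_matrix
    tau: float
    constraints: np.ndarray | None = None
    rank_deficiency: int = 0
    kron: tuple["Precision", "Precision"] | None = None
    _eig: tuple[np.ndarray, np.ndarray] | None = dc_field(
        default=None, repr=False, compare=False
    )

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def dense(self) -> np.ndarray:
        return self.Q.toarray()

    # -- spectral machinery --------------------------------------------
    def _eigendecomposition(self):
        """Cached full eigendecomposition (small matrices only)."""
        if self._eig is None:
            w, v = np.linalg.eigh(self.dense())
            self._eig = (w, v)
        return self._eig

    def generalized_logdet(self) -> float:
        """Sum of log non-null eigenvalues (log pseudo-determinant)."""
        if self.kron is not None:
            ws, _ = self.kron[0]._eigendecomposition()
            wt, _ = self.kron[1]._eigendecomposition()
            w = np.multiply.outer(ws, wt).ravel()
        else:
            w, _ = self._eigendecomposition()
        cut = _NULL_TOL * max(w.max(), 1.0)
        return float(np.sum(np.log(w[w > cut])))

    def rank(self) -> int:
        return self.n - self.rank_deficiency

    # -- serialization --------------------------------------------------
    def to_files(self, matrix_path, header_path) -> None:
        """Coordinate-format text matrix plus a JSON header."""
        coo = self.Q.tocoo()
        with open(matrix_path, "w") as fh:
            fh.write("row,col,value\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{int(r)},{int(c)},{float(v)!r}\n")
        header = {
            "n": self.n,
            "tau": self.tau,
            "rank_deficiency": self.rank_deficiency,
            "constraints": None
            if self.constraints is None
            else self.constraints.tolist(),
        }
        with open(header_path, "w") as fh:
            json.dump(header, fh)

    @classmethod
    def from_files(cls, matrix_path, header_path) -> "Precision":
        import pandas as pd

        with open(header_path) as fh:
            header = json.load(fh)
        df = pd.read_csv(matrix_path)
        q = sp.coo_matrix(
            (df["value"].to_numpy(float),
             (df["row"].to_numpy(int), df["col"].to_numpy(int))),
            shape=(header["n"], header["n"]),
        ).tocsr()
        cons = header["constraints"]
        return cls(
            Q=q,
            tau=header["tau"],
            constraints=None if cons is None else np.asarray(cons, float),
            rank_deficiency=header["rank_deficiency"],
        )


def _sum_to_zero(n: int) -> np.ndarray:
    return np.ones((1, n))


def icar_precision(graph: RegionGraph, tau: float) -> Precision:
    """Intrinsic CAR (Besag) precision ``tau * (D - A)`` on a region graph.

    Improper: rank deficiency 1 on a connected graph, with the constant
    vector as null space, hence a sum-to-zero constraint.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    a = graph.adjacency_matrix()
    d = sp.diags(np.asarray(a.sum(axis=1)).ravel())
    q = (tau * (d - a)).tocsr()
    return Precision(
        Q=q,
        tau=tau,
        constraints=_sum_to_zero(graph.n_regions),
        rank_deficiency=1,
    )


def ar1_precision(n: int, rho: float, tau: float) -> Precision:
    """Stationary AR(1) precision (tridiagonal, full rank).

    ``tau`` is the innovation precision: the implied stationary marginal
    variance is ``1 / (tau * (1 - rho**2))``.
    """
    if n < 2:
        raise ValueError("AR(1) needs n >= 2")
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    if tau <= 0:
        raise ValueError("tau must be positive")
    diag = np.full(n, 1.0 + rho * rho)
    diag[0] = diag[-1] = 1.0
    off = np.full(n - 1, -rho)
    q = tau * sp.diags([off, diag, off], offsets=[-1, 0, 1])
    return Precision(Q=q.tocsr(), tau=tau, constraints=None, rank_deficiency=0)


def iid_precision(n: int, tau: float) -> Precision:
    """Independent (``tau * I``) precision."""
    if n < 1 or tau <= 0:
        raise ValueError("need n >= 1 and tau > 0")
    return Precision(Q=(tau * sp.identity(n)).tocsr(), tau=tau)


def chain_precision(
    n_levels: int, kind: str, tau: float, rho: float = 0.0
) -> Precision:
    """Prior over ordered covariate categories linked consecutively.

    ``kind='ar'`` gives the AR(1) chain; ``kind='independent'`` gives
    ``tau * I``.  Used for the temperature (4 levels) and precipitation
    (3 levels) effect vectors.
    """
    if n_levels < 2:
        raise ValueError("a chain needs at least 2 levels")
    if kind == "ar":
        return ar1_precision(n_levels, rho, tau)
    if kind == "independent":
        return iid_precision(n_levels, tau)
    raise ValueError(f"unknown chain kind {kind!r}")


def grid2d_icar_precision(n1: int, n2: int, tau: float) -> Precision:
    """ICAR on the 4-neighbour ``n1 x n2`` lattice (interaction prior)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("grid needs n1, n2 >= 2")
    if tau <= 0:
        raise ValueError("tau must be positive")
    g = sp.csr_matrix(
        nx_grid_adjacency(n1, n2)
    )
    d = sp.diags(np.asarray(g.sum(axis=1)).ravel())
    q = (tau * (d - g)).tocsr()
    return Precision(
        Q=q, tau=tau, constraints=_sum_to_zero(n1 * n2), rank_deficiency=1
    )


def nx_grid_adjacency(n1: int, n2: int) -> sp.coo_matrix:
    """Adjacency of the n1 x n2 lattice with row-major node order."""
    rows, cols = [], []

    def node(i, j):
        return i * n2 + j

    for i in range(n1):
        for j in range(n2):
            if j + 1 < n2:
                rows += [node(i, j), node(i, j + 1)]
                cols += [node(i, j + 1), node(i, j)]
            if i + 1 < n1:
                rows += [node(i, j), node(i + 1, j)]
                cols += [node(i + 1, j), node(i, j)]
    data = np.ones(len(rows))
    return sp.coo_matrix((data, (rows, cols)), shape=(n1 * n2, n1 * n2))


def spacetime_precision(
    spatial: Precision, temporal: Precision, mode: str = "separable_kronecker"
) -> Precision:
    """Separable space-time precision over ``n * T`` cells.

    Cell order is region-major: cell ``(i, t) -> i * T + t``, so the
    Kronecker form is ``Q_space (x) Q_time``.  When the spatial part is
    intrinsic, one sum-to-zero constraint per week keeps each temporal
    slice identifiable against the intercept.
    """
    n, T = spatial.n, temporal.n
    if mode == "iid":
        tau = spatial.tau * temporal.tau
        q = (tau * sp.identity(n * T)).tocsr()
        return Precision(Q=q, tau=tau)
    if mode == "space_only_iid_time":
        temporal = iid_precision(T, temporal.tau)
    elif mode != "separable_kronecker":
        raise ValueError(f"unknown mode {mode!r}")
    q = sp.kron(spatial.Q, temporal.Q, format="csr")
    rank_def = spatial.rank_deficiency * temporal.rank() + (
        temporal.rank_deficiency * spatial.n
    )
    constraints = None
    if spatial.rank_deficiency == 1 and temporal.rank_deficiency == 0:
        # null(Q) = constants-over-space per week  <=>  per-week sum-to-zero
        c = np.zeros((T, n * T))
        for t in range(T):
            c[t, t::T] = 1.0
        constraints = c
    elif spatial.rank_deficiency or temporal.rank_deficiency:
        raise NotImplementedError(
            "constraint propagation implemented for intrinsic-space x "
            "full-rank-time only"
        )
    return Precision(
        Q=q,
        tau=spatial.tau * temporal.tau,
        constraints=constraints,
        rank_deficiency=rank_def,
        kron=(spatial, temporal),
    )


def sample_gmrf(
    p: Precision, seed: int | np.random.Generator, size: int = 1
) -> np.ndarray:
    """Exact samples from ``N(0, Q^-)`` restricted to the constraint space.

    Intrinsic directions (null eigenvalues) receive zero variance, which
    for ICAR-type structures realizes the sum-to-zero constraints exactly.
    Separable (Kronecker) precisions are sampled through their factor
    eigendecompositions, so the cost is governed by the factor sizes.

    Returns an array of shape ``(size, n)`` (``(n,)`` if ``size == 1``).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if p.kron is not None:
        ws, vs = p.kron[0]._eigendecomposition()
        wt, vt = p.kron[1]._eigendecomposition()
        w = np.multiply.outer(ws, wt)  # (ns, nt)
        cut = _NULL_TOL * max(w.max(), 1.0)
        scale = np.where(w > cut, 1.0 / np.sqrt(np.maximum(w, cut)), 0.0)
        z = rng.standard_normal((size, *w.shape))
        # x = (Vs kron Vt) diag(scale) z, done factor-wise
        zs = z * scale[None, :, :]
        x = np.einsum("ij,bjk,lk->bil", vs, zs, vt)
        out = x.reshape(size, p.n)
    else:
        w, v = p._eigendecomposition()
        cut = _NULL_TOL * max(w.max(), 1.0)
        keep = w > cut
        z = rng.standard_normal((size, int(keep.sum())))
        out = (v[:, keep] / np.sqrt(w[keep])) @ z.T
        out = out.T
    return out[0] if size == 1 else out


def constrained_pseudo_covariance(p: Precision) -> np.ndarray:
    """Moore-Penrose pseudo-inverse of Q (the sampling covariance)."""
    w, v = p._eigendecomposition()
    cut = _NULL_TOL * max(w.max(), 1.0)
    inv = np.where(w > cut, 1.0 / np.maximum(w, cut), 0.0)
    return (v * inv) @ v.T


def gmrf_logdensity(x: np.ndarray, p: Precision, tol: float = 1e-6) -> float:
    """Log density of a (possibly intrinsic) GMRF at ``x``.

    Uses the generalized determinant over non-null eigenvalues:
    ``0.5 * logdet+ - 0.5 * x' Q x - (rank/2) * log(2*pi)``.
    ``x`` must satisfy the constraints to within ``tol`` (relative to its
    own scale); intrinsic densities are otherwise undefined.
    """
    x = np.asarray(x, float)
    if x.shape != (p.n,):
        raise ValueError(f"x must have shape ({p.n},)")
    if p.constraints is not None:
        viol = np.abs(p.constraints @ x)
        scale = max(1.0, float(np.abs(x).max()))
        if np.any(viol > tol * scale * p.constraints.shape[1]):
            raise ValueError(
                f"x violates constraints (max violation {viol.max():.3g})"
            )
    quad = float(x @ (p.Q @ x))
    rank = p.rank()
    return 0.5 * p.generalized_logdet() - 0.5 * quad - 0.5 * rank * np.log(
        2.0 * np.pi
    )
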