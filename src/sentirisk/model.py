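"""Poisson relative-risk model and its Gaussian (Laplace) fitter.

The observation model for negative-document counts is

    NTw(i,t) ~ Poisson( theta_tot * TTW(i,t) * relrisk(i,t) ),
    log relrisk(i,t) = b0 + field(i,t) + f_temp[cat_T(i,t)]
                       + f_precip[cat_P(i,t)] [+ f_int[cat_T x cat_P]],

where ``theta_tot`` is the dataset-wide negative proportion entering as
a fixed offset together with the exposure ``TTW``, ``field`` is a
separable space-time GMRF (ICAR in space x AR(1) in time by default),
and the covariate effects carry chain priors over their ordered
categories.  A global intercept ``b0`` plus sum-to-zero constraints on
the field (per week) and on each effect block make the decomposition
identifiable; effects are therefore reported relative to their own mean.

Fitting is deterministic: an inner Newton ascent of the joint log
posterior over the latents (with equality constraints handled exactly
through a kriging correction) yields a Gaussian approximation centred at
the mode with covariance from the negative Hessian restricted to the
constraint subspace; optionally, an outer empirical-Bayes pass picks
hyperparameters by maximizing the Laplace-approximate marginal
likelihood over a configured grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
import datetime as dt
import logging
import math

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from . import gmrf
from .covariates import (
    CategoryScheme,
    EventWindows,
    PRECIPITATION_SCHEME,
    TEMPERATURE_SCHEME,
    categorize,
)
from .panel import ClimatePanel, SentimentPanel
from .regions import RegionGraph

__all__ = [
    "FitConfig",
    "Hyperparameters",
    "ModelSpec",
    "FitResult",
    "EffectSummary",
    "RRDifferenceMap",
    "compute_theta_tot",
    "build_model",
    "log_posterior",
    "fit",
    "effect_summary",
    "rr_difference",
    "mcmc_crosscheck",
]

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


# --------------------------------------------------------------------- #
# configuration                                                         #
# --------------------------------------------------------------------- #

@dataclass(frozen=True)
class Hyperparameters:
    """Precision/correlation hyperparameters of the latent blocks.

    The default field precision is deliberately weakly informative
    (prior marginal field sd around 10%): an analyst does not know the
    smoothness of the residual field in advance, and a vague field
    prior lets localized shocks (like a flood) be absorbed with little
    shrinkage while leaving the categorized covariate effects --
    identified mainly through spatially common variation the
    constrained field cannot represent -- essentially untouched.
    """

    tau_field: float = 200.0
    rho: float = 0.7
    tau_temp: float = 1.0
    tau_precip: float = 1.0
    tau_interaction: float = 1.0


@dataclass(frozen=True)
class FitConfig:
    """Model structure and fitter controls.

    ``field_structure`` is one of ``icar_ar1`` (default), ``icar_iid``,
    ``iid_ar1``, ``iid`` — the four combinations of intrinsic CAR or
    independent in space with AR(1) or independent in time.  Chain
    priors for the covariate effects default to independent
    (``effect_prior='independent'``); ``'ar'`` links consecutive
    categories.  Empirical Bayes, when enabled, scans
    ``tau_field * f for f in eb_tau_factors`` crossed with ``eb_rhos``
    (None keeps the configured rho).
    """

    field_structure: str = "icar_ar1"
    effect_prior: str = "independent"
    effect_rho: float = 0.8
    interaction: bool = False
    hypers: Hyperparameters = dc_field(default_factory=Hyperparameters)
    intercept_precision: float = 1e-6
    empirical_bayes: bool = False
    eb_tau_factors: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    eb_rhos: tuple[float, ...] | None = None
    hyperprior_a: float = 1.0
    hyperprior_b: float = 5e-5
    max_iter: int = 50
    tol: float = 1e-9
    theta_tot: float | None = None  # None -> computed from the panel


# --------------------------------------------------------------------- #
# model assembly                                                        #
# --------------------------------------------------------------------- #

def compute_theta_tot(panel: SentimentPanel) -> float:
    """Dataset-wide negative proportion: sum(NTw) / sum(TTW)."""
    total = int(panel.ttw.sum())
    if total == 0:
        raise ValueError("panel has all-zero exposure")
    return float(panel.ntw.sum()) / total


def _align_regions(p, graph: RegionGraph):
    """Reorder a panel's rows into the graph's region-index order."""
    if tuple(p.region_ids) == tuple(graph.region_ids):
        return p
    if set(p.region_ids) != set(graph.region_ids):
        raise ValueError(
            "panel regions do not match the graph regions"
        )
    order = [p.region_ids.index(r) for r in graph.region_ids]
    kwargs = {"region_ids": tuple(graph.region_ids),
              "week_starts": p.week_starts}
    if isinstance(p, SentimentPanel):
        kwargs.update(ntw=p.ntw[order], ttw=p.ttw[order])
        return SentimentPanel(**kwargs)
    kwargs.update(
        temperature=p.temperature[order], precipitation=p.precipitation[order]
    )
    return ClimatePanel(**kwargs)


@dataclass
class ModelSpec:
    """Assembled latent structure ready for fitting.

    Latent vector layout: ``[intercept | field (region-major i*T+t) |
    f_temp | f_precip | f_interaction?]``; ``slices`` maps block names
    to index ranges.  ``offset = log(theta_tot * TTW)`` on cells with
    positive exposure; zero-exposure cells are dropped from the
    likelihood but keep their field coordinates so the GMRF smooths
    over them.
    """

    panel: SentimentPanel
    climate: ClimatePanel
    graph: RegionGraph
    temp_scheme: CategoryScheme
    precip_scheme: CategoryScheme
    config: FitConfig
    theta_tot: float
    tcat: np.ndarray
    pcat: np.ndarray
    slices: dict[str, slice]
    n_latent: int
    design: sp.csr_matrix  # likelihood cells x latents
    y: np.ndarray  # NTw on likelihood cells
    offset: np.ndarray  # log(theta_tot * TTW) on likelihood cells
    cell_index: np.ndarray  # (n_cells, 2) region, week of each likelihood cell

    @property
    def n_regions(self) -> int:
        return self.graph.n_regions

    @property
    def n_weeks(self) -> int:
        return self.panel.n_weeks

    # -- priors --------------------------------------------------------
    def block_precisions(
        self, hypers: Hyperparameters | None = None
    ) -> dict[str, gmrf.Precision]:
        """Per-block prior precisions under the given hyperparameters."""
        h = hypers or self.config.hypers
        cfg = self.config
        n, T = self.n_regions, self.n_weeks
        structure = cfg.field_structure
        if structure == "icar_ar1":
            fld = gmrf.spacetime_precision(
                gmrf.icar_precision(self.graph, h.tau_field),
                gmrf.ar1_precision(T, h.rho, 1.0),
            )
        elif structure == "icar_iid":
            fld = gmrf.spacetime_precision(
                gmrf.icar_precision(self.graph, h.tau_field),
                gmrf.iid_precision(T, 1.0),
                mode="space_only_iid_time",
            )
        elif structure == "iid_ar1":
            fld = gmrf.spacetime_precision(
                gmrf.iid_precision(n, h.tau_field),
                gmrf.ar1_precision(T, h.rho, 1.0),
            )
        elif structure == "iid":
            fld = gmrf.iid_precision(n * T, h.tau_field)
        else:
            raise ValueError(f"unknown field structure {structure!r}")
        blocks = {
            "field": fld,
            "temperature": gmrf.chain_precision(
                self.temp_scheme.n_categories, cfg.effect_prior,
                h.tau_temp, cfg.effect_rho,
            ),
            "precipitation": gmrf.chain_precision(
                self.precip_scheme.n_categories, cfg.effect_prior,
                h.tau_precip, cfg.effect_rho,
            ),
        }
        if cfg.interaction:
            blocks["interaction"] = gmrf.grid2d_icar_precision(
                self.temp_scheme.n_categories,
                self.precip_scheme.n_categories,
                h.tau_interaction,
            )
        return blocks

    def prior_matrices(
        self, hypers: Hyperparameters | None = None
    ) -> tuple[sp.csr_matrix, np.ndarray]:
        """Joint prior precision Q (n_latent x n_latent) and constraints C.

        Constraint rows: one per week on the field when the spatial part
        is intrinsic, plus one sum-to-zero row per covariate-effect
        block (identifiability against the intercept).
        """
        blocks = self.block_precisions(hypers)
        parts = [sp.csr_matrix([[self.config.intercept_precision]])]
        c_rows: list[np.ndarray] = []
        for name in self._block_names():
            p = blocks[name]
            parts.append(p.Q)
            sl = self.slices[name]
            if p.constraints is not None:
                for row in p.constraints:
                    full = np.zeros(self.n_latent)
                    full[sl] = row
                    c_rows.append(full)
            elif name in ("temperature", "precipitation"):
                full = np.zeros(self.n_latent)
                full[sl] = 1.0
                c_rows.append(full)
        q = sp.block_diag(parts, format="csr")
        c = np.vstack(c_rows) if c_rows else np.zeros((0, self.n_latent))
        return q, c

    def _block_names(self) -> list[str]:
        names = ["field", "temperature", "precipitation"]
        if self.config.interaction:
            names.append("interaction")
        return names

    def prior_generalized_logdet(
        self, hypers: Hyperparameters | None = None
    ) -> float:
        """Sum of per-block generalized log-determinants (incl. intercept)."""
        total = math.log(self.config.intercept_precision)
        for name, p in self.block_precisions(hypers).items():
            total += p.generalized_logdet()
        return total


def build_model(
    panel: SentimentPanel,
    climate: ClimatePanel,
    graph: RegionGraph,
    temp_scheme: CategoryScheme = TEMPERATURE_SCHEME,
    precip_scheme: CategoryScheme = PRECIPITATION_SCHEME,
    config: FitConfig | None = None,
) -> ModelSpec:
    """Assemble the latent structure for a panel/climate/graph triple."""
    config = config or FitConfig()
    n, T = graph.n_regions, panel.n_weeks
    if panel.ntw.shape != (n, T):
        raise ValueError("panel does not match the region graph")
    if climate.temperature.shape != (n, T):
        raise ValueError(
            "climate panel does not match the sentiment panel: cells with "
            "TTW > 0 need complete climate values"
        )
    panel = _align_regions(panel, graph)
    climate = _align_regions(climate, graph)
    theta_tot = (
        config.theta_tot
        if config.theta_tot is not None
        else compute_theta_tot(panel)
    )
    if not 0.0 < theta_tot <= 1.0:
        raise ValueError("theta_tot must lie in (0, 1]")

    tcat = categorize(climate.temperature, temp_scheme)
    pcat = categorize(climate.precipitation, precip_scheme)

    n_temp = temp_scheme.n_categories
    n_precip = precip_scheme.n_categories
    slices = {"intercept": slice(0, 1), "field": slice(1, 1 + n * T)}
    pos = 1 + n * T
    slices["temperature"] = slice(pos, pos + n_temp)
    pos += n_temp
    slices["precipitation"] = slice(pos, pos + n_precip)
    pos += n_precip
    if config.interaction:
        slices["interaction"] = slice(pos, pos + n_temp * n_precip)
        pos += n_temp * n_precip
    n_latent = pos

    regions, weeks = np.nonzero(panel.ttw > 0)
    n_cells = len(regions)
    y = panel.ntw[regions, weeks].astype(float)
    offset = np.log(theta_tot * panel.ttw[regions, weeks].astype(float))

    entries_per_cell = 5 if config.interaction else 4
    rows = np.repeat(np.arange(n_cells), entries_per_cell)
    cols = np.empty((n_cells, entries_per_cell), dtype=np.int64)
    cols[:, 0] = 0  # intercept
    cols[:, 1] = slices["field"].start + regions * T + weeks
    cols[:, 2] = slices["temperature"].start + tcat[regions, weeks]
    cols[:, 3] = slices["precipitation"].start + pcat[regions, weeks]
    if config.interaction:
        cols[:, 4] = (
            slices["interaction"].start
            + tcat[regions, weeks] * n_precip
            + pcat[regions, weeks]
        )
    design = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols.ravel())), shape=(n_cells, n_latent)
    )
    return ModelSpec(
        panel=panel,
        climate=climate,
        graph=graph,
        temp_scheme=temp_scheme,
        precip_scheme=precip_scheme,
        config=config,
        theta_tot=theta_tot,
        tcat=tcat,
        pcat=pcat,
        slices=slices,
        n_latent=n_latent,
        design=design,
        y=y,
        offset=offset,
        cell_index=np.column_stack([regions, weeks]),
    )


# --------------------------------------------------------------------- #
# joint posterior                                                       #
# --------------------------------------------------------------------- #

def _poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Poisson log likelihood up to the data-only constant."""
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    return float(y @ eta - np.exp(eta).sum())


def _hyperprior_logpdf(hypers: Hyperparameters, config: FitConfig) -> float:
    """Gamma(a, b) log prior on each precision; flat prior on rho."""
    a, b = config.hyperprior_a, config.hyperprior_b
    total = 0.0
    for tau in (hypers.tau_field, hypers.tau_temp, hypers.tau_precip):
        total += (
            a * math.log(b) - math.lgamma(a)
            + (a - 1.0) * math.log(tau) - b * tau
        )
    return total


def log_posterior(
    latents: np.ndarray,
    model: ModelSpec,
    hypers: Hyperparameters | None = None,
) -> float:
    """Exact joint log posterior (up to an additive constant).

    Poisson log likelihood over positive-exposure cells plus the GMRF
    log prior of every latent block (with generalized determinants for
    the intrinsic ones) plus the intercept prior and hyperprior terms.
    """
    u = np.asarray(latents, float)
    if u.shape != (model.n_latent,):
        raise ValueError(f"latents must have shape ({model.n_latent},)")
    eta = model.offset + model.design @ u
    value = _poisson_loglik(model.y, eta)
    b0 = u[model.slices["intercept"]][0]
    tau0 = model.config.intercept_precision
    value += 0.5 * math.log(tau0) - 0.5 * tau0 * b0 * b0 \
        - 0.5 * math.log(2.0 * math.pi)
    blocks = model.block_precisions(hypers)
    for name in model._block_names():
        value += gmrf.gmrf_logdensity(u[model.slices[name]], blocks[name])
    value += _hyperprior_logpdf(hypers or model.config.hypers, model.config)
    return value


# --------------------------------------------------------------------- #
# fitting                                                               #
# --------------------------------------------------------------------- #

class NotConvergedError(RuntimeError):
    def __init__(self, message, n_iter, grad_norm):
        super().__init__(message)
        self.n_iter = n_iter
        self.grad_norm = grad_norm


@dataclass
class FitResult:
    """Gaussian approximation to the posterior of all latents.

    ``mean`` and ``sd`` cover every latent coordinate in the layout
    given by ``slices``.  The object retains the factorized negative
    Hessian so that covariances of arbitrary linear functionals of the
    latents (effect contrasts, window-averaged fields) can be computed
    exactly under the Gaussian approximation via :meth:`cov_linear`.
    """

    mean: np.ndarray
    sd: np.ndarray
    slices: dict[str, slice]
    hypers: Hyperparameters
    theta_tot: float
    n_iter: int
    grad_norm: float
    converged: bool
    log_marginal_likelihood: float
    _cho: tuple[np.ndarray, bool] = dc_field(repr=False, default=None)
    _constraints: np.ndarray = dc_field(repr=False, default=None)
    _xc: np.ndarray = dc_field(repr=False, default=None)  # H^-1 C'
    _s: np.ndarray = dc_field(repr=False, default=None)  # C H^-1 C'

    def block_mean(self, name: str) -> np.ndarray:
        return self.mean[self.slices[name]]

    def block_sd(self, name: str) -> np.ndarray:
        return self.sd[self.slices[name]]

    def cov_linear(self, L: np.ndarray) -> np.ndarray:
        """Posterior covariance of ``L @ latents`` (constraint-corrected)."""
        L = np.atleast_2d(np.asarray(L, float))
        hl = sla.cho_solve(self._cho, L.T)  # n x m
        v = L @ hl
        if self._constraints is not None and len(self._constraints):
            lx = L @ self._xc  # m x k
            v -= lx @ np.linalg.solve(self._s, lx.T)
        return v

    def sample_latents(
        self, seed: int | np.random.Generator, size: int = 1
    ) -> np.ndarray:
        """Draws from the constrained Gaussian approximation."""
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        c, lower = self._cho
        n = c.shape[0]
        z = rng.standard_normal((n, size))
        # x ~ N(0, H^-1): solve L' x = z
        x = sla.solve_triangular(c, z, lower=lower, trans="T" if lower else "N")
        if self._constraints is not None and len(self._constraints):
            cx = self._constraints @ x
            x -= self._xc @ np.linalg.solve(self._s, cx)
        out = self.mean[:, None] + x
        return out[:, 0] if size == 1 else out.T


def _dense_hessian(
    model: ModelSpec, q: sp.csr_matrix, w: np.ndarray
) -> np.ndarray:
    a = model.design
    awa = (a.T.multiply(w) @ a).tocoo()
    h = q.toarray()
    np.add.at(h, (awa.row, awa.col), awa.data)
    return h


def _add_regularizer(h: np.ndarray, ctc: sp.coo_matrix | None, c_scale: float):
    if ctc is not None:
        np.add.at(h, (ctc.row, ctc.col), c_scale * ctc.data)
    return h


def _newton(
    model: ModelSpec,
    hypers: Hyperparameters,
    u0: np.ndarray | None = None,
    config: FitConfig | None = None,
):
    """Constrained Newton ascent of the joint log posterior.

    Returns the mode, the regularized-Hessian Cholesky pieces needed for
    covariances, and diagnostics.  Feasibility (C u = 0) is maintained
    exactly: the start point is feasible and every step is projected
    onto the constraint manifold through the kriging correction, which
    yields the exact equality-constrained Newton step.
    """
    cfg = config or model.config
    q, c_mat = model.prior_matrices(hypers)
    k = c_mat.shape[0]
    ctc = None
    c_scale = 0.0
    if k:
        c_sp = sp.csr_matrix(c_mat)
        ctc = (c_sp.T @ c_sp).tocoo()
        c_scale = max(float(q.diagonal().mean()), 1.0)

    a = model.design
    u = np.zeros(model.n_latent) if u0 is None else u0.copy()

    def objective(vec):
        eta = model.offset + a @ vec
        return _poisson_loglik(model.y, eta) - 0.5 * float(vec @ (q @ vec))

    f_u = objective(u)
    grad_norm = np.inf
    cho = xc = s_mat = None
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        eta = model.offset + a @ u
        w = np.exp(eta)
        grad = a.T @ (model.y - w) - q @ u
        grad_norm = float(np.abs(grad).max())
        h = _dense_hessian(model, q, w)
        _add_regularizer(h, ctc, c_scale)
        try:
            cho = sla.cho_factor(h, lower=True, check_finite=False)
        except np.linalg.LinAlgError as err:
            raise NotConvergedError(
                f"Hessian not positive definite on the constraint subspace "
                f"at iteration {n_iter}", n_iter, grad_norm,
            ) from err
        if k:
            rhs = np.column_stack([grad, c_mat.T])
            sol = sla.cho_solve(cho, rhs, check_finite=False)
            step, xc = sol[:, 0], sol[:, 1:]
            s_mat = c_mat @ xc
            step = step - xc @ np.linalg.solve(s_mat, c_mat @ step)
        else:
            step = sla.cho_solve(cho, grad, check_finite=False)
            xc, s_mat = np.zeros((model.n_latent, 0)), np.zeros((0, 0))
        # backtracking line search on the penalized objective
        scale = 1.0
        for _ in range(40):
            u_new = u + scale * step
            f_new = objective(u_new)
            if f_new >= f_u - 1e-12 * max(1.0, abs(f_u)):
                break
            scale *= 0.5
        else:
            raise NotConvergedError(
                f"line search failed at iteration {n_iter}",
                n_iter, grad_norm,
            )
        delta = float(np.abs(scale * step).max())
        u, f_u = u_new, f_new
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        raise NotConvergedError(
            f"Newton did not converge in {cfg.max_iter} iterations "
            f"(last |grad|_inf = {grad_norm:.3g})", n_iter, grad_norm,
        )
    # refresh Hessian pieces at the mode
    eta = model.offset + a @ u
    w = np.exp(eta)
    grad = a.T @ (model.y - w) - q @ u
    h = _dense_hessian(model, q, w)
    _add_regularizer(h, ctc, c_scale)
    cho = sla.cho_factor(h, lower=True, check_finite=False)
    if k:
        xc = sla.cho_solve(cho, c_mat.T, check_finite=False)
        s_mat = c_mat @ xc
    return {
        "mode": u,
        "objective": f_u,
        "cho": cho,
        "c_mat": c_mat if k else None,
        "xc": xc,
        "s_mat": s_mat,
        "q": q,
        "ctc": ctc,
        "c_scale": c_scale,
        "n_iter": n_iter,
        "grad_norm": float(np.abs(grad).max()),
    }


def _diag_inverse_from_cholesky(cho) -> np.ndarray:
    """diag(H^-1) from the Cholesky factor via triangular inversion."""
    c, lower = cho
    linv, info = sla.lapack.dtrtri(c, lower=int(lower))
    if info != 0:
        raise np.linalg.LinAlgError("triangular inversion failed")
    # dtrtri only touches the referenced triangle; mask out the rest
    linv = np.tril(linv) if lower else np.triu(linv)
    # H^-1 = L^-T L^-1 (lower): diag_i = sum_k Linv[k, i]^2
    return np.einsum("ki,ki->i", linv, linv) if lower else np.einsum(
        "ik,ik->i", linv, linv
    )


def _logdet_from_cholesky(cho) -> float:
    c, _ = cho
    return 2.0 * float(np.log(np.diag(c)).sum())


def _constrained_logdet(
    m_reg_cho, c_mat: np.ndarray | None, s_mat: np.ndarray
) -> float:
    """logdet of M restricted to null(C), from the regularized factor.

    Identity: logdet(B' M B) = logdet(M_reg) + logdet(C M_reg^-1 C')
    - logdet(C C') for any orthonormal null-space basis B and any
    regularizer c * C'C added inside M_reg.
    """
    out = _logdet_from_cholesky(m_reg_cho)
    if c_mat is not None and len(c_mat):
        sign, ld = np.linalg.slogdet(s_mat)
        out += ld
        gram = c_mat @ c_mat.T
        sign2, ld2 = np.linalg.slogdet(gram)
        out -= ld2
    return out


def _laplace_log_marginal(
    model: ModelSpec, hypers: Hyperparameters, newton: dict
) -> float:
    """Laplace-approximate log marginal likelihood at the latent mode."""
    cfg = model.config
    u = newton["mode"]
    q = newton["q"]
    c_mat = newton["c_mat"]
    # prior generalized logdet restricted to the constraint subspace:
    # reuse the same regularizer trick on Q
    q_reg = q.toarray()
    _add_regularizer(q_reg, newton["ctc"], newton["c_scale"])
    q_cho = sla.cho_factor(q_reg, lower=True, check_finite=False)
    if c_mat is not None:
        xq = sla.cho_solve(q_cho, c_mat.T, check_finite=False)
        sq = c_mat @ xq
    else:
        sq = np.zeros((0, 0))
    logdet_q = _constrained_logdet(q_cho, c_mat, sq)
    logdet_h = _constrained_logdet(newton["cho"], c_mat, newton["s_mat"])
    return (
        newton["objective"]
        + 0.5 * logdet_q
        - 0.5 * logdet_h
        + _hyperprior_logpdf(hypers, cfg)
    )


def fit(model: ModelSpec, config: FitConfig | None = None) -> FitResult:
    """Fit the model: Laplace approximation, optional empirical Bayes.

    Deterministic (no sampling).  Raises :class:`NotConvergedError` if
    the inner Newton ascent fails.
    """
    cfg = config or model.config
    if config is not None and config != model.config:
        # the design and slices depend on the config; rebuild
        model = build_model(
            model.panel, model.climate, model.graph,
            model.temp_scheme, model.precip_scheme, config,
        )
    hypers = cfg.hypers
    if cfg.empirical_bayes:
        candidates = []
        rhos = cfg.eb_rhos or (hypers.rho,)
        for f in cfg.eb_tau_factors:
            for r in rhos:
                candidates.append(
                    replace(hypers, tau_field=hypers.tau_field * f, rho=r)
                )
        best, best_ml, u_warm = None, -np.inf, None
        for cand in candidates:
            nwt = _newton(model, cand, u0=u_warm, config=cfg)
            u_warm = nwt["mode"]
            ml = _laplace_log_marginal(model, cand, nwt)
            logger.debug(
                "EB candidate tau_field=%.4g rho=%.3g -> logML %.4f",
                cand.tau_field, cand.rho, ml,
            )
            if ml > best_ml:
                best, best_ml = cand, ml
        hypers = best
    newton = _newton(model, hypers, config=cfg)
    log_ml = _laplace_log_marginal(model, hypers, newton)

    diag_hinv = _diag_inverse_from_cholesky(newton["cho"])
    var = diag_hinv.copy()
    if newton["c_mat"] is not None:
        xc, s_mat = newton["xc"], newton["s_mat"]
        var -= np.einsum(
            "ij,ij->i", xc, xc @ np.linalg.inv(s_mat)
        )
    var = np.maximum(var, 0.0)
    return FitResult(
        mean=newton["mode"],
        sd=np.sqrt(var),
        slices=model.slices,
        hypers=hypers,
        theta_tot=model.theta_tot,
        n_iter=newton["n_iter"],
        grad_norm=newton["grad_norm"],
        converged=True,
        log_marginal_likelihood=log_ml,
        _cho=newton["cho"],
        _constraints=newton["c_mat"],
        _xc=newton["xc"],
        _s=newton["s_mat"],
    )


# --------------------------------------------------------------------- #
# reporting surfaces                                                    #
# --------------------------------------------------------------------- #

@dataclass(frozen=True)
class EffectSummary:
    """Per-category effect with 95% bounds on log and percent-RR scales."""

    effect: str
    labels: tuple[str, ...]
    mean: np.ndarray  # log-RR scale
    sd: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    percent_mean: np.ndarray  # 100 * (exp(f) - 1)
    percent_lower95: np.ndarray
    percent_upper95: np.ndarray
    occupancy: np.ndarray  # likelihood cells per level
    significant: np.ndarray  # bool: 95% interval excludes 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "level": self.labels,
                "mean": self.mean,
                "lower95": self.lower95,
                "upper95": self.upper95,
                "percent_mean": self.percent_mean,
                "percent_lower95": self.percent_lower95,
                "percent_upper95": self.percent_upper95,
                "occupancy": self.occupancy,
                "significant": self.significant,
            }
        )


def effect_summary(
    fit_result: FitResult, model: ModelSpec, effect: str
) -> EffectSummary:
    """Posterior effect curve: mean +/- 1.96 sd per category level.

    Percent-scale columns report ``100 * (exp(.) - 1)``, the relative-
    risk change versus the block mean (the sum-to-zero reference).
    """
    if effect not in ("temperature", "precipitation", "interaction"):
        raise ValueError(f"unknown effect {effect!r}")
    if effect not in model.slices:
        raise ValueError(f"effect {effect!r} not present in this model")
    mean = fit_result.block_mean(effect)
    sd = fit_result.block_sd(effect)
    lo, hi = mean - _Z95 * sd, mean + _Z95 * sd
    if effect == "temperature":
        labels = model.temp_scheme.labels
        cats = model.tcat
        n_levels = model.temp_scheme.n_categories
    elif effect == "precipitation":
        labels = model.precip_scheme.labels
        cats = model.pcat
        n_levels = model.precip_scheme.n_categories
    else:
        n_p = model.precip_scheme.n_categories
        labels = tuple(
            f"{t}x{p}"
            for t in model.temp_scheme.labels
            for p in model.precip_scheme.labels
        )
        cats = model.tcat * n_p + model.pcat
        n_levels = len(labels)
    r, w = model.cell_index[:, 0], model.cell_index[:, 1]
    occupancy = np.bincount(cats[r, w], minlength=n_levels)
    return EffectSummary(
        effect=effect,
        labels=tuple(labels),
        mean=mean,
        sd=sd,
        lower95=lo,
        upper95=hi,
        percent_mean=100.0 * np.expm1(mean),
        percent_lower95=100.0 * np.expm1(lo),
        percent_upper95=100.0 * np.expm1(hi),
        occupancy=occupancy,
        significant=(lo > 0) | (hi < 0),
    )


@dataclass(frozen=True)
class RRDifferenceMap:
    """Per-region before -> during change in posterior log relative risk."""

    region_ids: tuple[str, ...]
    delta: np.ndarray  # log-RR scale
    sd: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    percent_change: np.ndarray  # 100 * (exp(delta) - 1)
    significant: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "region": self.region_ids,
                "delta": self.delta,
                "lower95": self.lower95,
                "upper95": self.upper95,
                "percent_change": self.percent_change,
                "significant": self.significant,
            }
        )


def rr_difference(
    fit_result: FitResult,
    model: ModelSpec,
    windows: EventWindows,
) -> RRDifferenceMap:
    """Window-averaged change in log relative risk, region by region.

    For each region, Delta = mean over 'during' weeks of the posterior
    log relative risk minus the mean over 'before' weeks, with the
    variance propagated through the full Gaussian-approximation
    covariance of the involved coordinates (field values plus the
    covariate-effect coordinates weighted by their window occupancy;
    the intercept cancels).  The significance flag marks regions whose
    95% interval excludes zero.
    """
    origin = model.panel.week_starts[0]
    widx = windows.week_indices(origin, model.n_weeks)
    before, during = widx["before"], widx["during"]
    if not before or not during:
        raise ValueError(
            "before/during windows must each contain at least one model week"
        )
    n, T = model.n_regions, model.n_weeks
    L = np.zeros((n, model.n_latent))
    f0 = model.slices["field"].start
    for i in range(n):
        for t in during:
            L[i, f0 + i * T + t] += 1.0 / len(during)
            _add_effect_weights(L, model, i, t, 1.0 / len(during))
        for t in before:
            L[i, f0 + i * T + t] -= 1.0 / len(before)
            _add_effect_weights(L, model, i, t, -1.0 / len(before))
    delta = L @ fit_result.mean
    var = np.maximum(np.diag(fit_result.cov_linear(L)), 0.0)
    sd = np.sqrt(var)
    lo, hi = delta - _Z95 * sd, delta + _Z95 * sd
    return RRDifferenceMap(
        region_ids=tuple(model.graph.region_ids),
        delta=delta,
        sd=sd,
        lower95=lo,
        upper95=hi,
        percent_change=100.0 * np.expm1(delta),
        significant=(lo > 0) | (hi < 0),
    )


def _add_effect_weights(
    L: np.ndarray, model: ModelSpec, i: int, t: int, weight: float
) -> None:
    L[i, model.slices["temperature"].start + model.tcat[i, t]] += weight
    L[i, model.slices["precipitation"].start + model.pcat[i, t]] += weight
    if "interaction" in model.slices:
        n_p = model.precip_scheme.n_categories
        L[
            i,
            model.slices["interaction"].start
            + model.tcat[i, t] * n_p
            + model.pcat[i, t],
        ] += weight


# --------------------------------------------------------------------- #
# optional MCMC cross-check                                             #
# --------------------------------------------------------------------- #

def mcmc_crosscheck(
    model: ModelSpec,
    fit_result: FitResult,
    n_samples: int = 2000,
    burn_in: int = 200,
    seed: int = 0,
) -> dict:
    """Independence Metropolis-Hastings check of the Laplace posterior.

    Proposes from the fitted constrained Gaussian and accepts with the
    exact joint posterior, so posterior means/sds from the chain are
    asymptotically exact.  Intended for validation on small models; off
    by default in every pipeline.
    """
    rng = np.random.default_rng(seed)
    q, _ = model.prior_matrices(fit_result.hypers)
    a = model.design

    def log_target(u):
        eta = model.offset + a @ u
        return _poisson_loglik(model.y, eta) - 0.5 * float(u @ (q @ u))

    def log_proposal(u):
        # -0.5 d' H_reg d; on the constraint manifold (C d = 0, which
        # sample_latents guarantees) the regularizer contributes nothing
        d = u - fit_result.mean
        return -0.5 * float(d @ _h_mat_vec(fit_result, d))

    current = fit_result.mean.copy()
    lt, lp = log_target(current), log_proposal(current)
    draws = np.empty((n_samples, model.n_latent))
    accepted = 0
    for s in range(n_samples + burn_in):
        prop = fit_result.sample_latents(rng)
        lt_p, lp_p = log_target(prop), log_proposal(prop)
        if math.log(rng.random()) < (lt_p - lt) - (lp_p - lp):
            current, lt, lp = prop, lt_p, lp_p
            accepted += 1
        if s >= burn_in:
            draws[s - burn_in] = current
    return {
        "mean": draws.mean(axis=0),
        "sd": draws.std(axis=0),
        "acceptance_rate": accepted / (n_samples + burn_in),
        "draws": draws,
    }


def _h_mat_vec(fit_result: FitResult, d: np.ndarray) -> np.ndarray:
    """(Regularized) Hessian times vector, from the stored factor."""
    c, lower = fit_result._cho
    # cho_factor leaves the unused triangle unreferenced; mask it out
    tri = np.tril(c) if lower else np.triu(c)
    if lower:
        return tri @ (tri.T @ d)
    return tri.T @ (tri @ d)
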