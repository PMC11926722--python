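"""Scikit-learn-style estimator facade over the risk model.

:class:`NegativeSentimentRiskModel` bundles model assembly, the Laplace
fit and the reporting surfaces behind the familiar
``__init__(params) / fit(...) / fitted attributes with trailing
underscore`` contract, so it composes with sklearn tooling
(``get_params`` / ``set_params`` / ``clone``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import model as _model
from .covariates import (
    CategoryScheme,
    EventWindows,
    FLOOD_WINDOWS,
    PRECIPITATION_SCHEME,
    TEMPERATURE_SCHEME,
)
from .panel import ClimatePanel, SentimentPanel
from .regions import RegionGraph

__all__ = ["NegativeSentimentRiskModel"]


class NegativeSentimentRiskModel(BaseEstimator):
    """Poisson relative-risk model for weekly region-level counts.

    Parameters mirror :class:`~sentirisk.model.FitConfig`; see that
    class and the module docstring of :mod:`sentirisk.model` for the
    statistical detail.

    Parameters
    ----------
    field_structure : str
        Space-time prior of the latent field: ``"icar_ar1"`` (default),
        ``"icar_iid"``, ``"iid_ar1"`` or ``"iid"``.
    interaction : bool
        Add the temperature x precipitation interaction block with a
        2-D ICAR prior.
    tau_field, rho, tau_temp, tau_precip, tau_interaction : float
        Hyperparameters of the latent blocks (field precision scale,
        temporal AR(1) correlation, effect-chain precisions).
    empirical_bayes : bool
        Optimize ``tau_field`` (and optionally ``rho``) by maximizing
        the Laplace marginal likelihood over a grid.
    theta_tot : float or None
        Baseline negative proportion; None computes it from the panel.

    Attributes
    ----------
    result_ : FitResult
        Full Gaussian-approximation posterior.
    model_ : ModelSpec
        The assembled latent structure.
    theta_tot_ : float
    converged_ : bool
    n_iter_ : int
    log_marginal_likelihood_ : float
    """

    def __init__(
        self,
        field_structure: str = "icar_ar1",
        effect_prior: str = "independent",
        effect_rho: float = 0.8,
        interaction: bool = False,
        tau_field: float = 200.0,
        rho: float = 0.7,
        tau_temp: float = 1.0,
        tau_precip: float = 1.0,
        tau_interaction: float = 1.0,
        empirical_bayes: bool = False,
        eb_tau_factors: tuple = (0.25, 0.5, 1.0, 2.0, 4.0),
        eb_rhos: tuple | None = None,
        intercept_precision: float = 1e-6,
        max_iter: int = 50,
        tol: float = 1e-9,
        theta_tot: float | None = None,
        temp_scheme: CategoryScheme | None = None,
        precip_scheme: CategoryScheme | None = None,
    ):
        self.field_structure = field_structure
        self.effect_prior = effect_prior
        self.effect_rho = effect_rho
        self.interaction = interaction
        self.tau_field = tau_field
        self.rho = rho
        self.tau_temp = tau_temp
        self.tau_precip = tau_precip
        self.tau_interaction = tau_interaction
        self.empirical_bayes = empirical_bayes
        self.eb_tau_factors = eb_tau_factors
        self.eb_rhos = eb_rhos
        self.intercept_precision = intercept_precision
        self.max_iter = max_iter
        self.tol = tol
        self.theta_tot = theta_tot
        self.temp_scheme = temp_scheme
        self.precip_scheme = precip_scheme

    # ------------------------------------------------------------------
    def _config(self) -> _model.FitConfig:
        return _model.FitConfig(
            field_structure=self.field_structure,
            effect_prior=self.effect_prior,
            effect_rho=self.effect_rho,
            interaction=self.interaction,
            hypers=_model.Hyperparameters(
                tau_field=self.tau_field,
                rho=self.rho,
                tau_temp=self.tau_temp,
                tau_precip=self.tau_precip,
                tau_interaction=self.tau_interaction,
            ),
            intercept_precision=self.intercept_precision,
            empirical_bayes=self.empirical_bayes,
            eb_tau_factors=tuple(self.eb_tau_factors),
            eb_rhos=None if self.eb_rhos is None else tuple(self.eb_rhos),
            max_iter=self.max_iter,
            tol=self.tol,
            theta_tot=self.theta_tot,
        )

    def fit(
        self,
        panel: SentimentPanel,
        climate: ClimatePanel,
        graph: RegionGraph,
    ) -> "NegativeSentimentRiskModel":
        """Assemble and fit; deterministic (no sampling involved)."""
        config = self._config()
        self.model_ = _model.build_model(
            panel,
            climate,
            graph,
            self.temp_scheme or TEMPERATURE_SCHEME,
            self.precip_scheme or PRECIPITATION_SCHEME,
            config,
        )
        self.result_ = _model.fit(self.model_)
        self.theta_tot_ = self.model_.theta_tot
        self.converged_ = self.result_.converged
        self.n_iter_ = self.result_.n_iter
        self.log_marginal_likelihood_ = self.result_.log_marginal_likelihood
        self.hyperparameters_ = self.result_.hypers
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("this estimator is not fitted yet")

    # -- reporting -----------------------------------------------------
    def effect_summary(self, effect: str) -> _model.EffectSummary:
        """Category effect curve with 95% bounds (log and percent scale)."""
        self._check_fitted()
        return _model.effect_summary(self.result_, self.model_, effect)

    def rr_difference(
        self, windows: EventWindows = FLOOD_WINDOWS
    ) -> _model.RRDifferenceMap:
        """Before -> during relative-risk change per region."""
        self._check_fitted()
        return _model.rr_difference(self.result_, self.model_, windows)

    def predict_log_relative_risk(self) -> np.ndarray:
        """Posterior mean log relative risk per region x week."""
        self._check_fitted()
        m = self.model_
        u = self.result_.mean
        field = u[m.slices["field"]].reshape(m.n_regions, m.n_weeks)
        out = (
            u[m.slices["intercept"]][0]
            + field
            + u[m.slices["temperature"]][m.tcat]
            + u[m.slices["precipitation"]][m.pcat]
        )
        if "interaction" in m.slices:
            n_p = m.precip_scheme.n_categories
            out = out + u[m.slices["interaction"]][m.tcat * n_p + m.pcat]
        return out

    def predict_relative_risk(self) -> np.ndarray:
        """Posterior mean relative risk (plug-in exp of the mean)."""
        return np.exp(self.predict_log_relative_risk())

    def predict(self) -> np.ndarray:
        """Fitted mean negative counts theta_tot * TTW * relrisk."""
        self._check_fitted()
        ttw = self.model_.panel.ttw
        return self.theta_tot_ * ttw * self.predict_relative_risk()
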