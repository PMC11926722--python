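"""Synthetic study generator: a known-truth twin of the tweet panel.

Everything downstream (categorization, GMRF priors, the Laplace fitter,
the reporting surfaces) is exercised against data drawn from the model's
own generative form,

    NTw(i,t) ~ Poisson( theta_tot * TTW(i,t) * relrisk(i,t) ),
    log relrisk(i,t) = field(i,t) + f_temp[cat(T)] + f_precip[cat(P)]
                       + event_effect * 1{exposed region, event week},

with the latent field drawn from the constrained ICAR x AR(1) GMRF and
the climate covariates shaped like the study's: a yearly temperature
sinusoid spanning roughly -1..24 deg C and right-skewed precipitation in
[0, 0.07] with a planted 4-week high-precipitation event in a contiguous
block of regions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import datetime as dt
import json
import logging
import math

import numpy as np

from . import gmrf
from .panel import ClimatePanel, SentimentPanel, DEFAULT_WEEK_ORIGIN
from .regions import RegionGraph, make_region_graph

__all__ = [
    "EventSpec",
    "TrueParams",
    "SyntheticBundle",
    "simulate_climate",
    "simulate_panel",
    "default_bundle",
]

logger = logging.getLogger(__name__)

#: Model-week indices of the flood (origin 2019-01-01): 2021-06-22..07-19.
FLOOD_EVENT_WEEKS = (129, 130, 131, 132)


@dataclass(frozen=True)
class EventSpec:
    """A planted high-precipitation event."""

    weeks: tuple[int, ...] = FLOOD_EVENT_WEEKS
    regions: tuple[int, ...] = ()
    precip_boost: float = 0.035


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth effects for the generative model.

    ``intercept`` is the log baseline negative proportion, i.e.
    ``theta_tot = exp(intercept)``; the default corresponds to 10% of
    documents being negative.  Effect vectors are on the log-relative-
    risk scale; any common shift is absorbed by the intercept, so
    recovery is defined up to mean-centring (the fitted blocks carry a
    sum-to-zero constraint).
    """

    intercept: float = math.log(0.1)
    f_temp: tuple[float, ...] = (0.0, -0.005, 0.0, 0.020)
    f_precip: tuple[float, ...] = (-0.0025, 0.0, 0.011)
    field_tau: float = 2500.0
    ar_rho: float = 0.7
    event_effect: float = math.log(1.10)
    exposed_regions: tuple[int, ...] = ()
    event_weeks: tuple[int, ...] = FLOOD_EVENT_WEEKS

    def __post_init__(self):
        if self.field_tau <= 0:
            raise ValueError("field_tau must be positive")
        if not -1.0 < self.ar_rho < 1.0:
            raise ValueError("ar_rho must be in (-1, 1)")
        ws = sorted(self.event_weeks)
        if ws and ws != list(range(ws[0], ws[0] + len(ws))):
            raise ValueError("event_weeks must be contiguous")


@dataclass(frozen=True)
class SyntheticBundle:
    graph: RegionGraph
    climate: ClimatePanel
    panel: SentimentPanel
    latent_field: np.ndarray  # (n_regions, n_weeks)
    log_relrisk: np.ndarray  # (n_regions, n_weeks), excl. intercept
    params: TrueParams
    seed: int

    def __post_init__(self):
        if self.panel.ntw.shape != self.climate.temperature.shape:
            raise ValueError("panel and climate dimensions disagree")

    def params_json(self) -> str:
        d = {
            k: getattr(self.params, k)
            for k in (
                "intercept", "f_temp", "f_precip", "field_tau", "ar_rho",
                "event_effect", "exposed_regions", "event_weeks",
            )
        }
        d["seed"] = self.seed
        return json.dumps(d, default=list)


def simulate_climate(
    graph: RegionGraph,
    n_weeks: int,
    start_date: dt.date = DEFAULT_WEEK_ORIGIN,
    event: EventSpec | None = None,
    seed: int = 0,
    temp_range: tuple[float, float] = (-1.0, 24.0),
    precip_range: tuple[float, float] = (0.0, 0.07),
) -> ClimatePanel:
    """Weekly temperature and precipitation with a planted event.

    Temperature follows a yearly sinusoid (trough late January) plus a
    small fixed regional offset and weekly noise, clipped to
    ``temp_range``; precipitation is right-skewed gamma noise clipped to
    ``precip_range``, with event cells shifted up by
    ``event.precip_boost`` before clipping.  Deterministic given seed.
    """
    if n_weeks < 8:
        raise ValueError("need n_weeks >= 8 to host before/during/after windows")
    event = event or EventSpec(weeks=(), regions=())
    if any(not 0 <= w < n_weeks for w in event.weeks):
        raise ValueError("event weeks outside the simulated range")
    if any(not 0 <= r < graph.n_regions for r in event.regions):
        raise ValueError("event regions outside the graph")
    rng = np.random.default_rng(seed)
    n = graph.n_regions

    day0 = start_date.timetuple().tm_yday
    week_days = day0 + 7.0 * np.arange(n_weeks) + 3.5  # mid-week day-of-year
    seasonal = 11.5 + 12.0 * np.sin(2 * np.pi * (week_days - 114.0) / 365.25)
    region_offset = rng.normal(0.0, 0.5, size=n)
    temp = (
        seasonal[None, :]
        + region_offset[:, None]
        + rng.normal(0.0, 1.2, size=(n, n_weeks))
    )
    temp = np.clip(temp, *temp_range)

    precip = rng.gamma(shape=1.6, scale=0.008, size=(n, n_weeks))
    if event.regions and len(event.weeks) and event.precip_boost:
        idx = np.ix_(
            np.asarray(event.regions, int), np.asarray(event.weeks, int)
        )
        precip[idx] += event.precip_boost
    precip = np.clip(precip, *precip_range)

    weeks = tuple(
        start_date + dt.timedelta(days=7 * t) for t in range(n_weeks)
    )
    return ClimatePanel(graph.region_ids, weeks, temp, precip)


def _draw_ttw(
    rng: np.random.Generator,
    shape: tuple[int, int],
    mean_ttw: float,
    allow_zero: bool,
) -> np.ndarray:
    """Overdispersed (negative binomial) weekly tweet totals."""
    k = 5.0  # dispersion: var = mean + mean^2 / k
    p = k / (k + mean_ttw)
    ttw = rng.negative_binomial(k, p, size=shape).astype(np.int64)
    if not allow_zero:
        zero = ttw == 0
        while np.any(zero):
            ttw[zero] = rng.negative_binomial(k, p, size=int(zero.sum()))
            zero = ttw == 0
    return ttw


def simulate_panel(
    graph: RegionGraph,
    climate: ClimatePanel,
    params: TrueParams,
    mean_ttw: float = 5000.0,
    seed: int = 0,
    allow_zero_ttw: bool = False,
) -> SyntheticBundle:
    """Draw exposures, the latent field and Poisson negative counts.

    The rare Poisson draw exceeding its cell's total is redrawn (the
    observed pipeline counts negatives among totals, so NTw <= TTW must
    hold); redraws are counted in a logged warning.
    """
    from .covariates import categorize_panel

    if mean_ttw < 1:
        raise ValueError("mean_ttw must be >= 1")
    n, T = graph.n_regions, climate.n_weeks
    if len(climate.region_ids) != n:
        raise ValueError("climate panel does not match the graph")
    ss = np.random.SeedSequence(seed)
    rng_ttw, rng_field, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    ttw = _draw_ttw(rng_ttw, (n, T), mean_ttw, allow_zero_ttw)

    spatial = gmrf.icar_precision(graph, params.field_tau)
    temporal = gmrf.ar1_precision(T, params.ar_rho, 1.0)
    q_st = gmrf.spacetime_precision(spatial, temporal)
    field = gmrf.sample_gmrf(q_st, rng_field).reshape(n, T)

    tcat, pcat = categorize_panel(climate)
    f_temp = np.asarray(params.f_temp, float)
    f_precip = np.asarray(params.f_precip, float)
    log_rr = field + f_temp[tcat] + f_precip[pcat]
    if params.exposed_regions and len(params.event_weeks):
        idx = np.ix_(
            np.asarray(params.exposed_regions, int),
            np.asarray(params.event_weeks, int),
        )
        log_rr[idx] += params.event_effect

    theta_tot = math.exp(params.intercept)
    mu = theta_tot * ttw * np.exp(log_rr)
    if np.any(mu > 1e7):
        raise ValueError("expected counts exceed 1e7 per cell; aborting")

    ntw = rng_counts.poisson(mu)
    bad = ntw > ttw
    n_redraws = 0
    while np.any(bad):
        n_redraws += int(bad.sum())
        ntw[bad] = rng_counts.poisson(mu[bad])
        bad = ntw > ttw
    if n_redraws:
        logger.warning(
            "simulate_panel redrew %d cells with NTw > TTW", n_redraws
        )

    panel = SentimentPanel(graph.region_ids, climate.week_starts, ntw, ttw)
    return SyntheticBundle(
        graph=graph,
        climate=climate,
        panel=panel,
        latent_field=field,
        log_relrisk=log_rr,
        params=params,
        seed=seed,
    )


def default_bundle(
    seed: int = 0,
    n_rows: int = 4,
    n_cols: int = 4,
    n_weeks: int = 150,
    mean_ttw: float = 5000.0,
    params: TrueParams | None = None,
    with_event: bool = True,
) -> SyntheticBundle:
    """The package's reference synthetic study.

    A 4x4 region lattice observed for 150 weeks from 2019-01-01 with
    ~5000 tweets per region-week; the flood event occupies model weeks
    129-132 (exactly the 2021-06-22..2021-07-19 window) in a contiguous
    2x2 block of regions.
    """
    graph = make_region_graph(n_rows, n_cols, seed=seed)
    # contiguous block: rows 1-2 x cols 1-2 of the lattice (when possible)
    if with_event:
        rows = range(min(1, n_rows - 1), min(3, n_rows))
        cols = range(min(1, n_cols - 1), min(3, n_cols))
        exposed = tuple(sorted({r * n_cols + c for r in rows for c in cols}))
    else:
        exposed = ()
    event_weeks = tuple(w for w in FLOOD_EVENT_WEEKS if w < n_weeks)
    if params is None:
        params = TrueParams(exposed_regions=exposed, event_weeks=event_weeks)
    else:
        params = replace(
            params, exposed_regions=exposed, event_weeks=event_weeks
        )
    event = EventSpec(weeks=event_weeks, regions=exposed) if with_event \
        else EventSpec(weeks=(), regions=())
    climate = simulate_climate(
        graph, n_weeks, DEFAULT_WEEK_ORIGIN, event, seed=seed
    )
    return simulate_panel(graph, climate, params, mean_ttw, seed=seed)
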