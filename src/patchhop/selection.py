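"""Bayesian model comparison via log2 marginal likelihoods.

For each candidate model ``M`` with free parameters ``theta`` the evidence

    P(D | M) = integral of  P(D | theta, M) pi(theta)  d theta

is computed by integrating the sequence likelihood of the observed
crossing outcomes over a parameter prior, and reported as
``log2 P(D | M)``.  The model under which the data are most probable is
selected; evidence differences are log2 Bayes factors.

Priors default to log-uniform over ``[2^-6, 2^6]`` for multiplicative
factors (``gamma, g, alpha, a, b``; ``s`` over ``[1 + 2^-6, 2^6]``) and
uniform over ``[-5, 5]`` for the linear slope ``beta``.  The default
integrator is a deterministic tensor grid (trapezoid masses, 513 points
per dimension, evaluated in the prior's natural coordinate: log2 for
multiplicative parameters, linear for ``beta``); a seeded Monte Carlo
estimate of the same integral is available as an independent cross-check.

Two entry styles are provided: plain functions
(:func:`log_marginal_likelihood`, :func:`compare_models`,
:func:`posterior_summary`) and model/results classes
(:class:`CrossingDecisionModel` -> :class:`CrossingDecisionResults`,
:class:`ModelComparison` -> :class:`ModelComparisonResults`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .eventlog import Dataset, Trial, read_event_log
from .models import (
    PARAM_BOUNDS,
    ModelSpec,
    _loglik2_from_stats,
    get_model,
    list_models,
    log_likelihood,
    sufficient_stats,
)

__all__ = [
    "Prior",
    "IntegrationSettings",
    "PosteriorGrid",
    "ModelEvidence",
    "ComparisonTable",
    "default_priors",
    "log_marginal_likelihood",
    "compare_models",
    "posterior_summary",
    "CrossingDecisionModel",
    "CrossingDecisionResults",
    "ModelComparison",
    "ModelComparisonResults",
]

_LN2 = math.log(2.0)
_CHUNK = 65536


@dataclass(frozen=True)
class Prior:
    """A normalized one-dimensional prior: log-uniform or uniform."""

    kind: str  # "log_uniform" | "uniform"
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.kind not in ("log_uniform", "uniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if not self.lo < self.hi:
            raise ValueError(f"prior needs lo < hi, got [{self.lo}, {self.hi}]")
        if self.kind == "log_uniform" and not self.lo > 0:
            raise ValueError("log_uniform prior needs lo > 0")

    @property
    def transform(self) -> str:
        """Coordinate the prior is flat in: 'log2' or 'linear'."""
        return "log2" if self.kind == "log_uniform" else "linear"

    def to_coord(self, x: np.ndarray) -> np.ndarray:
        return np.log2(x) if self.kind == "log_uniform" else np.asarray(x, float)

    def from_coord(self, u: np.ndarray) -> np.ndarray:
        return 2.0**u if self.kind == "log_uniform" else np.asarray(u, float)

    def grid(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(natural values, flat coordinates, log trapezoid masses)."""
        lo_u, hi_u = float(self.to_coord(self.lo)), float(self.to_coord(self.hi))
        u = np.linspace(lo_u, hi_u, n)
        du = (hi_u - lo_u) / (n - 1)
        w = np.full(n, du)
        w[0] = w[-1] = du / 2.0
        w /= hi_u - lo_u  # flat density in the coordinate; masses sum to 1
        return self.from_coord(u), u, np.log(w)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo_u, hi_u = float(self.to_coord(self.lo)), float(self.to_coord(self.hi))
        return self.from_coord(rng.uniform(lo_u, hi_u, size=n))


def default_priors() -> dict[str, Prior]:
    priors = {
        name: Prior("log_uniform", lo, hi)
        for name, (lo, hi) in PARAM_BOUNDS.items()
        if name != "beta"
    }
    priors["beta"] = Prior("uniform", *PARAM_BOUNDS["beta"])
    return priors


@dataclass(frozen=True)
class IntegrationSettings:
    """How the evidence integral is evaluated."""

    method: str = "grid"  # "grid" | "monte_carlo"
    grid_points_per_dim: int = 513
    mc_samples: int = 20000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("grid", "monte_carlo"):
            raise ValueError(f"unknown integration method {self.method!r}")
        if self.grid_points_per_dim < 3:
            raise ValueError("grid_points_per_dim must be >= 3")
        if self.mc_samples < 100:
            raise ValueError("mc_samples must be >= 100")


@dataclass(frozen=True)
class PosteriorGrid:
    """Normalized posterior masses on a tensor parameter grid."""

    param_names: tuple[str, ...]
    values: tuple[np.ndarray, ...]  # natural scale, per dimension
    coords: tuple[np.ndarray, ...]  # integration coordinate, per dimension
    transforms: tuple[str, ...]
    masses: np.ndarray  # shape (n1, ..., nk), sums to 1

    def marginal(self, param: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(natural values, coordinates, marginal masses) for one parameter."""
        i = self.param_names.index(param)
        axes = tuple(j for j in range(len(self.param_names)) if j != i)
        return self.values[i], self.coords[i], self.masses.sum(axis=axes)


@dataclass(frozen=True)
class ModelEvidence:
    """Evidence and posterior of one model on one dataset."""

    model: str
    log2_evidence: float
    map_params: dict[str, float]
    n_informative: int
    method: str
    priors: dict[str, Prior]
    posterior: PosteriorGrid | None = None

    @property
    def spec(self) -> ModelSpec:
        return get_model(self.model)


def _free_params(spec: ModelSpec, environment_mode: str) -> tuple[str, ...]:
    # the asymmetric configuration adds a refuge-side bias factor b
    if environment_mode == "asymmetric":
        return spec.param_names + ("b",)
    return spec.param_names


def _check_finite(ll2: np.ndarray, model: str, names: Sequence[str],
                  values: Sequence[np.ndarray], offset: int) -> None:
    bad = ~(np.isfinite(ll2) | np.isneginf(ll2))
    if bad.any():
        i = int(np.argmax(bad))
        point = {n: float(v[i]) for n, v in zip(names, values)}
        raise FloatingPointError(
            f"model {model}: non-finite likelihood at grid point "
            f"{offset + i} ({point})"
        )


def log_marginal_likelihood(
    model: str,
    data: Dataset | Trial,
    priors: Mapping[str, Prior] | None = None,
    settings: IntegrationSettings | None = None,
    *,
    memory_window_s: float = 3.5,
    include_focal: bool = False,
    environment_mode: str = "symmetric",
) -> ModelEvidence:
    """log2 evidence of ``model`` on ``data``.

    A model with no free parameters (M0 in the symmetric arena) has a
    zero-dimensional integral: its evidence equals its log-likelihood
    exactly.  A dataset without informative decision points gives evidence
    0 for every model.
    """
    spec = get_model(model)
    settings = settings or IntegrationSettings()
    all_priors = dict(default_priors())
    if priors:
        all_priors.update(priors)
    names = _free_params(spec, environment_mode)
    used_priors = {n: all_priors[n] for n in names}
    stats = sufficient_stats(data, memory_window_s)
    n_informative = int(stats["count"].sum()) if not stats.empty else 0
    kwargs = dict(include_focal=include_focal, environment_mode=environment_mode)

    if not names:
        ll2 = float(_loglik2_from_stats(model, {}, stats, **kwargs)[0])
        return ModelEvidence(model, ll2, {}, n_informative, settings.method,
                             used_priors, None)

    if settings.method == "grid":
        grids = [used_priors[n].grid(settings.grid_points_per_dim) for n in names]
        axes_vals = [g[0] for g in grids]
        axes_coords = [g[1] for g in grids]
        mesh = np.meshgrid(*axes_vals, indexing="ij")
        flat_vals = [m.reshape(-1) for m in mesh]
        lw_mesh = np.meshgrid(*[g[2] for g in grids], indexing="ij")
        flat_logmass = sum(m.reshape(-1) for m in lw_mesh)
        n_total = flat_vals[0].size
        ln_post = np.empty(n_total)
        for start in range(0, n_total, _CHUNK):
            stop = min(start + _CHUNK, n_total)
            chunk_params = {n: v[start:stop] for n, v in zip(names, flat_vals)}
            ll2 = _loglik2_from_stats(model, chunk_params, stats, **kwargs)
            _check_finite(ll2, model, names,
                          [v[start:stop] for v in flat_vals], start)
            ln_post[start:stop] = _LN2 * ll2 + flat_logmass[start:stop]
        log2_ev = float(logsumexp(ln_post) / _LN2)
        masses = np.exp(ln_post - logsumexp(ln_post)).reshape(
            [settings.grid_points_per_dim] * len(names)
        )
        imap = int(np.argmax(ln_post))
        map_params = {n: float(v[imap]) for n, v in zip(names, flat_vals)}
        posterior = PosteriorGrid(
            param_names=tuple(names),
            values=tuple(axes_vals),
            coords=tuple(axes_coords),
            transforms=tuple(used_priors[n].transform for n in names),
            masses=masses,
        )
        return ModelEvidence(model, log2_ev, map_params, n_informative,
                             "grid", used_priors, posterior)

    # Monte Carlo: log of the mean likelihood under prior draws
    rng = np.random.default_rng(settings.rng_seed)
    draws = {n: used_priors[n].sample(settings.mc_samples, rng) for n in names}
    ll2_all = np.empty(settings.mc_samples)
    for start in range(0, settings.mc_samples, _CHUNK):
        stop = min(start + _CHUNK, settings.mc_samples)
        chunk = {n: v[start:stop] for n, v in draws.items()}
        ll2 = _loglik2_from_stats(model, chunk, stats, **kwargs)
        _check_finite(ll2, model, names, [v[start:stop] for v in draws.values()],
                      start)
        ll2_all[start:stop] = ll2
    log2_ev = float(
        (logsumexp(_LN2 * ll2_all) - math.log(settings.mc_samples)) / _LN2
    )
    ibest = int(np.argmax(ll2_all))
    map_params = {n: float(v[ibest]) for n, v in draws.items()}
    return ModelEvidence(model, log2_ev, map_params, n_informative,
                         "monte_carlo", used_priors, None)


def posterior_summary(evidence: ModelEvidence) -> pd.DataFrame:
    """Per-parameter posterior mean, mode and 95% credible interval.

    Means and standard deviations are reported in the integration
    coordinate (log2 for multiplicative parameters), modes and interval
    endpoints on the natural scale.
    """
    if evidence.posterior is None:
        raise ValueError(
            "posterior summary needs a grid posterior; the model has no free "
            "parameters or was integrated by Monte Carlo"
        )
    rows = []
    post = evidence.posterior
    for name, transform in zip(post.param_names, post.transforms):
        values, coords, mass = post.marginal(name)
        mass = mass / mass.sum()
        mean_u = float(np.sum(mass * coords))
        sd_u = float(np.sqrt(np.sum(mass * (coords - mean_u) ** 2)))
        mode = float(values[int(np.argmax(mass))])
        cdf = np.cumsum(mass)
        lo_u = float(np.interp(0.025, cdf, coords))
        hi_u = float(np.interp(0.975, cdf, coords))
        prior = evidence.priors[name]
        rows.append(
            {
                "param": name,
                "transform": transform,
                "mean": mean_u,
                "sd": sd_u,
                "mode": mode,
                "ci_low": float(prior.from_coord(np.asarray(lo_u))),
                "ci_high": float(prior.from_coord(np.asarray(hi_u))),
            }
        )
    return pd.DataFrame(rows).set_index("param")


@dataclass(frozen=True)
class ComparisonTable:
    """Ranked model evidences (descending; ties keep registry order)."""

    evidences: tuple[ModelEvidence, ...]

    def __post_init__(self) -> None:
        ranked = sorted(self.evidences, key=lambda e: -e.log2_evidence)
        object.__setattr__(self, "evidences", tuple(ranked))

    @property
    def best_model(self) -> str:
        return self.evidences[0].model

    def evidence(self, model: str) -> ModelEvidence:
        for e in self.evidences:
            if e.model == model:
                return e
        raise KeyError(model)

    def evidence_ratio(self, model_a: str, model_b: str) -> float:
        """log2 Bayes factor of ``model_a`` over ``model_b``."""
        return self.evidence(model_a).log2_evidence - self.evidence(model_b).log2_evidence

    def ratios_frame(self) -> pd.DataFrame:
        names = [e.model for e in self.evidences]
        vals = np.array([e.log2_evidence for e in self.evidences])
        return pd.DataFrame(vals[:, None] - vals[None, :], index=names, columns=names)

    def to_frame(self) -> pd.DataFrame:
        best = self.evidences[0].log2_evidence
        rows = []
        for rank, e in enumerate(self.evidences, start=1):
            rows.append(
                {
                    "model": e.model,
                    "class": e.spec.model_class,
                    "n_params": len(e.map_params),
                    "log2_evidence": e.log2_evidence,
                    "delta_log2": e.log2_evidence - best,
                    "map_params": ";".join(
                        f"{k}={v:.6g}" for k, v in e.map_params.items()
                    ),
                    "rank": rank,
                }
            )
        return pd.DataFrame(rows)


def compare_models(
    data: Dataset | Trial,
    models: Sequence[str] | None = None,
    priors: Mapping[str, Prior] | None = None,
    settings: IntegrationSettings | None = None,
    **kwargs,
) -> ComparisonTable:
    """Evidence for each candidate model, ranked.

    ``models`` defaults to the seven core models.  Keyword arguments are
    forwarded to :func:`log_marginal_likelihood`.
    """
    if models is None:
        models = [spec.name for spec in list_models()]
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    evidences = tuple(
        log_marginal_likelihood(m, data, priors, settings, **kwargs) for m in models
    )
    return ComparisonTable(evidences)


def _priors_header(priors: Mapping[str, Prior]) -> str:
    parts = [
        f"{name}~{p.kind}[{p.lo:.6g},{p.hi:.6g}]" for name, p in priors.items()
    ]
    return "priors: " + (", ".join(parts) if parts else "(none)")


class CrossingDecisionModel:
    """One candidate crossing-decision model bound to a dataset.

    Parameters
    ----------
    data
        :class:`~patchhop.eventlog.Dataset` (or single trial) of crossing
        events.
    model
        Registry name (``M0, S1, S2, S3, S4, D1, D2, C1``).
    priors
        Optional per-parameter prior overrides.
    memory_window_s
        Memory window tau for the recent-movers rule (D2), seconds.
    include_focal
        Whether a fish counts itself when comparing side occupancies.
    environment_mode
        ``"symmetric"`` (two identical patches) or ``"asymmetric"``
        (refuge vs open water, adds the side-bias factor ``b``).  By
        default inferred from the trial metadata.

    Examples
    --------
    >>> res = CrossingDecisionModel(data, "D1").fit()
    >>> res.log2_evidence, res.map_params["alpha"]
    """

    def __init__(
        self,
        data: Dataset | Trial,
        model: str = "D1",
        priors: Mapping[str, Prior] | None = None,
        *,
        memory_window_s: float = 3.5,
        include_focal: bool = False,
        environment_mode: str | None = None,
    ) -> None:
        self.data = data if isinstance(data, Dataset) else Dataset((data,))
        self.spec = get_model(model)
        self.priors = dict(priors) if priors else None
        self.memory_window_s = memory_window_s
        self.include_focal = include_focal
        if environment_mode is None:
            modes = {t.metadata.environment_mode for t in self.data} or {"symmetric"}
            environment_mode = (
                "asymmetric" if modes == {"asymmetric"} else "symmetric"
            )
        self.environment_mode = environment_mode

    @classmethod
    def from_csv(
        cls,
        events_path,
        metadata_path,
        roster_path=None,
        model: str = "D1",
        **kwargs,
    ) -> "CrossingDecisionModel":
        data = read_event_log(events_path, metadata_path, roster_path)
        return cls(data, model, **kwargs)

    def loglik(self, params: Mapping[str, float], base: float = 2.0) -> float:
        return log_likelihood(
            self.spec.name,
            params,
            self.data,
            base,
            include_focal=self.include_focal,
            memory_window_s=self.memory_window_s,
            environment_mode=self.environment_mode,
        )

    def fit(
        self,
        method: str = "grid",
        grid_points_per_dim: int = 513,
        mc_samples: int = 20000,
        seed: int = 0,
    ) -> "CrossingDecisionResults":
        settings = IntegrationSettings(
            method=method,
            grid_points_per_dim=grid_points_per_dim,
            mc_samples=mc_samples,
            rng_seed=seed,
        )
        evidence = log_marginal_likelihood(
            self.spec.name,
            self.data,
            self.priors,
            settings,
            memory_window_s=self.memory_window_s,
            include_focal=self.include_focal,
            environment_mode=self.environment_mode,
        )
        return CrossingDecisionResults(self, evidence)


class CrossingDecisionResults:
    """Fitted evidence, MAP parameters and posterior of one model."""

    def __init__(self, model: CrossingDecisionModel, evidence: ModelEvidence):
        self.model = model
        self.evidence = evidence

    @property
    def log2_evidence(self) -> float:
        return self.evidence.log2_evidence

    @property
    def map_params(self) -> dict[str, float]:
        return dict(self.evidence.map_params)

    @property
    def posterior(self) -> PosteriorGrid | None:
        return self.evidence.posterior

    def posterior_summary(self) -> pd.DataFrame:
        return posterior_summary(self.evidence)

    def loglik_at_map(self) -> float:
        return self.model.loglik(self.map_params)

    def simulate(
        self,
        group_size: int,
        initial_left: int,
        duration_s: float | None = 600.0,
        n_events: int | None = None,
        seed: int = 0,
        params: Mapping[str, float] | None = None,
        base_rate: float = 0.08,
    ) -> Trial:
        """Simulate one trial from this model (MAP parameters by default)."""
        from .simulate import SimulationDesign, simulate_trial

        design = SimulationDesign(
            group_size=group_size,
            initial_left=initial_left,
            model=self.evidence.model,
            params=dict(params if params is not None else self.map_params),
            duration_s=duration_s,
            n_events=n_events,
            base_rate=base_rate,
            seed=seed,
            environment_mode=self.model.environment_mode,
            memory_window_s=self.model.memory_window_s,
            include_focal=self.model.include_focal,
        )
        return simulate_trial(design)

    def summary(self) -> str:
        e = self.evidence
        lines = [
            "Crossing decision model fit",
            "===========================",
            f"model:            {e.model} ({e.spec.description})",
            f"events used:      {e.n_informative} informative decision points",
            f"integration:      {e.method}",
            f"{_priors_header(e.priors)}",
            f"log2 evidence:    {e.log2_evidence:.4f}",
        ]
        if e.map_params:
            lines.append(
                "MAP parameters:   "
                + ", ".join(f"{k}={v:.4g}" for k, v in e.map_params.items())
            )
        if e.posterior is not None:
            lines.append("")
            lines.append(posterior_summary(e).to_string())
        return "\n".join(lines)


class ModelComparison:
    """Fit several candidate models to one dataset and rank them."""

    def __init__(
        self,
        data: Dataset | Trial,
        models: Sequence[str] | None = None,
        priors: Mapping[str, Prior] | None = None,
        *,
        include_extensions: bool = False,
        memory_window_s: float = 3.5,
        include_focal: bool = False,
        environment_mode: str | None = None,
    ) -> None:
        if models is None:
            models = [s.name for s in list_models(include_extensions)]
        self.models = list(models)
        self._template = CrossingDecisionModel(
            data,
            self.models[0],
            priors,
            memory_window_s=memory_window_s,
            include_focal=include_focal,
            environment_mode=environment_mode,
        )
        self.priors = dict(priors) if priors else None

    def fit(
        self,
        method: str = "grid",
        grid_points_per_dim: int = 513,
        mc_samples: int = 20000,
        seed: int = 0,
    ) -> "ModelComparisonResults":
        t = self._template
        settings = IntegrationSettings(method, grid_points_per_dim, mc_samples, seed)
        table = compare_models(
            t.data,
            self.models,
            self.priors,
            settings,
            memory_window_s=t.memory_window_s,
            include_focal=t.include_focal,
            environment_mode=t.environment_mode,
        )
        return ModelComparisonResults(self, table)


class ModelComparisonResults:
    """Ranked evidences with summary table and bar plot."""

    def __init__(self, comparison: ModelComparison, table: ComparisonTable):
        self.comparison = comparison
        self.table = table

    @property
    def best_model(self) -> str:
        return self.table.best_model

    def to_frame(self) -> pd.DataFrame:
        return self.table.to_frame()

    def evidence_ratio(self, model_a: str, model_b: str) -> float:
        return self.table.evidence_ratio(model_a, model_b)

    def summary(self) -> str:
        priors = {}
        for e in self.table.evidences:
            priors.update(e.priors)
        lines = [
            "Model comparison (log2 marginal likelihoods)",
            "============================================",
            _priors_header(priors),
            f"best model: {self.best_model}",
            "",
            self.to_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of log2 evidences, best model first."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.to_frame()
        colors = ["#555555" if c in ("dynamic", "combined") else "#bbbbbb"
                  for c in frame["class"]]
        ax.bar(frame["model"], frame["log2_evidence"], color=colors)
        ax.set_ylabel(r"$\log_2 P(\mathcal{D}\,|\,M_i)$")
        ax.set_xlabel("model")
        return ax
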