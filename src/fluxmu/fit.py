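"""Flux estimation from measured isotopologue fractions.

Free net fluxes and exchange fluxes are estimated by minimizing the
variance-weighted sum of squared residuals between simulated and measured
IFs.  Goodness of fit is judged against a chi-square quantile at 95%
confidence with degrees of freedom equal to the number of independent
measurements minus the number of free fluxes; flux confidence intervals are
percentiles of Monte Carlo refits on noise-corrupted measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .emu import EMUSimulator, TracerSpec
from .errors import (
    InsufficientDataError,
    OptimizationFailureError,
    ScenarioError,
    UnidentifiableFluxError,
)
from .network import FluxNetwork

_MEAS_COLUMNS = ["metabolite", "iso", "value", "sd", "include", "inflation"]


@dataclass
class MeasurementSet:
    """Measured IFs with standard uncertainties, inclusion mask and inflation.

    The table has one row per (metabolite, isotopologue): ``value`` is the
    measured fraction, ``sd`` its analytical standard uncertainty,
    ``include`` whether the entry enters the fit, ``inflation`` a
    multiplicative factor on ``sd`` (biological-variance scenarios).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col, default in (("include", True), ("inflation", 1.0)):
            if col not in df.columns:
                df[col] = default
        missing = [c for c in _MEAS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table lacks columns {missing}")
        df = df[_MEAS_COLUMNS].reset_index(drop=True)
        bad = df[df["include"] & (df["sd"] <= 0)]
        if len(bad):
            raise ValueError(
                f"included measurements need sd > 0 (rows {list(bad.index)})"
            )
        self.data = df

    @classmethod
    def from_ifs(
        cls,
        ifs: Mapping[str, np.ndarray],
        sds: Mapping[str, np.ndarray] | float,
    ) -> "MeasurementSet":
        rows = []
        for met, vec in ifs.items():
            vec = np.asarray(vec, dtype=float)
            sd_vec = (
                np.full_like(vec, float(sds))
                if np.isscalar(sds)
                else np.asarray(sds[met], dtype=float)
            )
            for k, (v, s) in enumerate(zip(vec, sd_vec)):
                rows.append((met, k, float(v), float(s), True, 1.0))
        return cls(pd.DataFrame(rows, columns=_MEAS_COLUMNS))

    @property
    def metabolites(self) -> list[str]:
        return list(dict.fromkeys(self.data["metabolite"]))

    @property
    def included(self) -> pd.DataFrame:
        return self.data[self.data["include"]]

    def effective_sd(self) -> pd.Series:
        return self.data["sd"] * self.data["inflation"]

    @property
    def n_independent(self) -> int:
        """Included IFs minus one closure constraint per metabolite present."""
        inc = self.included
        return len(inc) - inc["metabolite"].nunique()

    def copy(self) -> "MeasurementSet":
        return MeasurementSet(self.data.copy())


@dataclass(frozen=True)
class ScenarioSpec:
    """Measurement-set manipulations applied before fitting, in order.

    1. mask IFs below ``abundance_threshold`` (None keeps everything);
    2. multiply all SDs by ``sd_inflation`` (biological-variance proxy);
    3. reset inflation to 1 for ``keep_analytical`` entries (metabolite, iso)
       so critical analytes keep their analytical precision.
    """

    abundance_threshold: float | None = 0.02
    sd_inflation: float = 1.0
    keep_analytical: tuple[tuple[str, int], ...] = ()


def scenario_engine(meas: MeasurementSet, spec: ScenarioSpec) -> MeasurementSet:
    """Apply a :class:`ScenarioSpec` and return a new measurement set."""
    df = meas.data.copy()
    if spec.abundance_threshold is not None:
        df["include"] = df["include"] & (df["value"] >= spec.abundance_threshold)
    df["inflation"] = float(spec.sd_inflation)
    for met, iso in spec.keep_analytical:
        sel = (df["metabolite"] == met) & (df["iso"] == iso)
        df.loc[sel, "inflation"] = 1.0
    if not df["include"].any():
        raise ScenarioError("scenario masks every measurement")
    return MeasurementSet(df)


# ----------------------------------------------------------------------
@dataclass
class FitResult:
    """Point estimate of the flux fit plus goodness-of-fit bookkeeping."""

    param_names: list[str]
    theta: np.ndarray
    nets: dict[str, float]
    exchanges: dict[str, float]
    ssr: float
    dof: int
    chi2_critical: float
    chi2_pass: bool | None  #: None when dof <= 0 (no test possible)
    residuals: pd.DataFrame  #: metabolite, iso, measured, simulated, weighted
    jacobian: np.ndarray  #: weighted residual Jacobian at the optimum
    n_free: int
    seed: int | None = None
    restarts: int = 1
    n_failed_starts: int = 0
    fixed_exchanges: dict[str, float] = field(default_factory=dict)

    @property
    def weighted_residuals(self) -> np.ndarray:
        return self.residuals["weighted"].to_numpy()


def chi2_gof(ssr: float, n_meas: int, n_free: int, alpha: float = 0.05) -> tuple[bool, float]:
    """Chi-square goodness-of-fit verdict: (passed, critical value)."""
    dof = n_meas - n_free
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({n_meas} - {n_free})")
    crit = float(stats.chi2.ppf(1.0 - alpha, dof))
    return ssr <= crit, crit


class _Problem:
    """Parameter packing and residual evaluation for one (network, measurement) pair."""

    def __init__(
        self,
        network: FluxNetwork,
        meas: MeasurementSet,
        tracer: TracerSpec,
        basis_value: float = 1.0,
        exch_cap: float = 0.99,
        fixed_exchanges: Mapping[str, float] | None = None,
    ):
        self.network = network
        self.meas = meas
        self.tracer = tracer
        self.basis_value = basis_value
        self.exch_cap = exch_cap
        self.fixed_exchanges = dict(fixed_exchanges or {})
        self.sim = EMUSimulator(network, meas.metabolites, tracer)
        basis = network.basis_reaction
        self.free_nets = [r for r in network.free_reactions if r != basis]
        self.rev = [
            r for r in network.reversible_reactions if r not in self.fixed_exchanges
        ]
        self.param_names = [f"net {r}" for r in self.free_nets] + [
            f"exch {r}" for r in self.rev
        ]
        self.lb = np.zeros(len(self.param_names))
        self.ub = np.concatenate(
            [np.full(len(self.free_nets), basis_value), np.full(len(self.rev), exch_cap)]
        )
        inc = meas.included
        self._inc_idx = [
            (row.metabolite, int(row.iso)) for row in inc.itertuples()
        ]
        self._values = inc["value"].to_numpy()
        self._sds = (inc["sd"] * inc["inflation"]).to_numpy()

    def unpack(self, theta: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
        k = len(self.free_nets)
        free = {r: float(v) for r, v in zip(self.free_nets, theta[:k])}
        if self.network.basis_reaction:
            free[self.network.basis_reaction] = self.basis_value
        nets = self.network.solve_net(free)
        # bounded transform u -> u/(1-u): u in [0, 0.99] covers exchanges 0..99
        exch = {
            r: float(u / (1.0 - u)) for r, u in zip(self.rev, theta[k:])
        }
        exch.update(self.fixed_exchanges)
        return nets, exch

    def pack_exchange(self, exch: Mapping[str, float]) -> np.ndarray:
        return np.array([exch.get(r, 0.0) / (1.0 + exch.get(r, 0.0)) for r in self.rev])

    def simulated(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        nets, exch = self.unpack(theta)
        return self.sim.simulate(nets, exch)

    def residual(self, theta: np.ndarray, values: np.ndarray | None = None) -> np.ndarray:
        ifs = self.simulated(theta)
        vals = self._values if values is None else values
        sim = np.array([ifs[m][k] for m, k in self._inc_idx])
        return (sim - vals) / self._sds

    def perturbed_values(self, rng: np.random.Generator, renormalize: bool = False) -> np.ndarray:
        vals = self._values + rng.normal(0.0, self._sds)
        if renormalize:
            out = vals.copy()
            mets = np.array([m for m, _ in self._inc_idx])
            for met in np.unique(mets):
                sel = mets == met
                tot = out[sel].sum()
                if tot > 0:
                    out[sel] /= tot
            vals = out
        return vals


def fit_fluxes(
    network: FluxNetwork,
    meas: MeasurementSet,
    tracer: TracerSpec,
    restarts: int = 20,
    seed: int | None = None,
    x0: np.ndarray | None = None,
    basis_value: float = 1.0,
    alpha: float = 0.05,
    fixed_exchanges: Mapping[str, float] | None = None,
) -> FitResult:
    """Multistart weighted least-squares flux estimation.

    ``fixed_exchanges`` pins selected exchange fluxes instead of fitting
    them (structurally unidentifiable directions, e.g. an aldolase
    recombination exchange when both product pools are measured).
    """
    if meas.n_independent < 1:
        raise InsufficientDataError("no included measurements")
    prob = _Problem(
        network, meas, tracer, basis_value=basis_value, fixed_exchanges=fixed_exchanges
    )
    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    else:
        starts.append(0.5 * (prob.lb + prob.ub))
    while len(starts) < max(restarts, 1):
        starts.append(rng.uniform(prob.lb, prob.ub))

    best = None
    n_failed = 0
    for s in starts:
        try:
            res = optimize.least_squares(
                prob.residual, s, bounds=(prob.lb, prob.ub), method="trf", xtol=1e-12
            )
        except Exception:
            n_failed += 1
            continue
        if not res.success:
            n_failed += 1
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise OptimizationFailureError(
            f"all {len(starts)} starts failed (last residual could not be evaluated)"
        )

    theta = best.x
    nets, exch = prob.unpack(theta)
    ssr = float(2.0 * best.cost)
    n_free = len(prob.param_names)
    n_ind = meas.n_independent
    if n_ind > n_free:
        passed, crit = chi2_gof(ssr, n_ind, n_free, alpha=alpha)
    else:  # saturated/underdetermined problem: no test possible
        passed, crit = None, float("nan")
    ifs = prob.simulated(theta)
    inc = meas.included
    resid_df = pd.DataFrame(
        {
            "metabolite": inc["metabolite"].to_numpy(),
            "iso": inc["iso"].to_numpy(),
            "measured": inc["value"].to_numpy(),
            "simulated": [ifs[m][k] for m, k in prob._inc_idx],
        }
    )
    resid_df["weighted"] = (resid_df["simulated"] - resid_df["measured"]) / prob._sds
    return FitResult(
        param_names=prob.param_names,
        theta=theta,
        nets=nets,
        exchanges=exch,
        ssr=ssr,
        dof=n_ind - n_free,
        chi2_critical=crit,
        chi2_pass=passed,
        residuals=resid_df,
        jacobian=best.jac,
        n_free=n_free,
        seed=seed,
        restarts=len(starts),
        n_failed_starts=n_failed,
        fixed_exchanges=dict(fixed_exchanges or {}),
    )


# ----------------------------------------------------------------------
@dataclass
class ConfidenceIntervals:
    """Percentile confidence intervals of Monte Carlo refits."""

    table: pd.DataFrame  #: index flux name; point, lo, hi, width
    n_samples: int
    n_failed: int
    seed: int | None

    @property
    def failure_warning(self) -> bool:
        return self.n_failed > 0.2 * self.n_samples


def mc_confidence_intervals(
    network: FluxNetwork,
    meas: MeasurementSet,
    tracer: TracerSpec,
    fit: FitResult,
    n_samples: int = 10_000,
    seed: int | None = None,
    renormalize: bool = False,
    alpha: float = 0.05,
) -> ConfidenceIntervals:
    """CIs from refits on measurements corrupted with normal noise.

    Noise is drawn independently per included IF on the fraction scale (no
    renormalization by default).  Each replicate is refit from the point
    estimate; non-convergent replicates are counted and skipped.
    """
    prob = _Problem(network, meas, tracer, fixed_exchanges=fit.fixed_exchanges)
    rng = np.random.default_rng(seed)
    names = [f"net {r}" for r in network.by_id] + [
        f"exch {r}" for r in network.reversible_reactions
    ]
    draws = []
    n_failed = 0
    for _ in range(n_samples):
        vals = prob.perturbed_values(rng, renormalize=renormalize)
        try:
            res = optimize.least_squares(
                lambda t: prob.residual(t, values=vals),
                fit.theta,
                bounds=(prob.lb, prob.ub),
                method="trf",
            )
        except Exception:
            n_failed += 1
            continue
        if not res.success:
            n_failed += 1
            continue
        nets, exch = prob.unpack(res.x)
        draws.append(
            [nets[r] for r in network.by_id]
            + [exch[r] for r in network.reversible_reactions]
        )
    if not draws:
        raise OptimizationFailureError("every CI replicate failed to refit")
    arr = np.asarray(draws)
    lo, hi = np.percentile(arr, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    point = np.array(
        [fit.nets[r] for r in network.by_id]
        + [fit.exchanges[r] for r in network.reversible_reactions]
    )
    table = pd.DataFrame(
        {"point": point, "lo": lo, "hi": hi, "width": hi - lo}, index=names
    )
    return ConfidenceIntervals(table, n_samples, n_failed, seed)


# ----------------------------------------------------------------------
@dataclass
class ResidualDiagnostics:
    residuals: np.ndarray
    mean: float
    sd: float
    shapiro_stat: float
    shapiro_p: float
    plotting_positions: np.ndarray  #: theoretical normal quantiles
    ordered_residuals: np.ndarray


def residual_diagnostics(fit_or_residuals: FitResult | np.ndarray) -> ResidualDiagnostics:
    """Normality report for the standard-deviation-weighted residuals.

    A well-specified model yields residuals with mean 0 and SD 1; systematic
    deviations flag model error or mis-stated measurement uncertainties.
    """
    r = (
        fit_or_residuals.weighted_residuals
        if isinstance(fit_or_residuals, FitResult)
        else np.asarray(fit_or_residuals, dtype=float)
    )
    if r.size < 3:
        raise InsufficientDataError("need at least 3 residuals")
    if np.ptp(r) == 0:
        raise ValueError("residuals are constant; normality test degenerate")
    w, p = stats.shapiro(r)
    ordered = np.sort(r)
    pp = stats.norm.ppf((np.arange(1, r.size + 1) - 0.5) / r.size)
    return ResidualDiagnostics(
        residuals=r,
        mean=float(r.mean()),
        sd=float(r.std(ddof=1)),
        shapiro_stat=float(w),
        shapiro_p=float(p),
        plotting_positions=pp,
        ordered_residuals=ordered,
    )


def contribution_matrix(fit: FitResult) -> pd.DataFrame:
    """Share (%) of each flux parameter's variance due to each measurement.

    With J the weighted residual Jacobian at the optimum, the linearized
    estimator has covariance C = (J'J)^-1 and gain K = C J'; measurement m
    contributes K[j, m]^2 / C[j, j] of parameter j's variance (weighted
    measurements have unit variance).  Columns sum to 100 per parameter.
    """
    J = np.asarray(fit.jacobian, dtype=float)
    JtJ = J.T @ J
    cond = np.linalg.cond(JtJ)
    if not np.isfinite(cond) or cond > 1e12:
        _, _, vt = np.linalg.svd(JtJ)
        null = {n: round(float(v), 4) for n, v in zip(fit.param_names, vt[-1])}
        raise UnidentifiableFluxError(
            f"Fisher information singular (cond={cond:.2e}); null direction {null}"
        )
    C = np.linalg.inv(JtJ)
    K = C @ J.T  # params x measurements
    shares = 100.0 * K**2 / np.diag(C)[:, None]
    labels = [
        f"{m} M+{k}" for m, k in zip(fit.residuals["metabolite"], fit.residuals["iso"])
    ]
    return pd.DataFrame(shares.T, index=labels, columns=fit.param_names)


# ----------------------------------------------------------------------
class FluxEstimator(BaseEstimator):
    """Scikit-learn style estimator for flux fitting.

    Parameters
    ----------
    network : FluxNetwork
    tracer : TracerSpec
    restarts : int
        Multistart count for the point estimate.
    scenario : ScenarioSpec or None
        Applied to the measurement set before fitting.
    seed : int or None
    alpha : float
        Significance level of the chi-square test and CIs.

    Fitted attributes: ``fluxes_`` (net flux dict), ``exchanges_``,
    ``ssr_``, ``dof_``, ``chi2_critical_``, ``chi2_pass_``, ``residuals_``,
    ``result_`` (the full :class:`FitResult`).
    """

    def __init__(
        self,
        network: FluxNetwork,
        tracer: TracerSpec,
        restarts: int = 20,
        scenario: ScenarioSpec | None = None,
        seed: int | None = None,
        alpha: float = 0.05,
        fixed_exchanges: Mapping[str, float] | None = None,
    ):
        self.network = network
        self.tracer = tracer
        self.restarts = restarts
        self.scenario = scenario
        self.seed = seed
        self.alpha = alpha
        self.fixed_exchanges = fixed_exchanges

    def fit(self, X: MeasurementSet | pd.DataFrame, y=None) -> "FluxEstimator":
        meas = X if isinstance(X, MeasurementSet) else MeasurementSet(X)
        if self.scenario is not None:
            meas = scenario_engine(meas, self.scenario)
        self.measurements_ = meas
        self.result_ = fit_fluxes(
            self.network,
            meas,
            self.tracer,
            restarts=self.restarts,
            seed=self.seed,
            alpha=self.alpha,
            fixed_exchanges=self.fixed_exchanges,
        )
        self.fluxes_ = self.result_.nets
        self.exchanges_ = self.result_.exchanges
        self.ssr_ = self.result_.ssr
        self.dof_ = self.result_.dof
        self.chi2_critical_ = self.result_.chi2_critical
        self.chi2_pass_ = self.result_.chi2_pass
        self.residuals_ = self.result_.residuals
        return self

    def predict(self, X=None) -> pd.DataFrame:
        """Simulated IFs at the fitted fluxes (tidy frame)."""
        sim = EMUSimulator(self.network, self.measurements_.metabolites, self.tracer)
        ifs = sim.simulate(self.fluxes_, self.exchanges_)
        rows = [
            (met, k, float(v)) for met, vec in ifs.items() for k, v in enumerate(vec)
        ]
        return pd.DataFrame(rows, columns=["metabolite", "iso", "if_sim"])

    def confidence_intervals(
        self, n_samples: int = 10_000, seed: int | None = None, renormalize: bool = False
    ) -> ConfidenceIntervals:
        return mc_confidence_intervals(
            self.network,
            self.measurements_,
            self.tracer,
            self.result_,
            n_samples=n_samples,
            seed=self.seed if seed is None else seed,
            renormalize=renormalize,
            alpha=self.alpha,
        )

    def contribution_matrix(self) -> pd.DataFrame:
        return contribution_matrix(self.result_)

    def diagnostics(self) -> ResidualDiagnostics:
        return residual_diagnostics(self.result_)
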