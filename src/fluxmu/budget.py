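"""Monte Carlo uncertainty budgeting of isotopologue fractions.

Each iteration draws every uncertainty component (ion counting, peak
integration, ionization, natural abundances), forms the intermediate areas,
runs the interference-correction cascade with clamping, normalizes to
isotopologue fractions, and accumulates the output distribution.  The
variance-contribution analysis ranks components by their squared Spearman
rank correlation with each output, normalized to 100% — the tornado-style
decomposition of spreadsheet risk add-ins, robust to the clamping
nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .abundances import IsotopeAbundances
from .correction import (
    DerivativeComposition,
    build_shift_distribution,
    cascade_correct,
)
from .errors import UndefinedRatioError
from .uncertainty import TRIANGULAR_HALF_WIDTH_FACTOR, MeasurementModel

DEFAULT_ITERATIONS = 100_000


@dataclass
class BudgetResult:
    """Per-IF uncertainty budget of one metabolite."""

    metabolite: str
    summary: pd.DataFrame  #: index M+k; mean, sd, rel_combined_pct, p2.5, p97.5
    shares: pd.DataFrame  #: variance-contribution shares (%), component x IF
    n_iter: int
    seed: int | None
    corrected: bool

    def relative_combined_uncertainty(self, k: int) -> float:
        """Relative combined uncertainty (%) of IF M+k."""
        return float(self.summary.loc[f"M+{k}", "rel_combined_pct"])


def contribution_shares(
    component_draws: Mapping[str, np.ndarray], output: np.ndarray
) -> pd.Series:
    """Variance-contribution shares (%) of input components for one output.

    Squared Spearman rank correlation between each component's draws and the
    output draws, normalized across components to sum to 100.  Returns
    all-NaN shares when the output has zero variance.
    """
    out = np.asarray(output, dtype=float)
    names = list(component_draws)
    if np.std(out) == 0:
        return pd.Series(np.nan, index=names)
    r_out = rankdata(out)
    r_out = (r_out - r_out.mean()) / (r_out.std() or 1.0)
    sq = np.empty(len(names))
    for i, name in enumerate(names):
        x = np.asarray(component_draws[name], dtype=float)
        r_x = rankdata(x)
        s = r_x.std()
        if s == 0:  # constant component: no contribution
            sq[i] = 0.0
            continue
        r_x = (r_x - r_x.mean()) / s
        sq[i] = float(np.mean(r_x * r_out)) ** 2
    total = sq.sum()
    if total == 0:
        return pd.Series(np.nan, index=names)
    return pd.Series(100.0 * sq / total, index=names)


def _draw_components(
    model: MeasurementModel,
    ab: IsotopeAbundances,
    n_iter: int,
    rng: np.random.Generator,
    abundance_draws: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
) -> tuple[np.ndarray, dict[str, np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """All component draws plus the intermediate areas they produce."""
    n_iso = model.raw_areas.size
    components: dict[str, np.ndarray] = {}

    if model.poisson:
        a_raw = rng.poisson(model.raw_areas, size=(n_iter, n_iso)).astype(float)
    else:
        a_raw = np.broadcast_to(model.raw_areas, (n_iter, n_iso)).copy()
    for k in range(n_iso):
        components[f"counting M+{k}"] = a_raw[:, k]

    s_eff = model.effective_integration_sds()
    if model.shared_integration:
        u = rng.random((n_iter, 1)) - rng.random((n_iter, 1))
        f_int = 1.0 + TRIANGULAR_HALF_WIDTH_FACTOR * s_eff * u
        components["integration"] = u[:, 0]
    else:
        u = rng.random((n_iter, n_iso)) - rng.random((n_iter, n_iso))
        f_int = 1.0 + TRIANGULAR_HALF_WIDTH_FACTOR * s_eff * u
        for k in range(n_iso):
            components[f"integration M+{k}"] = u[:, k]

    if model.ion_sd > 0:
        f_ion = rng.normal(1.0, model.ion_sd, size=(n_iter, n_iso))
        for k in range(n_iso):
            components[f"ionization M+{k}"] = f_ion[:, k]
    else:
        f_ion = 1.0

    if abundance_draws is None:
        abundance_draws = draw_abundances(ab, n_iter, rng)
    a_s, b_s, c_s = abundance_draws
    components["abundance a (30Si)"] = a_s
    components["abundance b (29Si)"] = b_s
    components["abundance c (13C)"] = c_s

    areas = a_raw * f_int * f_ion
    return areas, components, abundance_draws


def draw_abundances(
    ab: IsotopeAbundances, n_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normal draws of a, b, c — one set per iteration, shared by all metabolites."""
    a = rng.normal(ab.a, ab.u_a, n_iter) if ab.u_a > 0 else np.full(n_iter, ab.a)
    b = rng.normal(ab.b, ab.u_b, n_iter) if ab.u_b > 0 else np.full(n_iter, ab.b)
    c = rng.normal(ab.c, ab.u_c, n_iter) if ab.u_c > 0 else np.full(n_iter, ab.c)
    return a, b, c


def _summarize(
    metabolite: str,
    ifs: np.ndarray,
    components: Mapping[str, np.ndarray],
    n_iter: int,
    seed: int | None,
    corrected: bool,
) -> BudgetResult:
    n_iso = ifs.shape[1]
    index = [f"M+{k}" for k in range(n_iso)]
    mean = ifs.mean(axis=0)
    sd = ifs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean != 0, 100.0 * sd / np.abs(mean), np.nan)
    lo, hi = np.percentile(ifs, [2.5, 97.5], axis=0)
    summary = pd.DataFrame(
        {"mean": mean, "sd": sd, "rel_combined_pct": rel, "p2.5": lo, "p97.5": hi},
        index=index,
    )
    shares = pd.DataFrame(
        {f"M+{k}": contribution_shares(components, ifs[:, k]) for k in range(n_iso)}
    )
    return BudgetResult(metabolite, summary, shares, n_iter, seed, corrected)


def run_budget(
    areas: np.ndarray,
    comp: DerivativeComposition,
    model: MeasurementModel | None = None,
    ab: IsotopeAbundances | None = None,
    n_iter: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    abundance_draws: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    clamp: bool = True,
) -> BudgetResult:
    """MC uncertainty budget of the corrected isotopologue fractions.

    ``areas`` are the integrated raw areas M+0..M+n (ion counts).  A
    default :class:`MeasurementModel` is built from them when none is given.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    areas = np.asarray(areas, dtype=float)
    if areas.sum() <= 0:
        raise UndefinedRatioError(f"{comp.metabolite}: all-zero areas")
    ab = ab or IsotopeAbundances()
    model = model or MeasurementModel(raw_areas=areas)
    rng = rng or np.random.default_rng(seed)

    inter, components, ab_draws = _draw_components(model, ab, n_iter, rng, abundance_draws)
    dist = build_shift_distribution(comp)
    n_iso = areas.size
    coeffs = np.empty((n_iter, n_iso))
    coeffs[:, 0] = 1.0
    a_s, b_s, c_s = ab_draws
    for k in range(1, n_iso):
        coeffs[:, k] = dist.coefficient_samples(k, a_s, b_s, c_s)
    corrected, _, flags = cascade_correct(inter, coeffs, clamp=clamp)
    retained = corrected * flags
    totals = retained.sum(axis=1)
    if np.all(totals <= 0):
        raise UndefinedRatioError(f"{comp.metabolite}: corrected areas sum to zero")
    safe = np.where(totals > 0, totals, np.nan)
    ifs = retained / safe[:, None]
    return _summarize(comp.metabolite, ifs, components, n_iter, seed, corrected=True)


def uncorrected_budget(
    areas: np.ndarray,
    model: MeasurementModel | None = None,
    ab: IsotopeAbundances | None = None,
    n_iter: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    abundance_draws: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> BudgetResult:
    """Budget of the *measured* IFs, skipping the correction cascade."""
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    areas = np.asarray(areas, dtype=float)
    if areas.sum() <= 0:
        raise UndefinedRatioError("all-zero areas")
    ab = ab or IsotopeAbundances()
    model = model or MeasurementModel(raw_areas=areas)
    rng = rng or np.random.default_rng(seed)
    inter, components, _ = _draw_components(model, ab, n_iter, rng, abundance_draws)
    totals = inter.sum(axis=1)
    safe = np.where(totals > 0, totals, np.nan)
    ifs = inter / safe[:, None]
    return _summarize("(uncorrected)", ifs, components, n_iter, seed, corrected=False)


def run_budgets(
    area_table: Mapping[str, np.ndarray],
    compositions: Mapping[str, DerivativeComposition],
    models: Mapping[str, MeasurementModel] | None = None,
    ab: IsotopeAbundances | None = None,
    n_iter: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
) -> dict[str, BudgetResult]:
    """Budgets for several metabolites with shared abundance draws.

    Natural abundances are physical constants, so one set of (a, b, c) draws
    per iteration is shared across all metabolites; counting, integration
    and ionization draws are independent per metabolite.
    """
    ab = ab or IsotopeAbundances()
    rng = np.random.default_rng(seed)
    shared = draw_abundances(ab, n_iter, rng)
    results = {}
    for met, areas in area_table.items():
        model = models.get(met) if models else None
        results[met] = run_budget(
            np.asarray(areas, dtype=float),
            compositions[met],
            model=model,
            ab=ab,
            n_iter=n_iter,
            seed=seed,
            rng=rng,
            abundance_draws=shared,
        )
    return results
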