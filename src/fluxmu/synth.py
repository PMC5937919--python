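"""Synthetic GC-MS isotopologue data with the pipeline's assumed structure.

Runs the measurement chain *forwards*: simulate backbone labeling from a
ground-truth flux distribution, convolve with each derivative's
natural-abundance envelope, scale to ion counts, and perturb with the
counting / integration / ionization noise model.  Every generator records
its ground truth so downstream stages can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .abundances import IsotopeAbundances
from .correction import DerivativeComposition, build_shift_distribution, forward_convolve
from .emu import EMUSimulator, TracerSpec, glucose_1_6_13c2, unlabeled_tracer
from .fit import MeasurementSet
from .network import FluxNetwork
from .uncertainty import MeasurementModel


@dataclass
class SyntheticScenario:
    """Ground truth plus noise settings for one simulated experiment."""

    name: str
    free_nets: dict[str, float]  #: free net fluxes (basis uptake implied = 1)
    exchanges: dict[str, float]
    tracer: TracerSpec
    total_counts: float = 1.0e6  #: summed measured area per metabolite (ion counts)
    integration_sd: float = 0.02
    ion_sd: float = 0.01
    bio_replicates: int = 3
    bio_sd: float = 0.0  #: lognormal sigma of between-replicate IF multipliers
    poisson: bool = True  #: ion-counting noise (off = noise-free forward model)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.total_counts <= 0:
            raise ValueError("total_counts must be positive")
        if self.bio_replicates < 1:
            raise ValueError("need at least one replicate")


def reference_scenario(seed: int | None = 0, **overrides) -> SyntheticScenario:
    """[1,6-13C2]glucose experiment with an active PPP branch.

    The PPP split (G6PDH / uptake = 0.25) and moderate exchange fluxes are
    representative of a glucose-grown yeast; see the methods note.
    """
    defaults = dict(
        name="reference",
        free_nets={"G6PDH": 0.25},
        exchanges={
            "PGI": 0.5,
            "FBA": 0.1,
            "TPI": 2.0,
            "RPE": 0.3,
            "RPI": 0.3,
            "TKT1": 0.1,
            "TKT2": 0.1,
            "TALA": 0.1,
        },
        tracer=glucose_1_6_13c2(),
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticScenario(**defaults)


def unlabeled_scenario(seed: int | None = 0, **overrides) -> SyntheticScenario:
    """Unlabeled standard: every backbone stays at M+0; isolates the envelope."""
    defaults = dict(
        name="unlabeled_standard",
        free_nets={"G6PDH": 0.25},
        exchanges={"PGI": 0.5, "TPI": 2.0},
        tracer=unlabeled_tracer(),
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticScenario(**defaults)


def low_abundance_scenario(seed: int | None = 0, **overrides) -> SyntheticScenario:
    """Pathologically low ion counts: clamping of overcorrected IFs triggers."""
    defaults = dict(
        name="low_abundance_clamping",
        free_nets={"G6PDH": 0.25},
        exchanges={"PGI": 0.5, "TPI": 2.0},
        tracer=glucose_1_6_13c2(),
        total_counts=2.0e3,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticScenario(**defaults)


@dataclass
class SyntheticDataset:
    """Raw area replicates plus the ground truth that generated them."""

    areas: dict[str, np.ndarray]  #: metabolite -> (n_replicates, n_isotopologues)
    backbone_ifs: dict[str, np.ndarray]  #: noise-free tracer-derived IFs
    true_areas: dict[str, np.ndarray]  #: noise-free measured-window areas
    nets: dict[str, float]
    exchanges: dict[str, float]
    scenario: SyntheticScenario

    def mean_areas(self) -> dict[str, np.ndarray]:
        return {m: a.mean(axis=0) for m, a in self.areas.items()}


def generate_raw_areas(
    scenario: SyntheticScenario,
    network: FluxNetwork,
    compositions: Mapping[str, DerivativeComposition],
    ab: IsotopeAbundances | None = None,
    targets: list[str] | None = None,
) -> SyntheticDataset:
    """Forward-simulate raw isotopologue peak areas for every measured pool."""
    ab = ab or IsotopeAbundances()
    rng = np.random.default_rng(scenario.seed)
    targets = targets or list(compositions)
    sim = EMUSimulator(network, targets, scenario.tracer)
    nets = network.solve_net(scenario.free_nets)
    ifs = sim.simulate(nets, scenario.exchanges)

    areas: dict[str, np.ndarray] = {}
    true_areas: dict[str, np.ndarray] = {}
    for met in targets:
        comp = compositions[met]
        dist = build_shift_distribution(comp)
        backbone = ifs[met]
        reps = []
        measured = forward_convolve(backbone, dist, ab)
        scale = scenario.total_counts / measured.sum()
        true_areas[met] = scale * measured
        for _ in range(scenario.bio_replicates):
            x = backbone
            if scenario.bio_sd > 0:
                mult = rng.lognormal(0.0, scenario.bio_sd, size=backbone.size)
                x = backbone * mult
                x = x / x.sum()
            window = forward_convolve(x, dist, ab)
            target = scenario.total_counts * window / window.sum()
            model = MeasurementModel(
                raw_areas=target,
                integration_sd=scenario.integration_sd,
                ion_sd=scenario.ion_sd,
                poisson=scenario.poisson,
            )
            reps.append(model.sample_intermediate_areas(rng, n_draws=1)[0])
        areas[met] = np.asarray(reps)
    return SyntheticDataset(
        areas=areas,
        backbone_ifs={m: ifs[m] for m in targets},
        true_areas=true_areas,
        nets=nets,
        exchanges=dict(scenario.exchanges),
        scenario=scenario,
    )


def generate_validation_pairs(
    n_pairs: int = 30,
    n_replicates: int = 6,
    true_slope: float = 0.015,
    area_range: tuple[float, float] = (1.0e4, 1.0e7),
    seed: int | None = 0,
) -> tuple[np.ndarray, float]:
    """(area, replicate SD) pairs with a known proportional noise component.

    Mimics method-validation data: each nominal area is measured
    ``n_replicates`` times under Poisson counting plus a proportional
    ionization factor of relative SD ``true_slope``; the empirical SD is
    paired with the mean area.  Returns (pairs, true_slope) for
    slope-recovery tests of the ionization-factor regression.
    """
    if n_pairs < 5:
        raise ValueError("need at least 5 areas")
    rng = np.random.default_rng(seed)
    nominal = np.geomspace(area_range[0], area_range[1], n_pairs)
    pairs = np.empty((n_pairs, 2))
    for i, mu in enumerate(nominal):
        counts = rng.poisson(mu, size=n_replicates).astype(float)
        factors = rng.normal(1.0, true_slope, size=n_replicates) if true_slope > 0 else 1.0
        reps = counts * factors
        pairs[i] = (reps.mean(), reps.std(ddof=1))
    return pairs, true_slope


def measurement_set_from_scenario(
    scenario: SyntheticScenario,
    network: FluxNetwork,
    targets: list[str],
    rel_sd: float = 0.02,
    abs_sd_floor: float = 0.002,
    noise: bool = True,
    renormalize: bool = True,
    seed: int | None = None,
) -> tuple[MeasurementSet, dict[str, float], dict[str, float]]:
    """Measurement set drawn around the scenario's true labeling.

    SDs follow the ~2% relative precision typical of the analytical method
    with a small absolute floor for near-zero fractions; when ``noise`` is
    on, values are the truth plus N(0, sd) on the fraction scale.  Measured
    fractions are normalized quantities, so each metabolite's noisy vector
    is renormalized to sum to 1 by default (the closure constraint the
    degrees-of-freedom bookkeeping assumes).  Returns (measurements, true
    nets, true exchanges).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    sim = EMUSimulator(network, targets, scenario.tracer)
    nets = network.solve_net(scenario.free_nets)
    ifs = sim.simulate(nets, scenario.exchanges)
    values = {}
    sds = {}
    for met in targets:
        truth = ifs[met]
        sd = np.maximum(rel_sd * np.abs(truth), abs_sd_floor)
        vals = truth + rng.normal(0.0, sd) if noise else truth.copy()
        if noise and renormalize:
            vals = vals / vals.sum()
        values[met] = vals
        sds[met] = sd
    return MeasurementSet.from_ifs(values, sds), nets, dict(scenario.exchanges)
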