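"""Measurement-uncertainty components of isotopologue peak areas.

The intermediate area entering the interference correction is modelled as

    A_n = A_n_raw * f_int * f_n_ion

where ``A_n_raw`` is Poisson ion-counting noise around the integrated raw
area, ``f_int`` a triangular peak-integration factor (expectation 1) and
``f_n_ion`` a normal ionization/ion-transmission factor (expectation 1)
drawn independently per isotopologue.  The empirical 2% integration
repeatability already includes counting noise, so the triangular scale is
deflated by the Poisson relative variance of the same peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import InsufficientDataError

DistributionKind = Literal["poisson", "triangular", "normal", "constant"]

#: Empirical relative standard uncertainty of automated peak integration.
DEFAULT_INTEGRATION_SD = 0.02

#: Half-width over SD for a symmetric triangular distribution.
TRIANGULAR_HALF_WIDTH_FACTOR = math.sqrt(6.0)


@dataclass(frozen=True)
class UncertaintyComponent:
    """One uncertainty component: a named distribution with a standard uncertainty."""

    name: str
    kind: DistributionKind
    location: float = 1.0
    scale: float = 0.0  #: standard uncertainty in the units of the quantity

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError(f"{self.name}: scale must be >= 0")


def fit_ion_factor(
    areas: Sequence[float], sds: Sequence[float] | None = None
) -> float:
    """Relative standard uncertainty of the ionization/ion-transmission factor.

    Replicate validation data (integrated area, replicate SD) are regressed
    through the origin; the slope is the relative SD of ``f_ion``.  Accepts
    either two sequences or one sequence of (area, sd) pairs.
    """
    if sds is None:
        pairs = np.asarray(areas, dtype=float)
        areas, sds = pairs[:, 0], pairs[:, 1]
    areas = np.asarray(areas, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if areas.size < 3:
        raise InsufficientDataError("need at least 3 (area, SD) pairs")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    # OLS through the origin: slope = <x y> / <x^2>
    return float(areas @ sds / (areas @ areas))


def effective_integration_sd(
    a_raw: float | np.ndarray, base_sd: float = DEFAULT_INTEGRATION_SD
) -> float | np.ndarray:
    """Integration relative SD with the counting-statistics part removed.

    The empirical repeatability ``base_sd`` of automated integration already
    contains Poisson noise (relative variance 1/A); since counting noise is
    modelled separately, the triangular factor keeps only the excess:
    ``sqrt(max(0, base_sd**2 - 1/A_raw))``.
    """
    a = np.asarray(a_raw, dtype=float)
    if np.any(a <= 0):
        raise ValueError("raw area must be positive")
    out = np.sqrt(np.maximum(0.0, base_sd**2 - 1.0 / a))
    return float(out) if np.isscalar(a_raw) else out


def sample_triangular_factor(
    rng: np.random.Generator, sd: float | np.ndarray, size=None
) -> np.ndarray:
    """Symmetric triangular factor, mode 1, standard deviation ``sd``.

    The half-width is ``sd * sqrt(6)`` so the SD equals the stated standard
    uncertainty.  Implemented as 1 + w*(U1 - U2), whose density is the
    symmetric triangle on [1-w, 1+w].
    """
    u = rng.random(size) - rng.random(size)
    return 1.0 + TRIANGULAR_HALF_WIDTH_FACTOR * np.asarray(sd) * u


@dataclass
class MeasurementModel:
    """Noise model for one metabolite's isotopologue areas.

    Parameters
    ----------
    raw_areas : array
        Integrated raw areas (ion counts) for M+0..M+n; used as Poisson means.
    integration_sd : float
        Empirical relative SD of automated integration before the
        counting-statistics deflation.
    ion_sd : float
        Relative SD of the ionization/transmission factor (regression slope).
    shared_integration : bool
        Draw one integration deviate per metabolite per iteration (one
        integration event per peak group) instead of independently per peak.
    poisson : bool
        Include ion-counting noise.
    """

    raw_areas: np.ndarray
    integration_sd: float = DEFAULT_INTEGRATION_SD
    ion_sd: float = 0.0
    shared_integration: bool = True
    poisson: bool = True

    def __post_init__(self) -> None:
        self.raw_areas = np.asarray(self.raw_areas, dtype=float)
        if np.any(self.raw_areas < 0):
            raise ValueError("raw areas must be non-negative")
        if self.integration_sd < 0 or self.ion_sd < 0:
            raise ValueError("standard uncertainties must be >= 0")

    def effective_integration_sds(self) -> np.ndarray:
        """Per-isotopologue triangular scales after the Poisson deflation."""
        if self.integration_sd == 0:
            return np.zeros_like(self.raw_areas)
        safe = np.maximum(self.raw_areas, 1.0)
        out = np.sqrt(np.maximum(0.0, self.integration_sd**2 - 1.0 / safe))
        return np.where(self.raw_areas > 0, out, 0.0)

    def sample_intermediate_areas(
        self, rng: np.random.Generator, n_draws: int = 1
    ) -> np.ndarray:
        """Draw intermediate areas A_n, shape (n_draws, n_isotopologues)."""
        n_iso = self.raw_areas.size
        if self.poisson:
            a_raw = rng.poisson(self.raw_areas, size=(n_draws, n_iso)).astype(float)
        else:
            a_raw = np.broadcast_to(self.raw_areas, (n_draws, n_iso)).copy()
        s_eff = self.effective_integration_sds()
        if self.shared_integration:
            # One integration event per peak group: a single standard deviate
            # scaled by each isotopologue's effective SD (perfect correlation).
            u = rng.random((n_draws, 1)) - rng.random((n_draws, 1))
            f_int = 1.0 + TRIANGULAR_HALF_WIDTH_FACTOR * s_eff * u
        else:
            f_int = sample_triangular_factor(rng, s_eff, size=(n_draws, n_iso))
        if self.ion_sd > 0:
            f_ion = rng.normal(1.0, self.ion_sd, size=(n_draws, n_iso))
        else:
            f_ion = np.ones((n_draws, n_iso))
        return a_raw * f_int * f_ion


def sample_intermediate_area(
    model: MeasurementModel, rng: np.random.Generator
) -> np.ndarray:
    """One draw of the intermediate area vector (thin wrapper)."""
    return model.sample_intermediate_areas(rng, n_draws=1)[0]
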