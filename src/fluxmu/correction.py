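"""Natural isotope interference correction for derivatized metabolites.

The measured ion of a derivatized metabolite contains, besides the labeled
backbone, natural-abundance carbon and silicon introduced by the
derivatization groups.  Each combination of heavy atoms shifts part of the
signal to higher isotopologues: :sup:`29`\\ Si and :sup:`13`\\ C by +1 mass
unit, :sup:`30`\\ Si by +2.  The correction expands

    (1 + b + a) ** n_Si  *  (1 + c) ** n_C

grouped by total mass shift, and subtracts from every isotopologue the
signal that lower isotopologues push into it.  The coefficients are exact
multinomial/binomial counts; the expansion reproduces, term for term, the
published correction cascades used by spreadsheet-era MFA software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy
from sklearn.base import BaseEstimator, TransformerMixin

from .abundances import IsotopeAbundances
from .errors import InvalidCompositionError, UndefinedRatioError


@dataclass(frozen=True)
class DerivativeGroup:
    """One derivatization group attached to the metabolite."""

    name: str
    carbons: int
    silicons: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 0 or self.silicons < 0:
            raise InvalidCompositionError(f"negative atom count in group {self.name!r}")


#: Common derivatization groups for GC analysis of sugar phosphates.
TMS = DerivativeGroup("TMS", carbons=3, silicons=1)
ETHOXIME = DerivativeGroup("EtOx", carbons=2, silicons=0)
METHOXIME = DerivativeGroup("MeOx", carbons=1, silicons=0)


@dataclass(frozen=True)
class DerivativeComposition:
    """Atom bookkeeping for the measured ion of a derivatized metabolite.

    ``extra_carbons`` and ``silicon_atoms`` are the natural-abundance atoms
    that must be corrected for; backbone carbons carry the tracer label and
    are not part of the interference model.
    """

    metabolite: str
    backbone_carbons: int
    groups: tuple[DerivativeGroup, ...] = ()
    neutral_loss_carbons: int = 0

    def __post_init__(self) -> None:
        if self.backbone_carbons < 0 or self.neutral_loss_carbons < 0:
            raise InvalidCompositionError("negative atom count")
        if self.extra_carbons < 0:
            raise InvalidCompositionError(
                f"{self.metabolite}: neutral loss removes more carbon than the "
                "derivatization groups provide"
            )

    @property
    def extra_carbons(self) -> int:
        """Natural-abundance C atoms in the measured ion (group C minus neutral loss)."""
        return sum(g.carbons for g in self.groups) - self.neutral_loss_carbons

    @property
    def silicon_atoms(self) -> int:
        return sum(g.silicons for g in self.groups)

    @property
    def n_isotopologues(self) -> int:
        return self.backbone_carbons + 1


@dataclass(frozen=True)
class ShiftTerm:
    """One monomial ``multiplier * a**p * b**q * c**r`` (mass shift 2p + q + r)."""

    multiplier: int
    p: int  # 30Si count
    q: int  # 29Si count
    r: int  # 13C count

    @property
    def shift(self) -> int:
        return 2 * self.p + self.q + self.r

    def value(self, ab: IsotopeAbundances) -> float:
        return self.multiplier * ab.a**self.p * ab.b**self.q * ab.c**self.r

    def symbol(self) -> sympy.Expr:
        a, b, c = sympy.symbols("a b c")
        return self.multiplier * a**self.p * b**self.q * c**self.r


@dataclass(frozen=True)
class ShiftDistribution:
    """Interference coefficients of a derivative, grouped by mass shift.

    ``terms[k]`` holds the monomials whose total mass shift is ``k``; their
    numeric sum is the fraction of a backbone isotopologue's signal that
    appears ``k`` mass units higher (relative to its unshifted signal).
    """

    composition: DerivativeComposition
    terms: Mapping[int, tuple[ShiftTerm, ...]] = field(repr=False)

    @property
    def max_shift(self) -> int:
        return max(self.terms)

    def coefficient(self, shift: int, ab: IsotopeAbundances) -> float:
        """Numeric coefficient at a mass shift (0 for shifts never produced)."""
        return float(sum(t.value(ab) for t in self.terms.get(shift, ())))

    def coefficients(self, ab: IsotopeAbundances, n_shifts: int | None = None) -> np.ndarray:
        """Vector d with d[k] = coefficient at shift k; d[0] = 1."""
        n = self.max_shift + 1 if n_shifts is None else n_shifts
        return np.array([self.coefficient(k, ab) for k in range(n)])

    def coefficient_samples(
        self, shift: int, a: np.ndarray, b: np.ndarray, c: np.ndarray
    ) -> np.ndarray:
        """Coefficient at one shift for arrays of abundance draws (MC use)."""
        out = np.zeros(np.broadcast(a, b, c).shape)
        for t in self.terms.get(shift, ()):
            out = out + t.multiplier * a**t.p * b**t.q * c**t.r
        return out

    def pure_carbon_multiplier(self, shift: int) -> int:
        """Integer multiplier of the pure c**shift monomial (binomial count)."""
        for t in self.terms.get(shift, ()):
            if t.p == 0 and t.q == 0 and t.r == shift:
                return t.multiplier
        return 0

    def expression(self, shift: int) -> sympy.Expr:
        """Symbolic coefficient at one shift, e.g. ``5*a + 10*b**2 + 80*b*c + 120*c**2``."""
        return sympy.Add(*[t.symbol() for t in self.terms.get(shift, ())])

    def cascade_expressions(self) -> list[sympy.Expr]:
        """Symbolic correction cascade A_k_corr for the metabolite's window.

        Row k reads ``A_k - sum_j coeff(k - j) * A_j_corr`` with the
        published term ordering (lower shift first, then monomial degree).
        """
        n = self.composition.backbone_carbons
        A = [sympy.Symbol("A_0")] + [
            sympy.Symbol(f"A_{k}corr") for k in range(1, n + 1)
        ]
        rows: list[sympy.Expr] = [A[0]]
        for k in range(1, n + 1):
            expr: sympy.Expr = sympy.Symbol(f"A_{k}")
            for j in range(k):
                for t in sorted(self.terms.get(k - j, ()), key=lambda t: (t.r, t.q, t.p)):
                    expr = expr - t.symbol() * A[j]
            rows.append(expr)
        return rows


def build_shift_distribution(
    comp: DerivativeComposition, ab: IsotopeAbundances | None = None
) -> ShiftDistribution:
    """Expand the derivative's natural-abundance envelope by mass shift.

    The multiplier of ``a**p * b**q * c**r`` is the number of ways of placing
    p 30Si and q 29Si among the silicon atoms times the number of ways of
    choosing r of the extra carbons to be 13C:
    ``multinomial(nSi; p, q) * binomial(nC, r)``.
    """
    n_c, n_si = comp.extra_carbons, comp.silicon_atoms
    if n_c < 0 or n_si < 0:
        raise InvalidCompositionError("negative atom counts")
    terms: dict[int, list[ShiftTerm]] = {}
    for p in range(n_si + 1):
        for q in range(n_si - p + 1):
            si_mult = math.comb(n_si, p) * math.comb(n_si - p, q)
            for r in range(n_c + 1):
                mult = si_mult * math.comb(n_c, r)
                t = ShiftTerm(mult, p, q, r)
                terms.setdefault(t.shift, []).append(t)
    canon = {
        k: tuple(sorted(v, key=lambda t: (t.p + t.q + t.r, t.r, t.q, t.p)))
        for k, v in sorted(terms.items())
    }
    return ShiftDistribution(composition=comp, terms=canon)


@dataclass(frozen=True)
class CorrectedAreas:
    """Result of the interference-correction cascade for one metabolite."""

    metabolite: str
    a_raw: np.ndarray  #: intermediate areas entering the cascade
    a_corr: np.ndarray  #: corrected areas (clamped entries reported as 0)
    signed: np.ndarray  #: cascade values before clamping (diagnostics)
    flags: np.ndarray  #: F_n in {0, 1}; 0 where overcorrection clamped the entry

    @property
    def retained(self) -> np.ndarray:
        return self.a_corr * self.flags


def cascade_correct(
    A: np.ndarray, coeffs: np.ndarray, clamp: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sequential interference correction, vectorized over leading axes.

    ``A[..., k]`` are areas for isotopologues M+0..M+n; ``coeffs[..., k]``
    the shift coefficients (``coeffs[..., 0] == 1``).  Returns
    ``(corrected, signed, flags)``.  The monoisotopic M+0 area is never
    modified.  With ``clamp`` on, negative corrected areas are set to zero
    and the already-clamped values feed the higher-order rows, matching the
    solution process of dedicated correction software.
    """
    A = np.asarray(A, dtype=float)
    coeffs = np.broadcast_to(np.asarray(coeffs, dtype=float), A.shape[:-1] + (coeffs.shape[-1],))
    n = A.shape[-1]
    signed = np.empty_like(A)
    eff = np.empty_like(A)  # values propagated into higher rows
    flags = np.ones(A.shape, dtype=float)
    signed[..., 0] = A[..., 0]
    eff[..., 0] = A[..., 0]
    for k in range(1, n):
        val = A[..., k].copy()
        for j in range(k):
            d = k - j
            if d < coeffs.shape[-1]:
                val -= coeffs[..., d] * eff[..., j]
        signed[..., k] = val
        if clamp:
            neg = val < 0
            flags[..., k] = np.where(neg, 0.0, 1.0)
            eff[..., k] = np.where(neg, 0.0, val)
        else:
            eff[..., k] = val
    corrected = eff if clamp else signed
    return corrected, signed, flags


def correct_areas(
    A: Sequence[float] | np.ndarray,
    dist: ShiftDistribution,
    ab: IsotopeAbundances | None = None,
    clamp: bool = True,
) -> CorrectedAreas:
    """Apply the correction cascade of ``dist`` to one area vector."""
    ab = ab or IsotopeAbundances()
    A = np.asarray(A, dtype=float)
    n_expected = dist.composition.n_isotopologues
    if A.shape != (n_expected,):
        raise ValueError(
            f"{dist.composition.metabolite}: expected {n_expected} areas (M+0..M+{n_expected - 1}), "
            f"got shape {A.shape}"
        )
    coeffs = dist.coefficients(ab, n_shifts=n_expected)
    corrected, signed, flags = cascade_correct(A, coeffs, clamp=clamp)
    return CorrectedAreas(
        metabolite=dist.composition.metabolite,
        a_raw=A,
        a_corr=corrected,
        signed=signed,
        flags=flags if clamp else np.ones_like(flags),
    )


def compute_ifs(corr: CorrectedAreas) -> np.ndarray:
    """Isotopologue fractions from clamped corrected areas (sum to 1)."""
    retained = corr.retained
    total = retained.sum()
    if total <= 0:
        raise UndefinedRatioError(f"{corr.metabolite}: no positive corrected area")
    return retained / total


def interference_share(A_measured: np.ndarray, corr: CorrectedAreas) -> float:
    """Percent of the total measured signal attributable to natural heavy isotopes."""
    A_measured = np.asarray(A_measured, dtype=float)
    total = A_measured.sum()
    if total == 0:
        raise UndefinedRatioError("total measured area is zero")
    return 100.0 * (total - corr.retained.sum()) / total


def forward_convolve(
    backbone: Sequence[float] | np.ndarray,
    dist: ShiftDistribution,
    ab: IsotopeAbundances | None = None,
) -> np.ndarray:
    """Forward model: convolve backbone areas with the natural envelope.

    Returns areas on the measured M+0..M+n window (mass shifted beyond the
    window falls outside the recorded isotopologues, as in the instrument).
    """
    ab = ab or IsotopeAbundances()
    x = np.asarray(backbone, dtype=float)
    n = x.shape[-1]
    d = dist.coefficients(ab, n_shifts=n)
    out = np.zeros_like(x)
    for k in range(n):
        for j in range(k + 1):
            out[..., k] += d[k - j] * x[..., j]
    return out


def convolution_matrix(
    dist: ShiftDistribution, ab: IsotopeAbundances | None = None, n: int | None = None
) -> np.ndarray:
    """Lower-triangular matrix M with M @ backbone = measured (oracle form)."""
    ab = ab or IsotopeAbundances()
    n = n or dist.composition.n_isotopologues
    d = dist.coefficients(ab, n_shifts=n)
    M = np.zeros((n, n))
    for k in range(n):
        for j in range(k + 1):
            M[k, j] = d[k - j]
    return M


class NaturalAbundanceCorrector(BaseEstimator, TransformerMixin):
    """Transformer removing natural-abundance interference from area tables.

    Parameters
    ----------
    composition : DerivativeComposition
        Atom bookkeeping of the measured derivative ion.
    abundances : IsotopeAbundances, optional
        Light-isotope-normalized a, b, c; defaults to the bundled values.
    clamp : bool, default True
        Set overcorrected (negative) areas to zero during the cascade.

    After :meth:`fit`, ``shift_distribution_`` holds the combinatorial
    expansion and ``coefficients_`` its numeric evaluation.  ``transform``
    accepts an array of shape (n_samples, backbone_carbons + 1) — or a
    single vector — of measured areas and returns corrected areas.
    """

    def __init__(
        self,
        composition: DerivativeComposition,
        abundances: IsotopeAbundances | None = None,
        clamp: bool = True,
    ):
        self.composition = composition
        self.abundances = abundances
        self.clamp = clamp

    def fit(self, X=None, y=None) -> "NaturalAbundanceCorrector":
        ab = self.abundances or IsotopeAbundances()
        self.shift_distribution_ = build_shift_distribution(self.composition, ab)
        self.coefficients_ = self.shift_distribution_.coefficients(
            ab, n_shifts=self.composition.n_isotopologues
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "shift_distribution_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        corrected, _, _ = cascade_correct(np.atleast_2d(X), self.coefficients_, clamp=self.clamp)
        return corrected[0] if single else corrected

    def correct(self, A) -> CorrectedAreas:
        """Full cascade result (flags, signed values) for one area vector."""
        if not hasattr(self, "shift_distribution_"):
            self.fit()
        return correct_areas(
            A, self.shift_distribution_, self.abundances or IsotopeAbundances(), clamp=self.clamp
        )

    def fractions(self, A) -> np.ndarray:
        """Corrected isotopologue fractions for one area vector."""
        return compute_ifs(self.correct(A))
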