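"""Natural heavy-isotope abundances of carbon and silicon.

GC-amenable derivatives of sugar phosphates carry trimethylsilyl and
alkoxime groups, so the isotope envelope of a measured ion is shaped by the
natural abundances of :sup:`13`\\ C, :sup:`29`\\ Si and :sup:`30`\\ Si.  All
abundances here are expressed *normalized to the light isotope of the
element* (ratios, not fractions): ``a`` = 30Si/28Si, ``b`` = 29Si/28Si,
``c`` = 13C/12C.  Heavy isotopes of H, N and O are orders of magnitude less
abundant and are deliberately excluded from the correction model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

#: Representative isotopic-composition fractions (IUPAC technical report).
IUPAC_FRACTIONS = {
    "28Si": 0.92223,
    "29Si": 0.04685,
    "30Si": 0.03092,
    "12C": 0.9893,
    "13C": 0.0107,
}


@dataclass(frozen=True)
class IsotopeAbundances:
    """Light-isotope-normalized abundances and their standard uncertainties.

    Defaults are the ratios obtained from the IUPAC representative isotopic
    fractions, rounded to the precision conventional in uncertainty
    budgeting for this kind of correction.
    """

    a: float = 0.03353  #: 30Si / 28Si
    b: float = 0.05080  #: 29Si / 28Si
    c: float = 0.01082  #: 13C / 12C
    u_a: float = 5.5e-5
    u_b: float = 4.0e-5
    u_c: float = 4.0e-4

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "u_a", "u_b", "u_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_fractions(
        cls,
        si28: float,
        si29: float,
        si30: float,
        c12: float,
        c13: float,
        **uncertainties: float,
    ) -> "IsotopeAbundances":
        """Normalize raw isotopic fractions to the light isotope."""
        if min(si28, c12) <= 0:
            raise ValueError("light-isotope fractions must be positive")
        return cls(a=si30 / si28, b=si29 / si28, c=c13 / c12, **uncertainties)

    @classmethod
    def from_iupac(cls) -> "IsotopeAbundances":
        """Abundances computed from :data:`IUPAC_FRACTIONS` (full precision)."""
        f = IUPAC_FRACTIONS
        return cls.from_fractions(f["28Si"], f["29Si"], f["30Si"], f["12C"], f["13C"])

    def exact(self) -> "IsotopeAbundances":
        """Zero-interference copy (a = b = c = 0) for diagnostics."""
        return replace(self, a=0.0, b=0.0, c=0.0, u_a=0.0, u_b=0.0, u_c=0.0)
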