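"""Metabolic network with carbon atom transitions.

Reactions are written in letter notation, e.g.::

    FBP (abcdef) -> DHAP (cba) + GAP (def)

Every substrate carbon maps to exactly one product carbon (losses such as
CO2 must be declared as explicit products).  Net fluxes live on the
null space of the stoichiometric matrix of balanced metabolites; one
reaction may be marked ``basis`` and is fixed (glucose uptake = 1 by
convention — labeling depends only on flux ratios).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy

from .errors import NetworkValidationError

_TERM_RE = re.compile(r"^\s*(?P<met>[\w.\-]+)\s*\(\s*(?P<atoms>[a-zA-Z]*)\s*\)\s*$")


@dataclass(frozen=True)
class Reaction:
    """One reaction with per-atom carbon mappings."""

    id: str
    substrates: tuple[tuple[str, str], ...]  #: (metabolite, atom letters)
    products: tuple[tuple[str, str], ...]
    reversible: bool = False
    basis: bool = False  #: net flux fixed by convention (e.g. uptake = 1)

    def __post_init__(self) -> None:
        sub_atoms = "".join(a for _, a in self.substrates)
        prod_atoms = "".join(a for _, a in self.products)
        for side, atoms in (("substrate", sub_atoms), ("product", prod_atoms)):
            if len(set(atoms)) != len(atoms):
                raise NetworkValidationError(
                    f"{self.id}: duplicate atom letter on {side} side"
                )
        if sorted(sub_atoms) != sorted(prod_atoms):
            raise NetworkValidationError(
                f"{self.id}: atom balance violated "
                f"(substrates carry {sorted(sub_atoms)}, products {sorted(prod_atoms)})"
            )

    @property
    def metabolites(self) -> set[str]:
        return {m for m, _ in self.substrates} | {m for m, _ in self.products}


def _parse_side(text: str, rxn_id: str) -> tuple[tuple[str, str], ...]:
    terms = []
    for raw in text.split("+"):
        m = _TERM_RE.match(raw)
        if not m:
            raise NetworkValidationError(f"{rxn_id}: cannot parse term {raw.strip()!r}")
        terms.append((m.group("met"), m.group("atoms")))
    return tuple(terms)


def parse_equation(rxn_id: str, equation: str, reversible: bool, basis: bool = False) -> Reaction:
    """Parse ``A (ab) + B (c) -> C (abc)`` into a :class:`Reaction`."""
    arrow = "<->" if "<->" in equation else "->"
    parts = equation.split(arrow)
    if len(parts) != 2:
        raise NetworkValidationError(f"{rxn_id}: equation needs exactly one arrow")
    reversible = reversible or arrow == "<->"
    return Reaction(
        id=rxn_id,
        substrates=_parse_side(parts[0], rxn_id),
        products=_parse_side(parts[1], rxn_id),
        reversible=reversible,
        basis=basis,
    )


class FluxNetwork:
    """Validated reaction network with stoichiometric bookkeeping.

    Metabolites never produced are *inputs* (tracer entry points), those
    never consumed are *sinks*; everything else is balanced and must satisfy
    steady state.  Free net fluxes are the non-pivot columns of the reduced
    stoichiometric matrix; reactions flagged as preferred (``free`` column in
    the file, or the basis reaction) are pushed into the free set whenever
    the stoichiometry allows.
    """

    def __init__(
        self,
        reactions: Sequence[Reaction],
        preferred_free: Iterable[str] = (),
    ) -> None:
        if not reactions:
            raise NetworkValidationError("network has no reactions")
        ids = [r.id for r in reactions]
        if len(set(ids)) != len(ids):
            raise NetworkValidationError("duplicate reaction ids")
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.by_id = {r.id: r for r in self.reactions}

        # metabolite sizes must be consistent across reactions
        self.met_size: dict[str, int] = {}
        for r in self.reactions:
            for met, atoms in r.substrates + r.products:
                n = len(atoms)
                if self.met_size.setdefault(met, n) != n:
                    raise NetworkValidationError(
                        f"{met}: inconsistent carbon count across reactions"
                    )

        produced = {m for r in self.reactions for m, _ in r.products}
        consumed = {m for r in self.reactions for m, _ in r.substrates}
        self.inputs = sorted(consumed - produced)
        self.sinks = sorted(produced - consumed)
        self.balanced = sorted(produced & consumed)
        if not self.inputs:
            raise NetworkValidationError("network has no input metabolite")

        # stoichiometric matrix of balanced metabolites (net fluxes)
        met_idx = {m: i for i, m in enumerate(self.balanced)}
        S = np.zeros((len(self.balanced), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, _ in r.substrates:
                if m in met_idx:
                    S[met_idx[m], j] -= 1
            for m, _ in r.products:
                if m in met_idx:
                    S[met_idx[m], j] += 1
        self.stoichiometry = S

        basis_rxns = [r.id for r in self.reactions if r.basis]
        if len(basis_rxns) > 1:
            raise NetworkValidationError("at most one basis reaction allowed")
        self.basis_reaction: str | None = basis_rxns[0] if basis_rxns else None

        preferred = [rid for rid in preferred_free if rid in self.by_id]
        if self.basis_reaction and self.basis_reaction not in preferred:
            preferred.append(self.basis_reaction)
        self._solve_structure(preferred)

    def _solve_structure(self, preferred: list[str]) -> None:
        """Pick free columns of S (preferred ones last so rref frees them)."""
        n = len(self.reactions)
        pref_idx = [i for i, r in enumerate(self.reactions) if r.id in preferred]
        other_idx = [i for i in range(n) if i not in pref_idx]
        order = other_idx + pref_idx
        M = sympy.Matrix(self.stoichiometry[:, order].astype(int))
        _, pivots = M.rref()
        pivot_cols = [order[p] for p in pivots]
        free_cols = [j for j in order if j not in pivot_cols]
        self.pivot_reactions = [self.reactions[j].id for j in sorted(pivot_cols)]
        self.free_reactions = [self.reactions[j].id for j in sorted(free_cols)]
        if self.basis_reaction and self.basis_reaction not in self.free_reactions:
            raise NetworkValidationError("basis reaction is not stoichiometrically free")
        S = self.stoichiometry
        P, F = sorted(pivot_cols), sorted(free_cols)
        self._pivot_cols, self._free_cols = P, F
        # v_P = T @ v_F from S_P v_P + S_F v_F = 0
        self._free_to_pivot = -np.linalg.lstsq(S[:, P], S[:, F], rcond=None)[0]

    # ------------------------------------------------------------------
    @property
    def reversible_reactions(self) -> list[str]:
        return [r.id for r in self.reactions if r.reversible]

    def solve_net(self, free_values: Mapping[str, float]) -> dict[str, float]:
        """Full net flux vector from values of the free net fluxes.

        The basis reaction defaults to 1 when omitted.  Raises if a derived
        irreversible net comes out negative.
        """
        vals = dict(free_values)
        if self.basis_reaction and self.basis_reaction not in vals:
            vals[self.basis_reaction] = 1.0
        missing = [r for r in self.free_reactions if r not in vals]
        if missing:
            raise ValueError(f"missing free flux values: {missing}")
        vF = np.array([vals[self.reactions[j].id] for j in self._free_cols])
        vP = self._free_to_pivot @ vF
        nets = {}
        for j, v in zip(self._pivot_cols, vP):
            nets[self.reactions[j].id] = float(v)
        for j, v in zip(self._free_cols, vF):
            nets[self.reactions[j].id] = float(v)
        for r in self.reactions:
            if not r.reversible and nets[r.id] < -1e-9:
                raise ValueError(f"{r.id}: irreversible net flux is negative ({nets[r.id]:.3g})")
        return nets

    def residual_steady_state(self, nets: Mapping[str, float]) -> float:
        v = np.array([nets[r.id] for r in self.reactions])
        return float(np.max(np.abs(self.stoichiometry @ v), initial=0.0))


def parse_network(path: str | Path) -> FluxNetwork:
    """Read a network CSV (columns: id, equation, reversible[, basis, free])."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise NetworkValidationError(f"{path}: empty network file")
    reactions: list[Reaction] = []
    preferred: list[str] = []
    reader = csv.DictReader(text.splitlines())
    if reader.fieldnames is None or "id" not in reader.fieldnames or "equation" not in reader.fieldnames:
        raise NetworkValidationError(f"{path}: need columns id, equation")
    for row in reader:
        if not row["id"] or not row["id"].strip():
            continue
        rxn = parse_equation(
            row["id"].strip(),
            row["equation"],
            reversible=str(row.get("reversible", "0")).strip() in ("1", "true", "yes"),
            basis=str(row.get("basis", "0")).strip() in ("1", "true", "yes"),
        )
        reactions.append(rxn)
        if str(row.get("free", "0")).strip() in ("1", "true", "yes"):
            preferred.append(rxn.id)
    return FluxNetwork(reactions, preferred_free=preferred)
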