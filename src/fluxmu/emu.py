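"""Steady-state labeling simulation via elementary metabolite units (EMUs).

An EMU is a metabolite plus a subset of its carbon atoms; its
mass-isotopomer distribution (MID) obeys a linear balance once the MIDs of
smaller EMUs are known, so the network decomposes into a cascade of small
dense linear systems ordered by EMU size.  Only the EMUs reachable
backwards from the measured full-backbone fragments are generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import NetworkValidationError, SingularNetworkError
from .network import FluxNetwork, Reaction

_ZERO_FLUX = 1e-12


@dataclass(frozen=True)
class EMU:
    met: str
    atoms: frozenset[int]  #: 0-based carbon positions

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:  # compact: GAP{1,2}
        return f"{self.met}{{{','.join(str(i) for i in sorted(self.atoms))}}}"


@dataclass(frozen=True)
class TracerSpec:
    """Per-atom 13C enrichment of every input metabolite.

    ``enrichments[met][i]`` is the probability that carbon i of the input
    metabolite carries a 13C label; atoms are independent, so the MID of any
    input EMU is the convolution of per-atom [1-p, p] vectors.
    """

    enrichments: Mapping[str, tuple[float, ...]]

    def emu_mid(self, met: str, atoms: Iterable[int]) -> np.ndarray:
        probs = self.enrichments[met]
        mid = np.array([1.0])
        for i in sorted(atoms):
            p = probs[i]
            mid = np.convolve(mid, [1.0 - p, p])
        return mid


def glucose_1_6_13c2(purity: float = 1.0, input_met: str = "GLC.ext") -> TracerSpec:
    """[1,6-13C2]glucose tracer: carbons 1 and 6 labeled at the given purity."""
    return TracerSpec({input_met: (purity, 0.0, 0.0, 0.0, 0.0, purity)})


def unlabeled_tracer(input_met: str = "GLC.ext", n_atoms: int = 6) -> TracerSpec:
    return TracerSpec({input_met: (0.0,) * n_atoms})


def fully_labeled_tracer(input_met: str = "GLC.ext", n_atoms: int = 6) -> TracerSpec:
    return TracerSpec({input_met: (1.0,) * n_atoms})


# (reaction id, direction): direction "f" is as written, "r" the reverse.
FluxKey = tuple[str, str]


def _directions(r: Reaction):
    yield (r.id, "f"), r.substrates, r.products
    if r.reversible:
        yield (r.id, "r"), r.products, r.substrates


def decompose_emu(
    network: FluxNetwork, targets: Sequence[str]
) -> dict[EMU, list[tuple[FluxKey, tuple[EMU, ...]]]]:
    """Backward-trace the EMUs feeding the targets' full-backbone fragments.

    Returns, for every internal EMU, its producer terms: a flux key and the
    source EMU(s) whose (convolved) MID it injects.
    """
    for t in targets:
        if t not in network.met_size:
            raise NetworkValidationError(f"target metabolite {t!r} not in network")
        if t in network.inputs:
            raise NetworkValidationError(f"target {t!r} is an input metabolite")
    inputs = set(network.inputs)
    producers: dict[EMU, list[tuple[FluxKey, tuple[EMU, ...]]]] = {}
    queue = [EMU(t, frozenset(range(network.met_size[t]))) for t in targets]
    seen = set(queue)
    while queue:
        emu = queue.pop()
        terms: list[tuple[FluxKey, tuple[EMU, ...]]] = []
        found_producer = False
        for r in network.reactions:
            for fluxkey, subs, prods in _directions(r):
                for met, atoms in prods:
                    if met != emu.met:
                        continue
                    found_producer = True
                    needed = [atoms[i] for i in sorted(emu.atoms)]
                    by_sub: dict[int, set[int]] = {}
                    for letter in needed:
                        for si, (smet, satoms) in enumerate(subs):
                            pos = satoms.find(letter)
                            if pos >= 0:
                                by_sub.setdefault(si, set()).add(pos)
                                break
                    sources = tuple(
                        EMU(subs[si][0], frozenset(pos))
                        for si, pos in sorted(by_sub.items())
                    )
                    terms.append((fluxkey, sources))
                    for s in sources:
                        if s.met not in inputs and s not in seen:
                            seen.add(s)
                            queue.append(s)
        if not found_producer:
            raise NetworkValidationError(
                f"{emu.met}: not reachable from any substrate (no producing reaction)"
            )
        producers[emu] = terms
    return producers


class EMUSimulator:
    """Reusable labeling simulator for a fixed network / target / tracer triple.

    The EMU decomposition is done once; :meth:`simulate` then only assembles
    and solves the small per-size linear systems for a given flux vector.
    """

    def __init__(self, network: FluxNetwork, targets: Sequence[str], tracer: TracerSpec):
        self.network = network
        self.targets = list(targets)
        self.tracer = tracer
        self.producers = decompose_emu(network, self.targets)
        self.sizes = sorted({e.size for e in self.producers})
        self._by_size = {
            s: sorted((e for e in self.producers if e.size == s), key=repr)
            for s in self.sizes
        }
        inputs = set(network.inputs)
        self._input_mids: dict[EMU, np.ndarray] = {}
        for terms in self.producers.values():
            for _, sources in terms:
                for s in sources:
                    if s.met in inputs and s not in self._input_mids:
                        if s.met not in tracer.enrichments:
                            raise NetworkValidationError(
                                f"tracer does not specify input metabolite {s.met!r}"
                            )
                        self._input_mids[s] = tracer.emu_mid(s.met, s.atoms)

    # ------------------------------------------------------------------
    def _flux_values(
        self, nets: Mapping[str, float], exchanges: Mapping[str, float]
    ) -> dict[FluxKey, float]:
        flux: dict[FluxKey, float] = {}
        for r in self.network.reactions:
            net = nets[r.id]
            if r.reversible:
                x = float(exchanges.get(r.id, 0.0))
                if x < 0:
                    raise ValueError(f"{r.id}: exchange flux must be >= 0")
                flux[(r.id, "f")] = x + max(net, 0.0)
                flux[(r.id, "r")] = x + max(-net, 0.0)
            else:
                if net < -1e-9:
                    raise ValueError(f"{r.id}: negative irreversible net flux")
                flux[(r.id, "f")] = max(net, 0.0)
        return flux

    def _production_totals(self, flux: Mapping[FluxKey, float]) -> dict[str, float]:
        total: dict[str, float] = {}
        for r in self.network.reactions:
            for fluxkey, _, prods in _directions(r):
                v = flux.get(fluxkey, 0.0)
                for met, _ in prods:
                    total[met] = total.get(met, 0.0) + v
        return total

    def simulate(
        self,
        nets: Mapping[str, float],
        exchanges: Mapping[str, float] | None = None,
    ) -> dict[str, np.ndarray]:
        """MIDs (isotopologue fractions) of the target backbones.

        ``nets`` maps every reaction to its net flux (see
        :meth:`FluxNetwork.solve_net`); ``exchanges`` maps reversible
        reactions to their exchange fluxes (missing entries mean 0).
        """
        exchanges = exchanges or {}
        flux = self._flux_values(nets, exchanges)
        production = self._production_totals(flux)
        mids: dict[EMU, np.ndarray] = dict(self._input_mids)

        # prune EMUs reached only through zero-flux branches (e.g. an idle
        # PPP): they contribute nothing and would make their balance singular
        needed: set[EMU] = set()
        stack = [
            EMU(t, frozenset(range(self.network.met_size[t]))) for t in self.targets
        ]
        while stack:
            e = stack.pop()
            if e in needed or e not in self.producers:
                continue
            needed.add(e)
            for fluxkey, sources in self.producers[e]:
                if flux.get(fluxkey, 0.0) > _ZERO_FLUX:
                    stack.extend(sources)

        for size in self.sizes:
            emus = [e for e in self._by_size[size] if e in needed]
            if not emus:
                continue
            idx = {e: i for i, e in enumerate(emus)}
            m = len(emus)
            A = np.zeros((m, m))
            B = np.zeros((m, size + 1))
            for i, e in enumerate(emus):
                turnover = production.get(e.met, 0.0)
                if turnover <= _ZERO_FLUX:
                    raise SingularNetworkError(
                        f"pool {e.met} has zero throughput; labeling balance singular"
                    )
                A[i, i] = turnover
                for fluxkey, sources in self.producers[e]:
                    v = flux.get(fluxkey, 0.0)
                    if v <= _ZERO_FLUX:
                        continue
                    if len(sources) == 1 and sources[0] in idx:
                        A[i, idx[sources[0]]] -= v
                    else:
                        mid = np.array([1.0])
                        for s in sources:
                            mid = np.convolve(mid, mids[s])
                        B[i] += v * mid
            try:
                X = np.linalg.solve(A, B)
            except np.linalg.LinAlgError as exc:
                pools = sorted({e.met for e in emus})
                raise SingularNetworkError(
                    f"labeling balance singular at EMU size {size} (pools {pools})"
                ) from exc
            for e, row in zip(emus, X):
                # a valid balance conserves mass; a deficit means the pool is
                # fed only by (numerically) zero-throughput cycles
                if abs(row.sum() - 1.0) > 1e-6:
                    raise SingularNetworkError(
                        f"pool {e.met} receives no labeling input "
                        f"(EMU {e!r} mass {row.sum():.3g}); zero throughput"
                    )
                mids[e] = row

        out = {}
        for t in self.targets:
            full = EMU(t, frozenset(range(self.network.met_size[t])))
            out[t] = mids[full]
        return out


def simulate_ifs(
    network: FluxNetwork,
    targets: Sequence[str],
    tracer: TracerSpec,
    nets: Mapping[str, float],
    exchanges: Mapping[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """One-shot wrapper around :class:`EMUSimulator`."""
    return EMUSimulator(network, targets, tracer).simulate(nets, exchanges)
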