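"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own algorithms: shift
coefficients are found by exhaustive enumeration over isotope assignments,
the correction cascade is checked against a dense triangular solve, and the
EMU simulator against a full 2^n isotopomer fixed-point iteration.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

from fluxmu.network import FluxNetwork


def enumerate_shift_terms(n_carbons: int, n_silicons: int) -> dict[int, Counter]:
    """Exhaustive enumeration of heavy-isotope assignments.

    Every silicon is 28Si, 29Si (+1) or 30Si (+2); every carbon 12C or 13C
    (+1).  Returns, per total mass shift, a Counter over monomials
    (p30Si, q29Si, r13C) -> multiplicity.
    """
    out: dict[int, Counter] = {}
    for si_states in itertools.product((0, 1, 2), repeat=n_silicons):
        for c_states in itertools.product((0, 1), repeat=n_carbons):
            p = sum(1 for s in si_states if s == 2)
            q = sum(1 for s in si_states if s == 1)
            r = sum(c_states)
            shift = 2 * p + q + r
            out.setdefault(shift, Counter())[(p, q, r)] += 1
    return out


def solve_correction_linear(A: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Correction as the solution of the lower-triangular system M x = A."""
    n = A.size
    M = np.zeros((n, n))
    for k in range(n):
        for j in range(k + 1):
            M[k, j] = coeffs[k - j] if k - j < coeffs.size else 0.0
    return np.linalg.solve(M, A)


# ----------------------------------------------------------------------
def _pattern_mid(dist: np.ndarray, n: int) -> np.ndarray:
    """Collapse a 2^n isotopomer vector to a mass-isotopomer distribution."""
    mid = np.zeros(n + 1)
    for pattern, w in enumerate(dist):
        mid[bin(pattern).count("1")] += w
    return mid


def brute_force_ifs(
    network: FluxNetwork,
    nets: dict[str, float],
    exchanges: dict[str, float],
    tracer,
    targets: list[str],
    tol: float = 1e-14,
    max_iter: int = 200_000,
) -> dict[str, np.ndarray]:
    """Full isotopomer steady state by fixed-point iteration.

    Each metabolite with n carbons carries 2^n isotopomer fractions; the
    update sets each balanced pool to the flux-weighted average of the
    isotopomer distributions its producers inject (joint distributions of
    two substrates are outer products).  Gauss-Seidel iteration to a sup-norm
    tolerance; intentionally brute force.
    """
    sizes = network.met_size
    flux: dict[tuple[str, str], float] = {}
    for r in network.reactions:
        net = nets[r.id]
        if r.reversible:
            x = exchanges.get(r.id, 0.0)
            flux[(r.id, "f")] = x + max(net, 0.0)
            flux[(r.id, "r")] = x + max(-net, 0.0)
        else:
            flux[(r.id, "f")] = max(net, 0.0)

    def directions(r):
        yield (r.id, "f"), r.substrates, r.products
        if r.reversible:
            yield (r.id, "r"), r.products, r.substrates

    # input isotopomer distributions from per-atom enrichments
    state: dict[str, np.ndarray] = {}
    for met in network.inputs:
        n = sizes[met]
        probs = tracer.enrichments[met]
        d = np.zeros(2**n)
        for pattern in range(2**n):
            w = 1.0
            for i in range(n):
                bit = (pattern >> i) & 1
                w *= probs[i] if bit else 1.0 - probs[i]
            d[pattern] = w
        state[met] = d
    for met in network.balanced:
        d = np.zeros(2 ** sizes[met])
        d[0] = 1.0
        state[met] = d

    # precompute producer terms per balanced metabolite
    producers: dict[str, list] = {m: [] for m in network.balanced}
    production: dict[str, float] = {m: 0.0 for m in network.balanced}
    for r in network.reactions:
        for fluxkey, subs, prods in directions(r):
            v = flux.get(fluxkey, 0.0)
            for met, atoms in prods:
                if met not in producers:
                    continue
                production[met] += v
                # map: product bit i <- (substrate index, substrate bit)
                src = []
                for i, letter in enumerate(atoms):
                    for si, (smet, satoms) in enumerate(subs):
                        pos = satoms.find(letter)
                        if pos >= 0:
                            src.append((si, pos))
                            break
                producers[met].append((v, [m for m, _ in subs], src))

    for _ in range(max_iter):
        delta = 0.0
        for met in network.balanced:
            tot = production[met]
            if tot <= 0:
                continue
            acc = np.zeros_like(state[met])
            for v, sub_mets, src in producers[met]:
                if v <= 0:
                    continue
                if len(sub_mets) == 1:
                    joint = state[sub_mets[0]]
                    joint_bits = [sizes[sub_mets[0]]]
                else:
                    joint = np.outer(state[sub_mets[0]], state[sub_mets[1]]).ravel()
                    joint_bits = [sizes[sub_mets[0]], sizes[sub_mets[1]]]
                # product pattern index for each joint substrate pattern;
                # outer(a, b).ravel() puts substrate 1 in the low bits
                n_out = len(src)
                idx = np.zeros(joint.size, dtype=np.int64)
                for out_bit, (si, sbit) in enumerate(src):
                    offset = joint_bits[1] if (si == 0 and len(joint_bits) == 2) else 0
                    for jp in range(joint.size):
                        if (jp >> (offset + sbit)) & 1:
                            idx[jp] |= 1 << out_bit
                contrib = np.zeros(2**n_out)
                np.add.at(contrib, idx, joint)
                acc += v * contrib
            new = acc / tot
            # bilinear feedback amplifies any drift of the total above 1;
            # project back onto the simplex (the true solution is normalized)
            s = new.sum()
            if s > 0:
                new = new / s
            delta = max(delta, float(np.max(np.abs(new - state[met]))))
            state[met] = new
        if delta < tol:
            break
    return {t: _pattern_mid(state[t], sizes[t]) for t in targets}
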