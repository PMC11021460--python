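"""Independent brute-force elementary-mode oracle for small networks.

Enumerates every reaction subset; a subset is the support of an
elementary mode iff the internal stoichiometric matrix restricted to it
has a one-dimensional nullspace whose generator has full support on the
subset and can be oriented to respect irreversibility.  Support
minimality is enforced by filtering candidates against each other.
Exponential in the reaction count — usable up to ~10 reactions — and
entirely independent of the tableau implementation it checks.
"""

from fractions import Fraction
from itertools import combinations
from math import gcd

import sympy


def _canonical(vec, reactions):
    denom = 1
    for x in vec:
        denom = denom * x.denominator // gcd(denom, x.denominator)
    ints = [int(x * denom) for x in vec]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    ints = [x // g for x in ints]
    first = next(v for v in ints if v != 0)
    if first < 0:
        ints = [-v for v in ints]
        if any(not reactions[j].reversible and ints[j] < 0 for j in range(len(ints))):
            return None
    if any(not reactions[j].reversible and ints[j] < 0 for j in range(len(ints))):
        # try the opposite orientation before giving up
        ints = [-v for v in ints]
        if any(not reactions[j].reversible and ints[j] < 0 for j in range(len(ints))):
            return None
    return tuple(ints)


def brute_force_efms(network):
    """All EFMs as canonical coprime-integer tuples over network.reactions."""
    reactions = network.reactions
    internal = [s.id for s in network.internal_species]
    n = len(reactions)
    candidates = {}
    for k in range(1, n + 1):
        for subset in combinations(range(n), k):
            cols = [[reactions[j].stoich.get(sid, Fraction(0)) for j in subset]
                    for sid in internal]
            m = sympy.Matrix(cols) if internal else sympy.zeros(1, len(subset))
            null = m.nullspace()
            if len(null) != 1:
                continue
            gen = [Fraction(int(r.p), int(r.q))
                   for r in (sympy.Rational(x) for x in null[0])]
            if any(x == 0 for x in gen):
                continue  # support smaller than subset; found elsewhere
            full = [Fraction(0)] * n
            for j, x in zip(subset, gen):
                full[j] = x
            canon = _canonical(full, reactions)
            if canon is not None:
                candidates[frozenset(subset)] = canon
    supports = list(candidates)
    return {
        candidates[s]
        for s in supports
        if not any(o < s for o in supports)
    }


def modes_as_tuples(modes, network):
    """Convert FluxMode objects to the oracle's canonical representation."""
    out = set()
    for m in modes:
        vec = [m.fluxes.get(r.id, Fraction(0)) for r in network.reactions]
        canon = _canonical(vec, network.reactions)
        assert canon is not None
        out.add(canon)
    return out
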