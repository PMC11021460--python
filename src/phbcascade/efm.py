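"""Exact elementary-flux-mode analysis.

Elementary flux modes (EFMs) are the minimal-support steady-state flux
vectors of a metabolic network that respect irreversibility.  Their exact
rational coefficients give the precise stoichiometry of every independent
route through the cascade — e.g. the 3:3:1:2 split of flux over
aGP/PGM/PGI/G6PDH and the signed -2 on the second transketolase reaction
in the Xu5P-phosphoketolase pathway.

The enumeration is the classical tableau (double description) algorithm
run in exact integer arithmetic: reversible reactions are split into
forward/backward halves internally, the pointed cone ``{v >= 0, S v = 0}``
is processed one internal species at a time with a support-minimality
filter, and the split halves are recombined into signed fluxes at the end.
Reversible-only cycles that appear twice with opposite sign are reported
once with a canonical sign (first reaction in network order positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import Sequence

import pandas as pd

from .network import Network, net_equation
from .util import round_half_up

__all__ = [
    "FluxMode",
    "YieldReport",
    "elementary_modes",
    "normalize_mode",
    "mode_yields",
    "cofactor_closure",
    "pathway_modes",
]

#: Moiety definitions for cofactor-closure reporting: moiety -> species
#: membership weights (number of moiety units carried by one molecule).
_MOIETIES: dict[str, str] = {
    "NADP(H)": "NADPm",
    "CoA": "CoAm",
    "phosphate": "P",
}


@dataclass(frozen=True)
class FluxMode:
    """A steady-state flux vector with exact rational entries."""

    fluxes: dict[str, Fraction]
    normalization: tuple[str, Fraction] | None = None

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(r for r, v in self.fluxes.items() if v != 0)

    def flux(self, rid: str) -> Fraction:
        return self.fluxes.get(rid, Fraction(0))

    def to_series(self) -> pd.Series:
        return pd.Series(self.fluxes, dtype=object)


@dataclass(frozen=True)
class YieldReport:
    """Theoretical yields of a PHB-producing mode.

    ``molar_yield``: 100 x PHB-monomer flux / glucose-unit consumption.
    ``carbon_yield``: 100 x 4 x PHB flux / (6 x glucose-unit flux), i.e.
    exactly two thirds of the molar yield.  Both are exact Fractions;
    use :attr:`molar_percent` / :attr:`carbon_percent` for the one-decimal
    display convention.
    """

    molar_yield: Fraction
    carbon_yield: Fraction
    co2_per_3_glucose: Fraction

    @property
    def molar_percent(self) -> float:
        return round_half_up(self.molar_yield, 1)

    @property
    def carbon_percent(self) -> float:
        return round_half_up(self.carbon_yield, 1)


# ---------------------------------------------------------------------------
# enumeration


def _integerize(row: Sequence[Fraction]) -> tuple[int, ...]:
    """Scale a rational vector to coprime integers."""
    denom = 1
    for x in row:
        denom = denom * x.denominator // gcd(denom, x.denominator)
    ints = [int(x * denom) for x in row]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    if g > 1:
        ints = [x // g for x in ints]
    return tuple(ints)


def elementary_modes(network: Network) -> list[FluxMode]:
    """Enumerate all elementary flux modes of ``network``.

    Returns modes with signed flux on reversible reactions, ordered
    lexicographically by support (reaction order of the network).  Exact
    by construction; an empty reaction list yields an empty result.
    """
    reactions = network.reactions
    if not reactions:
        return []
    internal = [s.id for s in network.internal_species]

    # Split columns: one per irreversible reaction, two per reversible.
    cols: list[tuple[int, int]] = []  # (reaction index, sign)
    for j, r in enumerate(reactions):
        cols.append((j, +1))
        if r.reversible:
            cols.append((j, -1))
    n = len(cols)

    # Tableau rows: (flux over split columns, residual internal balances).
    rows: list[tuple[tuple[int, ...], tuple[Fraction, ...]]] = []
    for k, (j, sgn) in enumerate(cols):
        flux = tuple(1 if i == k else 0 for i in range(n))
        bal = tuple(sgn * reactions[j].stoich.get(sid, Fraction(0)) for sid in internal)
        rows.append((flux, bal))

    for m in range(len(internal)):
        zero = [row for row in rows if row[1][m] == 0]
        pos = [row for row in rows if row[1][m] > 0]
        neg = [row for row in rows if row[1][m] < 0]
        new_rows = list(zero)
        for fp, bp in pos:
            for fn, bn in neg:
                a, b = -bn[m], bp[m]  # positive combination weights
                joint = _integerize(
                    [Fraction(a * x + b * y) for x, y in zip(fp, fn)]
                    + [a * x + b * y for x, y in zip(bp, bn)]
                )
                flux = joint[:n]
                bal = tuple(Fraction(v) for v in joint[n:])
                new_rows.append((flux, bal))
        # drop exact duplicates, then rows whose support strictly contains
        # another row's support (classical elementarity filter)
        dedup: dict[tuple, tuple] = {}
        for f, b in new_rows:
            dedup.setdefault((f, b), (f, b))
        new_rows = list(dedup.values())
        supports = [frozenset(i for i, x in enumerate(f) if x != 0) for f, _ in new_rows]
        keep = []
        for i, si in enumerate(supports):
            if not any(k != i and sk < si for k, sk in enumerate(supports)):
                keep.append(new_rows[i])
        rows = keep

    # Recombine split halves into signed modes; drop forward/backward
    # two-cycles; deduplicate sign-symmetric reversible modes.
    modes: dict[tuple[Fraction, ...], None] = {}
    nr = len(reactions)
    for flux, _bal in rows:
        signed = [Fraction(0)] * nr
        for k, (j, sgn) in enumerate(cols):
            signed[j] += sgn * flux[k]
        if all(v == 0 for v in signed):
            continue  # futile split two-cycle
        ints = _integerize(signed)
        # canonical sign: first nonzero entry positive (irreversible
        # support already forces this; reversible-only modes get it here)
        first = next(v for v in ints if v != 0)
        if first < 0:
            if any(not reactions[j].reversible and ints[j] != 0 for j in range(nr)):
                continue  # would violate irreversibility; keep other copy
            ints = tuple(-v for v in ints)
        if any(not reactions[j].reversible and ints[j] < 0 for j in range(nr)):
            continue
        modes[tuple(Fraction(v) for v in ints)] = None

    def _key(vec: tuple[Fraction, ...]):
        return tuple(j for j, v in enumerate(vec) if v != 0)

    out = []
    for vec in sorted(modes, key=_key):
        out.append(FluxMode(fluxes={r.id: v for r, v in zip(reactions, vec) if v != 0}))
    return out


def normalize_mode(mode: FluxMode, reference: str, value: Fraction | int = 1) -> FluxMode:
    """Rescale a mode so ``reference`` carries exactly ``value``."""
    ref = mode.flux(reference)
    if ref == 0:
        raise ValueError(f"cannot normalize: zero flux on {reference!r}")
    scale = Fraction(value) / ref
    return FluxMode(
        fluxes={r: v * scale for r, v in mode.fluxes.items()},
        normalization=(reference, Fraction(value)),
    )


def mode_yields(mode: FluxMode, network: Network) -> YieldReport:
    """Theoretical PHB yields of a mode, from its boundary net exchange."""
    net = net_equation(mode, network)
    glucose = -net.get("MD", Fraction(0))
    if glucose <= 0:
        raise ValueError("mode consumes no glucose units; yield undefined")
    phb = net.get("PHB", Fraction(0))
    co2 = net.get("CO2", Fraction(0))
    molar = Fraction(100) * phb / glucose
    return YieldReport(
        molar_yield=molar,
        carbon_yield=molar * Fraction(2, 3),
        co2_per_3_glucose=co2 * Fraction(3) / glucose,
    )


def cofactor_closure(mode: FluxMode, network: Network) -> dict[str, Fraction]:
    """Net production flux of the NADP(H), CoA and phosphate moieties.

    Zero for a moiety certifies that the mode cycles it in a self-sustained
    way (the scaffold is neither created nor destroyed), even when the
    redox state of the pool shifts (as in the essential variants, which
    over-produce NADPH at the expense of NADP+).
    """
    fluxes = mode.fluxes
    out: dict[str, Fraction] = {}
    for label, token in _MOIETIES.items():
        total = Fraction(0)
        for r in network.reactions:
            v = fluxes.get(r.id, Fraction(0))
            if v == 0:
                continue
            for sid, c in r.stoich.items():
                count = network.species_by_id(sid).composition.get(token, 0)
                if count:
                    total += v * c * count
        out[label] = total
    return out


def pathway_modes(network: Network) -> list[FluxMode]:
    """The PHB-producing pathway mode(s): positive aGP and PhaC flux."""
    return [
        m for m in elementary_modes(network)
        if m.flux("aGP") > 0 and m.flux("PhaC") > 0
    ]
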