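"""Declarative model of the maltodextrin->PHB enzymatic cascade.

The cascade converts the glucose units of maltodextrin into PHB monomer
units through glycolytic/pentose-phosphate chemistry, bifunctional
phosphoketolase (XPK/FPK activities) and the PhaA-PhaB-PhaC cascade.
Species carry element compositions (with opaque ``CoAm``/``NADPm`` moiety
tokens for the non-transferable CoA and NADP scaffolds) so that every
reaction can be checked for exact C/H/O/P balance.  All stoichiometric
coefficients are :class:`fractions.Fraction`; nothing in this module is
floating point.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Species",
    "Reaction",
    "Network",
    "VARIANTS",
    "build_network",
    "load_network_yaml",
    "stoichiometric_matrix",
    "atom_balance_check",
    "net_equation",
]

#: Variant label -> reactions removed relative to the full network.
_VARIANT_REMOVALS: dict[str, frozenset[str]] = {
    "full": frozenset(),
    "xpk_only": frozenset({"FPK"}),
    "fpk_only": frozenset({"XPK"}),
    # "essential" pathways: the seven carbon-rearranging booster enzymes
    # plus the complementary phosphoketolase activity removed.
    "xpk_essential": frozenset({"TK1", "TK2", "TIM", "ALD", "FBP", "TAL", "RPI", "PGI", "FPK"}),
    "fpk_essential": frozenset({"TK1", "TK2", "TIM", "ALD", "FBP", "TAL", "RPI", "RPE", "XPK"}),
}

#: Species that must be re-designated boundary for a steady-state mode to
#: exist in the essential variants: with the carbon-rearrangement module
#: removed the pathway over-produces NADPH and exports phosphorylated
#: byproducts (G3P, or E4P and Ru5P), and Pi is no longer regenerated.
_VARIANT_EXTRA_BOUNDARY: dict[str, frozenset[str]] = {
    "full": frozenset(),
    "xpk_only": frozenset(),
    "fpk_only": frozenset(),
    # xpk_essential over-produces NADPH (3 excess per 2 glucose units), so
    # the NADP(H) pool cannot be balanced; fpk_essential balances NADP(H)
    # exactly (that coupling is what fixes its 40% yield) so the pool stays
    # internal there.
    "xpk_essential": frozenset({"G3P", "NADP", "NADPH", "Pi"}),
    "fpk_essential": frozenset({"E4P", "Ru5P", "Pi"}),
}

VARIANTS: tuple[str, ...] = tuple(_VARIANT_REMOVALS)


@dataclass(frozen=True)
class Species:
    """A chemical species of the cascade.

    ``composition`` maps element symbols (C, H, O, N, P, S) or opaque
    moiety tokens (``CoAm``, ``NADPm``) to non-negative integer counts.
    ``role`` is ``"internal"`` (balanced at steady state) or ``"boundary"``
    (exempt from the steady-state constraint).
    """

    id: str
    name: str
    role: str
    composition: Mapping[str, int] = field(default_factory=dict)
    initial_conc: float = 0.0  # mM; used only by the kinetics engine

    def __post_init__(self) -> None:
        if self.role not in ("internal", "boundary"):
            raise ValueError(f"species {self.id!r}: role must be internal|boundary")
        for elem, count in self.composition.items():
            if not (isinstance(count, int) and count >= 0):
                raise ValueError(f"species {self.id!r}: composition[{elem!r}] must be a non-negative integer")


@dataclass(frozen=True)
class Reaction:
    """A reaction with exact rational stoichiometry.

    ``stoich`` maps species id -> coefficient (negative = consumed).
    """

    id: str
    name: str
    stoich: Mapping[str, Fraction]
    reversible: bool

    def __post_init__(self) -> None:
        coeffs = {s: Fraction(c) for s, c in self.stoich.items() if c != 0}
        object.__setattr__(self, "stoich", coeffs)
        if not any(c < 0 for c in coeffs.values()) or not any(c > 0 for c in coeffs.values()):
            raise ValueError(f"reaction {self.id!r}: needs at least one reactant and one product")

    @property
    def substrates(self) -> dict[str, Fraction]:
        return {s: -c for s, c in self.stoich.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {s: c for s, c in self.stoich.items() if c > 0}


@dataclass(frozen=True)
class Network:
    """An ordered collection of species and reactions."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    variant: str = "custom"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate species ids")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            raise ValueError("duplicate reaction ids")
        known = set(ids)
        for r in self.reactions:
            missing = set(r.stoich) - known
            if missing:
                raise ValueError(f"reaction {r.id!r} references unknown species {sorted(missing)}")

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def internal_species(self) -> tuple[Species, ...]:
        return tuple(s for s in self.species if s.role == "internal")

    @property
    def boundary_species(self) -> tuple[Species, ...]:
        return tuple(s for s in self.species if s.role == "boundary")

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def reaction_by_id(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def without_reactions(self, rids: Iterable[str], variant: str = "custom") -> "Network":
        drop = set(rids)
        unknown = drop - set(self.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reactions {sorted(unknown)}")
        return Network(
            species=self.species,
            reactions=tuple(r for r in self.reactions if r.id not in drop),
            variant=variant,
        )

    def with_roles(self, boundary_ids: Iterable[str], variant: str | None = None) -> "Network":
        """Return a copy where exactly ``boundary_ids`` are boundary."""
        bset = set(boundary_ids)
        sp = tuple(
            Species(s.id, s.name, "boundary" if s.id in bset else "internal", s.composition, s.initial_conc)
            for s in self.species
        )
        return Network(species=sp, reactions=self.reactions, variant=variant or self.variant)

    def species_table(self) -> pd.DataFrame:
        rows = [
            {"id": s.id, "name": s.name, "role": s.role,
             "composition": " ".join(f"{e}{c}" for e, c in sorted(s.composition.items()))}
            for s in self.species
        ]
        return pd.DataFrame(rows)

    def reaction_table(self) -> pd.DataFrame:
        rows = []
        for r in self.reactions:
            lhs = " + ".join(f"{-c} {s}" if c != -1 else s for s, c in sorted(r.stoich.items()) if c < 0)
            rhs = " + ".join(f"{c} {s}" if c != 1 else s for s, c in sorted(r.stoich.items()) if c > 0)
            arrow = "<=>" if r.reversible else "->"
            rows.append({"id": r.id, "name": r.name, "equation": f"{lhs} {arrow} {rhs}",
                         "reversible": r.reversible})
        return pd.DataFrame(rows)


def load_network_yaml(path_or_stream) -> Network:
    """Load a network from the shipped YAML schema."""
    if hasattr(path_or_stream, "read"):
        doc = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            doc = yaml.safe_load(fh)
    species = tuple(
        Species(
            id=str(rec["id"]),
            name=rec.get("name", str(rec["id"])),
            role=rec.get("role", "internal"),
            composition={k: int(v) for k, v in (rec.get("composition") or {}).items()},
            initial_conc=float(rec.get("initial_conc", 0.0)),
        )
        for rec in doc["species"]
    )
    reactions = tuple(
        Reaction(
            id=str(rec["id"]),
            name=rec.get("name", str(rec["id"])),
            stoich={s: Fraction(c) for s, c in rec["stoich"].items()},
            reversible=bool(rec["reversible"]),
        )
        for rec in doc["reactions"]
    )
    return Network(species=species, reactions=reactions, variant=doc.get("variant", "custom"))


def _load_full() -> Network:
    ref = importlib.resources.files("phbcascade.data.networks") / "full.yaml"
    with ref.open("r") as fh:
        return load_network_yaml(fh)


def build_network(variant: str = "full") -> Network:
    """Build a shipped network variant.

    ``full`` is the 19-reaction cascade; ``xpk_only``/``fpk_only`` restrict
    the bifunctional phosphoketolase to a single activity; the
    ``*_essential`` variants additionally drop the seven carbon-rearranging
    booster enzymes and re-designate the resulting dead-end species
    (accumulating byproducts and the unbalanced NADP(H)/Pi pools) as
    boundary.
    """
    if variant not in _VARIANT_REMOVALS:
        raise ValueError(f"unknown variant {variant!r}; valid variants: {sorted(_VARIANT_REMOVALS)}")
    net = _load_full()
    if variant == "full":
        return net
    net = net.without_reactions(_VARIANT_REMOVALS[variant], variant=variant)
    extra = _VARIANT_EXTRA_BOUNDARY[variant]
    if extra:
        boundary = {s.id for s in net.boundary_species} | set(extra)
        net = net.with_roles(boundary, variant=variant)
    return net


def stoichiometric_matrix(network: Network, scope: str = "internal") -> pd.DataFrame:
    """Exact stoichiometric matrix (rows = species in scope, cols = reactions).

    Entries are :class:`fractions.Fraction` held in an object-dtype frame so
    downstream linear algebra stays exact.
    """
    if scope not in ("internal", "all"):
        raise ValueError("scope must be 'internal' or 'all'")
    species = network.species if scope == "all" else network.internal_species
    data = {
        r.id: [r.stoich.get(s.id, Fraction(0)) for s in species]
        for r in network.reactions
    }
    return pd.DataFrame(data, index=[s.id for s in species], dtype=object)


def atom_balance_check(network: Network) -> dict[str, dict[str, Fraction] | None]:
    """Per-reaction net element deltas (products minus reactants).

    A balanced reaction maps every element to zero.  A reaction touching a
    species with an empty composition is reported as ``None`` (unchecked),
    never as silently zero.
    """
    out: dict[str, dict[str, Fraction] | None] = {}
    comp = {s.id: dict(s.composition) for s in network.species}
    for r in network.reactions:
        if any(not comp[sid] for sid in r.stoich):
            out[r.id] = None
            continue
        delta: dict[str, Fraction] = {}
        for sid, c in r.stoich.items():
            for elem, count in comp[sid].items():
                delta[elem] = delta.get(elem, Fraction(0)) + c * count
        out[r.id] = {e: d for e, d in delta.items()}
    return out


def net_equation(mode, network: Network) -> dict[str, Fraction]:
    """Aggregate boundary exchange of a steady-state flux vector.

    ``mode`` may be a :class:`~phbcascade.efm.FluxMode` or a plain mapping
    reaction-id -> flux.  Internal species must net to exactly zero,
    otherwise the vector is not at steady state and a ``ValueError`` is
    raised.  Returns only the nonzero boundary exchanges.
    """
    fluxes = getattr(mode, "fluxes", mode)
    net: dict[str, Fraction] = {s.id: Fraction(0) for s in network.species}
    for r in network.reactions:
        v = Fraction(fluxes.get(r.id, 0))
        if v == 0:
            continue
        for sid, c in r.stoich.items():
            net[sid] += c * v
    internal = {s.id for s in network.internal_species}
    bad = {sid: val for sid, val in net.items() if sid in internal and val != 0}
    if bad:
        raise ValueError(f"not a steady-state flux vector; internal imbalance: {bad}")
    return {sid: val for sid, val in net.items() if sid not in internal and val != 0}
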