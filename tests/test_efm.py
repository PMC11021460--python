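from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from phbcascade.efm import (cofactor_closure, elementary_modes, mode_yields,
                            normalize_mode, pathway_modes)
from phbcascade.network import build_network, net_equation

from conftest import make_network
from efm_oracle import brute_force_efms, modes_as_tuples

TOY_NETWORKS = {
    "chain": make_network(
        {"A": "boundary", "x": "internal", "B": "boundary"},
        [("r1", {"A": -1, "x": 1}, False), ("r2", {"x": -1, "B": 1}, False)]),
    "branch": make_network(
        {"A": "boundary", "x": "internal", "B": "boundary", "C": "boundary"},
        [("r1", {"A": -1, "x": 1}, False), ("r2", {"x": -1, "B": 1}, False),
         ("r3", {"x": -1, "C": 1}, False)]),
    "futile_cycle": make_network(
        {"x": "internal", "y": "internal"},
        [("r1", {"x": -1, "y": 1}, True), ("r2", {"y": -1, "x": 1}, True)]),
    "diamond_reversible": make_network(
        {"A": "boundary", "x": "internal", "y": "internal", "B": "boundary"},
        [("in", {"A": -1, "x": 1}, False), ("iso", {"x": -1, "y": 1}, True),
         ("out_x", {"x": -1, "B": 1}, False), ("out_y", {"y": -1, "B": 1}, False)]),
    "split_merge": make_network(
        {"A": "boundary", "x": "internal", "y": "internal", "z": "internal",
         "B": "boundary"},
        [("in", {"A": -1, "x": 2}, False), ("up", {"x": -1, "y": 1}, True),
         ("down", {"x": -1, "z": 1}, False),
         ("join", {"y": -1, "z": -1, "B": 1}, True),
         ("leak", {"y": -2, "B": 1}, False)]),
    "cofactor_loop": make_network(
        {"A": "boundary", "B": "boundary", "x": "internal", "n": "internal",
         "nh": "internal"},
        [("ox", {"A": -1, "n": -1, "x": 1, "nh": 1}, False),
         ("red", {"x": -1, "nh": -1, "B": 1, "n": 1}, False),
         ("shunt", {"x": -1, "B": 1}, False),
         ("valve", {"nh": -1, "n": 1}, True)]),
}


class TestEnumeration:
    @pytest.mark.parametrize("name", sorted(TOY_NETWORKS))
    def test_matches_bruteforce_oracle(self, name):
        net = TOY_NETWORKS[name]
        ours = modes_as_tuples(elementary_modes(net), net)
        assert ours == brute_force_efms(net)

    def test_unique_path_is_unit_mode(self):
        modes = elementary_modes(TOY_NETWORKS["chain"])
        assert len(modes) == 1
        assert modes[0].fluxes == {"r1": Fraction(1), "r2": Fraction(1)}

    def test_empty_network_reactions(self):
        from phbcascade.network import Network, Species
        net = Network(species=(Species(id="x", name="x", role="internal"),),
                      reactions=(), variant="empty")
        assert elementary_modes(net) == []

    def test_steady_state_exact_for_all_variants(self):
        for variant in ("full", "xpk_only", "fpk_only", "xpk_essential", "fpk_essential"):
            net = build_network(variant)
            for mode in elementary_modes(net):
                net_equation(mode, net)  # raises if S_internal . v != 0

    def test_deterministic_ordering(self, full_net):
        a = elementary_modes(full_net)
        b = elementary_modes(full_net)
        assert [m.fluxes for m in a] == [m.fluxes for m in b]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.data())
    def test_random_small_networks_match_oracle(self, data):
        n_int = data.draw(st.integers(2, 3))
        n_rx = data.draw(st.integers(3, 5))
        species = {"B0": "boundary", "B1": "boundary"}
        species.update({f"x{i}": "internal" for i in range(n_int)})
        ids = list(species)
        reactions = []
        for j in range(n_rx):
            cols = data.draw(st.lists(
                st.integers(-2, 2), min_size=len(ids), max_size=len(ids)))
            st_map = {s: c for s, c in zip(ids, cols) if c != 0}
            if not (any(c < 0 for c in st_map.values()) and any(c > 0 for c in st_map.values())):
                continue
            reactions.append((f"r{j}", st_map, data.draw(st.booleans())))
        if not reactions:
            return
        net = make_network(species, reactions)
        assert modes_as_tuples(elementary_modes(net), net) == brute_force_efms(net)


class TestPathwayModes:
    def test_xpk_mode_printed_coefficients(self):
        net = build_network("xpk_only")
        (mode,) = pathway_modes(net)
        mode = normalize_mode(mode, "aGP", 3)
        expect = {"aGP": 3, "PGM": 3, "PGI": 1, "G6PDH": 2, "XPK": 8, "TK2": -2}
        for rid, v in expect.items():
            assert mode.flux(rid) == v

    def test_fpk_mode_same_net_equation_as_xpk(self):
        nets = {v: build_network(v) for v in ("xpk_only", "fpk_only")}
        eqs = {}
        for v, net in nets.items():
            (mode,) = pathway_modes(net)
            eqs[v] = net_equation(normalize_mode(mode, "aGP", 3), net)
        assert eqs["xpk_only"] == eqs["fpk_only"]
        assert eqs["xpk_only"] == {"MD": Fraction(-3), "PHB": Fraction(4),
                                   "CO2": Fraction(2), "H2O": Fraction(3)}


class TestNormalization:
    def test_composition_equals_single_normalization(self):
        net = build_network("xpk_only")
        (mode,) = pathway_modes(net)
        twice = normalize_mode(normalize_mode(mode, "XPK", 5), "aGP", 3)
        once = normalize_mode(mode, "aGP", 3)
        assert twice.fluxes == once.fluxes

    def test_identity_normalization(self):
        net = build_network("xpk_only")
        (mode,) = pathway_modes(net)
        assert normalize_mode(mode, "aGP", mode.flux("aGP")).fluxes == mode.fluxes

    def test_zero_reference_rejected(self):
        net = build_network("xpk_only")
        (mode,) = pathway_modes(net)
        with pytest.raises(ValueError, match="zero flux"):
            normalize_mode(mode, "FPK", 1)


class TestYields:
    @pytest.mark.parametrize("variant,molar,carbon", [
        ("xpk_only", "133.3", "88.9"), ("fpk_only", "133.3", "88.9"),
        ("xpk_essential", "50.0", "33.3"), ("fpk_essential", "40.0", "26.7"),
    ])
    def test_theoretical_yields(self, variant, molar, carbon):
        net = build_network(variant)
        (mode,) = pathway_modes(net)
        y = mode_yields(mode, net)
        assert y.molar_percent == float(molar)
        assert y.carbon_percent == float(carbon)
        assert y.carbon_yield == y.molar_yield * Fraction(2, 3)

    def test_yield_bounded_by_400_over_3(self):
        for variant in ("full", "xpk_only", "fpk_only"):
            net = build_network(variant)
            for mode in pathway_modes(net):
                y = mode_yields(mode, net)
                assert 0 <= y.molar_yield <= Fraction(400, 3)

    def test_no_glucose_consumption_rejected(self):
        net = TOY_NETWORKS["chain"]
        (mode,) = elementary_modes(net)
        with pytest.raises(ValueError, match="glucose"):
            mode_yields(mode, net)


class TestCofactorClosure:
    @pytest.mark.parametrize("variant", ["xpk_only", "fpk_only", "xpk_essential"])
    def test_all_moieties_closed(self, variant):
        net = build_network(variant)
        (mode,) = pathway_modes(net)
        closure = cofactor_closure(mode, net)
        assert closure == {"NADP(H)": 0, "CoA": 0, "phosphate": 0}

    def test_no_phb_mode_without_phab(self, full_net):
        net = full_net.without_reactions(["PhaB"])
        assert pathway_modes(net) == []
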