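"""Shorthand lipid parsing, formatting, classification and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aromalip as al
from aromalip.lipids import (
    DEFAULT_REGISTRY,
    KEY_HAM_LIPIDS,
    LipidParseError,
)

# category expected for each of the 14-species ham panel
PANEL_CATEGORIES = {
    "TG(13:1_20:0_20:0)": "GL",
    "TG(O-8:0_14:0_14:1)": "GL",
    "TG(8:0_18:1_26:1)": "GL",
    "DG(O-15:1_20:3)": "GL",
    "PC(O-34:3)": "GP",
    "SM(11:1;2O/30:3)": "SP",
    "Cer(15:1;2O/26:5)": "SP",
    "SHexCer(37:1;2O)": "SP",
    "FAHFA(20:4/18:0)": "FA",
    "NAGly(16:0/18:1)": "FA",
    "PE-Cer(14:3;2O/23:1;O)": "SP",
    "DGCC(23:0_22:2)": "GL",
    "DGCC(18:0_30:0)": "GL",
    "ST(24:1;O3;T/20:1)": "ST",
}


class TestParse:
    def test_multi_chain_tg(self):
        sp = al.parse_lipid("TG(13:1_20:0_20:0)")
        assert sp.class_code == "TG" and sp.category == "GL"
        assert len(sp.chains) == 3
        assert sp.sum_carbons == 53 and sp.sum_double_bonds == 1
        assert not sp.sn_positions_known

    def test_printed_spaces_are_typography(self):
        assert (al.parse_lipid("TG(13: 1_20: 0_20: 0)")
                == al.parse_lipid("TG(13:1_20:0_20:0)"))

    def test_sum_composition_with_ether_prefix(self):
        sp = al.parse_lipid("PC(O-34:3)")
        assert sp.category == "GP" and sp.chains == ()
        assert sp.sum_carbons == 34 and sp.sum_double_bonds == 3
        assert sp.ether_prefix == "O-"

    def test_ceramide_with_oxygens_and_sn(self):
        sp = al.parse_lipid("Cer(15:1;2O/26:5)")
        assert sp.category == "SP" and sp.sn_positions_known
        assert sp.chains[0].extra_oxygens == 2
        assert sp.chains[1] == al.Chain(26, 5)
        assert sp.sum_extra_oxygens == 2

    def test_oxygen_dialects_equivalent(self):
        a = al.parse_lipid("ST(24:1;O2/20:1)")
        b = al.parse_lipid("ST(24:1;2O/20:1)")
        assert a.chains[0].extra_oxygens == b.chains[0].extra_oxygens == 2

    def test_uninterpretable_token_preserved(self):
        sp = al.parse_lipid("ST(24:1;O3;T/20:1)")
        assert sp.chains[0].extra_oxygens == 3
        assert sp.chains[0].extra_tokens == ("T",)
        assert sp.extra_tokens == ("T",)

    def test_unknown_class_code_lists_registry(self):
        with pytest.raises(LipidParseError, match="TG"):
            al.parse_lipid("XYZZY(16:0)")

    def test_malformed_chain_reports_position(self):
        with pytest.raises(LipidParseError, match="character"):
            al.parse_lipid("TG(16:0_bad_18:1)")

    def test_impossible_double_bonds_rejected(self):
        with pytest.raises(LipidParseError, match="double"):
            al.parse_lipid("FA(4:9)")

    def test_lenient_mode_unknown_code(self):
        sp = al.parse_lipid("QQ(16:0)", lenient=True)
        assert sp.category == "unknown"

    def test_chain_sum_consistency_panel(self):
        for name in KEY_HAM_LIPIDS:
            sp = al.parse_lipid(name)
            if sp.chains:
                assert sp.sum_carbons == sum(c.carbons for c in sp.chains)
                assert sp.sum_double_bonds == sum(
                    c.double_bonds for c in sp.chains)

    def test_panel_categories(self):
        for name, cat in PANEL_CATEGORIES.items():
            assert al.parse_lipid(name).category == cat, name


class TestFormat:
    def test_whitespace_normalization(self):
        sp = al.parse_lipid("TG(13: 1_20: 0_20: 0)")
        assert al.format_lipid(sp) == "TG(13:1_20:0_20:0)"

    def test_fahfa_round_trips_unchanged(self):
        name = "FAHFA(20:4/18:0)"
        assert al.format_lipid(al.parse_lipid(name)) == name

    def test_panel_round_trips(self):
        for name in KEY_HAM_LIPIDS:
            sp = al.parse_lipid(name)
            assert al.parse_lipid(al.format_lipid(sp)) == sp, name


@st.composite
def lipid_names(draw):
    """Grammar-fuzzed shorthand names (spaces included as typography)."""
    code = draw(st.sampled_from(sorted(DEFAULT_REGISTRY)))
    n_chains = draw(st.integers(1, 4))
    chains = []
    for _ in range(n_chains):
        carbons = draw(st.integers(2, 40))
        dbs = draw(st.integers(0, min(carbons, 8)))
        prefix = draw(st.sampled_from(["", "", "", "O-", "P-"]))
        suffix = draw(st.sampled_from(["", "", ";O", ";2O", ";3O"]))
        chains.append(f"{prefix}{carbons}:{dbs}{suffix}")
    sep = draw(st.sampled_from(["_", "/"]))
    body = sep.join(chains)
    if draw(st.booleans()):
        body = body.replace(":", ": ")
    return f"{code}({body})"


class TestGrammarFuzz:
    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(lipid_names())
    def test_parse_format_round_trip(self, name):
        sp = al.parse_lipid(name)
        canon = al.format_lipid(sp)
        again = al.parse_lipid(canon)
        assert again == sp
        assert al.format_lipid(again) == canon
        if sp.chains:
            assert sp.sum_carbons == sum(c.carbons for c in sp.chains)
            assert sp.sum_double_bonds == sum(
                c.double_bonds for c in sp.chains)


class TestCategorize:
    @pytest.mark.parametrize("code, cat", [
        ("TG", "GL"), ("SM", "SP"), ("NAGly", "FA"),
        ("PC", "GP"), ("PE-Cer", "SP"), ("CE", "ST"), ("PR", "PR"),
    ])
    def test_default_registry(self, code, cat):
        assert al.categorize(code) == cat

    def test_user_registry_overrides(self):
        assert al.categorize("NAGly", registry={"NAGly": "GP"}) == "GP"

    def test_unregistered_raises(self):
        with pytest.raises(KeyError):
            al.categorize("nope")


class TestShares:
    def test_single_species(self):
        t = pd.DataFrame([[1.0, 2.0]], index=["TG(16:0_18:1_18:2)"])
        out = al.class_shares(t, "class_code")
        assert out["share_percent"].iloc[0] == 100.0

    def test_two_classes_25_75(self):
        t = pd.DataFrame(
            [[1.0, 1.0], [3.0, 3.0]],
            index=["PC(34:2)", "TG(16:0_18:1_18:2)"],
        )
        out = al.class_shares(t, "category").set_index("category")
        assert out.loc["GL", "share_percent"] == 75.0
        assert out.loc["GP", "share_percent"] == 25.0

    def test_shares_sum_to_100_both_levels(self):
        t = al.generate_lipid_table(
            200, {"TG": 3, "DG": 2, "PC": 2, "SM": 1, "FAHFA": 1}, seed=5)
        for level in ("category", "class_code"):
            out = al.class_shares(t, level)
            assert out["share_percent"].sum() == pytest.approx(100.0)


class TestKeyLipids:
    def test_planted_order_recovered(self):
        names = ["TG(16:0_18:1_18:2)", "PC(34:2)", "SM(18:1;2O/16:0)"]
        t = pd.DataFrame(
            [[5.0, 5.0], [1.0, 1.0], [3.0, 3.0]], index=names)
        out = al.select_key_lipids(t, top_n=2)
        assert list(out["lipid"]) == [names[0], names[2]]
        assert list(out["rank"]) == [1, 2]

    def test_top_n_exceeding_count_returns_all(self, caplog):
        import logging
        t = pd.DataFrame([[1.0, 1.0]], index=["PC(34:2)"])
        with caplog.at_level(logging.WARNING, logger="aromalip"):
            out = al.select_key_lipids(t, top_n=14)
        assert len(out) == 1
        assert "exceeds" in caplog.text
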