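"""Audit framework: count identities, substitution network, category matrix."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishaudit.audit import (
    NameAudit,
    SubstitutionEdge,
    audit_all,
    audit_name,
    build_network,
    category_matrix,
    conservation_report,
    filter_focal_names,
    network_graph,
    round_half_up,
)
from fishaudit.labeling import Catalog


class TestNameAuditIdentities:
    def test_high_substitutability_name(self):
        # heavily demanded name: 58 sold, 52 correct, species substituted 15 times
        audit = NameAudit.from_counts("atun", 58, 52, 4, 15, 4)
        assert audit.mislabeling_frequency == 6
        assert audit.confirmed_samples == 67
        assert audit.over_sub_representation == -9
        assert round_half_up(audit.over_sub_representation_percentage) == -13.43
        assert round_half_up(audit.mislabeling_percentage) == 10.34

    def test_extreme_over_representation(self):
        # 18 sold, 1 genuine, never used as substitute
        audit = NameAudit.from_counts("marlin", 18, 1, 5, 0, 0)
        assert audit.confirmed_samples == 1
        assert audit.over_sub_representation == 17
        assert audit.over_sub_representation_percentage == pytest.approx(1700.0)

    def test_zero_mislabels_zero_substitutions(self):
        audit = NameAudit.from_counts("basa", 12, 12, 0, 0, 0)
        assert audit.confirmed_samples == 12
        assert audit.over_sub_representation == 0
        assert audit.over_sub_representation_percentage == 0.0

    def test_zero_confirmed_percentage_is_missing(self):
        audit = NameAudit.from_counts("ghost", 4, 0, 1, 0, 0)
        assert audit.confirmed_samples == 0
        assert audit.over_sub_representation_percentage is None
        assert audit.as_row()["over_sub_representation_percentage"] is None

    @given(
        verbal=st.integers(0, 500),
        correct=st.integers(0, 500),
        subfreq=st.integers(0, 200),
    )
    def test_identities_hold_for_any_counts(self, verbal, correct, subfreq):
        if correct > verbal:
            correct = verbal
        audit = NameAudit.from_counts("x", verbal, correct, 0, subfreq, 0)
        assert audit.verbal_sample_number == audit.correctly_labeled + audit.mislabeling_frequency
        assert audit.confirmed_samples == audit.correctly_labeled + audit.substitutability_frequency
        assert audit.over_sub_representation == audit.verbal_sample_number - audit.confirmed_samples
        if verbal:
            assert audit.mislabeling_percentage == pytest.approx(
                100.0 * audit.mislabeling_frequency / verbal
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            NameAudit("x", verbal_sample_number=5, correctly_labeled=3,
                      mislabeling_frequency=3, mislabeling_diversity=0,
                      substitutability_frequency=0, substitutability_diversity=0)


def _calls(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "commercial_name", "status", "candidates", "substitute"]
    )


@pytest.fixture
def toy_audit_calls():
    """Two names; 'Thunnus albacares' (accepted for atun) substitutes marlin."""
    rows = [
        ("s1", "atun", "correct", "Thunnus albacares", ""),
        ("s2", "atun", "correct", "Thunnus albacares", ""),
        ("s3", "atun", "mislabeled", "Salmo salar", "Salmo salar"),
        ("s4", "marlin", "mislabeled", "Thunnus albacares", "Thunnus albacares"),
        ("s5", "marlin", "mislabeled", "Thunnus albacares", "Thunnus albacares"),
        ("s6", "marlin", "correct", "Makaira nigricans", ""),
        ("s7", "pescado", "excluded_generic", "Salmo salar", ""),
    ]
    catalogs = [
        Catalog("c1", {"atun": frozenset({"Thunnus albacares"}),
                       "marlin": frozenset({"Makaira nigricans"})}),
    ]
    return _calls(rows), catalogs


class TestAuditFromCalls:
    def test_focal_name_tabulation(self, toy_audit_calls):
        calls, catalogs = toy_audit_calls
        atun = audit_name("atun", calls, catalogs)
        assert atun.verbal_sample_number == 3
        assert atun.correctly_labeled == 2
        assert atun.mislabeling_frequency == 1
        assert atun.mislabeling_diversity == 1
        # its species substituted marlin twice, one other name
        assert atun.substitutability_frequency == 2
        assert atun.substitutability_diversity == 1
        assert atun.confirmed_samples == 4
        assert atun.over_sub_representation == -1

    def test_absent_name_audits_to_zeros(self, toy_audit_calls):
        calls, catalogs = toy_audit_calls
        audit = audit_name("huachinango", calls, catalogs)
        assert audit.verbal_sample_number == 0
        assert audit.confirmed_samples == 0

    def test_excluded_statuses_out_of_denominators(self, toy_audit_calls):
        calls, catalogs = toy_audit_calls
        total_verbal = sum(a.verbal_sample_number for a in audit_all(calls, catalogs))
        assert total_verbal == 6  # the generic pescado sample is not counted

    def test_substitution_credited_once_to_largest_name(self):
        # species accepted under two names; events credit the better-sampled one
        calls = _calls(
            [
                ("s1", "atun", "correct", "Thunnus albacares", ""),
                ("s2", "atun", "correct", "Thunnus albacares", ""),
                ("s3", "bonito", "correct", "Thunnus albacares", ""),
                ("s4", "marlin", "mislabeled", "Thunnus albacares", "Thunnus albacares"),
            ]
        )
        catalogs = [
            Catalog("c1", {"atun": frozenset({"Thunnus albacares"}),
                           "bonito": frozenset({"Thunnus albacares"}),
                           "marlin": frozenset({"Makaira nigricans"})}),
        ]
        audits = {a.commercial_name: a for a in audit_all(calls, catalogs)}
        assert audits["atun"].substitutability_frequency == 1
        assert audits["bonito"].substitutability_frequency == 0
        both = {a.commercial_name: a for a in audit_all(calls, catalogs, credit="all")}
        assert both["atun"].substitutability_frequency == 1
        assert both["bonito"].substitutability_frequency == 1


class TestNetwork:
    def test_no_mislabels_empty_network(self):
        calls = _calls([("s1", "atun", "correct", "Thunnus albacares", "")])
        edges, n_sp, n_nm, n_combos = build_network(calls)
        assert edges == [] and n_sp == n_nm == n_combos == 0

    def test_repeated_substitution_single_edge(self):
        calls = _calls(
            [(f"s{i}", "marlin", "mislabeled", "Thunnus albacares", "Thunnus albacares")
             for i in range(3)]
        )
        edges, n_sp, n_nm, n_combos = build_network(calls)
        assert len(edges) == 1 and edges[0].count == 3 and n_combos == 1

    def test_edge_counts_sum_to_mislabeled_calls(self, small_calls):
        edges, *_ = build_network(small_calls)
        assert sum(e.count for e in edges) == int(
            (small_calls["status"] == "mislabeled").sum()
        )

    def test_degrees_reproduce_diversities(self, small_calls, small_catalogs):
        edges, *_ = build_network(small_calls)
        graph = network_graph(edges)
        for audit in audit_all(small_calls, small_catalogs):
            node = f"name:{audit.commercial_name}"
            in_degree = graph.in_degree(node) if node in graph else 0
            assert audit.mislabeling_diversity == in_degree

    def test_substitutability_sum_bounded_by_mislabeling_sum(self, small_calls, small_catalogs):
        audits = audit_all(small_calls, small_catalogs)
        assert sum(a.substitutability_frequency for a in audits) <= sum(
            a.mislabeling_frequency for a in audits
        )

    def test_edge_count_must_be_positive(self):
        with pytest.raises(ValueError):
            SubstitutionEdge("Salmo salar", "atun", 0)


class TestCategoryMatrix:
    def test_single_edge_full_percentage(self):
        edges = [SubstitutionEdge("Thunnus albacares", "marlin", 1)]
        counts, pct = category_matrix(
            edges, {"Thunnus albacares": "marine_bony"}, {"marlin": "marine_bony"}
        )
        assert counts.loc["marine_bony", "marine_bony"] == 1
        assert pct.loc["marine_bony", "marine_bony"] == 100.0
        assert pct.values.sum() == pytest.approx(100.0)

    def test_confined_substitution_design(self):
        edges = [
            SubstitutionEdge("Pangasianodon hypophthalmus", "mero", 5),
            SubstitutionEdge("Oreochromis niloticus", "huachinango", 3),
        ]
        counts, pct = category_matrix(
            edges,
            {"Pangasianodon hypophthalmus": "aquaculture_freshwater",
             "Oreochromis niloticus": "aquaculture_freshwater"},
            {"mero": "marine_bony", "huachinango": "marine_bony"},
        )
        assert pct.loc["aquaculture_freshwater", "marine_bony"] == 100.0
        assert counts.values.sum() == 8

    def test_unmapped_offenders_listed(self):
        edges = [SubstitutionEdge("Salmo salar", "trucha", 1)]
        with pytest.raises(ValueError, match="Salmo salar"):
            category_matrix(edges, {}, {"trucha": "marine_bony"})


class TestFilterFocalNames:
    def _audits(self):
        return [
            NameAudit.from_counts("a", 10, 8),
            NameAudit.from_counts("b", 6, 6),
            NameAudit.from_counts("c", 2, 1),
        ]

    def test_threshold_and_ordering(self):
        focal = filter_focal_names(self._audits(), min_verbal=6)
        assert [a.commercial_name for a in focal] == ["a", "b"]

    def test_min_one_keeps_all(self):
        assert len(filter_focal_names(self._audits(), min_verbal=1)) == 3

    def test_above_max_empty(self):
        assert filter_focal_names(self._audits(), min_verbal=11) == []


class TestConservationReport:
    def test_empty_status_table_all_unclassified(self, small_calls):
        empty = pd.DataFrame(columns=["species", "iucn", "cites"])
        report = conservation_report(small_calls, empty)
        assert (report["iucn"] == "unclassified").all()

    def test_threatened_rate_on_toy_counts(self):
        # 46 samples of listed species, six mislabeled -> 13.0%
        rows = []
        for i in range(40):
            rows.append((f"c{i}", "cazon", "correct", "Sphyrna lewini", ""))
        for i in range(6):
            rows.append((f"m{i}", "marlin", "mislabeled", "Alopias pelagicus",
                         "Alopias pelagicus"))
        calls = _calls(rows)
        status = pd.DataFrame(
            {
                "species": ["Sphyrna lewini", "Alopias pelagicus"],
                "iucn": ["critically endangered", "endangered"],
                "cites": ["II", "II"],
            }
        )
        report = conservation_report(calls, status)
        listed = report[report["iucn"] != "unclassified"]
        n, k = listed["n_samples"].sum(), listed["n_mislabeled"].sum()
        assert (n, k) == (46, 6)
        assert round(100.0 * k / n, 1) == 13.0

    def test_cites_tally(self):
        calls = _calls(
            [("s1", "cazon", "correct", "Sphyrna lewini", ""),
             ("s2", "cazon", "correct", "Sphyrna lewini", "")]
        )
        status = pd.DataFrame(
            {"species": ["Sphyrna lewini"], "iucn": ["critically endangered"],
             "cites": ["II"]}
        )
        report = conservation_report(calls, status)
        cites_ii = report[report["cites"] == "II"]
        assert cites_ii["n_samples"].sum() == 2


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected", [(0.125, 0.13), (53.845, 53.85), (-13.432835, -13.43), (2.5, 2.5)]
    )
    def test_round_half_up(self, value, expected):
        assert round_half_up(value) == expected
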