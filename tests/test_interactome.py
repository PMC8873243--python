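import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netperturb.interactome import (
    InterfaceRecord,
    InterfaceTableError,
    ResidueLocation,
    ResidueRsaRecord,
    assign_rsa_location,
    build_network,
    consensus_location,
    filter_interactions,
    parse_interface_table,
    records_to_table,
)

from conftest import net_from_dicts

C = ResidueLocation.CORE
S = ResidueLocation.SURFACE
U = ResidueLocation.UNRESOLVED


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _write_tsv(path, rows, header=("Uniprot1", "Uniprot2", "Uniprot1_residue")):
    pd.DataFrame(rows, columns=list(header)).to_csv(path, sep="\t", index=False)
    return path


def test_parse_basic_and_implied_interface_sets(tmp_path):
    path = _write_tsv(tmp_path / "t.tsv", [("P1", "P2", 10), ("P1", "P2", 12), ("P2", "P1", 5)])
    records = parse_interface_table(path)
    assert records == [
        InterfaceRecord("P1", "P2", 10),
        InterfaceRecord("P1", "P2", 12),
        InterfaceRecord("P2", "P1", 5),
    ]


def test_parse_deduplicates_rows_preserving_order(tmp_path):
    path = _write_tsv(
        tmp_path / "t.tsv",
        [("P1", "P2", 10), ("P1", "P2", 10), ("P2", "P1", 5), ("P1", "P2", 10)],
    )
    records = parse_interface_table(path)
    assert records == [InterfaceRecord("P1", "P2", 10), InterfaceRecord("P2", "P1", 5)]


def test_parse_xlsx_dialect(tmp_path):
    path = tmp_path / "t.xlsx"
    pd.DataFrame(
        [("P1", "P2", 3)], columns=["Uniprot1", "Uniprot2", "Uniprot1_residue"]
    ).to_excel(path, index=False)
    assert parse_interface_table(path) == [InterfaceRecord("P1", "P2", 3)]


def test_parse_missing_column_names_the_column(tmp_path):
    path = _write_tsv(tmp_path / "t.tsv", [("P1", "P2", 1)], header=("Uniprot1", "Uniprot2", "other"))
    with pytest.raises(InterfaceTableError, match="Uniprot1_residue"):
        parse_interface_table(path)


def test_parse_non_integer_residue_reports_row(tmp_path):
    path = _write_tsv(tmp_path / "t.tsv", [("P1", "P2", 1), ("P1", "P2", "x")])
    with pytest.raises(InterfaceTableError, match="row 1"):
        parse_interface_table(path)


def test_parse_roundtrip_is_identity(tmp_path):
    rows = [("P1", "P2", 10), ("P2", "P1", 5), ("P3", "P1", 2)]
    records = parse_interface_table(_write_tsv(tmp_path / "a.tsv", rows))
    records_to_table(records).to_csv(tmp_path / "b.tsv", sep="\t", index=False)
    assert parse_interface_table(tmp_path / "b.tsv") == records


# ---------------------------------------------------------------------------
# location rules
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "rsa,expected",
    [(3.0, C), (0.0, C), (4.999, C), (20.0, S), (15.001, S), (10.0, U), (5.0, U), (15.0, U)],
)
def test_rsa_thresholds(rsa, expected):
    assert assign_rsa_location(rsa) is expected


def test_negative_rsa_rejected():
    with pytest.raises(ValueError):
        assign_rsa_location(-0.1)


@pytest.mark.parametrize(
    "labels,expected",
    [
        ([C, C, S], C),
        ([S, S], S),
        ([C, S], U),
        ([U, U, U], U),
        ([C, U, U], C),
        ([S, C, S, C], U),
    ],
)
def test_consensus_majority_rule(labels, expected):
    assert consensus_location(labels) is expected


def test_consensus_empty_rejected():
    with pytest.raises(ValueError):
        consensus_location([])


@given(st.lists(st.sampled_from([C, S, U]), min_size=1, max_size=15))
@settings(max_examples=200, derandomize=True)
def test_consensus_matches_counting(labels):
    n_core = sum(1 for x in labels if x is C)
    n_surf = sum(1 for x in labels if x is S)
    expected = C if n_core > n_surf else S if n_surf > n_core else U
    assert consensus_location(labels) is expected


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _records(pair_sizes):
    """pair_sizes: {(a, b): (na, nb)} -> records with that many residues."""
    records = []
    for (a, b), (na, nb) in pair_sizes.items():
        records += [InterfaceRecord(a, b, i + 1) for i in range(na)]
        records += [InterfaceRecord(b, a, i + 1) for i in range(nb)]
    return records


def test_filter_requires_five_on_both_sides():
    kept = filter_interactions(_records({("P1", "P2"): (5, 5)}))
    assert len(kept) == 10
    dropped = filter_interactions(_records({("P1", "P2"): (6, 4)}))
    assert dropped == []


def test_filter_empty_input():
    assert filter_interactions([]) == []


def test_filter_counts_distinct_positions_not_rows():
    # 6 rows but only 4 distinct positions on P2's side
    records = _records({("P1", "P2"): (5, 4)})
    records.append(InterfaceRecord("P2", "P1", 4))  # duplicate position
    assert filter_interactions(records) == []


@given(
    st.dictionaries(
        st.tuples(st.sampled_from("ABCD"), st.sampled_from("EFGH")),
        st.tuples(st.integers(0, 8), st.integers(0, 8)),
        max_size=6,
    )
)
@settings(max_examples=100, derandomize=True)
def test_filter_monotone_in_threshold(pair_sizes):
    records = _records(pair_sizes)
    edge_count = lambda recs: len({tuple(sorted((r.protein_a, r.protein_b))) for r in recs})
    counts = [edge_count(filter_interactions(records, min_residues=t)) for t in range(1, 8)]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def test_build_toy_network_structure():
    net = net_from_dicts({("P1", "P2"): ({10, 12, 1, 2, 3}, {5, 6, 7, 8, 9})})
    assert net.nodes == ["P1", "P2"]
    assert net.edges == [("P1", "P2")]
    assert net.interface_positions("P1", "P2")["P1"] == {10, 12, 1, 2, 3}
    # symmetric access
    assert net.interface_positions("P2", "P1") == net.interface_positions("P1", "P2")


def test_interface_overrides_rsa_core_label():
    net = net_from_dicts(
        {("P1", "P2"): ({10, 11, 12, 13, 14}, {1, 2, 3, 4, 5})},
        rsa={("P1", 10): 3.0, ("P1", 20): 3.0},
    )
    assert net.location("P1", 10) is ResidueLocation.INTERFACE
    assert net.location("P1", 20) is ResidueLocation.CORE


def test_residues_of_dropped_edges_revert_to_rsa_labels():
    records = _records({("P1", "P2"): (5, 5), ("P1", "P3"): (6, 4)})
    rsa = [ResidueRsaRecord("P1", "A", 6, 50.0)]  # position 6 only in dropped edge
    net = build_network(filter_interactions(records), rsa)
    assert net.edges == [("P1", "P2")]
    assert net.location("P1", 6) is ResidueLocation.SURFACE


def test_self_interactions_excluded_by_default():
    records = _records({("P1", "P2"): (5, 5)}) + [
        InterfaceRecord("P3", "P3", i + 1) for i in range(10)
    ]
    net = build_network(filter_interactions(records), [])
    assert "P3" not in net.nodes
    net2 = build_network(filter_interactions(records), [], include_self_loops=True)
    assert "P3" in net2.nodes


def test_interface_labels_appear_only_in_edge_sets(small_bundle):
    net = small_bundle.network
    in_some_edge = {
        (p, pos)
        for sides in net.interface_map.values()
        for p, positions in sides.items()
        for pos in positions
    }
    for protein, positions in net.location_map.items():
        for pos, loc in positions.items():
            if loc is ResidueLocation.INTERFACE:
                assert (protein, pos) in in_some_edge
            else:
                assert (protein, pos) not in in_some_edge


def test_table_exports_roundtrip(small_bundle, tmp_path):
    net = small_bundle.network
    net.write_tables(tmp_path / "edges.tsv", tmp_path / "residues.tsv")
    edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    assert len(edges) == len(net.edges)
    assert (edges[["n_iface_a", "n_iface_b"]] >= 5).all().all()
    residues = pd.read_csv(tmp_path / "residues.tsv", sep="\t")
    assert set(residues["location"]) <= {"CORE", "SURFACE", "INTERFACE", "UNRESOLVED"}
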