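"""Interaction-table ingestion, alias harmonization and merging."""

import pytest

from lcenet.catalog import (
    InteractionCatalog,
    InteractionEdge,
    harmonize_and_merge,
    read_alias_map,
    read_interaction_table,
    read_catalog,
    write_catalog,
)


def write_tsv(path, rows, header="mirna\ttarget"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


def test_read_dedupes_and_counts(tmp_path):
    f = tmp_path / "t.tsv"
    write_tsv(f, ["miR-X\tGENE1", "miR-X\tGENE1", "miR-Y\tGENE2"])
    edges, rep = read_interaction_table(f, "mRNA", "dbA")
    assert len(edges) == 2
    assert rep.duplicates == 1 and rep.rows == 3


def test_read_drops_blank_rows(tmp_path):
    f = tmp_path / "t.tsv"
    write_tsv(f, ["miR-X\tGENE1", "miR-Y\t", "miR-Z\tGENE3"])
    edges, rep = read_interaction_table(f, "mRNA", "dbA")
    assert len(edges) == 2 and rep.dropped_blank == 1


def test_read_missing_column_names_the_column(tmp_path):
    f = tmp_path / "t.tsv"
    f.write_text("mirna\tgene\nmiR-X\tGENE1\n")
    with pytest.raises(ValueError, match="target"):
        read_interaction_table(f, "mRNA", "dbA")


def test_read_empty_file_warns(tmp_path):
    f = tmp_path / "t.tsv"
    f.write_text("mirna\ttarget\n")
    with pytest.warns(UserWarning):
        edges, rep = read_interaction_table(f, "mRNA", "dbA")
    assert edges == [] and rep.rows == 0


def test_merge_unions_sources_across_files(tmp_path):
    a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_tsv(a, ["miR-X\tGENE1"])
    write_tsv(b, ["mir-x\tgene1"])  # same pair, different case conventions
    ea, _ = read_interaction_table(a, "mRNA", "dbA")
    eb, _ = read_interaction_table(b, "mRNA", "dbB")
    cat, rep = harmonize_and_merge([ea, eb])
    assert len(cat.edges) == 1
    assert cat.edges[0].sources == {"dbA", "dbB"}
    assert rep.duplicates == 1


def _edge(m, t, cls="mRNA", src="db"):
    return InteractionEdge(m, t, cls, frozenset([src]))


def test_merge_dedupes_within_fragment():
    cat, _ = harmonize_and_merge([[_edge("m1", "A"), _edge("m1", "A"), _edge("m2", "B")]])
    assert len(cat.edges) == 2


def test_merge_excludes_unmapped_targets():
    aliases = {"RAW1": "GENE1"}
    cat, rep = harmonize_and_merge(
        [[_edge("m1", "RAW1"), _edge("m1", "RAW2")]], aliases=aliases
    )
    assert len(cat.edges) == 1 and rep.unmapped == 1
    assert cat.edges[0].target_id == "GENE1"


def test_merge_multiple_fragments_with_redundancy():
    # 5 fragments, 12 rows, 3 cross-file redundancies -> 9 edges
    frags = [
        [_edge("m1", "A"), _edge("m1", "B")],
        [_edge("m1", "A"), _edge("m2", "C")],
        [_edge("m3", "D"), _edge("m1", "B"), _edge("m3", "E")],
        [_edge("m4", "F", "lncRNA"), _edge("m4", "G", "lncRNA")],
        [_edge("m4", "F", "lncRNA"), _edge("m5", "H"), _edge("m5", "I")],
    ]
    expected = {
        (e.mirna_id, e.target_id, e.target_class) for frag in frags for e in frag
    }
    cat, rep = harmonize_and_merge(frags)
    assert len(cat.edges) == len(expected) == 9
    assert rep.rows == 12 and rep.duplicates == 3


def test_merge_idempotent_and_order_invariant():
    frags = [
        [_edge("m1", "A"), _edge("m2", "B", "lncRNA")],
        [_edge("m1", "A", src="db2"), _edge("m3", "C")],
    ]
    once, _ = harmonize_and_merge(frags)
    twice, _ = harmonize_and_merge([once.edges])
    assert set(once.edges) == set(twice.edges)
    rev, _ = harmonize_and_merge(frags[::-1])
    assert set(once.edges) == set(rev.edges)


def test_per_source_counts_bound_merged_count():
    frags = [
        [_edge("m1", "A", src="db1"), _edge("m2", "B", src="db1")],
        [_edge("m1", "A", src="db2"), _edge("m2", "C", src="db2")],
    ]
    cat, _ = harmonize_and_merge(frags)
    assert sum(len(f) for f in frags) >= len(cat.edges)


def test_ambiguous_alias_is_hard_error(tmp_path):
    f = tmp_path / "alias.tsv"
    f.write_text("RAW1\tGENE1\nRAW1\tGENE2\n")
    with pytest.raises(ValueError, match="ambiguous"):
        read_alias_map(f)


def test_pair_in_both_classes_warns_not_errors():
    frags = [[_edge("m1", "A", "mRNA"), _edge("m1", "A", "lncRNA")]]
    with pytest.warns(UserWarning, match="both"):
        cat, _ = harmonize_and_merge(frags)
    assert len(cat.edges) == 2


def test_universe_cannot_undercount_catalog_mirnas():
    with pytest.raises(ValueError):
        InteractionCatalog([_edge("m1", "A"), _edge("m2", "B")], n_mirna_universe=1)


def test_catalog_roundtrip(tmp_path, fixture_study):
    path = tmp_path / "catalog.tsv"
    write_catalog(fixture_study.catalog, path)
    back = read_catalog(path, fixture_study.catalog.n_mirna_universe)
    assert set(back.edges) == set(fixture_study.catalog.edges)
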