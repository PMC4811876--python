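"""Motif scanning, conserved-window discovery and annotation."""

import pytest

from grasfam.alignment import MultipleAlignment
from grasfam.family_model import ProteinRecord
from grasfam.motifs import (
    CORE_MOTIFS,
    ConservedWindowRule,
    MotifPattern,
    annotate,
    default_catalog,
    discover_conserved_windows,
    read_catalog,
    scan_pattern,
)
from grasfam.synthetic import SimulationConfig, simulate_family


def _rec(seq, name="p"):
    return ProteinRecord(id=name, sequence=seq)


class TestPatternLanguage:
    def test_literal_wildcard_and_sets(self):
        pat = MotifPattern(name="t", pattern="A[LIVF]X+R")
        pos = pat.positions
        assert pos[0] == frozenset("A")
        assert pos[1] == frozenset("LIVF")
        assert pos[2] is None and pos[3] is None
        assert len(pat) == 5

    def test_empty_alternative_set_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern(name="t", pattern="A[]R")


class TestScanPattern:
    def test_literal_della_found_exactly(self):
        hits = scan_pattern(_rec("MKRDELLAALGYKV"), MotifPattern("DELLA", "DELLA"))
        assert [(h.start, h.end, h.match_score) for h in hits] == [(4, 8, 1.0)]

    def test_lxxll_wildcards_unconstrained(self):
        hits = scan_pattern(_rec("LAALL"), MotifPattern("LXXLL", "LXXLL"))
        assert hits and hits[0].match_score == 1.0

    def test_alternative_set_position(self):
        pat = MotifPattern("LRITG", "[LIVF]RITG")
        for variant in ("LRITG", "IRITG", "VRITG", "FRITG"):
            assert scan_pattern(_rec("AA" + variant + "AA"), pat)
        assert scan_pattern(_rec("AAKRITGAA"), pat, min_score=1.0) == []

    def test_pattern_longer_than_sequence(self):
        assert scan_pattern(_rec("ML"), MotifPattern("t", "DELLA")) == []

    def test_partial_match_respects_score_floor(self):
        # DELLA with one substitution: 4/5 = 0.8
        hits = scan_pattern(_rec("MKRDELRAALGY"), MotifPattern("DELLA", "DELLA"), 0.7)
        assert hits and hits[0].match_score == pytest.approx(0.8)
        assert scan_pattern(_rec("MKRDELRAALGY"), MotifPattern("DELLA", "DELLA"), 0.9) == []

    def test_hits_non_overlapping_greedy_best_first(self):
        hits = scan_pattern(_rec("DELLADELLA"), MotifPattern("DELLA", "DELLA"))
        assert [(h.start, h.end) for h in hits] == [(1, 5), (6, 10)]


def _msa(rows):
    return MultipleAlignment(rows=list(rows))


class TestConservedWindows:
    def test_fully_conserved_block(self):
        rows = [(f"r{i}", "ACDEFGHIKLMN") for i in range(4)]
        windows = discover_conserved_windows(_msa(rows))
        assert len(windows) == 1
        (start, end), idents = windows[0]
        assert (start, end) == (1, 12)
        assert all(x == 1.0 for x in idents)

    def test_exactly_half_identity_is_reported(self):
        # 4 rows, every column has the modal residue in exactly 2 rows
        rows = [
            ("a", "AAAAAAAAAA"),
            ("b", "AAAAAAAAAA"),
            ("c", "CCCCCCCCCC"),
            ("d", "DDDDDDDDDD"),
        ]
        windows = discover_conserved_windows(_msa(rows))
        assert windows and windows[0][0] == (1, 10)
        assert all(x == 0.5 for x in windows[0][1])

    def test_gaps_count_against_identity(self):
        rows = [("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAA"), ("c", "-" * 10), ("d", "-" * 10)]
        assert discover_conserved_windows(_msa(rows))  # 0.5 with gaps against
        rows = [("a", "AAAAAAAAAA"), ("b", "-" * 10), ("c", "-" * 10), ("d", "-" * 10)]
        assert discover_conserved_windows(_msa(rows)) == []

    def test_nine_conserved_columns_below_min_length(self):
        rows = [
            ("a", "W" + "ACDEFGHIK" + "W"),
            ("b", "Y" + "ACDEFGHIK" + "F"),
            ("c", "F" + "ACDEFGHIK" + "Y"),
            ("d", "H" + "ACDEFGHIK" + "M"),
        ]
        assert discover_conserved_windows(_msa(rows)) == []

    def test_windows_are_maximal(self):
        rule = ConservedWindowRule()
        rows = [
            ("a", "WYFH" + "ACDEFGHIKLMN" + "WYFH"),
            ("b", "YFHW" + "ACDEFGHIKLMN" + "YFHW"),
            ("c", "FHWY" + "ACDEFGHIKLMN" + "FHWY"),
            ("d", "HWYF" + "ACDEFGHIKLMN" + "HWYF"),
        ]
        msa = _msa(rows)
        windows = discover_conserved_windows(msa, rule)
        assert windows and windows[0][0] == (5, 16)
        from grasfam.motifs import column_identity

        for (start, end), _ in windows:
            if start > 1:
                assert column_identity(msa, start - 2) < rule.min_identity
            if end < msa.length:
                assert column_identity(msa, end) < rule.min_identity

    def test_row_order_invariance(self):
        rows = [
            ("a", "AAAAAAAAAAWY"),
            ("b", "AAAAAAAAAAFH"),
            ("c", "CCCCAAAAAAHW"),
            ("d", "DDDDAAAAAAYF"),
        ]
        fwd = discover_conserved_windows(_msa(rows))
        rev = discover_conserved_windows(_msa(list(reversed(rows))))
        assert fwd == rev


@pytest.fixture(scope="module")
def planted():
    config = SimulationConfig(
        seed=5, n_subfamilies=3, members_per_subfamily=(2, 2),
        protein_length=(420, 460), n_tandem_arrays=0, n_segmental_pairs=0,
        lost_subfamilies=1, n_lineage_duplicates=0,
    )
    return simulate_family(config)


class TestAnnotate:
    def test_full_length_protein_has_all_core_motifs(self, planted):
        record = planted.genome1[0]
        ann = annotate(record, default_catalog())
        found = {h.motif for h in ann.hits}
        assert set(CORE_MOTIFS) <= found
        assert not set(CORE_MOTIFS) & set(ann.missing_expected)
        assert ann.order_warnings == []

    def test_core_hits_ordered_and_disjoint(self, planted):
        ann = annotate(planted.genome1[0], default_catalog())
        core = [h for h in ann.hits if h.motif in CORE_MOTIFS]
        assert [h.motif for h in core] == list(CORE_MOTIFS)
        for a, b in zip(core, core[1:]):
            assert a.end < b.start

    def test_truncation_before_pfyre_flags_downstream_motifs(self, planted):
        record = planted.genome1[0]
        ann_full = annotate(record, default_catalog())
        pfyre = next(h for h in ann_full.hits if h.motif == "PFYRE")
        truncated = ProteinRecord(id="trunc", sequence=record.sequence[: pfyre.start - 1])
        ann = annotate(truncated, default_catalog())
        assert {"PFYRE", "SAW"} <= set(ann.missing_expected)
        assert {"LHRI", "VHIID", "LHRII"} & {h.motif for h in ann.hits}

    def test_ham_like_protein_lacks_rver(self):
        config = SimulationConfig(seed=6)  # full 13-subfamily family incl. HAM
        sim = simulate_family(config)
        ham = next(r for r in sim.genome1 if r.subfamily == "HAM")
        ann = annotate(ham, default_catalog())
        assert "RVER" in ann.missing_expected
        della = next(r for r in sim.genome1 if r.subfamily == "DELLA")
        assert "RVER" not in annotate(della, default_catalog()).missing_expected

    def test_empty_catalog_roundtrip(self, tmp_path):
        catalog = default_catalog()
        p = tmp_path / "cat.tsv"
        with open(p, "w") as fh:
            for m in catalog:
                fh.write(f"{m.name}\t{m.region}\t{m.pattern}\n")
        again = read_catalog(p)
        assert again == catalog


def test_planted_motif_boundaries_recovered_exactly(small_sim):
    catalog = {m.name: m for m in default_catalog()}
    for record in small_sim.genome1:
        planted = small_sim.truth.motif_coordinates[record.id]
        for motif_name, (start, end) in planted.items():
            hits = scan_pattern(record, catalog[motif_name])
            assert (start, end) in {(h.start, h.end) for h in hits}
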