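"""Exact-match strain demultiplexing: scoring, collapsing, shares, exclusion."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainvade.demux import (
    BASELINE,
    END,
    MarkerDB,
    ShareTable,
    collapse_groups,
    combined_label,
    exclude_undetected,
    match_reads,
    relative_shares,
    reverse_complement,
    strain_gain_loss,
)

dna = st.text(alphabet="ACGT", min_size=8, max_size=40)


class TestMatchReads:
    def test_exact_match_counting(self, toy_db):
        reads = ["ACGTTGCA", "ACGTTGCA", "GGGGCCAA", "ACGTTGCC"]
        c = match_reads(reads, toy_db)
        assert c.counts == {"A": 2, "B": 1}
        assert c.n_unmatched == 1
        assert c.n_reads_total == 4

    def test_reverse_complement_orientation(self):
        db = MarkerDB(records={"A": ["AAACCGGG"]})
        c = match_reads(["CCCGGTTT"], db)
        assert c.counts == {"A": 1}

    def test_rc_rejected_when_disabled(self):
        db = MarkerDB(records={"A": ["AAACCGGG"]})
        c = match_reads(["CCCGGTTT"], db, allow_rc=False)
        assert c.counts == {}
        assert c.n_unmatched == 1

    def test_empty_read_set(self, toy_db):
        c = match_reads([], toy_db)
        assert c.counts == {} and c.n_reads_total == 0

    def test_n_containing_read_never_matches(self, toy_db):
        c = match_reads(["ACGTTGCN"], toy_db)
        assert c.n_unmatched == 1

    def test_invalid_characters_counted_unmatched(self, toy_db):
        c = match_reads(["ACGTXGCA"], toy_db)
        assert c.n_unmatched == 1

    def test_cross_contamination_reported(self, toy_db):
        c = match_reads(["GGGGCCAA"], toy_db, design_strains={"A"})
        assert c.cross_hits == {"B": 1}
        assert c.counts == {"B": 1}  # still counted; reported separately

    @given(marker=dna, pos=st.integers(min_value=0, max_value=200))
    @settings(max_examples=100, deadline=None)
    def test_single_substitution_never_matches(self, marker, pos):
        """The 100%-identity rule is strict: one mismatched base fails."""
        i = pos % len(marker)
        other = next(b for b in "ACGT" if b != marker[i])
        mutated = marker[:i] + other + marker[i + 1:]
        db = MarkerDB(records={"A": [marker]})
        assert match_reads([mutated], db).counts == {}

    @given(st.lists(dna, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_orientation_symmetry(self, reads):
        db = MarkerDB(records={"A": ["ACGTTGCA"], "B": ["GGGGCCAA"]})
        fwd = match_reads(reads, db)
        rc = match_reads([reverse_complement(r) for r in reads], db)
        assert fwd.counts == rc.counts


class TestMarkerDB:
    def test_duplicate_marker_across_strains_rejected(self):
        with pytest.raises(ValueError, match="shared by non-grouped"):
            MarkerDB(records={"A": ["ACGT"], "B": ["ACGT"]})

    def test_shared_marker_within_group_maps_to_combined_label(self):
        db = MarkerDB(records={"A": ["ACGTACGT"], "B": ["ACGTACGT"]},
                      groups=[frozenset({"A", "B"})])
        c = match_reads(["ACGTACGT"], db)
        assert c.counts == {"A and B": 1}

    def test_fasta_roundtrip_with_groups(self, grouped_db, tmp_path):
        path = tmp_path / "markers.fasta"
        grouped_db.to_fasta(path)
        back = MarkerDB.from_fasta(path)
        assert back.records == grouped_db.records
        assert set(back.groups) == set(grouped_db.groups)


class TestCollapseGroups:
    def test_both_designed_merged_under_combined_label(self, grouped_db):
        c = match_reads(
            ["ACGTACGTAC"] * 10 + ["TTGGCCAATT"] * 5, grouped_db
        )
        merged = collapse_groups(c, {"MEL07", "Peter07_149", "27F11"}, grouped_db)
        assert merged.counts == {"MEL07 and Peter07_149": 15}

    def test_single_member_designed_unchanged(self, grouped_db):
        c = match_reads(["AACCGGTTAA"] * 7, grouped_db)
        merged = collapse_groups(c, {"ZIE05", "27F11"}, grouped_db)
        assert merged.counts == {"ZIE05": 7}

    def test_no_grouped_strains_is_identity(self, grouped_db):
        c = match_reads(["CATGCATGCA"] * 3, grouped_db)
        merged = collapse_groups(c, {"27F11"}, grouped_db)
        assert merged.counts == c.counts

    def test_collapsing_preserves_total_matched(self, grouped_db):
        reads = (["ACGTACGTAC"] * 4 + ["TTGGCCAATT"] * 6 + ["AACCGGTTAA"] * 2
                 + ["GGAATTCCGG"] * 8 + ["CATGCATGCA"])
        c = match_reads(reads, grouped_db)
        merged = collapse_groups(
            c, {"MEL07", "Peter07_149", "ZIE05", "ZIE11", "27F11"}, grouped_db
        )
        assert sum(merged.counts.values()) == sum(c.counts.values()) == 21


class TestShares:
    def test_share_arithmetic(self, toy_db):
        c = match_reads(["ACGTTGCA"] * 2 + ["GGGGCCAA"], toy_db)
        t = relative_shares(c, BASELINE)
        assert t.shares == pytest.approx({"A": 2 / 3, "B": 1 / 3})

    def test_single_strain_share_one(self, toy_db):
        c = match_reads(["ACGTTGCA"] * 5, toy_db)
        assert relative_shares(c, END).shares == {"A": 1.0}

    def test_all_unmatched_flagged_undefined(self, toy_db):
        c = match_reads(["TTTTTTTT"] * 5, toy_db)
        t = relative_shares(c, BASELINE)
        assert t.undefined and t.shares == {}

    def test_label_universe_adds_zero_shares(self, toy_db):
        c = match_reads(["ACGTTGCA"] * 4, toy_db)
        t = relative_shares(c, BASELINE, labels={"A", "B"})
        assert t.shares == {"A": 1.0, "B": 0.0}


class TestGainLoss:
    def test_delta_arithmetic(self):
        base = ShareTable("m1", BASELINE, {"A": 1 / 3, "B": 1 / 3, "C": 1 / 3})
        end = ShareTable("m1", END, {"A": 2 / 3, "B": 1 / 6, "C": 1 / 6})
        gl = strain_gain_loss(base, end)
        assert gl.delta == pytest.approx({"A": 1 / 3, "B": -1 / 6, "C": -1 / 6})

    def test_identical_tables_zero_delta(self):
        base = ShareTable("m1", BASELINE, {"A": 0.4, "B": 0.6})
        end = ShareTable("m1", END, {"A": 0.4, "B": 0.6})
        assert all(d == 0 for d in strain_gain_loss(base, end).delta.values())

    def test_dominance_flag(self):
        base = ShareTable("m1", BASELINE, {"A": 0.5, "B": 0.5})
        end = ShareTable("m1", END, {"A": 0.7, "B": 0.3})
        assert strain_gain_loss(base, end).dominant == {"A"}

    def test_missing_label_treated_as_zero(self):
        base = ShareTable("m1", BASELINE, {"A": 1.0})
        end = ShareTable("m1", END, {"B": 1.0})
        gl = strain_gain_loss(base, end)
        assert gl.delta == {"A": -1.0, "B": 1.0}

    @given(st.lists(st.integers(min_value=0, max_value=100), min_size=2,
                    max_size=6),
           st.lists(st.integers(min_value=0, max_value=100), min_size=2,
                    max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_deltas_sum_to_zero(self, base_counts, end_counts):
        n = min(len(base_counts), len(end_counts))
        labels = [f"S{i}" for i in range(n)]
        bsum, esum = sum(base_counts[:n]), sum(end_counts[:n])
        if bsum == 0 or esum == 0:
            return
        base = ShareTable("m", BASELINE,
                          {l: c / bsum for l, c in zip(labels, base_counts)})
        end = ShareTable("m", END,
                         {l: c / esum for l, c in zip(labels, end_counts)})
        assert abs(sum(strain_gain_loss(base, end).delta.values())) < 1e-9


class TestExclusion:
    def test_undetected_designed_strain_excludes_mixture(self, grouped_db):
        base = ShareTable("m1", BASELINE, {"ZIE05": 0.5, "27F11": 0.5,
                                           "MEL07": 0.0})
        excluded, reason = exclude_undetected(
            {"ZIE05", "27F11", "MEL07"}, base, grouped_db
        )
        assert excluded and "MEL07" in reason

    def test_all_detected_not_excluded(self, grouped_db):
        base = ShareTable("m1", BASELINE, {"ZIE05": 0.5, "27F11": 0.5})
        excluded, reason = exclude_undetected({"ZIE05", "27F11"}, base,
                                              grouped_db)
        assert not excluded and reason is None

    def test_zero_match_sample_excluded(self, grouped_db):
        base = ShareTable("m1", BASELINE, {}, undefined=True)
        excluded, _ = exclude_undetected({"27F11"}, base, grouped_db)
        assert excluded

    def test_grouped_design_checked_under_combined_label(self, grouped_db):
        base = ShareTable(
            "m1", BASELINE, {combined_label(["MEL07", "Peter07_149"]): 1.0}
        )
        excluded, _ = exclude_undetected({"MEL07", "Peter07_149"}, base,
                                         grouped_db)
        assert not excluded
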