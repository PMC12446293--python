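from collections import Counter

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonoscope import (AirrTable, ChainRecord, ConstantRegionTable,
                        assign_hash, clean_airr, count_clonotypes, filter_ig,
                        filter_productive, pair_chains,
                        restore_constant_region, select_dominant_chain,
                        trim_pseudo_utr)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _airr(rows):
    cols = ["cell_id", "locus", "v_call", "d_call", "j_call", "c_call",
            "productive", "sequence_aa", "cdr3_aa", "umi_count"]
    return AirrTable(df=pd.DataFrame(rows, columns=cols))


def _row(cell, locus, seq="MACF", cdr3="CF", umi=3, productive=True,
         c_call="X", v="V1*01", d="", j="J1*01"):
    if c_call == "X":
        c_call = {"TRA": "TRAC", "TRB": "TRBC1", "TRG": "TRGC1",
                  "TRD": "TRDC"}.get(locus, "")
    return (cell, locus, v, d, j, c_call, productive, seq, cdr3, umi)


class TestFilters:
    def test_ig_rows_removed(self):
        rows = [_row("c1", "TRA"), _row("c2", "IGH"), _row("c3", "IGK"),
                _row("c4", "IGL"), _row("c5", "TRB")]
        assert len(filter_ig(_airr(rows))) == 2

    def test_all_tr_unchanged(self):
        rows = [_row("c1", "TRA"), _row("c1", "TRB")]
        assert len(filter_ig(_airr(rows))) == 2

    def test_all_ig_gives_empty(self):
        rows = [_row("c1", "IGH"), _row("c2", "IGK")]
        assert len(filter_ig(_airr(rows))) == 0

    def test_productive_and_umi_predicates(self):
        rows = [
            _row("c1", "TRA", productive=True, umi=3),   # pass
            _row("c2", "TRA", productive=False, umi=3),  # unproductive
            _row("c3", "TRA", productive=True, umi=0),   # below min_umi
            _row("c4", "TRA", productive=True, umi=1),   # pass
            _row("c5", "TRA", productive=False, umi=0),  # both fail
            _row("c6", "TRA", productive=True, umi=9),   # pass
        ]
        kept = filter_productive(_airr(rows), min_umi=1)
        assert list(kept.df["cell_id"]) == ["c1", "c4", "c6"]


class TestTrimPseudoUtr:
    @pytest.mark.parametrize("seq,expected", [
        ("MKT*RMAVQ", "MAVQ"),      # first M strictly after the last stop
        ("MAVQ", "MAVQ"),           # already starts at M
        ("GG*KK", None),            # no M after the last stop -> drop
        ("GGMKK", "MKK"),           # no stop: trim to first M
        ("LL*GG*RMA", "MA"),        # several stops: the last one anchors
        ("M", "M"),
    ])
    def test_examples(self, seq, expected):
        assert trim_pseudo_utr(seq) == expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            trim_pseudo_utr("MA-VQ")

    @given(st.text(alphabet=AA + "*", min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, seq):
        once = trim_pseudo_utr(seq)
        if once is not None:
            assert trim_pseudo_utr(once) == once
            assert once.startswith("M")


class TestRestoreConstantRegion:
    def test_empty_c_call_becomes_trbc1(self):
        rec = ChainRecord(cell_id="c1", locus="TRB", sequence_aa="MACF",
                          c_call="")
        assert restore_constant_region(rec).c_call == "TRBC1"

    @pytest.mark.parametrize("locus,expected", [
        ("TRA", "TRAC"), ("TRG", "TRGC1"), ("TRD", "TRDC")])
    def test_locus_defaults(self, locus, expected):
        rec = ChainRecord(cell_id="c1", locus=locus, sequence_aa="MACF",
                          c_call="")
        assert restore_constant_region(rec).c_call == expected

    def test_complete_record_unchanged(self):
        rec = ChainRecord(cell_id="c1", locus="TRB", sequence_aa="MACF",
                          c_call="TRBC2")
        assert restore_constant_region(rec) is rec

    def test_truncated_sequence_extended_to_canonical_terminus(self):
        # 15-aa toy constant; the chain carries its first 10 residues
        canonical = "EDLNKVFPPEVAVFE"
        table = ConstantRegionTable(
            canonical_suffixes={"TRBC1": canonical})
        rec = ChainRecord(cell_id="c1", locus="TRB",
                          sequence_aa="MACF" + canonical[:10], c_call="")
        out = restore_constant_region(rec, table)
        assert out.c_call == "TRBC1"
        assert out.sequence_aa == "MACF" + canonical
        assert out.sequence_aa.endswith(canonical)

    def test_sequence_with_full_constant_not_extended(self):
        canonical = "EDLNKVFPPEVAVFE"
        table = ConstantRegionTable(canonical_suffixes={"TRBC1": canonical})
        rec = ChainRecord(cell_id="c1", locus="TRB",
                          sequence_aa="MACF" + canonical, c_call="TRBC1")
        assert restore_constant_region(rec, table).sequence_aa == rec.sequence_aa


class TestSelectDominantChain:
    def _rec(self, seq, umi):
        return ChainRecord(cell_id="c", locus="TRB", sequence_aa=seq,
                           umi_count=umi)

    def test_highest_umi_wins(self):
        assert select_dominant_chain(
            [self._rec("MAAA", 3), self._rec("MCCC", 5)]).umi_count == 5

    def test_single_record_identity(self):
        rec = self._rec("MAAA", 1)
        assert select_dominant_chain([rec]) is rec

    def test_umi_tie_broken_lexicographically(self):
        winner = select_dominant_chain(
            [self._rec("CAT", 4), self._rec("CAS", 4)])
        assert winner.sequence_aa == "CAS"


class TestAssignHash:
    def test_deterministic(self):
        assert assign_hash("TRA:MA___TRB:MB") == assign_hash("TRA:MA___TRB:MB")

    def test_matches_independent_digest(self):
        # frozen from `printf 'TRA:MA___TRB:MB' | sha256sum` (first 8 bytes,
        # big-endian unsigned)
        assert assign_hash("TRA:MA___TRB:MB") == "8681076133803781604"

    def test_no_collisions_on_synthetic_pool(self, sim_default):
        contigs = set(sim_default.truth.expected_clonotypes["contig"])
        hashes = {assign_hash(c) for c in contigs}
        assert len(hashes) == len(contigs)


class TestPairChains:
    def test_complete_ab_pair_retained(self):
        rows = [_row("c1", "TRA", seq="MAQ", cdr3="AQ"),
                _row("c1", "TRB", seq="MBQ", cdr3="BQ")]
        paired, report = pair_chains(_airr(rows))
        assert len(paired) == 1
        pc = paired[0]
        assert pc.tcr_type == "AB"
        assert pc.clonotype_contig == "TRA:MAQ___TRB:MBQ"
        assert pc.cdr3_contig == "TRA:AQ___TRB:BQ"
        assert report.n_paired_ab == 1

    def test_unpaired_chain_discarded(self):
        paired, report = pair_chains(_airr([_row("c1", "TRA")]))
        assert paired == []
        assert report.n_unpaired_dropped == 1

    def test_dual_type_resolved_by_summed_umi(self):
        rows = [_row("c1", "TRA", umi=3), _row("c1", "TRB", umi=3),
                _row("c1", "TRG", umi=4), _row("c1", "TRD", umi=5)]
        paired, report = pair_chains(_airr(rows))
        assert [p.tcr_type for p in paired] == ["GD"]
        assert report.n_dual_type == 1

    def test_dual_type_tie_prefers_ab(self):
        rows = [_row("c1", "TRA", umi=4), _row("c1", "TRB", umi=4),
                _row("c1", "TRG", umi=4), _row("c1", "TRD", umi=4)]
        paired, _ = pair_chains(_airr(rows))
        assert paired[0].tcr_type == "AB"

    def test_multiplet_resolved_to_dominant(self):
        rows = [_row("c1", "TRA", seq="MAQ", umi=9),
                _row("c1", "TRA", seq="MZQ", umi=1),
                _row("c1", "TRB", seq="MBQ", umi=5)]
        paired, report = pair_chains(_airr(rows))
        assert paired[0].chain_1.sequence_aa == "MAQ"
        assert report.n_multiplet_resolved == 1

    def test_row_permutation_changes_nothing(self, sim_artifacts):
        cleaned = clean_airr(sim_artifacts.airr)
        paired_fwd, _ = pair_chains(cleaned)
        shuffled = AirrTable(df=cleaned.df.sample(
            frac=1.0, random_state=99).reset_index(drop=True))
        paired_rev, _ = pair_chains(shuffled)
        assert paired_fwd == paired_rev


class TestCountClonotypes:
    def test_matches_brute_force_grouping(self, paired_default):
        paired, _ = paired_default
        counts = count_clonotypes(paired)
        oracle = Counter(pc.clonotype_contig for pc in paired)
        assert dict(zip(counts["contig"], counts["n_cells"])) == dict(oracle)

    def test_sorted_by_size_then_contig(self):
        rows = []
        for cell, seq in [("c1", "MAQ"), ("c2", "MAQ"), ("c3", "MAQ"),
                          ("c4", "MBQ")]:
            rows += [_row(cell, "TRA", seq=seq), _row(cell, "TRB", seq="MZQ")]
        counts = count_clonotypes(pair_chains(_airr(rows))[0])
        assert counts["n_cells"].tolist() == [3, 1]
        assert counts.iloc[0]["contig"].startswith("TRA:MAQ")

    def test_empty_input_gives_empty_table(self):
        assert count_clonotypes([]).empty

    def test_all_unique_counts_conserved(self):
        rows = []
        for i in range(6):
            rows += [_row(f"c{i}", "TRA", seq=f"MA{AA[i]}"),
                     _row(f"c{i}", "TRB", seq=f"MB{AA[i]}")]
        counts = count_clonotypes(pair_chains(_airr(rows))[0])
        assert (counts["n_cells"] == 1).all()
        assert counts["n_cells"].sum() == 6

    def test_conservation_and_disjoint_partitions(self, paired_default):
        paired, report = paired_default
        counts = count_clonotypes(paired)
        assert counts["n_cells"].sum() == len(paired)
        ab = set(counts.loc[counts["tcr_type"] == "AB", "contig"])
        gd = set(counts.loc[counts["tcr_type"] == "GD", "contig"])
        assert not ab & gd
        assert report.n_paired_ab + report.n_paired_gd == len(paired)

    def test_member_ids_match_counts(self, paired_default):
        paired, _ = paired_default
        counts = count_clonotypes(paired)
        assert (counts["member_cell_ids"].map(len) == counts["n_cells"]).all()
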