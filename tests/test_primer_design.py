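"""In-group selection, window scanning, consensus, pairing, ranking."""

import numpy as np
import pytest

from cladeamp import primer_design as pdz
from cladeamp import seqcore
from cladeamp.alignment import Alignment, IdentityMap
from cladeamp.insilico_pcr import PcrParams
from cladeamp.primer_design import (
    CladeSelectionParams,
    DesignParams,
    consensus_column,
    degeneracy_profile,
    pair_primers,
    scan_windows,
    select_ingroup,
)


def _imap(ids, rows):
    return IdentityMap(ids, np.array(rows, dtype=float))


class TestSelectIngroup:
    def test_exact_match_only(self):
        imap = _imap(["A", "B"], [[100, 90], [90, 100]])
        assert select_ingroup(imap, CladeSelectionParams("A", 100, 100)) == {"A"}

    def test_boundary_filtering(self):
        ids = ["A", "B", "C", "D", "E"]
        row = [100.0, 95.0, 92.0, 90.5, 80.0]
        m = np.full((5, 5), 80.0)
        np.fill_diagonal(m, 100.0)
        m[0, :] = row
        m[:, 0] = row
        imap = _imap(ids, m)
        got = select_ingroup(imap, CladeSelectionParams("A", 91.0, 100.0))
        assert got == {"A", "B", "C"}  # D at 90.5 excluded

    @pytest.mark.parametrize("idlow", [91.0, 95.0, 92.0])
    def test_published_family_bounds_validate(self, idlow):
        p = CladeSelectionParams("ref", idlow, 100.0)
        assert p.idlow == idlow and p.idhigh == 100.0

    def test_unknown_reference_rejected(self):
        imap = _imap(["A", "B"], [[100, 95], [95, 100]])
        with pytest.raises(KeyError):
            select_ingroup(imap, CladeSelectionParams("Z", 90))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            CladeSelectionParams("A", 95.0, 90.0)


class TestConsensusColumn:
    def test_unanimous_base(self):
        assert consensus_column({"A": 10.0}, 90.0) == "A"

    def test_split_column_gets_code(self):
        assert consensus_column({"A": 6.0, "G": 4.0}, 90.0) == "R"

    def test_dominant_base_used_verbatim_at_threshold(self):
        # 95% >= 90% consensus: the single nucleotide is used
        assert consensus_column({"A": 95.0, "G": 5.0}, 90.0) == "A"

    def test_min_base_freq_floor_drops_rare_base(self):
        assert consensus_column({"A": 8.0, "G": 1.0, "T": 1.0}, 90.0, 0.15) == "A"

    def test_three_way_code(self):
        assert consensus_column({"A": 1.0, "C": 1.0, "T": 1.0}, 90.0) == "H"

    def test_all_gap_column_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            consensus_column({}, 90.0)


def _uniform_msa(seq, n_rows=3):
    return Alignment([f"s{i}" for i in range(n_rows)], [seq] * n_rows)


class TestScanWindows:
    def test_identical_rows_give_degeneracy_one_everywhere(self):
        seq = "ATGGCGTTACGATCCGGATTACGTGGC"  # 27 columns
        msa = _uniform_msa(seq)
        cands = scan_windows(msa, DesignParams(codons=7), "s0")
        fwd = [c for c in cands if c.orientation == "forward"]
        assert len(fwd) == 27 - 21 + 1
        assert all(c.degeneracy == 1 for c in fwd)
        assert all(c.sequence == seq[c.ref_start : c.ref_end] for c in fwd)

    def test_single_polymorphic_column_carries_code(self):
        seq = "ATGGCGTTACGATCCGGATTACGTGGC"
        rows = [seq, seq, seq[:10] + "A" + seq[11:]]  # G/G/A at column 10
        msa = Alignment(["r0", "r1", "r2"], rows)
        cands = scan_windows(msa, DesignParams(codons=7), "r0")
        for c in cands:
            if c.orientation != "forward":
                continue
            if c.aln_start <= 10 < c.aln_end:
                assert c.degeneracy == 2
                assert c.sequence[10 - c.aln_start] == "R"
            else:
                assert c.degeneracy == 1

    def test_every_primer_is_three_codons_long(self, candidates):
        assert all(len(c.sequence) == 21 for c in candidates)

    def test_reverse_is_revcomp_of_forward(self, candidates):
        by_start = {}
        for c in candidates:
            by_start.setdefault((c.aln_start, c.orientation), c)
        for (start, ori), c in by_start.items():
            if ori == "forward":
                rev = by_start[(start, "reverse")]
                assert rev.sequence == seqcore.revcomp(c.sequence)
                assert rev.degeneracy == c.degeneracy

    def test_degeneracy_field_consistent_with_seqcore(self, candidates):
        for c in candidates[::37]:
            assert c.degeneracy == seqcore.degeneracy(c.sequence)

    def test_non_greedy_steps_in_codons(self):
        seq = "ATGGCGTTACGATCCGGATTACGTGGCATC"  # 30 columns
        msa = _uniform_msa(seq)
        fwd = [
            c
            for c in scan_windows(msa, DesignParams(codons=7, greedy=False), "s0")
            if c.orientation == "forward"
        ]
        assert [c.ref_start for c in fwd] == [0, 3, 6, 9]

    def test_gapped_window_discarded(self):
        rows = ["ATGGCGTTACGATCCGGATTACGTGGC",
                "ATGGCGTTACGATCCGGATTACGTGGC",
                "ATGGCGTTAC-ATCCGGATTACGTGGC"]
        msa = Alignment(["a", "b", "c"], rows)
        cands = scan_windows(msa, DesignParams(codons=7), "a")
        assert all(
            not (c.aln_start <= 10 < c.aln_end) for c in cands
        )

    def test_window_wider_than_alignment_rejected(self):
        with pytest.raises(ValueError, match="wider"):
            scan_windows(_uniform_msa("ACGTACGT"), DesignParams(codons=7), "s0")

    def test_raising_consensus_never_lowers_degeneracy(self):
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list("ACGT"), 40))
        rows = []
        for _ in range(10):
            row = list(base)
            for i in rng.choice(40, size=4, replace=False):
                row[i] = "ACGT"[rng.integers(4)]
            rows.append("".join(row))
        msa = Alignment([f"t{i}" for i in range(10)], rows)
        lo = scan_windows(msa, DesignParams(consensus=90.0), "t0")
        hi = scan_windows(msa, DesignParams(consensus=100.0), "t0")
        lo_f = {c.aln_start: c for c in lo if c.orientation == "forward"}
        hi_f = {c.aln_start: c for c in hi if c.orientation == "forward"}
        for start, c in lo_f.items():
            assert hi_f[start].degeneracy >= c.degeneracy


class TestProfile:
    def test_uniform_msa_profile_all_ones(self):
        msa = _uniform_msa("ATGGCGTTACGATCCGGATTACGTGGC")
        prof = degeneracy_profile(scan_windows(msa, DesignParams(), "s0"))
        assert (prof == 1).all()
        assert len(prof) == 27 - 21 + 1

    def test_planted_windows_attain_minimum(self, family, candidates):
        """The planted conserved 21-mers are recovered as degeneracy-1
        minima of the profile."""
        prof = degeneracy_profile(candidates)
        assert prof.min() == 1
        for pos, _l in family.params.planted_windows:
            assert prof.loc[pos] == 1

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            degeneracy_profile([])


class TestPairing:
    def test_empty_candidates_give_no_pairs(self):
        assert pair_primers([], 100, 1000) == []

    def test_predicted_size_arithmetic(self):
        msa = _uniform_msa("A" * 30 + "TTGACGGCTAGCTGGACTATCACGATGCGATCAT" * 50)
        cands = scan_windows(msa, DesignParams(), "s0")
        fwd = next(c for c in cands if c.orientation == "forward" and c.ref_start == 0)
        rev = next(
            c for c in cands if c.orientation == "reverse" and c.ref_start == 1621
        )
        pairs = pair_primers([fwd, rev], 1000, 2000)
        assert len(pairs) == 1
        assert pairs[0].predicted_size_max == 1642  # 21 + 1600 + 21

    def test_degeneracy_ceiling_is_inclusive(self, candidates):
        pairs = pair_primers(candidates, 1000, 1400, max_degeneracy=96)
        assert all(
            p.forward.degeneracy <= 96 and p.reverse.degeneracy <= 96
            for p in pairs
        )
        # a synthetic candidate just over the ceiling is excluded
        over = pdz.CandidatePrimer(
            "N" * 3 + "R" + "A" * 17, 0, 21, 0, 21, "forward",
            seqcore.degeneracy("N" * 3 + "R" + "A" * 17),
        )
        assert over.degeneracy > 96
        assert pair_primers([over], 10, 5000, max_degeneracy=96) == []

    def test_sorted_by_size_then_degeneracy(self, candidates):
        pairs = pair_primers(candidates, 1000, 1400, 96)
        sizes = [p.predicted_size_max for p in pairs]
        assert sizes == sorted(sizes, reverse=True)

    def test_inverted_size_range_rejected(self):
        with pytest.raises(ValueError):
            pair_primers([], 1000, 100)


class TestOfftargetRanking:
    def test_clean_database_ranks_all_zero(self, family, candidates, taxonomy):
        ingroup_only = [
            r for r in family.gene_records if r[0].startswith("IN")
        ]
        pairs = pair_primers(candidates, 1200, 1400, 96,
                             family.params.target_family)[:3]
        ranked = pdz.rank_pairs_by_offtarget(
            pairs, ingroup_only, taxonomy, family.params.target_family,
            PcrParams(size_min=1000, size_max=1500),
        )
        for _, summary in ranked:
            if summary is not None:
                assert summary.off_target_rate == 0.0

    def test_planted_offtarget_site_ranks_pair_lower(self, family, candidates,
                                                     taxonomy):
        pairs = pair_primers(candidates, 1200, 1400, 96,
                             family.params.target_family)
        planted = next(
            p for p in pairs
            if p.forward.degeneracy == 1 and p.reverse.degeneracy == 1
        )
        other = next(p for p in pairs if p is not planted)
        # plant the other pair's binding sites into an out-group genome
        rng = np.random.default_rng(0)
        decoy = "".join(rng.choice(list("ACGT"), 2000))
        f = next(iter(__import__("cladeamp").seqcore.expand(
            other.forward.sequence, 10**6)))
        r = next(iter(__import__("cladeamp").seqcore.expand(
            __import__("cladeamp").seqcore.revcomp(other.reverse.sequence),
            10**6)))
        insert_len = other.predicted_size_max - 42
        decoy = (
            decoy[:100] + f + decoy[100 : 100 + insert_len] + r
            + decoy[100 + insert_len :]
        )
        templates = [x for x in family.gene_records if x[0].startswith("IN")]
        templates.append(("OUT_DECOY", decoy))
        tax_df = family.taxonomy.copy()
        tax_df.loc[len(tax_df)] = ["OUT_DECOY", "Bacteria", "Simulota",
                                   "Simulia", "Simulales",
                                   family.params.outgroup_family,
                                   "Outgenus", "Outgenus decoy"]
        from cladeamp.io import Taxonomy

        ranked = pdz.rank_pairs_by_offtarget(
            [planted, other], templates, Taxonomy(tax_df),
            family.params.target_family,
            PcrParams(size_min=1000, size_max=1500),
        )
        assert ranked[0][0] is planted
        assert ranked[1][1].off_target > 0

    def test_empty_template_db_rejected(self, candidates):
        with pytest.raises(ValueError, match="empty"):
            pdz.rank_pairs_by_offtarget([], [], None, "X")
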