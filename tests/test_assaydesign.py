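"""Assay-candidate selection: flank extraction, design-score tiers,
boundary pipelines, neighbourhood quality and per-contig ranking."""

import numpy as np
import pandas as pd
import pytest

from transnp import Boundary, ads_filter, ads_tier, boundary_consensus, \
    boundary_direct, boundary_projected, extract_flanks, neighborhood_quality, \
    rank_candidates
from transnp.assaydesign import panel_table
from transnp.io import parse_bracketed_assay


def _hits(rows, species="stickleback"):
    cols = ["query_id", "subject_id", "pct_identity", "align_length", "mismatches",
            "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value",
            "bit_score", "species"]
    data = []
    for r in rows:
        rec = {"query_id": "c1", "subject_id": "s1", "pct_identity": 95.0,
               "align_length": r.get("q_end", 100) - r.get("q_start", 1) + 1,
               "mismatches": 2, "gap_opens": 0, "e_value": 1e-20,
               "bit_score": 200.0, "s_start": 1, "s_end": 100, "species": species}
        rec.update(r)
        data.append(rec)
    return pd.DataFrame(data, columns=cols)


class TestExtractFlanks:
    CONTIG = "".join("ACGT"[i % 4] for i in range(200))

    def test_position_60_rejected_terminal(self):
        assert extract_flanks(60, self.CONTIG, "A", "G") is None

    def test_position_61_accepted(self):
        out = extract_flanks(61, self.CONTIG, self.CONTIG[60], "G")
        assert out is not None
        assert len(out["assay_region"]) == 121
        assert out["assay_region"] == self.CONTIG[:121]
        assert out["assay_region"][60] == self.CONTIG[60]

    def test_right_terminal_rejected(self):
        assert extract_flanks(141, self.CONTIG, "A", "G") is None
        assert extract_flanks(140, self.CONTIG, self.CONTIG[139], "G") is not None

    def test_rejection_count_matches_bruteforce(self, rng):
        length = 400
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        positions = rng.integers(1, length + 1, size=200)
        rejected = sum(extract_flanks(int(p), contig, contig[p - 1], "N") is None
                       for p in positions)
        brute = sum(1 for p in positions if p - 60 < 1 or p + 60 > length)
        assert rejected == brute


class TestAdsTiers:
    @pytest.mark.parametrize("score,tier", [
        (0.39, "reject"), (0.40, "acceptable"), (0.70, "acceptable"),
        (0.71, "preferred"), (1.0, "preferred"), (0.0, "reject"),
        (None, None), (float("nan"), None),
    ])
    def test_boundaries(self, score, tier):
        assert ads_tier(score) == tier

    def test_join_and_binning_matches_bruteforce(self, rng):
        n = 300
        cands = pd.DataFrame({"contig_id": [f"c{i}" for i in range(n)],
                              "position": [100] * n})
        scores = rng.uniform(0, 1, n).round(3)
        ads_table = pd.DataFrame({"contig_id": cands.contig_id,
                                  "position": 100, "ads": scores})
        out = ads_filter(cands, ads_table)
        brute = pd.Series(np.where(scores < 0.4, "reject",
                          np.where(scores > 0.7, "preferred", "acceptable")))
        assert (out.ads_tier.to_numpy() == brute.to_numpy()).all()


class TestBoundaryDirect:
    def test_full_containment_single_exon(self):
        calls = boundary_direct(250, _hits([{"q_start": 1, "q_end": 500}]))
        assert calls["stickleback"] == Boundary.SINGLE_EXON

    def test_hit_ending_inside_window_is_boundary(self):
        calls = boundary_direct(250, _hits([{"q_start": 1, "q_end": 280}]))
        assert calls["stickleback"] == Boundary.BOUNDARY

    def test_no_significant_hit_is_no_match(self):
        calls = boundary_direct(250, _hits([{"q_start": 1, "q_end": 500,
                                             "e_value": 1e-3}]))
        assert calls["stickleback"] == Boundary.NO_MATCH

    def test_best_hit_selection_order_invariant(self):
        rows = [{"q_start": 1, "q_end": 150, "e_value": 1e-30},   # shorter span
                {"q_start": 1, "q_end": 500, "e_value": 1e-10}]   # longer span wins
        c1 = boundary_direct(250, _hits(rows))
        c2 = boundary_direct(250, _hits(rows[::-1]))
        assert c1 == c2
        assert c1["stickleback"] == Boundary.SINGLE_EXON


class TestBoundaryProjected:
    def test_single_covering_segment(self):
        ctx = _hits([{"q_start": 1, "q_end": 400, "s_start": 1, "s_end": 400,
                      "subject_id": "tx9"}])
        seg = _hits([{"query_id": "tx9", "q_start": 1, "q_end": 400}])
        calls = boundary_projected(200, ctx, seg)
        assert calls["stickleback"] == Boundary.SINGLE_EXON

    def test_window_crossing_segment_edge_is_boundary(self):
        # exon segments [1,100] and [101,400]; SNP projects to 80: 80+60
        # crosses the first segment's right edge
        ctx = _hits([{"q_start": 1, "q_end": 400, "s_start": 1, "s_end": 400,
                      "subject_id": "tx9"}])
        segs = _hits([{"query_id": "tx9", "q_start": 1, "q_end": 100},
                      {"query_id": "tx9", "q_start": 101, "q_end": 400}])
        calls = boundary_projected(80, ctx, segs)
        assert calls["stickleback"] == Boundary.BOUNDARY

    def test_no_transcriptome_hit_is_no_match(self):
        ctx = _hits([{"q_start": 1, "q_end": 400, "e_value": 1.0}])
        calls = boundary_projected(200, ctx, _hits([]))
        assert calls["stickleback"] == Boundary.NO_MATCH

    def test_position_outside_alignment_unprojected(self):
        ctx = _hits([{"q_start": 100, "q_end": 400, "s_start": 1, "s_end": 301,
                      "subject_id": "tx9"}])
        seg = _hits([{"query_id": "tx9", "q_start": 1, "q_end": 400}])
        calls = boundary_projected(50, ctx, seg)
        assert calls["stickleback"] == Boundary.NO_MATCH

    def test_minus_strand_projection(self):
        # alignment maps contig [100,400] onto transcript [301,1] (minus)
        ctx = _hits([{"q_start": 100, "q_end": 400, "s_start": 301, "s_end": 1,
                      "subject_id": "tx9"}])
        seg = _hits([{"query_id": "tx9", "q_start": 1, "q_end": 301}])
        calls = boundary_projected(250, ctx, seg)   # projects to 301-150=151
        assert calls["stickleback"] == Boundary.SINGLE_EXON


class TestConsensus:
    def test_any_boundary_evidence_rejects(self):
        out = boundary_consensus({"a": Boundary.SINGLE_EXON},
                                 {"a": Boundary.BOUNDARY})
        assert out.call == Boundary.BOUNDARY

    def test_all_no_match(self):
        out = boundary_consensus({"a": Boundary.NO_MATCH},
                                 {"a": Boundary.NO_MATCH, "b": Boundary.NO_MATCH})
        assert out.call == Boundary.NO_MATCH
        assert out.evidence == []

    def test_support_counting(self):
        direct = {s: Boundary.SINGLE_EXON for s in "abc"}
        direct.update({"d": Boundary.NO_MATCH, "e": Boundary.NO_MATCH})
        out = boundary_consensus(direct, {})
        assert out.call == Boundary.SINGLE_EXON
        assert out.supporting_species == 3

    def test_monotone_adding_boundary_source(self):
        base = {"a": Boundary.SINGLE_EXON, "b": Boundary.NO_MATCH}
        for extra in (Boundary.SINGLE_EXON, Boundary.NO_MATCH, Boundary.BOUNDARY):
            out = boundary_consensus(base, {"z": Boundary.BOUNDARY, "y": extra})
            assert out.call == Boundary.BOUNDARY


class TestNeighborhoodQuality:
    def test_clean_flanks_zero_and_planted_columns_counted(self, small_run):
        piles = small_run["pileups"]
        truth = small_run["truth"]
        cands = small_run["candidates"]
        for row in cands.head(5).itertuples():
            pile = piles[row.contig_id]
            nsq = neighborhood_quality(row.position, pile)
            # brute force over the window
            lo = max(0, row.position - 61)
            hi = min(len(pile.consensus) - 1, row.position - 1 + 60)
            brute = 0
            for pos in range(lo, hi + 1):
                if pos == row.position - 1:
                    continue
                bases, _, _, _ = pile.column(pos)
                vals, counts = np.unique(bases, return_counts=True)
                if len(vals) >= 2 and sorted(counts)[-2] >= 2:
                    brute += 1
            assert nsq == brute


class TestRanking:
    def _table(self):
        rows = []
        for i, (tier, boundary, nsq, depth) in enumerate([
            ("preferred", "no_match", 0, 30),
            ("preferred", "single_exon", 2, 20),
            ("acceptable", "no_match", 0, 50),
            ("preferred", "boundary", 0, 99),
            ("reject", "no_match", 0, 10),
        ]):
            rows.append({"contig_id": "c1", "position": 100 + i, "depth": depth,
                         "flank_ok": True, "ads_tier": tier, "boundary": boundary,
                         "nsq": nsq})
        rows.append({"contig_id": "c1", "position": 50, "depth": 10,
                     "flank_ok": False, "ads_tier": None, "boundary": "no_match",
                     "nsq": 0})
        return pd.DataFrame(rows)

    def test_partition_and_selection(self):
        ranked, funnel = rank_candidates(self._table())
        assert sum(funnel.values()) == 6
        assert funnel["selected"] == 2
        assert funnel["terminal"] == 1
        assert funnel["ads_reject"] == 1
        assert funnel["boundary_reject"] == 1
        sel = ranked[ranked.stage == "selected"]
        assert set(sel.position) == {100, 101}   # preferred tier, low nsq first

    def test_boundary_candidates_never_selected(self):
        ranked, _ = rank_candidates(self._table())
        assert (ranked[ranked.boundary == "boundary"].stage == "boundary_reject").all()

    def test_order_invariance(self):
        t = self._table()
        r1, f1 = rank_candidates(t)
        r2, f2 = rank_candidates(t.sample(frac=1.0, random_state=3))
        assert f1 == f2
        assert set(r1[r1.stage == "selected"].position) == \
            set(r2[r2.stage == "selected"].position)

    def test_funnel_partition_on_synthetic_run(self, small_run):
        ranked = small_run["ranked"]
        assert (ranked.stage != "").all()
        counts = ranked.stage.value_counts()
        assert counts.sum() == len(ranked)


class TestPanelFormat:
    def test_bracketed_assay_round_trip(self, small_run):
        sel = small_run["selected"]
        assert not sel.empty
        table = panel_table(sel)
        for row, orig in zip(table.itertuples(), sel.itertuples()):
            s1, s2 = parse_bracketed_assay(row.assay_sequence)
            assert s1 == orig.assay_region
            assert len(s1) == len(s2) == 121
            diff = [i for i, (a, b) in enumerate(zip(s1, s2)) if a != b]
            assert diff == [60]
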