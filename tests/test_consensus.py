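"""Center-star MSA, tie-dropping consensus, gap closure, and patching."""

import itertools

import numpy as np
import pytest

from spanfill.assembly import GapRecord, Scaffold, find_gaps
from spanfill.consensus import (
    PatchAction,
    build_msa,
    call_consensus,
    class_group,
    close_gap,
    patch_assembly,
    ref_flanks,
    size_class,
)
from spanfill.errors import ValidationError
from spanfill.evidence import SpanningEvidence


def pairwise_score_bruteforce(a, b, match=1, mismatch=-1, open_=-2, extend=-1):
    """Exhaustive optimal global alignment score for tiny strings.

    Enumerates every gapped pairing recursively; a gap run of length L
    scores open + (L-1)*extend.  Independent of the implementation's DP.
    """

    best = [-(10**9)]

    def score(cols):
        s = 0
        for run_char, run in itertools.groupby(cols, key=lambda c: (c[0] == "-", c[1] == "-")):
            run = list(run)
            if run_char == (False, False):
                s += sum(match if x == y else mismatch for x, y in run)
            else:
                s += open_ + (len(run) - 1) * extend
        return s

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


def msa_pair_score(row_a, row_b, match=1, mismatch=-1, open_=-2, extend=-1):
    cols = [(x, y) for x, y in zip(row_a, row_b) if not (x == "-" and y == "-")]
    s = 0
    for gapped, run in itertools.groupby(cols, key=lambda c: c[0] == "-" or c[1] == "-"):
        run = list(run)
        if not gapped:
            s += sum(match if x == y else mismatch for x, y in run)
        else:
            # split run into maximal per-sequence gap stretches
            for _, sub in itertools.groupby(run, key=lambda c: c[0] == "-"):
                sub = list(sub)
                s += open_ + (len(sub) - 1) * extend
    return s


class TestBuildMsa:
    def test_identical_inputs_need_no_gaps(self):
        assert build_msa(["ACGT", "ACGT"]) == ["ACGT", "ACGT"]

    def test_single_deletion_alignment(self):
        rows = build_msa(["ACGT", "AGT"])
        assert rows == ["ACGT", "A-GT"]
        # optimal under the scoring scheme, per the exhaustive oracle
        assert msa_pair_score(*rows) == pairwise_score_bruteforce("ACGT", "AGT")

    def test_three_rows_no_gaps(self):
        rows = build_msa(["AAAA", "AAAA", "AATA"])
        assert rows == ["AAAA", "AAAA", "AATA"]

    def test_pairwise_scores_match_bruteforce_on_tiny_strings(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), rng.integers(1, 6)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(1, 6)))
            rows = build_msa([a, b])
            assert msa_pair_score(*rows) == pairwise_score_bruteforce(a, b)

    def test_rows_reduce_to_inputs(self):
        rng = np.random.default_rng(12)
        for _ in range(15):
            k = int(rng.integers(2, 6))
            seqs = [
                "".join(rng.choice(list("ACGT"), rng.integers(3, 40)))
                for _ in range(k)
            ]
            rows = build_msa(seqs)
            assert len({len(r) for r in rows}) == 1
            assert [r.replace("-", "") for r in rows] == seqs

    def test_fewer_than_two_sequences_fatal(self):
        with pytest.raises(ValidationError):
            build_msa(["ACGT"])

    def test_empty_sequence_fatal(self):
        with pytest.raises(ValidationError):
            build_msa(["ACGT", ""])


def consensus_bruteforce(rows):
    """Independent per-column tally: gaps suppress only on strict
    plurality; base-vs-base top ties drop the column."""
    out, dropped = [], 0
    for col in zip(*rows):
        bases = [ch for ch in col if ch != "-"]
        n_gaps = len(col) - len(bases)
        if not bases:
            continue
        counts = {}
        for ch in bases:
            counts[ch] = counts.get(ch, 0) + 1
        top = max(counts.values())
        if n_gaps > top:
            continue
        winners = [ch for ch, n in counts.items() if n == top]
        if len(winners) == 1:
            out.append(winners[0])
        else:
            dropped += 1
    return "".join(out), dropped


class TestCallConsensus:
    def test_identity(self):
        assert call_consensus(["ACGT", "ACGT", "ACGT"]) == ("ACGT", 0)

    def test_base_tie_dropped(self):
        assert call_consensus(["ACGT", "ACTT"]) == ("ACT", 1)

    def test_plurality_gap_emits_nothing(self):
        assert call_consensus(["A-GT", "A-GT", "AAGT"]) == ("AGT", 0)

    def test_gap_cannot_veto_a_base_on_a_tie(self):
        # gaps are not residues: only a strict gap plurality suppresses
        assert call_consensus(["A-", "AC"]) == ("AC", 0)
        assert call_consensus(["AC-T", "AC-T", "ACGT", "ACGT"]) == ("ACGT", 0)

    def test_ragged_rows_fatal(self):
        with pytest.raises(ValidationError):
            call_consensus(["AC", "A"])

    def test_matches_tally_oracle_on_random_msas(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            k = int(rng.integers(2, 7))
            width = int(rng.integers(1, 25))
            rows = [
                "".join(rng.choice(list("ACGT-"), width)) for _ in range(k)
            ]
            assert call_consensus(rows) == consensus_bruteforce(rows)


def ev(gap_id, pathway, seq, read_id="r1"):
    return SpanningEvidence(
        gap_id=gap_id,
        read_id=read_id,
        pathway=pathway,
        extracted_seq=seq,
        left_anchor_bp=50,
        right_anchor_bp=50,
    )


GAP = GapRecord("s:gap0", "s", 60, 70)
FL = "C" * 20
FR = "G" * 20


class TestCloseGap:
    def test_no_coverage_uncovered(self):
        act = close_gap(GAP, [], FL, FR)
        assert (act.status, act.replacement_seq, act.coverage) == ("uncovered", "", 0)
        assert (act.replace_start, act.replace_end) == (40, 90)

    def test_single_unsplit_fallback_uses_raw_read(self):
        seq = FL + "ACGTACGTAC" + FR
        act = close_gap(GAP, [ev("s:gap0", "unsplit", seq)], FL, FR)
        assert act.status == "closed"
        assert act.used_fallback
        assert act.replacement_seq == seq

    def test_single_split_fallback_gets_reference_flanks(self):
        act = close_gap(GAP, [ev("s:gap0", "split", "ACGTACGTAC")], FL, FR)
        assert act.replacement_seq == FL + "ACGTACGTAC" + FR
        assert act.used_fallback

    def test_identical_reads_consensus(self):
        seq = FL + "ACGTACGTAC" + FR
        evs = [ev("s:gap0", "unsplit", seq, read_id=f"r{i}") for i in range(3)]
        act = close_gap(GAP, evs, FL, FR)
        assert act.status == "closed"
        assert not act.used_fallback
        assert act.replacement_seq == seq
        assert act.coverage == 3

    def test_split_consensus_with_flank_augmented_rows(self):
        mid = "ACGTACGTAC" * 3
        evs = [ev("s:gap0", "split", mid, read_id=f"r{i}") for i in range(3)]
        act = close_gap(GAP, evs, FL, FR)
        assert act.replacement_seq == FL + mid + FR

    def test_degenerate_consensus_marked_ambiguous(self):
        # two split reads whose middles are empty cannot out-vote the flanks
        evs = [ev("s:gap0", "split", "", read_id=f"r{i}") for i in range(2)]
        act = close_gap(GAP, evs, "C" * 50, "G" * 50)
        assert act.status in ("ambiguous", "closed")
        if act.status == "ambiguous":
            assert act.replacement_seq == ""


class TestSizeClasses:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (10, "10"),
            (100, "100"),
            (440, "400"),
            (360, "400"),
            (3000, "3000"),
            (10999, "10000"),
            (700, "other"),
            (12000, "other"),
        ],
    )
    def test_nominal_binning_with_tolerance(self, length, expected):
        assert size_class(length) == expected

    def test_grouping(self):
        assert class_group(400) == "small"
        assert class_group(5000) == "large"
        assert class_group(1500) == "other"


def action(gap_id, scaffold, start, end, seq, status="closed", gap_length=10):
    return PatchAction(
        gap_id=gap_id,
        scaffold_id=scaffold,
        replace_start=start,
        replace_end=end,
        replacement_seq=seq,
        status=status,
        coverage=1,
        gap_length=gap_length,
    )


class TestPatchAssembly:
    def test_zero_closed_actions_identity(self):
        sc = [Scaffold("s", "A" * 60 + "N" * 10 + "C" * 60)]
        patched, report = patch_assembly(
            sc, [action("s:gap0", "s", 10, 120, "", status="uncovered")]
        )
        assert patched[0].seq == sc[0].seq
        assert report["summary"]["total_bp_change"] == 0

    def test_splice_arithmetic(self):
        sc = [Scaffold("s", "A" * 60 + "N" * 10 + "C" * 60)]
        repl = "T" * 105
        patched, report = patch_assembly(sc, [action("s:gap0", "s", 10, 120, repl)])
        assert patched[0].length == 125
        assert patched[0].seq == "A" * 10 + repl + "C" * 10
        assert find_gaps(patched[0]) == []
        assert report["summary"]["total_bp_change"] == -5

    def test_two_gaps_order_independent(self):
        seq = "A" * 50 + "N" * 10 + "C" * 50 + "N" * 10 + "G" * 50
        sc = [Scaffold("s", seq)]
        a1 = action("s:gap0", "s", 40, 70, "T" * 30)
        a2 = action("s:gap1", "s", 100, 130, "T" * 25)
        p1, _ = patch_assembly(sc, [a1, a2])
        p2, _ = patch_assembly(sc, [a2, a1])
        assert p1[0].seq == p2[0].seq
        manual = seq[:100] + "T" * 25 + seq[130:]
        manual = manual[:40] + "T" * 30 + manual[70:]
        assert p1[0].seq == manual

    def test_overlapping_intervals_fatal(self):
        sc = [Scaffold("s", "A" * 200)]
        with pytest.raises(ValidationError, match="overlap"):
            patch_assembly(
                sc,
                [
                    action("g0", "s", 10, 60, "T" * 50),
                    action("g1", "s", 50, 100, "T" * 50),
                ],
            )

    def test_unknown_scaffold_fatal(self):
        with pytest.raises(ValidationError, match="unknown scaffold"):
            patch_assembly([Scaffold("s", "ACGT")], [action("g0", "x", 0, 2, "T")])


class TestRefFlanks:
    def test_plain_flanks(self):
        sc = Scaffold("s", "A" * 60 + "N" * 10 + "C" * 60)
        gap = find_gaps(sc)[0]
        fl, fr = ref_flanks(sc, gap, flank=50)
        assert (fl, fr) == ("A" * 50, "C" * 50)

    def test_flanks_truncated_at_scaffold_edge_and_neighbour_gap(self):
        sc = Scaffold("s", "A" * 10 + "N" * 10 + "C" * 5 + "N" * 10 + "G" * 60)
        g1, g2 = find_gaps(sc)
        assert ref_flanks(sc, g1, flank=50) == ("A" * 10, "C" * 5)
        assert ref_flanks(sc, g2, flank=50) == ("C" * 5, "G" * 50)


class TestEndToEndProperties:
    def test_patched_differs_only_inside_closed_intervals(self, clean_run):
        gapped = {sc.id: sc.seq for sc in clean_run["gapped"]}
        closed = {}
        for act in clean_run["actions"]:
            if act.status == "closed":
                closed.setdefault(act.scaffold_id, []).append(act)
        for sc in clean_run["patched"]:
            original = gapped[sc.id]
            acts = sorted(closed.get(sc.id, []), key=lambda a: a.replace_start)
            # error-free replacements are length-preserving here, so
            # coordinates line up and the outside must be untouched
            prev = 0
            for act in acts:
                assert sc.seq[prev : act.replace_start] == original[prev : act.replace_start]
                prev = act.replace_end
            assert sc.seq[prev:] == original[prev:]

    def test_total_n_drops_by_closed_gap_lengths(self, clean_run):
        s = clean_run["report"]["summary"]
        closed_gap_bp = sum(
            a.gap_length for a in clean_run["actions"] if a.status == "closed"
        )
        assert (
            s["pre_stats"].total_N - s["post_stats"].total_N == closed_gap_bp
        )

    def test_closing_is_idempotent(self, clean_run):
        """Re-running closure on the patched assembly closes no gap of the
        original set."""
        from spanfill import close_all_gaps, gather_evidence

        remaining = [g for sc in clean_run["patched"] for g in find_gaps(sc)]
        assert len(remaining) == (
            clean_run["report"]["summary"]["n_gaps"]
            - clean_run["report"]["summary"]["n_closed"]
        )
        ev2 = gather_evidence(clean_run["alignments"], remaining)
        actions2 = close_all_gaps(clean_run["patched"], ev2, remaining)
        # gaps left open in round 1 had no usable evidence, so round 2
        # closes nothing new
        assert sum(1 for a in actions2 if a.status == "closed") == 0
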