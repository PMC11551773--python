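import itertools

import numpy as np
import pandas as pd
import pytest

from checflow.annotations import GenomeAnnotation, Promoter, PromoterSet, Transcript
from checflow.motifs import (
    XmerScoreTable,
    build_pwm,
    canonical_index,
    revcomp,
    score_xmers,
)
from checflow.tracks import SignalTrack


class TestCanonicalIndex:
    def test_seven_mer_class_count_by_enumeration(self):
        idx = canonical_index(7)
        assert idx.n_classes == 4 ** 7 // 2 == 8192
        # exhaustive oracle: no odd-length DNA word is its own revcomp
        seen = {}
        for mer in map("".join, itertools.product("ACGT", repeat=7)):
            assert mer != revcomp(mer)
            key = min(mer, revcomp(mer))
            seen.setdefault(key, set()).add(idx.index_of(mer))
        assert len(seen) == 8192
        assert all(len(v) == 1 for v in seen.values())

    def test_revcomp_shares_index(self):
        idx = canonical_index(7)
        assert idx.index_of("GATTACA") == idx.index_of(revcomp("GATTACA"))
        assert revcomp("GATTACA") == "TGTAATC"

    def test_dimer_classes_include_palindromes(self):
        idx = canonical_index(2)
        # 16 dimers = 4 palindromes (AT, TA, CG, GC) + 6 revcomp pairs
        assert idx.n_classes == 10
        mers = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
        assert len({idx.index_of(m) for m in mers}) == 10

    def test_representative_is_lexicographically_smaller_form(self):
        idx = canonical_index(3)
        for rep in idx.representatives:
            assert rep <= revcomp(rep)

    def test_out_of_range_x_rejected(self):
        with pytest.raises(ValueError):
            canonical_index(0)
        with pytest.raises(ValueError):
            canonical_index(13)


def brute_force_xmer_scores(genome, track, promoters, x, window):
    """Independent oracle: enumerate every promoter position with pure Python."""
    sums, counts = {}, {}
    half = window // 2
    for p in promoters:
        seq = genome[p.chrom]
        arr = track.data[p.chrom]
        for start in range(p.start, p.end):
            if start + x > len(seq):
                continue
            mer = seq[start:start + x].upper()
            if any(b not in "ACGT" for b in mer):
                continue
            mid = start + x // 2
            lo, hi = mid - half, mid - half + window
            if lo < 0 or hi > len(arr):
                continue
            key = min(mer, revcomp(mer))
            sums[key] = sums.get(key, 0.0) + arr[lo:hi].sum() / window
            counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}, counts


def small_genome_world(seed=0, chrom_len=5_000, x=5):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=chrom_len))
    arr = rng.poisson(3.0, size=chrom_len).astype(float)
    track = SignalTrack({"chrI": arr}, declared_total=arr.sum())
    proms = PromoterSet({
        "g1": Promoter("g1", "chrI", "+", 500, 1_200),
        "g2": Promoter("g2", "chrI", "-", 2_000, 2_500),
        "g3": Promoter("g3", "chrI", "+", 4_400, 4_999),
    })
    return {"chrI": seq}, track, proms


class TestScoreXmers:
    def test_single_occurrence_uniform_window(self):
        seq = "A" * 100 + "GATTACA" + "A" * 100
        arr = np.zeros(207)
        mid = 100 + 3
        arr[mid - 10: mid + 10] = 3.0
        track = SignalTrack({"chrI": arr}, declared_total=arr.sum())
        proms = PromoterSet({"g": Promoter("g", "chrI", "+", 95, 112)})
        table = score_xmers({"chrI": seq}, track, proms, x=7)
        idx = canonical_index(7)
        row = table.table.loc[idx.index_of("GATTACA")]
        assert row["mean_signal"] == pytest.approx(3.0)
        assert row["n_occurrences"] == 1

    def test_two_occurrences_averaged(self):
        seq = "C" * 50 + "GATTACA" + "C" * 50 + "GATTACA" + "C" * 50
        arr = np.zeros(len(seq))
        arr[50 + 3 - 10: 50 + 3 + 10] = 2.0
        arr[107 + 3 - 10: 107 + 3 + 10] = 4.0
        track = SignalTrack({"chrI": arr}, declared_total=arr.sum())
        proms = PromoterSet({"g": Promoter("g", "chrI", "+", 30, 130)})
        table = score_xmers({"chrI": seq}, track, proms, x=7)
        idx = canonical_index(7)
        row = table.table.loc[idx.index_of("GATTACA")]
        assert row["n_occurrences"] == 2
        assert row["mean_signal"] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle_exactly(self, seed):
        genome, track, proms = small_genome_world(seed=seed)
        x, window = 5, 20
        table = score_xmers(genome, track, proms, x=x, window=window)
        oracle_means, oracle_counts = brute_force_xmer_scores(
            genome, track, proms, x, window)
        idx = canonical_index(x)
        scored = table.table[table.table["n_occurrences"] > 0]
        assert len(scored) == len(oracle_means)
        for rep, mean, n in zip(scored["representative"], scored["mean_signal"],
                                scored["n_occurrences"]):
            assert n == oracle_counts[rep]
            assert mean == pytest.approx(oracle_means[rep], rel=1e-12)

    def test_strand_mirror_invariance(self):
        # reverse-complementing the genome and mirroring track + promoters
        # leaves the canonical score table unchanged (odd window: an even
        # window is asymmetric about the x-mer midpoint and shifts 1 bp
        # under mirroring)
        genome, track, proms = small_genome_world(seed=2)
        x, window = 5, 21
        t1 = score_xmers(genome, track, proms, x=x, window=window)
        L = len(genome["chrI"])
        rc_genome = {"chrI": revcomp(genome["chrI"])}
        rc_track = SignalTrack({"chrI": track.data["chrI"][::-1].copy()},
                               declared_total=track.declared_total)
        # an occurrence starting at s (length x) maps to start L-x-s on the mirror
        rc_proms = PromoterSet({
            p.gene_id: Promoter(p.gene_id, p.chrom,
                                "-" if p.strand == "+" else "+",
                                L - x + 1 - p.end, L - x + 1 - p.start)
            for p in proms
        })
        t2 = score_xmers(rc_genome, rc_track, rc_proms, x=x, window=window)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_window_out_of_bounds_skipped(self):
        seq = "GATTACA" + "A" * 50
        arr = np.ones(len(seq))
        track = SignalTrack({"chrI": arr}, declared_total=arr.sum())
        proms = PromoterSet({"g": Promoter("g", "chrI", "+", 0, 7)})
        table = score_xmers({"chrI": seq}, track, proms, x=7)
        assert table.n_skipped > 0

    def test_unnormalized_track_rejected(self):
        genome, track, proms = small_genome_world()
        track.declared_total = None
        with pytest.raises(ValueError, match="normalized"):
            score_xmers(genome, track, proms, x=5)


def table_from(entries, x=7):
    """entries: {sequence: (mean_signal, n)} on canonical representatives."""
    idx = canonical_index(x)
    df = pd.DataFrame({
        "representative": idx.representatives,
        "mean_signal": np.nan,
        "n_occurrences": 0,
    })
    for seq, (score, n) in entries.items():
        i = idx.index_of(seq)
        df.loc[i, "mean_signal"] = score
        df.loc[i, "n_occurrences"] = n
    return XmerScoreTable(x, df)


class TestBuildPwm:
    def test_identical_top_sequences_give_one_hot(self):
        # ten classes, all effectively the same sequence is impossible under
        # canonicalization, so use one dominant plus nine matching shifts of
        # itself trimmed away by the weight threshold
        entries = {"ACGTAGC": (100.0, 5)}
        fillers = ["AATTCCG", "AACCGGT", "AAACCCG", "AAATTTC", "AAAGGGC",
                   "AATTGGC", "AACCTTG", "AAAACCG", "AAAATTG"]
        for i, f in enumerate(fillers):
            entries[f] = (0.001 * (i + 1), 1)
        pwm = build_pwm(table_from(entries), top_n=10)
        # dominant weight concentrates on the anchor's 7 positions
        assert len(pwm) == 7
        assert pwm.consensus() == "ACGTAGC"
        assert (pwm.probs.max(axis=1) > 0.99).all()

    def test_weighted_column_frequencies(self):
        pwm = build_pwm(table_from({"AAAAAAA": (2.0, 3), "AAAAAAT": (1.0, 2)}),
                        top_n=2)
        assert len(pwm) == 7
        last = pwm.probs.iloc[-1]
        assert last["A"] == pytest.approx(2 / 3)
        assert last["T"] == pytest.approx(1 / 3)

    def test_reverse_complement_aligns_onto_anchor(self):
        # a motif equal to the anchor's reverse complement is flipped back
        # onto the anchor at offset 0, so it only doubles the weight
        from checflow.motifs import _align_to_anchor

        anchor = "ACGTAGC"
        oriented, offset = _align_to_anchor(anchor, revcomp(anchor), max_shift=6)
        assert oriented == anchor and offset == 0

    def test_column_stochasticity(self):
        rng = np.random.default_rng(3)
        mers = set()
        while len(mers) < 10:
            m = "".join(rng.choice(list("ACGT"), size=7))
            if m < revcomp(m):
                mers.add(m)
        entries = {m: (float(i + 1), 2) for i, m in enumerate(sorted(mers))}
        pwm = build_pwm(table_from(entries), top_n=10)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)
        assert ((pwm.probs >= 0) & (pwm.probs <= 1)).all().all()

    def test_zero_signal_top_rejected(self):
        entries = {m: (0.0, 1) for m in
                   ["AAAAAAC", "AAAAAAG", "AAAAACC", "AAAAACG", "AAAAAGC",
                    "AAAACCC", "AAAACCG", "AAAACGC", "AAAACGG", "AAAAGCC"]}
        with pytest.raises(ValueError, match="signal"):
            build_pwm(table_from(entries), top_n=10)

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            build_pwm(table_from({"AAAAAAC": (1.0, 1)}), top_n=10)


class TestEndToEndMotifRecovery:
    def test_planted_motif_is_top_scoring_class(self, small_world, small_promoters):
        from checflow import synthetic as syn
        from checflow.tracks import normalize_track

        annotation, genome, truth = small_world
        track = normalize_track(syn.simulate_chec_track(annotation, truth, "TF1", seed=9))
        table = score_xmers(genome, track, small_promoters, x=7)
        top_rep = table.top(1)["representative"].iloc[0]
        planted = truth.motifs["TF1"]
        assert top_rep == min(planted, revcomp(planted))
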