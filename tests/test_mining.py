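"""SSR mining: canonical families, perfect/imperfect finders vs naive oracles."""

from itertools import product

import numpy as np
import pytest

from polydonor.mining import (
    SSRHit,
    _is_degenerate,
    canonical_family,
    find_imperfect_ssrs,
    find_perfect_ssrs,
    mine_fasta,
    product_size_in_range,
    repeat_class_percentages,
)

ACGT = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def naive_perfect(seq, min_len=15, unit_lens=(2, 3, 4)):
    """Quadratic scanner: try every start and unit, extend greedily, keep
    maximal non-degenerate runs of sufficient length."""
    seq = seq.upper()
    n = len(seq)
    found = set()
    for u in unit_lens:
        for i in range(n):
            motif = seq[i:i + u]
            if len(motif) < u or any(c not in ACGT for c in motif):
                continue
            j = i + u
            while j < n and seq[j] in ACGT and seq[j] == seq[j - u]:
                j += 1
            # maximality
            if i > 0 and seq[i - 1] in ACGT and i - 1 + u < n and seq[i - 1] == seq[i - 1 + u]:
                continue
            if j - i >= min_len and not _is_degenerate(motif):
                found.add((i, j, u, motif))
    return found


def naive_imperfect(seq, min_len=15, unit_lens=(2, 3, 4), max_mismatch=2):
    """Exhaustive window oracle: all motifs x phases x windows, prefix-sum
    mismatch counts, maximality by one-step extension, then the same
    published tie-break (longest, fewest mismatches, leftmost; within-family
    overlap of at least one unit)."""
    seq = seq.upper()
    n = len(seq)
    segs = []
    start = None
    for i, ch in enumerate(seq + "!"):
        if ch in ACGT:
            if start is None:
                start = i
        elif start is not None:
            segs.append((start, i))
            start = None
    raw = {}
    for u in unit_lens:
        motifs = [
            "".join(p) for p in product(ACGT, repeat=u)
            if not _is_degenerate("".join(p))
        ]
        for segL, segR in segs:
            for motif in motifs:
                for phase in range(u):
                    mism = [0]
                    for i in range(segL, segR):
                        bad = seq[i] != motif[(i - phase) % u]
                        mism.append(mism[-1] + bad)

                    def mm(a, b):  # mismatches in [a, b)
                        return mism[b - segL] - mism[a - segL]

                    for a in range(segL, segR):
                        for b in range(a + min_len, segR + 1):
                            if mm(a, b) > max_mismatch:
                                continue
                            if a > segL and mm(a - 1, b) <= max_mismatch:
                                continue
                            if b < segR and mm(a, b + 1) <= max_mismatch:
                                continue
                            fam = canonical_family(motif)
                            key = (a, b, u, fam)
                            v = mm(a, b)
                            if key not in raw or v < raw[key]:
                                raw[key] = v
    order = sorted(raw.items(), key=lambda kv: (-(kv[0][1] - kv[0][0]), kv[1], kv[0]))
    kept = []
    for (a, b, u, fam), v in order:
        if any(
            f2 == fam and u2 == u and min(b, b2) - max(a, a2) >= u
            for a2, b2, u2, f2, _ in kept
        ):
            continue
        kept.append((a, b, u, fam, v))
    return {(a, b, u, fam, v) for a, b, u, fam, v in kept}


def random_seq_with_repeats(rng, n, n_plant=2):
    seq = rng.choice(list(ACGT), size=n)
    for _ in range(n_plant):
        u = int(rng.integers(2, 5))
        motif = "".join(rng.choice(list(ACGT), size=u))
        reps = int(rng.integers(4, 12))
        arr = list(motif * reps)
        pos = int(rng.integers(0, n - len(arr)))
        seq[pos:pos + len(arr)] = arr
    return "".join(seq)


# ---------------------------------------------------------------------------
# canonical families
# ---------------------------------------------------------------------------


class TestCanonicalFamily:
    @pytest.mark.parametrize("motif,family", [
        ("GA", "AG"), ("CT", "AG"), ("AG", "AG"), ("TC", "AG"),
        ("AT", "AT"), ("TA", "AT"), ("AC", "AC"), ("GT", "AC"),
        ("AAG", "AAG"), ("GGA", "AGG"), ("ATC", "ATC"),
    ])
    def test_known_families(self, motif, family):
        assert canonical_family(motif) == family

    def test_exhaustive_closure_under_rotation_and_revcomp(self):
        for u in (2, 3, 4):
            for p in product(ACGT, repeat=u):
                motif = "".join(p)
                if _is_degenerate(motif):
                    continue
                fam = canonical_family(motif)
                assert canonical_family(fam) == fam  # idempotent
                variants = [motif[i:] + motif[:i] for i in range(u)]
                variants += [revcomp(v) for v in variants]
                assert {canonical_family(v) for v in variants} == {fam}

    @pytest.mark.parametrize("bad", ["ATAT", "AA", "CCC", "A", "AGAGA", "ANG"])
    def test_invalid_motifs_rejected(self, bad):
        with pytest.raises(ValueError):
            canonical_family(bad)


# ---------------------------------------------------------------------------
# perfect finder
# ---------------------------------------------------------------------------


class TestPerfectFinder:
    def test_constructed_dinucleotide_run(self):
        hits = find_perfect_ssrs("ATATATATATATATAT")
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.unit_len, h.family, h.mismatches) == (0, 16, 2, "AT", 0)
        assert h.length == 16

    def test_below_length_threshold(self):
        assert find_perfect_ssrs("AAGAAGAAGAAGA") == []

    def test_n_breaks_runs(self):
        seq = "ATATATATNATATATATATATATAT"
        hits = find_perfect_ssrs(seq)
        assert [(h.start, h.end) for h in hits] == [(9, 25)]

    def test_partial_final_unit_included(self):
        seq = "AAGAAGAAGAAGAAGA"  # (AAG)5 + A, 16 nt
        hits = find_perfect_ssrs(seq)
        assert [(h.start, h.end, h.motif) for h in hits] == [(0, 16, "AAG")]

    def test_matches_naive_quadratic_scanner(self, rng):
        for n in (200, 400, 2000):
            for _ in range(4):
                seq = random_seq_with_repeats(rng, n, n_plant=3)
                got = {(h.start, h.end, h.unit_len, h.motif)
                       for h in find_perfect_ssrs(seq)}
                assert got == naive_perfect(seq)

    def test_empty_sequence(self):
        assert find_perfect_ssrs("") == []


# ---------------------------------------------------------------------------
# imperfect finder
# ---------------------------------------------------------------------------


class TestImperfectFinder:
    def test_single_substitution_array(self):
        hits = find_imperfect_ssrs("AAGAAGAAGAACAAG")
        assert len(hits) == 1
        h = hits[0]
        assert (h.family, h.length, h.mismatches) == ("AAG", 15, 1)

    def test_zero_mismatch_setting_equals_perfect_finder(self, rng):
        for n in (150, 600, 2000):
            seq = random_seq_with_repeats(rng, n, n_plant=3)
            perfect = {(h.start, h.end, h.unit_len, h.motif, 0)
                       for h in find_perfect_ssrs(seq)}
            imp = {(h.start, h.end, h.unit_len, h.motif, h.mismatches)
                   for h in find_imperfect_ssrs(seq, max_mismatch=0)}
            assert imp == perfect

    def test_matches_exhaustive_window_oracle(self, rng):
        for _ in range(4):
            seq = random_seq_with_repeats(rng, 80, n_plant=2)
            got = {(h.start, h.end, h.unit_len, h.family, h.mismatches)
                   for h in find_imperfect_ssrs(seq)}
            assert got == naive_imperfect(seq)

    def test_planted_mutated_arrays_recalled(self, rng):
        for _ in range(10):
            u = int(rng.integers(2, 5))
            motif = "".join(rng.choice(list(ACGT), size=u))
            if _is_degenerate(motif):
                continue
            reps = int(rng.integers(6, 10))
            arr = list(motif * reps)
            # one or two substitutions strictly inside the array
            for pos in rng.choice(range(1, len(arr) - 1), size=2, replace=False):
                arr[pos] = ACGT[(ACGT.index(arr[pos]) + 1) % 4]
            flank1 = "".join(rng.choice(list(ACGT), size=30))
            flank2 = "".join(rng.choice(list(ACGT), size=30))
            seq = flank1 + "".join(arr) + flank2
            fam = canonical_family(motif)
            hits = [h for h in find_imperfect_ssrs(seq) if h.family == fam]
            assert any(
                h.start <= 30 and h.end >= 30 + len(arr) - (u - 1)
                for h in hits
            ), f"planted {motif} array not recovered"

    def test_no_full_unit_overlap_within_family(self, rng):
        for _ in range(6):
            seq = random_seq_with_repeats(rng, 300, n_plant=4)
            hits = find_imperfect_ssrs(seq)
            by_fam = {}
            for h in hits:
                by_fam.setdefault((h.family, h.unit_len), []).append(h)
            for fam_hits in by_fam.values():
                fam_hits.sort(key=lambda h: h.start)
                for a, b in zip(fam_hits, fam_hits[1:]):
                    assert min(a.end, b.end) - max(a.start, b.start) < a.unit_len

    def test_hit_slices_match_reported_length(self, rng):
        seq = random_seq_with_repeats(rng, 500, n_plant=4)
        for h in find_imperfect_ssrs(seq):
            assert len(seq[h.start:h.end]) == h.length >= 15


# ---------------------------------------------------------------------------
# FASTA mining and summaries
# ---------------------------------------------------------------------------


class TestMineFasta:
    def test_planted_counts(self, tmp_path):
        fasta = tmp_path / "toy.fa"
        fasta.write_text(
            ">s1\n" + "GCGTTACGTA" + "AG" * 10 + "TTACGGATCC" + "\n"
            ">s2\n" + "TTGACCAGTA" + "AAG" * 6 + "CATGACCGTA" + "\n"
            ">s3\nGATTACACATTAGGCA\n"
        )
        summary, hits = mine_fasta(fasta)
        assert summary.n_sequences == 3
        assert summary.counts_by_unit_len == {2: 1, 3: 1, 4: 0}
        assert list(hits.seq_id) == ["s1", "s2"]
        assert summary.density_bp_per_ssr == summary.total_bases / 2

    def test_no_repeats_density_null(self, tmp_path):
        fasta = tmp_path / "flat.fa"
        fasta.write_text(">s1\nGATTACACATTAGGCAGATCCATG\n")
        summary, hits = mine_fasta(fasta)
        assert summary.n_hits == 0 and len(hits) == 0
        assert summary.density_bp_per_ssr is None

    def test_duplicate_record_ids_error(self, tmp_path):
        fasta = tmp_path / "dup.fa"
        fasta.write_text(">s1\nACGT\n>s1\nACGT\n")
        with pytest.raises(ValueError, match="s1"):
            mine_fasta(fasta)


class TestRepeatClassPercentages:
    def test_published_style_class_split(self):
        # counts with a known percentage split: 137/1400/140 -> 8.2/83.5/8.3
        assert repeat_class_percentages({2: 137, 3: 1400, 4: 140}) == {
            2: 8.2, 3: 83.5, 4: 8.3,
        }

    def test_degenerate_single_class(self):
        assert repeat_class_percentages({2: 1, 3: 0, 4: 0}) == {2: 100.0, 3: 0.0, 4: 0.0}

    def test_exact_rational_cross_check(self):
        from fractions import Fraction
        counts = {2: 71, 3: 27, 4: 2}
        got = repeat_class_percentages(counts)
        total = sum(counts.values())
        for u, c in counts.items():
            exact = Fraction(100 * c, total)
            assert abs(got[u] - float(exact)) <= 0.05
        assert abs(sum(got.values()) - 100.0) <= 0.2

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            repeat_class_percentages({2: 0, 3: 0, 4: 0})


def test_product_size_window():
    assert product_size_in_range(150)
    assert not product_size_in_range(89)
    assert not product_size_in_range(301)
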