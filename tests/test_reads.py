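"""Demultiplexing, pair merging, QC and the four-stage artifact filter."""

import numpy as np
import pytest

from bolatype.alleles import LocusConfig
from bolatype.reads import (FastqRead, FilterConfig, MidScheme, cluster_and_filter,
                            demultiplex, merge_pairs, quality_filter, retained,
                            revcomp, trim_primers)

Q = lambda phred, n: chr(phred + 33) * n


def mk(seq, phred=40, name="r"):
    return FastqRead(name, seq, Q(phred, len(seq)))


class TestDemultiplex:
    SCHEME = MidScheme({("AAAA", "CCCC"): "S1", ("GGGG", "TTTT"): "S2"})

    def test_exact_match_assigns_and_strips(self):
        pairs = [(mk("AAAA" + "ACGT"), mk("CCCC" + "TGCA")),
                 (mk("AAAA" + "GGTT"), mk("CCCC" + "AACC")),
                 (mk("GGGG" + "ACGT"), mk("TTTT" + "TGCA")),
                 (mk("AAAA" + "ACGT"), mk("TTTT" + "TGCA"))]
        out, unassigned = demultiplex(pairs, self.SCHEME)
        assert len(out["S1"]) == 2 and len(out["S2"]) == 1 and unassigned == 1
        assert out["S1"][0][0].seq == "ACGT" and out["S1"][0][1].seq == "TGCA"

    def test_single_mismatch_is_unassigned(self):
        pairs = [(mk("AAAT" + "ACGT"), mk("CCCC" + "TGCA"))]
        out, unassigned = demultiplex(pairs, self.SCHEME)
        assert unassigned == 1 and not out["S1"]

    def test_empty_scheme_rejected(self):
        with pytest.raises(ValueError):
            MidScheme({})


class TestMergePairs:
    def test_perfect_overlap_reconstructs_amplicon(self, rng):
        amplicon = "".join(rng.choice(list("ACGT"), size=324))
        r1 = mk(amplicon[:300])
        r2 = mk(revcomp(amplicon[-300:]))
        merged = merge_pairs(r1, r2, FilterConfig())
        assert merged is not None
        assert merged.seq == amplicon and len(merged.seq) == 324

    def test_quality_tie_break(self, rng):
        amplicon = "".join(rng.choice(list("ACGT"), size=60))
        r1 = mk(amplicon[:40], phred=40)
        tail = list(amplicon[-40:])
        # flip a base inside the 20 bp overlap on the low-quality mate
        tail[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tail[10]]
        r2 = mk(revcomp("".join(tail)), phred=10)
        merged = merge_pairs(r1, r2, FilterConfig())
        assert merged.seq == amplicon  # r1's high-quality base wins

    def test_no_admissible_overlap_fails(self):
        assert merge_pairs(mk("A" * 40), mk("A" * 40), FilterConfig()) is None


class TestQualityFilter:
    @pytest.mark.parametrize("phred,keep", [(30, True), (20, False), (28, False)])
    def test_mean_threshold_strictly_above(self, phred, keep):
        assert quality_filter(mk("ACGT" * 20, phred=phred), FilterConfig()) is keep


class TestTrimPrimers:
    CFG = LocusConfig("DQA", 64, 20, 24, primer_fwd="STGGRRGTGAAGACATYGTG",
                      primer_rev="GAYTTGGRAAACACAGYCAC")

    def _amplicon(self, insert):
        fwd = "CTGGAAGTGAAGACATCGTG"   # one realisation of the degenerate primer
        rev = "GACTTGGAAAACACAGCCAC"
        return fwd + insert + revcomp(rev)

    def test_iupac_semantics(self):
        from bolatype.reads import iupac_mismatches
        assert iupac_mismatches("S", "C") == 0
        assert iupac_mismatches("S", "G") == 0
        assert iupac_mismatches("S", "A") == 1

    def test_reverse_orientation_reoriented_and_trimmed(self):
        insert = "ACGTACGTACGTACGTACGTACGT"
        amp = self._amplicon(insert)
        assert trim_primers(revcomp(amp), self.CFG, FilterConfig()) == insert
        assert trim_primers(amp, self.CFG, FilterConfig()) == insert

    def test_failure_counted_as_none(self):
        assert trim_primers("ACGT" * 20, self.CFG, FilterConfig()) is None


from helpers import edit_distance_dp


def oracle_fates(counted, insert_length, tolerance=9, freq_threshold=0.0):
    """Independent re-statement of the filter chain: sorted processing,
    chimera membership via the explicit set of all crossover products,
    1 bp variants via a handwritten DP edit distance."""
    total = sum(n for _, n in counted)
    order = sorted(counted, key=lambda kv: (-kv[1], kv[0]))
    fates = {}
    survivors = []
    for seq, n in order:
        if "N" in seq:
            fates[seq] = "removed_N"
            continue
        if abs(len(seq) - insert_length) > tolerance:
            fates[seq] = "removed_length"
            continue
        parents = [s for s, m in survivors if m > n]
        chims = {p1[:i] + p2[i:] for p1 in parents for p2 in parents if p1 != p2
                 for i in range(1, min(len(p1), len(p2)))}
        chims -= set(parents)
        if seq in chims:
            fates[seq] = "removed_chimera"
            continue
        if any(edit_distance_dp(seq, p) == 1 for p in parents):
            fates[seq] = "removed_1bp"
            continue
        survivors.append((seq, n))
        fates[seq] = "below_threshold" if n / total < freq_threshold else "retained"
    return fates


def locus_for(length, freq_threshold=0.0):
    return LocusConfig("DQA", length, 0, 3, freq_threshold=freq_threshold)


class TestClusterAndFilter:
    def test_frequency_threshold_dqa_example(self):
        # four artifact-free clusters at 60/30/6/4 %: DQA threshold 7% keeps two
        seqs = ["AAAAAAAAAAAA", "CCCCCCCCCCCC", "GGGGGGGGGGGG", "TTTTTTTTTTTT"]
        reads = [s for s, n in zip(seqs, (60, 30, 6, 4)) for _ in range(n)]
        clusters, report = cluster_and_filter(reads, FilterConfig(collapse_1bp_enabled=False),
                                              locus_for(12, 0.07))
        fates = {c.nt_sequence: c.fate for c in clusters}
        assert fates[seqs[0]] == fates[seqs[1]] == "retained"
        assert fates[seqs[2]] == fates[seqs[3]] == "below_threshold"
        assert abs(sum(c.frequency for c in clusters) - 1.0) < 1e-9

    def test_length_filter_boundary(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=324))
        too_long = base + "".join(rng.choice(list("ACGT"), size=10))   # 334
        edge = base + "".join(rng.choice(list("ACGT"), size=9))        # 333
        reads = [base] * 10 + [too_long] * 3 + [edge] * 3
        clusters, _ = cluster_and_filter(reads, FilterConfig(collapse_1bp_enabled=False),
                                         locus_for(324))
        fates = {c.nt_sequence: c.fate for c in clusters}
        assert fates[too_long] == "removed_length"
        assert fates[edge] == "retained"

    def test_planted_chimera_flagged(self, rng):
        p1 = "".join(rng.choice(list("ACGT"), size=40))
        p2 = "".join(rng.choice(list("ACGT"), size=40))
        p3 = "".join(rng.choice(list("ACGT"), size=40))
        hybrid = p1[:17] + p2[17:]
        reads = [p1] * 50 + [p2] * 40 + [p3] * 30 + [hybrid] * 5
        clusters, _ = cluster_and_filter(reads, FilterConfig(), locus_for(40))
        fates = {c.nt_sequence: c.fate for c in clusters}
        assert fates[hybrid] == "removed_chimera"
        assert all(fates[p] == "retained" for p in (p1, p2, p3))

    def test_1bp_variant_substitution_and_indel(self, rng):
        p = "".join(rng.choice(list("ACGT"), size=40))
        sub = p[:5] + ("C" if p[5] != "C" else "G") + p[6:]
        indel = p[:12] + p[13:]
        reads = [p] * 50 + [sub] * 4 + [indel] * 3
        clusters, _ = cluster_and_filter(reads, FilterConfig(), locus_for(40))
        fates = {c.nt_sequence: c.fate for c in clusters}
        assert fates[sub] == "removed_1bp" and fates[indel] == "removed_1bp"

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        """Chimera and 1 bp flags equal the brute-force oracle, 200 trials."""
        alphabet = list("ACGT")
        for _ in range(200):
            n_parents = int(rng.integers(2, 5))
            L = int(rng.integers(10, 16))
            parents = set()
            while len(parents) < n_parents:
                parents.add("".join(rng.choice(alphabet, size=L)))
            parents = sorted(parents)
            counted = {p: int(rng.integers(20, 100)) for p in parents}
            for _ in range(int(rng.integers(0, 6))):   # derived artifact clusters
                p1, p2 = rng.choice(parents, size=2, replace=False)
                kind = rng.integers(0, 3)
                if kind == 0:
                    i = int(rng.integers(1, L))
                    seq = p1[:i] + p2[i:]
                elif kind == 1:
                    i = int(rng.integers(0, L))
                    seq = p1[:i] + rng.choice(alphabet) + p1[i + 1:]
                else:
                    seq = "".join(rng.choice(alphabet, size=L))
                if seq not in counted:
                    counted[seq] = int(rng.integers(1, 15))
            reads = [s for s, n in counted.items() for _ in range(n)]
            clusters, _ = cluster_and_filter(reads, FilterConfig(), locus_for(L))
            expected = oracle_fates(list(counted.items()), L)
            got = {c.nt_sequence: c.fate for c in clusters}
            assert got == expected

    def test_idempotent_on_retained(self, rng):
        p1 = "".join(rng.choice(list("ACGT"), size=30))
        p2 = "".join(rng.choice(list("ACGT"), size=30))
        reads = [p1] * 60 + [p2] * 40 + [p1[:15] + p2[15:]] * 5
        clusters, _ = cluster_and_filter(reads, FilterConfig(), locus_for(30))
        kept = retained(clusters)
        reads2 = [c.nt_sequence for c in kept for _ in range(c.count)]
        clusters2, _ = cluster_and_filter(reads2, FilterConfig(), locus_for(30))
        assert [(c.nt_sequence, c.count, c.fate) for c in clusters2] == \
               [(c.nt_sequence, c.count, c.fate) for c in kept]

    def test_empty_input(self):
        clusters, report = cluster_and_filter([], FilterConfig(), locus_for(30))
        assert clusters == [] and report.total_clusters == 0
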