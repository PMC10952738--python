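"""Read-level processing: demultiplexing, pair merging, QC and artifact filters.

A multiplexed MiSeq amplicon run is reduced to per-sample, per-locus
*clusters* of identical merged reads.  Clusters then pass through the four
artifact filters in a fixed order — ambiguous base calls (N), aberrant
length (more than +/-9 bp from the anticipated amplicon-region size), PCR
chimaeras (single-crossover hybrids of two more-abundant co-amplified
sequences), and 1 bp variants of a more-abundant sequence (PCR/sequencing
error) — followed by a per-locus read-frequency threshold that removes
low-frequency non-specific products (7% for DQA, 2% for DQB, 0.2% for the
class I amplicons).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib
from Bio.Seq import Seq

from .alleles import LocusConfig

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

FATES = ("retained", "removed_N", "removed_length", "removed_chimera",
         "removed_1bp", "below_threshold")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def iupac_mismatches(pattern: str, text: str) -> int:
    """Mismatch count of an IUPAC-degenerate pattern against plain DNA."""
    return sum(t not in IUPAC[p] for p, t in zip(pattern, text))


@dataclass(frozen=True)
class FilterConfig:
    q_threshold: float = 28.0
    length_tolerance: int = 9
    chimera_enabled: bool = True
    collapse_1bp_enabled: bool = True
    absorb_1bp_into_parent: bool = False
    renormalize_after_removal: bool = False
    min_overlap: int = 10
    max_mismatch_fraction: float = 0.25
    primer_mismatch_max: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.max_mismatch_fraction < 1:
            raise ValueError("max_mismatch_fraction must be in (0,1)")
        if self.length_tolerance < 0 or self.min_overlap < 1:
            raise ValueError("tolerances must be non-negative")


@dataclass
class ReadCluster:
    nt_sequence: str
    count: int
    frequency: float = 0.0
    fate: str = "retained"


@dataclass
class FilterReport:
    """Per-fate cluster and read tallies for one sample-locus."""

    clusters: Counter = field(default_factory=Counter)
    reads: Counter = field(default_factory=Counter)

    def record(self, cluster: ReadCluster) -> None:
        self.clusters[cluster.fate] += 1
        self.reads[cluster.fate] += cluster.count

    @property
    def total_clusters(self) -> int:
        return sum(self.clusters.values())

    def to_json(self) -> str:
        return json.dumps({"clusters": dict(self.clusters), "reads": dict(self.reads)})


@dataclass(frozen=True)
class FastqRead:
    name: str
    seq: str
    qual: str  # Phred+33

    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual]

    def __len__(self) -> int:
        return len(self.seq)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                return
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            yield FastqRead(header[1:].split()[0], seq, qual)


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


@dataclass
class MidScheme:
    """Map of (forward MID, reverse MID) tag combinations to sample ids."""

    assignments: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("empty MID scheme")
        fwd_lens = {len(f) for f, _ in self.assignments}
        rev_lens = {len(r) for _, r in self.assignments}
        if len(fwd_lens) != 1 or len(rev_lens) != 1:
            raise ValueError("MIDs must be equal length within each side")
        if len(set(self.assignments.values())) != len(self.assignments):
            raise ValueError("MID combinations must map to unique samples")
        self.fwd_len = fwd_lens.pop()
        self.rev_len = rev_lens.pop()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MidScheme":
        assignments = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                assignments[(parts[idx["mid_fwd"]], parts[idx["mid_rev"]])] = parts[idx["sample_id"]]
        return cls(assignments)


def demultiplex(pairs: Iterable[tuple[FastqRead, FastqRead]], scheme: MidScheme,
                ) -> tuple[dict[str, list[tuple[FastqRead, FastqRead]]], int]:
    """Assign read pairs to samples by exact match of both 5' MID tags.

    Matched MIDs are removed from the assigned reads; pairs whose tag
    combination is not in the scheme are counted and discarded.
    """
    out: dict[str, list[tuple[FastqRead, FastqRead]]] = {s: [] for s in scheme.assignments.values()}
    unassigned = 0
    for r1, r2 in pairs:
        key = (r1.seq[: scheme.fwd_len], r2.seq[: scheme.rev_len])
        sample = scheme.assignments.get(key)
        if sample is None:
            unassigned += 1
            continue
        out[sample].append((
            FastqRead(r1.name, r1.seq[scheme.fwd_len:], r1.qual[scheme.fwd_len:]),
            FastqRead(r2.name, r2.seq[scheme.rev_len:], r2.qual[scheme.rev_len:]),
        ))
    return out, unassigned


def merge_pairs(r1: FastqRead, r2: FastqRead, cfg: FilterConfig) -> FastqRead | None:
    """Merge a read pair by its best-scoring ungapped 3' overlap.

    The reverse mate is reverse-complemented; every overlap length from
    ``min_overlap`` up is scored as matches minus mismatches, overlaps with
    a mismatch fraction above ``max_mismatch_fraction`` are inadmissible,
    and disagreeing bases resolve to the higher-quality call.  Returns
    ``None`` when no admissible overlap exists.
    """
    s2 = revcomp(r2.seq)
    q2 = r2.qual[::-1]
    best = None  # (score, overlap)
    max_o = min(len(r1), len(r2))
    for o in range(cfg.min_overlap, max_o + 1):
        a = r1.seq[-o:]
        b = s2[:o]
        if a == b:
            mm = 0
        else:
            mm = sum(x != y for x, y in zip(a, b))
        if mm > cfg.max_mismatch_fraction * o:
            continue
        score = o - 2 * mm
        if best is None or score > best[0] or (score == best[0] and o > best[1]):
            best = (score, o)
    if best is None:
        return None
    o = best[1]
    head = r1.seq[:-o] if o < len(r1) else ""
    head_q = r1.qual[:-o] if o < len(r1) else ""
    mid_seq = []
    mid_q = []
    p1 = r1.phred()[-o:]
    p2 = [ord(c) - 33 for c in q2[:o]]
    for i in range(o):
        x, y = r1.seq[len(r1) - o + i], s2[i]
        if x == y or p1[i] >= p2[i]:
            mid_seq.append(x)
            mid_q.append(chr(max(p1[i], p2[i]) + 33))
        else:
            mid_seq.append(y)
            mid_q.append(chr(p2[i] + 33))
    return FastqRead(r1.name, head + "".join(mid_seq) + s2[o:],
                     head_q + "".join(mid_q) + q2[o:])


def quality_filter(read: FastqRead, cfg: FilterConfig) -> bool:
    """Keep a read iff its mean Phred score is strictly above the threshold."""
    phred = read.phred()
    if not phred:
        return False
    return sum(phred) / len(phred) > cfg.q_threshold


def trim_primers(seq: str, cfg_locus: LocusConfig, cfg: FilterConfig) -> str | None:
    """Orient a merged read and strip the locus primer pair.

    Both orientations are tried; a primer matches its end of the read with
    at most ``primer_mismatch_max`` mismatches, degenerate positions
    matching their IUPAC set.  Returns the forward-oriented insert, or
    ``None`` when neither orientation is admissible.
    """
    fwd, rev = cfg_locus.primer_fwd, cfg_locus.primer_rev
    rev_rc = revcomp(rev)
    for candidate in (seq, revcomp(seq)):
        if len(candidate) < len(fwd) + len(rev):
            continue
        if (iupac_mismatches(fwd, candidate[: len(fwd)]) <= cfg.primer_mismatch_max
                and iupac_mismatches(rev_rc, candidate[-len(rev):]) <= cfg.primer_mismatch_max):
            return candidate[len(fwd): len(candidate) - len(rev)]
    return None


def _is_chimera(seq: str, parents: Sequence[str]) -> bool:
    """True iff seq = prefix(P1, i) + suffix(P2, i) for an internal crossover
    of two distinct parents, and seq differs from both parents."""
    for p1 in parents:
        for p2 in parents:
            if p1 == p2:
                continue
            hi = min(len(p1), len(p2), len(seq))
            for i in range(1, hi):
                if seq == p1[:i] + p2[i:] and seq != p1 and seq != p2:
                    return True
    return False


def cluster_and_filter(inserts: Iterable[str], fcfg: FilterConfig, locus: LocusConfig,
                       ) -> tuple[list[ReadCluster], FilterReport]:
    """Cluster identical inserts and run the artifact filter chain.

    Clusters are ordered by count (descending) then sequence; frequencies
    are computed over all clustered reads of the sample-locus before any
    removal.  Fates are assigned in the order N -> length -> chimera ->
    1 bp variant -> frequency threshold.  Chimera parents and 1 bp-variant
    parents must both have survived the earlier filters and have strictly
    greater counts than the flagged cluster.
    """
    counts = Counter(inserts)
    report = FilterReport()
    if not counts:
        return [], report
    total = sum(counts.values())
    clusters = [ReadCluster(seq, n, n / total) for seq, n in
                sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    surviving: list[ReadCluster] = []  # passed N/length/chimera/1bp so far
    for c in clusters:
        if "N" in c.nt_sequence:
            c.fate = "removed_N"
        elif abs(len(c.nt_sequence) - locus.insert_length) > fcfg.length_tolerance:
            c.fate = "removed_length"
        else:
            parents = [s for s in surviving if s.count > c.count]
            if fcfg.chimera_enabled and _is_chimera(c.nt_sequence, [p.nt_sequence for p in parents]):
                c.fate = "removed_chimera"
            elif fcfg.collapse_1bp_enabled and any(
                    edlib.align(c.nt_sequence, p.nt_sequence, task="distance", k=1)["editDistance"] == 1
                    for p in parents):
                c.fate = "removed_1bp"
                if fcfg.absorb_1bp_into_parent:
                    nearest = min((p for p in parents
                                   if edlib.align(c.nt_sequence, p.nt_sequence, task="distance",
                                                  k=1)["editDistance"] == 1),
                                  key=lambda p: (-p.count, p.nt_sequence))
                    nearest.count += c.count
            else:
                surviving.append(c)
    if fcfg.renormalize_after_removal:
        kept_total = sum(c.count for c in surviving)
        for c in surviving:
            c.frequency = c.count / kept_total if kept_total else 0.0
    for c in surviving:
        if c.frequency < locus.freq_threshold:
            c.fate = "below_threshold"
    for c in clusters:
        report.record(c)
    return clusters, report


def retained(clusters: Sequence[ReadCluster]) -> list[ReadCluster]:
    return [c for c in clusters if c.fate == "retained"]


def clusters_to_tsv(path: str | Path, clusters: Sequence[ReadCluster],
                    sample: str = "", locus: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("sample\tlocus\tsequence\tcount\tfrequency\tfate\n")
        for c in clusters:
            fh.write(f"{sample}\t{locus}\t{c.nt_sequence}\t{c.count}\t{c.frequency:.6g}\t{c.fate}\n")
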