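"""Synthetic cohorts with fully known truth, for end-to-end validation.

The generator emulates the study's data-generating process: a reference set
of allelic groups (members of a group differ by at most four amino acids in
exon 2, groups differ by far more), a haplotype pool with a long-tailed
geometric rank-frequency law (the continuous descending spectrum seen in
real cohorts), diploid animals drawn from the pool under Hardy-Weinberg
(two independent draws), and amplicon reads carrying the artifact taxonomy
the pipeline filters: substitution errors (yielding 1 bp variants),
single-crossover PCR chimaeras between co-amplified alleles, ambiguous
base calls, and length artifacts.  Every dataset ships truth tables so
pipeline output is always compared to planted truth, never to other
pipeline output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alleles import (AlleleDatabase, AlleleName, AlleleRecord, DEFAULT_LOCI,
                      LocusConfig, translate_exon2)
from .reads import FastqRead, revcomp, write_fastq, IUPAC

_CODONS = [a + b + c for a, b, c in product("ACGT", repeat=3)]
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [c for c in _CODONS if c not in _STOPS]
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    seed: int = 0
    loci: tuple[str, ...] = ("DRB3", "DQA", "DQB")
    groups_per_locus: Mapping[str, int] = field(default_factory=lambda: {
        "DQA": 12, "DQB": 12, "DRB3": 8, "MHCI": 20})
    members_per_group: int = 2
    pool_size: int = 15                 # MHCII haplotype pool
    mhci_pool_size: int = 15
    duplicated_dq_fraction: float = 0.5
    geometric_r: float = 0.75           # rank-frequency decay of the pool
    cohort_size: int = 200
    depth: int = 1000                   # reads per sample-locus
    error_rate: float = 0.001           # substitutions per base
    chimera_fraction: float = 0.0
    n_fraction: float = 0.0
    length_artifact_fraction: float = 0.0
    read_length: int = 250
    mid_length: int = 8

    def __post_init__(self) -> None:
        for r in (self.error_rate, self.chimera_fraction, self.n_fraction,
                  self.length_artifact_fraction, self.duplicated_dq_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 0.0 < self.geometric_r < 1.0:
            raise ValueError("geometric_r must lie in (0, 1)")


def _random_codons(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_SENSE) for _ in range(n))


def _mutate_codons(exon2: str, n_changes: int, rng: np.random.Generator) -> str:
    """Substitute n_changes codons for codons encoding different residues."""
    from Bio.Seq import Seq
    codons = [exon2[i:i + 3] for i in range(0, len(exon2) - len(exon2) % 3, 3)]
    pos = rng.choice(len(codons), size=n_changes, replace=False)
    for p in pos:
        aa = str(Seq(codons[p]).translate())
        alts = [c for c in _SENSE if str(Seq(c).translate()) != aa]
        codons[p] = alts[rng.integers(len(alts))]
    return "".join(codons)


def make_reference(config: SimulationConfig, *, loci: Mapping[str, LocusConfig] | None = None,
                   ) -> tuple[AlleleDatabase, dict[str, dict[str, int]]]:
    """Generate per-locus allele references with planted group structure.

    Returns the database and a truth table mapping allele name -> group
    index per locus.  Within a group, members differ by 1..4 amino acids;
    between groups, exon-2 sequences are independent random codons (far
    beyond 4 differences, asserted).
    """
    rng = np.random.default_rng(config.seed)
    loci = dict(loci or DEFAULT_LOCI)
    db = AlleleDatabase(loci=loci)
    groups: dict[str, dict[str, int]] = {}
    for locus in sorted(set(config.loci)):
        cfg = loci[locus]
        n_groups = config.groups_per_locus[locus]
        head = _random_codons(cfg.insert_exon2_offset // 3 + 1, rng)[: cfg.insert_exon2_offset]
        tail_len = cfg.insert_length - cfg.insert_exon2_offset - cfg.exon2_length
        tail = _random_codons(tail_len // 3 + 1, rng)[: max(tail_len, 0)]
        n_codons = cfg.exon2_length // 3
        group_exon2: list[str] = []
        while len(group_exon2) < n_groups:
            cand = _random_codons(n_codons, rng)
            from Bio.Seq import Seq
            pep = str(Seq(cand).translate())
            if all(sum(a != b for a, b in zip(pep, str(Seq(g).translate()))) > 8
                   for g in group_exon2):
                group_exon2.append(cand)
        groups[locus] = {}
        for gi, base in enumerate(group_exon2, start=1):
            for mi in range(1, config.members_per_group + 1):
                exon2 = base if mi == 1 else _mutate_codons(base, int(rng.integers(1, 5)), rng)
                nt = head + exon2 + tail
                name = AlleleName(f"BoLA-{locus}", (f"{gi:03d}", f"{mi:02d}"))
                if db.lookup_sequence(locus, nt) is not None:
                    continue  # rare duplicate mutation; skip member
                pep = translate_exon2(nt, cfg)
                db.add(AlleleRecord(name, locus, nt, pep))
                groups[locus][str(name)] = gi
    return db, groups


@dataclass(frozen=True)
class PlantedHaplotype:
    index: int
    alleles: tuple[tuple[str, tuple[str, ...]], ...]   # locus -> alleles

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return dict(self.alleles)

    def dq_pairs(self) -> tuple[tuple[str, str], ...]:
        """Planted DQA/DQB pairs; by convention the k-th (sorted) DQA allele
        pairs with the k-th (sorted) DQB allele of the haplotype."""
        d = self.as_dict()
        return tuple(zip(d.get("DQA", ()), d.get("DQB", ())))


@dataclass
class PlantedCohort:
    pool: list[PlantedHaplotype]
    frequencies: np.ndarray
    animals: dict[str, tuple[int, int]]                 # animal -> pool indexes

    def genotype(self, animal: str) -> dict[str, frozenset]:
        i, j = self.animals[animal]
        g: dict[str, set] = {}
        for hap in (self.pool[i], self.pool[j]):
            for locus, alleles in hap.alleles:
                g.setdefault(locus, set()).update(alleles)
        return {k: frozenset(v) for k, v in g.items()}

    def homozygous_fraction(self) -> float:
        return sum(i == j for i, j in self.animals.values()) / len(self.animals)


def make_cohort(config: SimulationConfig, db: AlleleDatabase) -> PlantedCohort:
    """Draw a haplotype pool and a diploid cohort from it.

    MHCII haplotypes carry one DRB3 allele and one or two DQA/DQB pairs
    (about half duplicated); MHCI haplotypes carry 1-4 class I alleles.
    Pools are allele-disjoint so that co-segregation alone identifies
    them; pool frequencies follow a geometric law by rank and animals are
    two independent draws (Hardy-Weinberg).
    """
    rng = np.random.default_rng(config.seed + 1)
    avail = {locus: [str(r.name) for r in db.records(locus)] for locus in config.loci}
    for locus in avail:
        avail[locus] = list(rng.permutation(avail[locus]))
    pool: list[PlantedHaplotype] = []
    mhc2 = all(l in config.loci for l in ("DRB3", "DQA", "DQB"))
    if not mhc2 and "MHCI" not in config.loci:
        raise ValueError("cohort simulation needs either DRB3+DQA+DQB or MHCI in loci")
    size = config.pool_size if mhc2 else config.mhci_pool_size
    for k in range(size):
        alleles: dict[str, tuple[str, ...]] = {}
        if mhc2:
            n_dq = 2 if rng.random() < config.duplicated_dq_fraction else 1
            if len(avail["DRB3"]) < 1 or len(avail["DQA"]) < n_dq or len(avail["DQB"]) < n_dq:
                raise ValueError("reference too small for the requested pool")
            alleles["DRB3"] = (avail["DRB3"].pop(),)
            alleles["DQA"] = tuple(sorted(avail["DQA"].pop() for _ in range(n_dq)))
            alleles["DQB"] = tuple(sorted(avail["DQB"].pop() for _ in range(n_dq)))
        else:
            n = int(rng.integers(1, 5))
            if len(avail["MHCI"]) < n:
                raise ValueError("reference too small for the requested pool")
            alleles["MHCI"] = tuple(sorted(avail["MHCI"].pop() for _ in range(n)))
        pool.append(PlantedHaplotype(k, tuple(sorted(alleles.items()))))
    freqs = config.geometric_r ** np.arange(size)
    freqs = freqs / freqs.sum()
    draws = rng.choice(size, size=(config.cohort_size, 2), p=freqs)
    animals = {f"AN{i:04d}": (int(a), int(b)) for i, (a, b) in enumerate(draws)}
    return PlantedCohort(pool, freqs, animals)


# ---------------------------------------------------------------------------
# read generation

def simulate_sample_locus(alleles: Mapping[str, str], depth: int, config: SimulationConfig,
                          rng: np.random.Generator,
                          weights: Mapping[str, float] | None = None,
                          ) -> tuple[list[str], Counter]:
    """Simulate the merged, primer-trimmed inserts for one sample-locus.

    ``alleles`` maps allele name -> insert sequence.  Returns the insert
    list and a truth tally over {clean, error, chimera, n_inject, length}.
    """
    names = sorted(alleles)
    seqs = [alleles[n] for n in names]
    if weights is None:
        probs = np.full(len(names), 1.0 / len(names))
    else:
        w = np.array([weights[n] for n in names], dtype=float)
        probs = w / w.sum()
    counts = rng.multinomial(depth, probs)
    reads: list[str] = []
    truth: Counter = Counter()
    for idx, n_reads in enumerate(counts):
        for _ in range(n_reads):
            seq = seqs[idx]
            kind = "clean"
            if len(seqs) > 1 and rng.random() < config.chimera_fraction:
                j = int(rng.integers(len(seqs) - 1))
                j = j if j < idx else j + 1
                other = seqs[j]
                cut = int(rng.integers(1, min(len(seq), len(other))))
                seq = seq[:cut] + other[cut:]
                kind = "chimera"
            if config.error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                hits = np.nonzero(rng.random(len(arr)) < config.error_rate)[0]
                if hits.size:
                    for h in hits:
                        cur = arr[h].decode()
                        alts = [b for b in "ACGT" if b != cur]
                        arr[h] = alts[int(rng.integers(3))].encode()
                    seq = arr.tobytes().decode()
                    if kind == "clean":
                        kind = "error"
            if rng.random() < config.n_fraction:
                p = int(rng.integers(len(seq)))
                seq = seq[:p] + "N" + seq[p + 1:]
                kind = "n_inject"
            if rng.random() < config.length_artifact_fraction:
                span = int(rng.integers(10, 31))
                if rng.random() < 0.5 and len(seq) > span + 10:
                    p = int(rng.integers(len(seq) - span))
                    seq = seq[:p] + seq[p + span:]
                else:
                    p = int(rng.integers(len(seq)))
                    block = "".join(_BASES[rng.integers(0, 4, size=span)])
                    seq = seq[:p] + block + seq[p:]
                kind = "length"
            reads.append(seq)
            truth[kind] += 1
    return reads, truth


def realize_primer(primer: str) -> str:
    """Pick a concrete base at each degenerate position (first of the set)."""
    return "".join(IUPAC[c][0] for c in primer)


def insert_to_pair(insert: str, cfg: LocusConfig, mid_f: str, mid_r: str,
                   read_length: int) -> tuple[str, str]:
    amplicon = realize_primer(cfg.primer_fwd) + insert + revcomp(realize_primer(cfg.primer_rev))
    frag = mid_f + amplicon + revcomp(mid_r)
    return frag[:read_length], revcomp(frag)[:read_length]


@dataclass
class SimulatedRun:
    config: SimulationConfig
    db: AlleleDatabase
    groups: dict[str, dict[str, int]]
    cohort: PlantedCohort
    reads: dict[tuple[str, str], list[str]]             # (animal, locus) -> inserts
    truth: dict[tuple[str, str], Counter]


def make_reads(config: SimulationConfig, db: AlleleDatabase, cohort: PlantedCohort,
               groups: dict[str, dict[str, int]] | None = None) -> SimulatedRun:
    """Simulate merged inserts for every animal and locus in the cohort."""
    rng = np.random.default_rng(config.seed + 2)
    reads: dict[tuple[str, str], list[str]] = {}
    truth: dict[tuple[str, str], Counter] = {}
    for animal in sorted(cohort.animals):
        g = cohort.genotype(animal)
        for locus in config.loci:
            seqs = {a: db.get(locus, a).nt_sequence for a in g.get(locus, ())}
            if not seqs:
                continue
            reads[(animal, locus)], truth[(animal, locus)] = simulate_sample_locus(
                seqs, config.depth, config, rng)
    return SimulatedRun(config, db, groups or {}, cohort, reads, truth)


def write_run(run: SimulatedRun, outdir: str | Path, *, paired: bool = False) -> None:
    """Write a simulated run: FASTQ (merged or paired), MID sheet, truth TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(run.config.seed + 3)
    animals = sorted(run.cohort.animals)
    mids: dict[str, tuple[str, str]] = {}
    seen = set()
    for a in animals:
        while True:
            f = "".join(_BASES[rng.integers(0, 4, size=run.config.mid_length)])
            r = "".join(_BASES[rng.integers(0, 4, size=run.config.mid_length)])
            if (f, r) not in seen:
                seen.add((f, r))
                mids[a] = (f, r)
                break
    with open(out / "mids.tsv", "w") as fh:
        fh.write("sample_id\tmid_fwd\tmid_rev\n")
        for a in animals:
            fh.write(f"{a}\t{mids[a][0]}\t{mids[a][1]}\n")
    with open(out / "truth_genotypes.tsv", "w") as fh:
        fh.write("animal\tlocus\talleles\thap1\thap2\n")
        for a in animals:
            i, j = run.cohort.animals[a]
            g = run.cohort.genotype(a)
            for locus in sorted(g):
                fh.write(f"{a}\t{locus}\t{','.join(sorted(g[locus]))}\t{i}\t{j}\n")
    with open(out / "truth_pool.tsv", "w") as fh:
        fh.write("index\tfrequency\talleles\n")
        for hap, f in zip(run.cohort.pool, run.cohort.frequencies):
            cell = ";".join(f"{locus}:{','.join(v)}" for locus, v in hap.alleles)
            fh.write(f"{hap.index}\t{f:.6g}\t{cell}\n")
    for locus in run.config.loci:
        cfg = run.db.loci[locus]
        if paired:
            r1s, r2s = [], []
            for a in animals:
                for k, insert in enumerate(run.reads.get((a, locus), [])):
                    m1, m2 = insert_to_pair(insert, cfg, *mids[a], run.config.read_length)
                    r1s.append(FastqRead(f"{a}:{locus}:{k}/1", m1, "I" * len(m1)))
                    r2s.append(FastqRead(f"{a}:{locus}:{k}/2", m2, "I" * len(m2)))
            write_fastq(out / f"{locus}_R1.fastq", r1s)
            write_fastq(out / f"{locus}_R2.fastq", r2s)
        else:
            merged = [FastqRead(f"{a}:{locus}:{k}", s, "I" * len(s))
                      for a in animals for k, s in enumerate(run.reads.get((a, locus), []))]
            write_fastq(out / f"{locus}_merged.fastq", merged)
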