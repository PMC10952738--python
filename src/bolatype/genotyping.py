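"""Per-animal allele calling from retained read clusters.

Retained clusters either match a reference allele exactly at the
nucleotide level or are routed through novelty classification (and, via
the nomenclature registry, named immediately so downstream haplotyping
treats known and novel alleles uniformly).  Class I genotypes merge two
redundant PCR reactions (For1/Rev2 and For3/Rev1); an allele may be seen
by either or both sets, and per-set normalised frequencies are kept
separate.  Quality flags mark animals with insufficient read depth or
with more called alleles than a diploid genotype allows (cross-sample
contamination).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .alleles import AlleleDatabase, LocusConfig, NoveltyResult, classify_novelty, \
    make_record_from_novelty
from .nomenclature import NameRegistry
from .reads import ReadCluster, retained

#: maximum called alleles per locus in a clean diploid genotype
DIPLOID_MAX = {"MHCI": 8, "DRB3": 2, "DQA": 4, "DQB": 4}


@dataclass
class AlleleCall:
    allele: str
    frequency: float                     # normalised over called clusters
    novelty: NoveltyResult | None = None
    primer_sets: dict[str, float] = field(default_factory=dict)

    @property
    def is_novel(self) -> bool:
        return self.novelty is not None and self.novelty.kind != "exact"


@dataclass
class LocusGenotype:
    locus: str
    calls: list[AlleleCall] = field(default_factory=list)
    total_reads: int = 0
    not_amplified: bool = False

    def alleles(self) -> list[str]:
        return [c.allele for c in self.calls]


@dataclass
class Genotype:
    animal: str
    loci: dict[str, LocusGenotype] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def alleles(self, locus: str) -> list[str]:
        lg = self.loci.get(locus)
        return lg.alleles() if lg else []


def call_alleles(clusters: Sequence[ReadCluster], db: AlleleDatabase, cfg: LocusConfig,
                 *, registry: NameRegistry | None = None, country_code: str = "zm",
                 locus_prefix: str | None = None, add_novel_to_db: bool = True,
                 ) -> LocusGenotype:
    """Convert a sample-locus' retained clusters into allele calls.

    Exact nucleotide matches keep their reference names; unmatched
    sequences are classified for novelty and, when a registry is supplied,
    named provisionally.  Frequencies are re-normalised over the called
    clusters.
    """
    kept = retained(clusters)
    lg = LocusGenotype(cfg.locus_tag, total_reads=sum(c.count for c in kept))
    total = sum(c.count for c in kept)
    if not kept:
        return lg
    prefix = locus_prefix or f"BoLA-{cfg.locus_tag}"
    for c in kept:
        hit = db.lookup_sequence(cfg.locus_tag, c.nt_sequence)
        if hit is not None:
            lg.calls.append(AlleleCall(hit, c.count / total))
            continue
        res = classify_novelty(c.nt_sequence, db, cfg)
        if registry is not None:
            name = registry.name_novel_allele(res, prefix, country_code,
                                              sequence_key=f"{cfg.locus_tag}:{c.nt_sequence}")
            if add_novel_to_db and db.lookup_sequence(cfg.locus_tag, c.nt_sequence) is None:
                try:
                    db.add(make_record_from_novelty(name, c.nt_sequence, cfg, res))
                except ValueError:
                    pass  # translation failures stay call-only
            label = str(name)
        else:
            label = f"novel:{res.kind}:{res.nearest}"
        lg.calls.append(AlleleCall(label, c.count / total, novelty=res))
    lg.calls.sort(key=lambda c: (-c.frequency, c.allele))
    return lg


def reconcile_mhci(set_a: LocusGenotype | None, set_b: LocusGenotype | None) -> LocusGenotype:
    """Merge the two redundant class I primer sets into one genotype.

    The allele set is the union; each call records its per-set normalised
    frequency, and a set that produced no amplicon at all is recorded as
    not-amplified (distinct from an allele merely absent from that set).
    """
    a_has = set_a is not None and set_a.calls
    b_has = set_b is not None and set_b.calls
    merged = LocusGenotype("MHCI",
                           total_reads=(set_a.total_reads if set_a else 0)
                           + (set_b.total_reads if set_b else 0))
    if not a_has and not b_has:
        merged.not_amplified = True
        return merged
    by_allele: dict[str, AlleleCall] = {}
    for label, lg in (("For1/Rev2", set_a), ("For3/Rev1", set_b)):
        if lg is None or not lg.calls:
            continue
        for call in lg.calls:
            tgt = by_allele.setdefault(call.allele,
                                       AlleleCall(call.allele, 0.0, novelty=call.novelty))
            tgt.primer_sets[label] = call.frequency
    for call in by_allele.values():
        call.frequency = sum(call.primer_sets.values()) / len(call.primer_sets)
    merged.calls = sorted(by_allele.values(), key=lambda c: (-c.frequency, c.allele))
    return merged


def flag_data_quality(genotype: Genotype, *, min_reads: int = 200,
                      required_loci: Iterable[str] = ()) -> set[str]:
    """Set ``insufficient_data`` / ``contamination_suspect`` flags.

    ``min_reads`` defaults to 200 per locus, at which the 7% DQA frequency
    threshold still corresponds to >= 14 reads.
    """
    flags = set()
    for locus in required_loci or genotype.loci:
        lg = genotype.loci.get(locus)
        if lg is None or lg.total_reads < min_reads:
            flags.add("insufficient_data")
    for locus, lg in genotype.loci.items():
        if len(lg.calls) > DIPLOID_MAX.get(locus, 4):
            flags.add("contamination_suspect")
    genotype.flags |= flags
    return flags


# ---------------------------------------------------------------------------
# Genotype table round-trip (one row per animal-locus; the read-free entry
# point for users starting from allele-call tables)

def genotypes_to_tsv(genotypes: Iterable[Genotype], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("animal\tlocus\talleles\ttotal_reads\tflags\n")
        for g in sorted(genotypes, key=lambda g: g.animal):
            for locus in sorted(g.loci):
                lg = g.loci[locus]
                cell = ",".join(f"{c.allele}={c.frequency:.4f}" for c in lg.calls)
                fh.write(f"{g.animal}\t{locus}\t{cell}\t{lg.total_reads}\t"
                         f"{';'.join(sorted(g.flags))}\n")


def genotypes_from_tsv(path: str | Path) -> dict[str, Genotype]:
    out: dict[str, Genotype] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            animal, locus = parts[idx["animal"]], parts[idx["locus"]]
            g = out.setdefault(animal, Genotype(animal))
            lg = LocusGenotype(locus, total_reads=int(parts[idx["total_reads"]] or 0))
            cell = parts[idx["alleles"]]
            if cell:
                for item in cell.split(","):
                    allele, _, freq = item.partition("=")
                    lg.calls.append(AlleleCall(allele, float(freq or 0)))
            g.loci[locus] = lg
            flags = parts[idx["flags"]] if "flags" in idx and len(parts) > idx["flags"] else ""
            if flags:
                g.flags |= set(flags.split(";"))
    return out
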