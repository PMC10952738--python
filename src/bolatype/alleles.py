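"""Allele reference databases for BoLA amplicon typing.

The unit of reference data is an *allele record*: the primer-trimmed
amplicon-region nucleotide sequence of one expressed MHC allele together
with the translation of its exon 2 (the peptide-binding-groove exon, where
essentially all of the polymorphism that matters for typing resides).

Allele names follow the colon-delimited convention used for non-human MHC
sequences: an optional locus prefix (``BoLA-DQA``, ``BoLA-3``, ``MHCI`` ...),
a ``*`` separator, then 2-4 colon-separated fields.  The first field is the
allelic group (numeric, e.g. ``024``, or country-coded for provisional
groups, e.g. ``zm1``); the second distinguishes protein variants within the
group; later fields distinguish synonymous/near-synonymous variants.
Provisional (non-official) protein and synonym fields are double capital
letters (``AA``, ``AB`` ...) so they can never collide with official numeric
assignments.  A trailing ``N`` marks a null (non-expressed) allele.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

import edlib
from Bio import SeqIO
from Bio.Seq import Seq


class AlleleNameError(ValueError):
    """Raised when an allele name string cannot be parsed."""


class AlleleCollisionError(ValueError):
    """Raised when two reference records collide on name or sequence."""


class NullAlleleError(ValueError):
    """Raised when a non-null record translates with an internal stop."""


_FIELD_RE = re.compile(r"^(\d+|[A-Z]{2}|[a-z]{2,3}\d+)$")
_NULLABLE_RE = re.compile(r"^(\d+|[A-Z]{2})N$")


@dataclass(frozen=True)
class AlleleName:
    """Structured allele name; ``parse``/``str`` round-trip byte-identically."""

    prefix: str
    fields: tuple[str, ...]
    null: bool = False

    @property
    def group(self) -> str:
        return self.fields[0]

    @property
    def protein_field(self) -> str | None:
        return self.fields[1] if len(self.fields) > 1 else None

    @property
    def synonym_fields(self) -> tuple[str, ...]:
        return self.fields[2:]

    @property
    def is_provisional(self) -> bool:
        return any(f.isalpha() and f.isupper() for f in self.fields[1:]) or not self.fields[0][0].isdigit()

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        raw = text.strip().strip("*")
        if not raw:
            raise AlleleNameError("empty allele name")
        prefix, _, body = raw.rpartition("*")
        fields = body.split(":")
        null = False
        last = fields[-1]
        if _NULLABLE_RE.match(last):
            null = True
            fields[-1] = last[:-1]
        for f in fields:
            if not _FIELD_RE.match(f):
                raise AlleleNameError(f"unparseable allele name {text!r} (field {f!r})")
        return cls(prefix=prefix, fields=tuple(fields), null=null)

    def __str__(self) -> str:
        body = ":".join(self.fields) + ("N" if self.null else "")
        return f"{self.prefix}*{body}" if self.prefix else body


@dataclass(frozen=True)
class LocusConfig:
    """Amplicon geometry for one locus.

    ``amplicon_length`` is the full PCR product excluding MID tags but
    including the primer annealing sites; ``exon2_offset`` is the 0-based
    start of exon 2 within that amplicon.  For the class II loci the exon
    partition sums to the amplicon length; the class I amplicon spans two
    exons and is not partitioned this way.
    """

    locus_tag: Literal["MHCI", "DRB3", "DQA", "DQB"]
    amplicon_length: int
    exon2_offset: int
    exon2_length: int
    reading_frame_offset: int = 0
    primer_fwd: str = ""
    primer_rev: str = ""
    freq_threshold: float = 0.02

    def __post_init__(self) -> None:
        if not (0 <= self.reading_frame_offset <= 2):
            raise ValueError("reading_frame_offset must be 0-2")
        if self.locus_tag in ("DQA", "DQB") and self.exon2_offset + self.exon2_length > self.amplicon_length:
            raise ValueError(f"{self.locus_tag}: exon 2 does not fit in the amplicon")

    @property
    def insert_length(self) -> int:
        """Expected length of the primer-trimmed amplicon region."""
        return self.amplicon_length - len(self.primer_fwd) - len(self.primer_rev)

    @property
    def insert_exon2_offset(self) -> int:
        return self.exon2_offset - len(self.primer_fwd)


# Primer pairs used by the typing platform (IUPAC-degenerate, 5'->3').
DQA_PRIMERS = ("STGGRRGTGAAGACATYGTG", "GAYTTGGRAAACACAGYCAC")
DQB_PRIMERS = ("GGRCYGAGGGCAGAGACT", "GGRGAGATGGTCACTGTAGG")

#: Default locus geometries.  DQA: 324 bp = 36 bp exon 1 + 267 bp exon 2 +
#: 21 bp exon 3; DQB: 320 bp = 24 + 270 + 26 (the exon partition).  The
#: DRB3 and MHCI amplicons are handled by the same machinery; their
#: geometries are package defaults for simulation and length filtering.
DEFAULT_LOCI: Mapping[str, LocusConfig] = {
    "DQA": LocusConfig("DQA", 324, 36, 267, 0, *DQA_PRIMERS, freq_threshold=0.07),
    "DQB": LocusConfig("DQB", 320, 24, 270, 0, *DQB_PRIMERS, freq_threshold=0.02),
    "DRB3": LocusConfig("DRB3", 320, 24, 270, 0, *DQB_PRIMERS, freq_threshold=0.02),
    "MHCI": LocusConfig("MHCI", 414, 24, 270, 0, *DQB_PRIMERS, freq_threshold=0.002),
}


@dataclass(frozen=True)
class AlleleRecord:
    name: AlleleName
    locus: str
    nt_sequence: str
    peptide: str
    provenance: Literal["reference", "novel"] = "reference"


def translate_exon2(nt_sequence: str, cfg: LocusConfig, *, null: bool = False,
                    from_insert: bool = True) -> str:
    """Translate the exon-2 portion of an amplicon-region sequence.

    ``from_insert`` interprets the sequence as primer-trimmed (the usual
    case for both reference records and pipeline inserts).  An internal
    stop codon raises :class:`NullAlleleError` unless ``null`` is set, in
    which case translation stops at the stop codon.
    """
    offset = cfg.insert_exon2_offset if from_insert else cfg.exon2_offset
    if offset < 0 or offset + 3 > len(nt_sequence):
        raise ValueError("sequence does not cover exon 2")
    exon2 = nt_sequence[offset + cfg.reading_frame_offset: offset + cfg.exon2_length]
    exon2 = exon2[: len(exon2) - len(exon2) % 3]
    pep = str(Seq(exon2).translate())
    if "*" in pep:
        if not null:
            raise NullAlleleError("internal stop codon in a non-null allele (null candidate)")
        pep = pep[: pep.index("*")]
    return pep


def aa_distance(a: str, b: str, *, mode: str = "auto") -> int:
    """Protein distance between two peptides.

    Equal-length peptides are compared position-wise (Hamming count);
    unequal lengths fall back to unit-cost edit distance (substitutions and
    single-residue indels each cost 1).  ``mode="hamming"`` refuses
    unequal lengths instead.
    """
    if not a or not b:
        raise ValueError("peptides must be non-empty")
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b))
    if mode == "hamming":
        raise ValueError("unequal-length peptides under hamming-only mode")
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class AlleleDatabase:
    """Per-locus allele reference set, indexed by name and by sequence."""

    loci: dict[str, LocusConfig] = field(default_factory=dict)
    _by_name: dict[str, dict[str, AlleleRecord]] = field(default_factory=dict)
    _by_seq: dict[str, dict[str, str]] = field(default_factory=dict)

    def add(self, record: AlleleRecord) -> None:
        locus = record.locus
        cfg = self.loci.get(locus)
        if cfg is None:
            raise KeyError(f"unknown locus {locus!r}; register its LocusConfig first")
        if abs(len(record.nt_sequence) - cfg.insert_length) > 9:
            raise ValueError(
                f"{record.name}: sequence length {len(record.nt_sequence)} departs from the "
                f"expected {cfg.insert_length} bp amplicon region by more than 9 bp")
        names = self._by_name.setdefault(locus, {})
        seqs = self._by_seq.setdefault(locus, {})
        key = str(record.name)
        if key in names:
            raise AlleleCollisionError(f"duplicate allele name {key!r} at locus {locus}")
        if record.nt_sequence in seqs:
            raise AlleleCollisionError(
                f"identical sequence for {key!r} and {seqs[record.nt_sequence]!r} at locus {locus}")
        names[key] = record
        seqs[record.nt_sequence] = key

    def get(self, locus: str, name: str) -> AlleleRecord:
        return self._by_name[locus][name]

    def lookup_sequence(self, locus: str, nt: str) -> str | None:
        return self._by_seq.get(locus, {}).get(nt)

    def records(self, locus: str) -> list[AlleleRecord]:
        return list(self._by_name.get(locus, {}).values())

    def size(self, locus: str | None = None) -> int:
        if locus is not None:
            return len(self._by_name.get(locus, {}))
        return sum(len(v) for v in self._by_name.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["name", "locus", "length", "peptide"])
            for locus in sorted(self._by_name):
                for rec in self._by_name[locus].values():
                    w.writerow([str(rec.name), locus, len(rec.nt_sequence), rec.peptide])


def load_allele_fasta(path: str | Path, cfg: LocusConfig,
                      db: AlleleDatabase | None = None) -> AlleleDatabase:
    """Load a per-locus reference FASTA of amplicon-region sequences.

    Headers must carry parseable allele names; lowercase sequence is
    accepted and normalised.  Duplicate sequences or names raise
    :class:`AlleleCollisionError` naming both records.
    """
    if db is None:
        db = AlleleDatabase()
    db.loci.setdefault(cfg.locus_tag, cfg)
    for seqrec in SeqIO.parse(str(path), "fasta"):
        try:
            name = AlleleName.parse(seqrec.id)
        except AlleleNameError as exc:
            raise AlleleNameError(f"unparseable FASTA header {seqrec.description!r}: {exc}") from exc
        nt = str(seqrec.seq).upper()
        if set(nt) - set("ACGT"):
            raise ValueError(f"{seqrec.id}: non-ACGT characters in reference sequence")
        pep = translate_exon2(nt, cfg, null=name.null)
        db.add(AlleleRecord(name=name, locus=cfg.locus_tag, nt_sequence=nt, peptide=pep))
    return db


@dataclass(frozen=True)
class NoveltyResult:
    """Outcome of querying an unmatched sequence against the reference set."""

    kind: Literal["exact", "synonymous_variant", "new_member", "new_group"]
    nearest: str | None = None
    distance: int | None = None
    peptide: str | None = None


def classify_novelty(query_nt: str, db: AlleleDatabase, cfg: LocusConfig,
                     *, max_group_distance: int = 4) -> NoveltyResult:
    """Decide what an unmatched amplicon-region sequence represents.

    Exact nucleotide match -> ``exact``; identical exon-2 peptide to some
    record -> ``synonymous_variant``; within ``max_group_distance`` amino
    acid changes of the closest record -> ``new_member`` of that record's
    allelic group; further than that from everything -> ``new_group``.
    Null alleles are kept in the database but excluded from peptide
    searches; ties on distance resolve to the lexicographically smallest
    allele name.
    """
    locus = cfg.locus_tag
    records = db.records(locus)
    if not records:
        raise ValueError(f"empty allele database for locus {locus}")
    hit = db.lookup_sequence(locus, query_nt)
    if hit is not None:
        return NoveltyResult("exact", nearest=hit, distance=0)
    pep = translate_exon2(query_nt, cfg)
    best_name, best_d = None, None
    for rec in sorted(records, key=lambda r: str(r.name)):
        if rec.name.null:
            continue
        d = aa_distance(pep, rec.peptide)
        if best_d is None or d < best_d:
            best_name, best_d = str(rec.name), d
    if best_d == 0:
        return NoveltyResult("synonymous_variant", nearest=best_name, distance=0, peptide=pep)
    if best_d is not None and best_d <= max_group_distance:
        return NoveltyResult("new_member", nearest=best_name, distance=best_d, peptide=pep)
    return NoveltyResult("new_group", nearest=best_name, distance=best_d, peptide=pep)


def make_record_from_novelty(name: AlleleName, query_nt: str, cfg: LocusConfig,
                             result: NoveltyResult) -> AlleleRecord:
    pep = result.peptide if result.peptide is not None else translate_exon2(query_nt, cfg, null=name.null)
    return AlleleRecord(name=name, locus=cfg.locus_tag, nt_sequence=query_nt,
                        peptide=pep, provenance="novel")
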