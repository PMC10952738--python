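"""Bundled haplotype catalogues transcribed from the typing study.

Two tables ship with the package: the MHCII haplotype catalogue for the
Holstein-Friesian and Zambian cohorts (DRB3 allele plus one or two DQA/DQB
pairs, with observation counts per cohort) and the catalogue of novel MHCI
haplotypes from the Zambian cohort.  They drive the desk-scale validation
suite — pair/haplotype counting, association-graph classification,
nomenclature round-trips and frequency recomputation — without any
sequencing data.

Two MHCII rows (DR1.1|DQ1.1 and DR14.1|DQ14.1) carry DQA alleles known
from earlier studies but not amplified by this platform's DQA primers;
they are flagged ``dqa1_presumed`` and can be included (default) or
excluded from complete-pair counting.  A ``?`` marks orphan pairs whose
DQA partner was never identified.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal

from .alleles import AlleleName
from .nomenclature import NameRegistry

Cohort = Literal["hf", "zm"]


@dataclass(frozen=True)
class Mhc2Row:
    haplotype: str
    prev: str
    drb3: str
    pairs: tuple[tuple[str, str], ...]   # (dqa, dqb); dqa may be '?'
    dq_tokens: tuple[str, ...]
    hf_n: int
    zm_n: int
    presumed_dqa: tuple[bool, ...]

    @property
    def unconfirmed(self) -> bool:
        return self.haplotype.startswith("un")

    @property
    def base_name(self) -> str:
        return self.haplotype[2:] if self.unconfirmed else self.haplotype

    def count(self, cohort: Cohort) -> int:
        return self.hf_n if cohort == "hf" else self.zm_n


@dataclass(frozen=True)
class Mhc1Row:
    haplotype: str
    alleles: tuple[str, ...]
    obs: int
    pct: float

    @property
    def unconfirmed(self) -> bool:
        return self.haplotype.startswith("un")


def _read_tsv(name: str) -> list[dict[str, str]]:
    with resources.files("bolatype.data").joinpath(name).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = []
        for row in reader:
            rows.append({k: (v or "") for k, v in row.items()})
        return rows


def load_mhc2_table() -> list[Mhc2Row]:
    rows = []
    for r in _read_tsv("mhc2_haplotypes.tsv"):
        pairs, presumed = [], []
        for slot in ("1", "2"):
            dqb = r[f"dqb{slot}"]
            if dqb:
                pairs.append((r[f"dqa{slot}"], dqb))
                presumed.append(slot == "1" and r.get("dqa1_presumed") == "1")
        name = r["haplotype"]
        base = name[2:] if name.startswith("un") else name
        tokens = tuple(base.split("|")[1:])
        assert len(tokens) == len(pairs)
        rows.append(Mhc2Row(name, r["prev"], r["drb3"], tuple(pairs), tokens,
                            int(r["hf_n"]), int(r["zm_n"]), tuple(presumed)))
    return rows


def load_mhc1_table() -> list[Mhc1Row]:
    rows = []
    for r in _read_tsv("mhc1_novel_haplotypes.tsv"):
        alleles = tuple(r[f"allele{i}"] for i in range(1, 5) if r[f"allele{i}"])
        rows.append(Mhc1Row(r["haplotype"], alleles, int(r["obs"]), float(r["pct"])))
    return rows


def cohort_rows(rows: Iterable[Mhc2Row], cohort: Cohort) -> list[Mhc2Row]:
    return [r for r in rows if r.count(cohort) > 0]


def count_dq_pairs(rows: Iterable[Mhc2Row], cohort: Cohort, *,
                   level: Literal["token", "allele"] = "token",
                   complete_only: bool = False,
                   include_presumed: bool = True) -> int:
    """Count distinct DQA/DQB pairs in a cohort.

    ``level="token"`` counts distinct DQ-pair tokens (the DQm.n names);
    ``level="allele"`` counts distinct (DQA, DQB) allele combinations.
    ``complete_only`` drops orphan pairs (no DQA identified), and
    ``include_presumed=False`` additionally treats the two
    literature-presumed DQA alleles as unidentified.
    """
    seen = set()
    for r in cohort_rows(rows, cohort):
        for (dqa, dqb), token, pres in zip(r.pairs, r.dq_tokens, r.presumed_dqa):
            if not include_presumed and pres:
                dqa = "?"
            if complete_only and dqa == "?":
                continue
            seen.add(token if level == "token" else (dqa, dqb))
    return len(seen)


def count_dq_haplotypes(rows: Iterable[Mhc2Row], cohort: Cohort) -> tuple[int, int, int]:
    """(total, duplicated, single) distinct DQ haplotypes in a cohort."""
    haps = {tuple(sorted(r.dq_tokens)) for r in cohort_rows(rows, cohort)}
    dup = sum(len(h) == 2 for h in haps)
    return len(haps), dup, len(haps) - dup


def primed_registry(mhc2: Iterable[Mhc2Row] | None = None,
                    mhc1: Iterable[Mhc1Row] | None = None) -> NameRegistry:
    """Registry pre-loaded from the printed tables in row order, so that
    regenerated names match the published catalogue."""
    reg = NameRegistry()
    if mhc2 is not None:
        for row in mhc2:
            for (dqa, dqb), token in zip(row.pairs, row.dq_tokens):
                a = None if dqa == "?" else AlleleName.parse(dqa)
                reg.prime_dq_pair(a, AlleleName.parse(dqb), token)
    if mhc1 is not None:
        for row in mhc1:
            reg.prime_mhc1_haplotype(row.alleles, row.haplotype)
    return reg


def all_printed_allele_names(mhc2: Iterable[Mhc2Row], mhc1: Iterable[Mhc1Row]) -> list[str]:
    """Every allele name string appearing in the two tables (ambiguous
    'a/b' entries contribute each alternative)."""
    names: list[str] = []
    for r in mhc2:
        cells = [r.drb3] + [x for p in r.pairs for x in p]
        for cell in cells:
            if cell and cell != "?":
                names.extend(cell.split("/"))
    for r in mhc1:
        for cell in r.alleles:
            names.extend(cell.split("/"))
    return names
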