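"""Haplotype inference from per-animal genotypes by recurrent co-segregation.

No pedigree or statistical phasing is used: a diploid cohort's haplotype
catalogue is built from the fixed point of a seed-and-subtract procedure.
Animals are visited in order of (genotype size, id).  An animal resolves
when its called alleles partition exactly into one (homozygous) or two
catalogued haplotypes; otherwise, if one catalogued haplotype is a proper
subset of the genotype and the remainder is a class-valid haplotype, the
remainder enters the catalogue (subtraction); otherwise, if the genotype
itself fits within single-haplotype bounds it seeds the catalogue.  The
loop repeats until nothing changes.  A final pass re-derives every
animal's decompositions against the finished catalogue: more than one
distinct decomposition marks the animal ambiguous, none marks it
unresolved (genotypes beyond diploid bounds are additionally tested for a
three-haplotype decomposition — blood-chimaeric twins).  Haplotypes are
confirmed when observed in at least two resolved animals.

Class bounds: an MHCII haplotype is one DRB3 allele plus one or two DQ
pairs; an MHCI haplotype is one to four class I alleles.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: per-locus (min, max) element counts of a single haplotype
MHC2_BOUNDS: Mapping[str, tuple[int, int]] = {"DRB3": (1, 1), "DQ": (1, 2)}
MHC1_BOUNDS: Mapping[str, tuple[int, int]] = {"MHCI": (1, 4)}

Genotype = Mapping[str, frozenset]


@dataclass(frozen=True)
class Haplotype:
    """An ordered (locus -> sorted elements) allele combination."""

    alleles: tuple[tuple[str, tuple[str, ...]], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "Haplotype":
        return cls(tuple((locus, tuple(sorted(v))) for locus, v in sorted(d.items()) if v))

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return dict(self.alleles)

    def elements(self) -> list[str]:
        return [e for _, v in self.alleles for e in v]

    def __str__(self) -> str:
        return "; ".join(f"{locus}:{','.join(v)}" for locus, v in self.alleles)


def _valid(d: Mapping[str, frozenset], bounds: Mapping[str, tuple[int, int]]) -> bool:
    for locus, (lo, hi) in bounds.items():
        if not lo <= len(d.get(locus, frozenset())) <= hi:
            return False
    return not (set(d) - set(bounds))


def _subset(h: Haplotype, g: Genotype) -> bool:
    return all(set(v) <= g.get(locus, frozenset()) for locus, v in h.alleles)


def _subtract(g: Genotype, h: Haplotype) -> dict[str, frozenset]:
    hd = h.as_dict()
    return {locus: g.get(locus, frozenset()) - frozenset(hd.get(locus, ()))
            for locus in set(g) | set(hd)}


def _exceeds_diploid(g: Genotype, bounds: Mapping[str, tuple[int, int]]) -> bool:
    return any(len(g.get(locus, frozenset())) > 2 * hi for locus, (_, hi) in bounds.items())


def decompositions(g: Genotype, catalogue: Sequence[Haplotype],
                   bounds: Mapping[str, tuple[int, int]], *,
                   max_parts: int = 2) -> list[tuple[Haplotype, ...]]:
    """All distinct exact partitions of a genotype into 1..max_parts
    catalogued haplotypes (unordered; parts must be pairwise disjoint and
    their union must equal the genotype)."""
    g = {k: frozenset(v) for k, v in g.items() if v}
    subs = [h for h in catalogue if _subset(h, g)]
    found: list[tuple[Haplotype, ...]] = []
    total = sum(len(v) for v in g.values())
    for h in subs:
        if sum(len(v) for v in h.as_dict().values()) == total:
            found.append((h,))
    for n in range(2, max_parts + 1):
        for combo in combinations(range(len(subs)), n):
            parts = [subs[i] for i in combo]
            if sum(sum(len(v) for v in p.as_dict().values()) for p in parts) != total:
                continue
            merged: dict[str, set] = defaultdict(set)
            ok = True
            for p in parts:
                for locus, v in p.alleles:
                    if merged[locus] & set(v):
                        ok = False
                        break
                    merged[locus] |= set(v)
                if not ok:
                    break
            if ok and all(merged[locus] == set(g.get(locus, frozenset())) for locus in merged) \
                    and set(merged) == set(g):
                found.append(tuple(sorted(parts, key=str)))
    return found


@dataclass
class AnimalAssignment:
    animal: str
    haplotypes: list[Haplotype]
    zygosity: str      # homozygous | heterozygous | multi | none
    resolution: str    # resolved | ambiguous | unresolved


@dataclass
class CatalogueEntry:
    haplotype: Haplotype
    n_animals: int = 0
    n_observations: int = 0
    name: str = ""

    @property
    def status(self) -> str:
        return "confirmed" if self.n_animals >= 2 else "unconfirmed"


@dataclass
class CohortResult:
    catalogue: list[CatalogueEntry]
    assignments: dict[str, AnimalAssignment]

    def entry(self, h: Haplotype) -> CatalogueEntry:
        return next(e for e in self.catalogue if e.haplotype == h)

    def observation_profile(self) -> dict[str, int]:
        return {e.name or str(e.haplotype): e.n_observations for e in self.catalogue}


def infer_catalogue(genotypes: Mapping[str, Mapping[str, Iterable[str]]],
                    bounds: Mapping[str, tuple[int, int]] = MHC2_BOUNDS) -> CohortResult:
    """Infer the haplotype catalogue and per-animal assignments for a cohort.

    ``genotypes`` maps animal id -> locus -> called elements (alleles, or
    DQ-pair tokens for the MHCII ``DQ`` pseudo-locus).  Animals carrying
    quality flags should be excluded by the caller.
    """
    if not genotypes:
        raise ValueError("empty cohort")
    gts: dict[str, dict[str, frozenset]] = {
        a: {locus: frozenset(v) for locus, v in g.items() if v}
        for a, g in genotypes.items()}
    order = sorted(gts, key=lambda a: (sum(len(v) for v in gts[a].values()), a))
    catalogue: list[Haplotype] = []
    assigned: dict[str, tuple[Haplotype, ...]] = {}
    changed = True
    while changed:
        changed = False
        for animal in order:
            if animal in assigned:
                continue
            g = gts[animal]
            decs = decompositions(g, catalogue, bounds)
            if decs:
                assigned[animal] = decs[0]
                changed = True
                continue
            placed = False
            for h in catalogue:
                if _subset(h, g):
                    rest = _subtract(g, h)
                    if any(rest.values()) and _valid(rest, bounds):
                        partner = Haplotype.from_dict(rest)
                        catalogue.append(partner)
                        assigned[animal] = tuple(sorted((h, partner), key=str))
                        placed = changed = True
                        break
            if placed:
                continue
            if _valid(g, bounds):
                seed = Haplotype.from_dict(g)
                catalogue.append(seed)
                assigned[animal] = (seed,)
                changed = True
    # final pass: re-derive every animal against the finished catalogue
    assignments: dict[str, AnimalAssignment] = {}
    animal_sets: dict[Haplotype, set] = defaultdict(set)
    observations: dict[Haplotype, int] = defaultdict(int)
    for animal in order:
        g = gts[animal]
        decs = decompositions(g, catalogue, bounds)
        if len(decs) == 1:
            haps = list(decs[0])
            zyg = {1: "homozygous", 2: "heterozygous"}[len(haps)]
            assignments[animal] = AnimalAssignment(animal, haps, zyg, "resolved")
            for h in haps:
                animal_sets[h].add(animal)
                observations[h] += 2 if len(haps) == 1 else 1
        elif len(decs) > 1:
            assignments[animal] = AnimalAssignment(animal, [], "none", "ambiguous")
        else:
            if _exceeds_diploid(g, bounds):
                multi = decompositions(g, catalogue, bounds, max_parts=3)
                if len(multi) == 1 and len(multi[0]) == 3:
                    haps = list(multi[0])
                    assignments[animal] = AnimalAssignment(animal, haps, "multi", "resolved")
                    for h in haps:
                        animal_sets[h].add(animal)
                        observations[h] += 1
                    continue
            assignments[animal] = AnimalAssignment(animal, [], "none", "unresolved")
    entries = [CatalogueEntry(h, len(animal_sets[h]), observations[h])
               for h in catalogue if animal_sets[h]]
    return CohortResult(entries, assignments)


# ---------------------------------------------------------------------------
# DQ pairing by cohort-wide co-occurrence

class DQPairingError(ValueError):
    pass


def pair_dq_loci(genotypes: Mapping[str, Mapping[str, Iterable[str]]],
                 ) -> tuple[list[tuple[str | None, str]], dict[str, list[tuple[str | None, str]]]]:
    """Pair DQA with DQB alleles whose presence across animals coincides.

    Alleles amplify from the same DQ locus on the same haplotype, so a
    genuine pair is perfectly correlated across the cohort.  DQB alleles
    with no matching DQA signature become orphan pairs (DQA ``None``); a
    DQA signature with more DQA than DQB alleles is a consistency error.
    Returns the cohort-wide pair list and per-animal pair lists.
    """
    pres: dict[str, dict[str, frozenset]] = {"DQA": {}, "DQB": {}}
    for animal, g in genotypes.items():
        for locus in ("DQA", "DQB"):
            for allele in g.get(locus, ()):  # presence sets
                pres[locus].setdefault(allele, frozenset())
                pres[locus][allele] |= {animal}
    by_sig: dict[frozenset, tuple[list[str], list[str]]] = defaultdict(lambda: ([], []))
    for allele, sig in pres["DQA"].items():
        by_sig[sig][0].append(allele)
    for allele, sig in pres["DQB"].items():
        by_sig[sig][1].append(allele)
    pairs: list[tuple[str | None, str]] = []
    dqa_of: dict[str, str | None] = {}
    for sig, (dqas, dqbs) in sorted(by_sig.items(), key=lambda kv: sorted(kv[0])):
        dqas, dqbs = sorted(dqas), sorted(dqbs)
        if len(dqas) > len(dqbs):
            raise DQPairingError(
                f"more DQA than DQB alleles share an occurrence pattern: {dqas} vs {dqbs}")
        for a, b in zip(dqas, dqbs):
            pairs.append((a, b))
            dqa_of[b] = a
        for b in dqbs[len(dqas):]:
            pairs.append((None, b))
            dqa_of[b] = None
    per_animal = {
        animal: sorted(((dqa_of[b], b) for b in g.get("DQB", ())), key=lambda p: (p[1], p[0] or ""))
        for animal, g in genotypes.items()}
    return sorted(pairs, key=lambda p: (p[1], p[0] or "")), per_animal


# ---------------------------------------------------------------------------
# MHCI primer-set concordance

def primer_concordance(points: Sequence[tuple[float, float]]) -> tuple[float, float] | None:
    """OLS of primer-set-B on primer-set-A normalised allele frequencies
    pooled over a haplotype's carriers; returns (R^2, slope) or ``None``
    when fewer than three points or degenerate variance."""
    if len(points) < 3:
        return None
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return r2, float(slope)


# ---------------------------------------------------------------------------
# 'Variant' MHCI haplotype grouping

def group_variant_haplotypes(entries: Sequence[tuple[str, Sequence[str]]],
                             group_of=None) -> list[list[str]]:
    """Group MHCI haplotypes that express alleles from the same allelic
    groups but differ at the allelic level, or differ by one appended
    allele; only groups of two or more haplotypes are reported."""
    if group_of is None:
        from .diversification import _allele_group as group_of
    names = [name for name, _ in entries]
    allele_sets = [tuple(sorted(a)) for _, a in entries]
    group_sets = [tuple(sorted(group_of(x) for x in a)) for a in allele_sets]
    parent = list(range(len(entries)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(entries)), 2):
        if allele_sets[i] == allele_sets[j]:
            continue
        related = group_sets[i] == group_sets[j]
        if not related:
            small, big = sorted((allele_sets[i], allele_sets[j]), key=len)
            if len(big) == len(small) + 1:
                rem = list(big)
                for x in small:
                    if x in rem:
                        rem.remove(x)
                related = len(rem) == 1
        if related:
            parent[find(i)] = find(j)
    comps: dict[int, list[str]] = defaultdict(list)
    for i in range(len(entries)):
        comps[find(i)].append(names[i])
    return sorted([sorted(v) for v in comps.values() if len(v) >= 2])


# ---------------------------------------------------------------------------
# TSV round-trips

def catalogue_to_tsv(result: CohortResult, path: str | Path) -> None:
    total = sum(e.n_observations for e in result.catalogue)
    with open(path, "w") as fh:
        fh.write("name\talleles\tstatus\tn_animals\tn_observations\tfrequency\n")
        for e in sorted(result.catalogue, key=lambda e: (-e.n_observations, str(e.haplotype))):
            freq = e.n_observations / total if total else 0.0
            fh.write(f"{e.name}\t{e.haplotype}\t{e.status}\t{e.n_animals}"
                     f"\t{e.n_observations}\t{freq:.6g}\n")


def assignments_to_tsv(result: CohortResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("animal\tzygosity\tresolution\thaplotypes\n")
        for a in sorted(result.assignments):
            asg = result.assignments[a]
            haps = " || ".join(str(h) for h in asg.haplotypes)
            fh.write(f"{a}\t{asg.zygosity}\t{asg.resolution}\t{haps}\n")
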