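"""Provisional naming of novel alleles and of MHCI/MHCII haplotypes.

Novel alleles get alphabetic fields (``BoLA-DQA*024:AA``; synonymous
variants ``BoLA-DQA*012:05:AA``) so they cannot collide with official
numeric assignments, and sequences more than four amino acids from every
known allele found a new country-coded allelic group (``BoLA-DQB*zm1:01``).

MHCII haplotypes are named by concatenating a DR token (``BoLA-DRB3*023:01``
-> ``DR23.1``) with one or two DQ-pair tokens: ``DQm.n`` where ``m`` keys a
unique combination of DQA and DQB allelic groups and ``n`` counts distinct
allele-level pairs within it (``DR23.1|DQ30.1``).  MHCI haplotypes are
``HP1.family.variant``, the family keyed by the multiset of allelic groups
expressed and the variant by the allele-level composition.  Haplotypes seen
in a single animal carry an ``un`` (unconfirmed) prefix.

All naming is a pure function of the inputs and a :class:`NameRegistry`;
a registry serialises to JSON and replays to byte-identical names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .alleles import AlleleName, NoveltyResult

_ALPHA = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class RegistryError(RuntimeError):
    pass


def alpha_suffix(index: int) -> str:
    """0 -> AA, 1 -> AB, ... 675 -> ZZ."""
    if not 0 <= index < 676:
        raise RegistryError("provisional suffix space exhausted")
    return _ALPHA[index // 26] + _ALPHA[index % 26]


def normalize_prefix(prefix: str) -> str:
    """Collapse naming dialects: 'BoLA-3' and '3' refer to the same locus."""
    p = prefix.replace("‐", "-")
    if p.startswith("BoLA-"):
        p = p[5:]
    return p


def group_key(name: AlleleName) -> tuple[str, str]:
    return (normalize_prefix(name.prefix), name.group)


def dr_token(name: AlleleName) -> str:
    """Abbreviate a DRB3 allele: numeric fields lose leading zeros, numeric
    synonym fields are dropped, alphabetic (provisional) fields kept."""
    parts = [str(int(name.group)) if name.group.isdigit() else name.group]
    if name.protein_field is not None:
        f = name.protein_field
        parts.append(str(int(f)) if f.isdigit() else f)
    for f in name.synonym_fields:
        if not f.isdigit():
            parts.append(f)
    return "DR" + ".".join(parts)


@dataclass
class NameRegistry:
    """Deterministic issue of provisional allele names and haplotype tokens."""

    # allele naming
    member_suffixes: dict[str, int] = field(default_factory=dict)    # "prefix*group" -> next index
    synonym_suffixes: dict[str, int] = field(default_factory=dict)   # base name -> next index
    country_ordinals: dict[str, int] = field(default_factory=dict)   # "prefix|cc" -> next ordinal
    issued: dict[str, str] = field(default_factory=dict)             # sequence-key -> issued name
    # DQ pair tokens
    dq_pairs: dict[str, str] = field(default_factory=dict)           # "dqa|dqb" -> "DQm.n"
    dq_families: dict[str, int] = field(default_factory=dict)        # "dqa_group|dqb_group" -> m
    dq_variants: dict[str, int] = field(default_factory=dict)        # str(m) -> next n
    # MHCI haplotype names
    hp_compositions: dict[str, str] = field(default_factory=dict)    # composition -> "f.v"
    hp_families: dict[str, str] = field(default_factory=dict)        # group-multiset -> family label
    hp_variants: dict[str, int] = field(default_factory=dict)        # family -> next variant

    # -- persistence ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "NameRegistry":
        text = str(text_or_path)
        if isinstance(text_or_path, Path) or not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        return cls(**json.loads(text))

    # -- novel alleles ----------------------------------------------------
    def name_novel_allele(self, result: NoveltyResult, locus_prefix: str,
                          country_code: str, *, sequence_key: str | None = None) -> AlleleName:
        """Issue a provisional name for a novel allele.

        ``new_member`` -> nearest allele's group with the next alphabetic
        protein field; ``synonymous_variant`` -> the nearest allele's full
        name with the next alphabetic synonym field; ``new_group`` -> the
        next country-coded group ordinal with protein field ``01``.
        A ``sequence_key`` makes re-naming the same sequence idempotent.
        """
        if sequence_key is not None and sequence_key in self.issued:
            return AlleleName.parse(self.issued[sequence_key])
        if result.kind == "exact":
            raise ValueError("exact matches keep their reference name")
        if result.kind == "new_group":
            ck = f"{locus_prefix}|{country_code}"
            ordinal = self.country_ordinals.get(ck, 0) + 1
            self.country_ordinals[ck] = ordinal
            name = AlleleName(locus_prefix, (f"{country_code}{ordinal}", "01"))
        else:
            nearest = AlleleName.parse(result.nearest)
            if result.kind == "new_member":
                gk = f"{locus_prefix}*{nearest.group}"
                idx = self.member_suffixes.get(gk, 0)
                self.member_suffixes[gk] = idx + 1
                name = AlleleName(locus_prefix, (nearest.group, alpha_suffix(idx)))
            else:  # synonymous_variant
                base = str(AlleleName(locus_prefix, nearest.fields))
                idx = self.synonym_suffixes.get(base, 0)
                self.synonym_suffixes[base] = idx + 1
                name = AlleleName(locus_prefix, nearest.fields + (alpha_suffix(idx),))
        if sequence_key is not None:
            self.issued[sequence_key] = str(name)
        return name

    # -- DQ pair tokens ---------------------------------------------------
    def dq_pair_token(self, dqa: AlleleName | None, dqb: AlleleName) -> str:
        """Token for a DQA/DQB pair; ``dqa=None`` marks an orphan pair whose
        DQA partner was not amplified."""
        pk = f"{dqa if dqa else '?'}|{dqb}"
        if pk in self.dq_pairs:
            return self.dq_pairs[pk]
        fk = f"{dqa.group if dqa else '?'}|{dqb.group}"
        if fk in self.dq_families:
            m = self.dq_families[fk]
        else:
            m = max(self.dq_families.values(), default=0) + 1
            self.dq_families[fk] = m
        n = self.dq_variants.get(str(m), 0) + 1
        self.dq_variants[str(m)] = n
        token = f"DQ{m}.{n}"
        self.dq_pairs[pk] = token
        return token

    def prime_dq_pair(self, dqa: AlleleName | None, dqb: AlleleName, token: str) -> None:
        """Register a printed pair->token mapping (fixture priming).

        The exact pair mapping always wins; family numbers and variant
        counters are advanced so fresh pairs continue the printed series.
        """
        pk = f"{dqa if dqa else '?'}|{dqb}"
        self.dq_pairs.setdefault(pk, token)
        m_str, _, n_str = token[2:].partition(".")
        m, n = int(m_str), int(n_str)
        fk = f"{dqa.group if dqa else '?'}|{dqb.group}"
        self.dq_families.setdefault(fk, m)
        self.dq_variants[str(m)] = max(self.dq_variants.get(str(m), 0), n)

    # -- MHCII haplotype names --------------------------------------------
    @staticmethod
    def mhc2_haplotype_name(drb3: AlleleName, dq_tokens: Sequence[str],
                            observed_in: int) -> str:
        if not dq_tokens:
            raise ValueError("an MHCII haplotype needs at least one DQ pair token")
        name = "|".join([dr_token(drb3), *dq_tokens])
        return ("un" if observed_in == 1 else "") + name

    # -- MHCI haplotype names ---------------------------------------------
    @staticmethod
    def _hp_keys(alleles: Iterable[str]) -> tuple[str, str]:
        """(family key, composition key) for an MHCI allele set.

        Ambiguous calls ('a/b') key on their first alternative's group.
        """
        groups, comp = [], []
        for a in sorted(alleles):
            first = AlleleName.parse(a.split("/")[0])
            groups.append("{}*{}".format(*group_key(first)))
            comp.append(a)
        return ";".join(sorted(groups)), ";".join(comp)

    def mhc1_haplotype_name(self, alleles: Iterable[str], observed_in: int) -> str:
        fam_key, comp_key = self._hp_keys(alleles)
        if comp_key in self.hp_compositions:
            fv = self.hp_compositions[comp_key]
        else:
            if fam_key in self.hp_families:
                fam = self.hp_families[fam_key]
            else:
                numeric = [int(f) for f in self.hp_families.values() if f.isdigit()]
                fam = str(max(numeric, default=0) + 1)
                self.hp_families[fam_key] = fam
            v = self.hp_variants.get(fam, 0) + 1
            self.hp_variants[fam] = v
            fv = f"{fam}.{v}"
            self.hp_compositions[comp_key] = fv
        return ("un" if observed_in == 1 else "") + f"HP1.{fv}"

    def prime_mhc1_haplotype(self, alleles: Iterable[str], printed_name: str) -> None:
        fam_key, comp_key = self._hp_keys(alleles)
        base = printed_name[2:] if printed_name.startswith("un") else printed_name
        fam, _, v = base[len("HP1."):].rpartition(".")
        self.hp_compositions.setdefault(comp_key, f"{fam}.{v}")
        self.hp_families.setdefault(fam_key, fam)
        self.hp_variants[fam] = max(self.hp_variants.get(fam, 0), int(v))
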