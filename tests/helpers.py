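"""Shared independent oracles and sequence-editing helpers for the test suite."""


def edit_distance_dp(a: str, b: str) -> int:
    """Unit-cost edit distance by the full dynamic-programming recurrence."""
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def mutate_exon2_codons(nt: str, cfg, n: int, rng) -> str:
    """Substitute n exon-2 codons for codons encoding different residues."""
    from Bio.Seq import Seq
    off = cfg.insert_exon2_offset
    codons = [nt[off + i: off + i + 3] for i in range(0, cfg.exon2_length - 2, 3)]
    pos = rng.choice(len(codons), size=n, replace=False)
    for p in pos:
        aa = str(Seq(codons[p]).translate())
        for cand in ("GCT", "TGT", "GAT", "GAA", "TTT"):
            if str(Seq(cand).translate()) != aa:
                codons[p] = cand
                break
    body = "".join(codons)
    return nt[:off] + body + nt[off + len(body):]
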