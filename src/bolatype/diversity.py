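"""Repertoire overlap and diversity statistics on haplotype profiles.

A :class:`FrequencyProfile` is a population's haplotype observation counts
(two observations per animal, homozygotes counted twice).  On top of it:
Jaccard overlap (presence only), Morisita-Horn overlap (frequency
weighted), D90 (number of most-frequent haplotypes covering 90% of
observations), Shannon entropy (natural log), Simpson diversity
(1 - sum p_i^2) and Hill numbers of order alpha, plus bootstrap
subsampling of equal-sized animal cohorts for cross-population comparison.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass
class FrequencyProfile:
    label: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        self.counts = {k: int(v) for k, v in self.counts.items() if v > 0}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        return len(self.counts)

    def p(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            raise ValueError(f"profile {self.label!r} has no observations")
        return {k: v / t for k, v in self.counts.items()}

    @classmethod
    def from_observations(cls, label: str, observations: Iterable[str]) -> "FrequencyProfile":
        return cls(label, dict(Counter(observations)))


def jaccard(a: FrequencyProfile, b: FrequencyProfile) -> float:
    """|A n B| / |A u B| on haplotype identity; counts are ignored."""
    sa, sb = set(a.counts), set(b.counts)
    if not sa and not sb:
        raise ValueError("Jaccard undefined for two empty profiles")
    return len(sa & sb) / len(sa | sb)


def morisita_horn(a: FrequencyProfile, b: FrequencyProfile) -> float:
    """2 sum(p_i q_i) / (sum p_i^2 + sum q_i^2)."""
    pa, pb = a.p(), b.p()
    cross = sum(pa[k] * pb[k] for k in pa.keys() & pb.keys())
    return 2.0 * cross / (sum(v * v for v in pa.values()) + sum(v * v for v in pb.values()))


def d90(profile: FrequencyProfile, *, coverage: float = 0.90) -> int:
    """Smallest number of most-frequent haplotypes whose cumulative
    frequency reaches the coverage fraction (ties broken by name)."""
    total = profile.total
    if total == 0:
        raise ValueError("empty profile")
    acc = 0
    for k, (_, c) in enumerate(sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0])), 1):
        acc += c
        if acc >= coverage * total - 1e-12:
            return k
    return profile.richness


def shannon(profile: FrequencyProfile) -> float:
    return -sum(p * math.log(p) for p in profile.p().values())


def simpson(profile: FrequencyProfile) -> float:
    return 1.0 - sum(p * p for p in profile.p().values())


def hill_number(profile: FrequencyProfile, alpha: float) -> float:
    """Diversity of order alpha: (sum p_i^alpha)^(1/(1-alpha)); the
    alpha -> 1 limit is exp(Shannon), alpha = 0 is richness."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    ps = list(profile.p().values())
    if abs(alpha - 1.0) < 1e-9:
        return math.exp(shannon(profile))
    return sum(p ** alpha for p in ps) ** (1.0 / (1.0 - alpha))


@dataclass
class DiversityResult:
    shannon: float
    simpson: float
    hill: dict[float, float]
    d90: int
    richness: int


def entropy_suite(profile: FrequencyProfile,
                  alpha_grid: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 4.0)) -> DiversityResult:
    return DiversityResult(
        shannon=shannon(profile),
        simpson=simpson(profile),
        hill={a: hill_number(profile, a) for a in alpha_grid},
        d90=d90(profile),
        richness=profile.richness,
    )


@dataclass
class BootstrapResult:
    label: str
    n_animals: int
    reps: int
    d90_values: list[int]
    mean_curve: np.ndarray
    lo_curve: np.ndarray
    hi_curve: np.ndarray

    @property
    def d90_mean(self) -> float:
        return float(np.mean(self.d90_values))


def bootstrap_compare(assignments: Mapping[str, Mapping[str, Sequence[str]]],
                      *, n_animals: int = 100, reps: int = 100, seed: int = 0,
                      with_replacement: bool = False) -> dict[str, BootstrapResult]:
    """Bootstrap equal-sized subsamples of animals per population.

    ``assignments`` maps population label -> animal id -> that animal's
    haplotype list (one entry per chromosome: homozygotes list their
    haplotype twice).  Each replicate draws ``n_animals`` animals without
    replacement (with replacement if the population is smaller, or on
    request), builds the observation profile and computes the cumulative
    frequency curve and D90.  The mean curve and its min-max envelope are
    reported per population.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, BootstrapResult] = {}
    for label in sorted(assignments):
        animals = sorted(assignments[label])
        if not animals:
            raise ValueError(f"population {label!r} is empty")
        replace = with_replacement or len(animals) < n_animals
        curves, d90s = [], []
        for _ in range(reps):
            chosen = rng.choice(len(animals), size=n_animals, replace=replace)
            obs = [h for i in chosen for h in assignments[label][animals[i]]]
            prof = FrequencyProfile.from_observations(label, obs)
            d90s.append(d90(prof))
            freqs = np.sort(np.array(list(prof.counts.values()), dtype=float))[::-1] / prof.total
            curves.append(np.cumsum(freqs))
        width = max(len(c) for c in curves)
        padded = np.ones((reps, width))
        for i, c in enumerate(curves):
            padded[i, : len(c)] = c
        out[label] = BootstrapResult(label, n_animals, reps, d90s,
                                     padded.mean(axis=0), padded.min(axis=0), padded.max(axis=0))
    return out


def pairwise_matrix(profiles: Sequence[FrequencyProfile], metric: str = "morisita_horn",
                    *, min_animals: int | None = None,
                    animal_counts: Mapping[str, int] | None = None) -> dict[tuple[str, str], float]:
    """Pairwise overlap matrix; populations below ``min_animals`` (given
    ``animal_counts``) are excluded, mirroring small-site exclusion."""
    fn = {"morisita_horn": morisita_horn, "jaccard": jaccard}[metric]
    kept = [p for p in profiles
            if min_animals is None or animal_counts is None
            or animal_counts.get(p.label, 0) >= min_animals]
    out = {}
    for i, a in enumerate(kept):
        for b in kept[i:]:
            val = fn(a, b)
            out[(a.label, b.label)] = val
            out[(b.label, a.label)] = val
    return out
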