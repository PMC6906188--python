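"""Paternity-adjacent statistics and mating-system filtering.

Provides the marker-information summaries used to judge whether a locus
battery can discriminate fathers (probability of identity, paternity
exclusion probability), a compatibility + likelihood-ratio classifier for
selfed seeds, and construction of the three analysis datasets:

* Model A — outcrossed seeds only, one random seed per fruit
  (independent pollination events);
* Model B — one random seed per fruit, selfed seeds retained;
* Model C — all seeds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .gametes import PollenHaplotype
from .genotypes import AllelePair, Dataset, Genotype

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# marker information content


def probability_of_identity(
    freqs_per_locus: dict[str, dict[str, float]]
) -> tuple[dict[str, float], float]:
    """P(ID): probability two random individuals share a multilocus genotype.

    Per locus under HWE: sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2; multilocus
    is the product over loci.  Loci with no frequency data are excluded.
    """
    per_locus: dict[str, float] = {}
    multi = 1.0
    for loc, freqs in freqs_per_locus.items():
        if not freqs:
            logger.warning("P(ID): locus %s has no data, excluded", loc)
            continue
        p = np.asarray(list(freqs.values()))
        hom = np.sum(p**4)
        het = sum(
            (2 * pi * pj) ** 2 for pi, pj in itertools.combinations(p, 2)
        )
        per_locus[loc] = float(hom + het)
        multi *= per_locus[loc]
    return per_locus, multi


def _exclusion_single_locus(freqs: dict[str, float]) -> float:
    """Second-parent exclusion probability at one locus.

    With the mother's genotype known and mother, true father, offspring
    drawn under HWE + Mendelian segregation, this is the probability that
    a random unrelated individual carries no allele compatible with the
    offspring's possible paternal alleles.  Enumerates mother genotypes
    and transmitted/paternal alleles; the random candidate is collapsed
    analytically: P(no allele of set T) = (1 - sum_{a in T} p_a)^2.
    """
    alleles = list(freqs)
    p = freqs
    pe = 0.0
    for m1, m2 in itertools.combinations_with_replacement(alleles, 2):
        p_m = p[m1] ** 2 if m1 == m2 else 2 * p[m1] * p[m2]
        if p_m == 0:
            continue
        for maternal, w_mat in ((m1, 0.5), (m2, 0.5)) if m1 != m2 else ((m1, 1.0),):
            for c in alleles:
                if p[c] == 0:
                    continue
                o1, o2 = maternal, c
                if o1 == o2:
                    possible = {o1} if o1 in (m1, m2) else set()
                else:
                    possible = set()
                    if o2 in (m1, m2):
                        possible.add(o1)
                    if o1 in (m1, m2):
                        possible.add(o2)
                p_t = sum(p[a] for a in possible)
                pe += p_m * w_mat * p[c] * (1.0 - p_t) ** 2
    return pe


def exclusion_probability(
    freqs_per_locus: dict[str, dict[str, float]]
) -> tuple[dict[str, float], float]:
    """Paternity exclusion probability per locus and combined over loci.

    Multilocus: P_E = 1 - prod_l (1 - P_E,l) (excluded if excludable at
    any locus).  Loci with no data are excluded with a warning.
    """
    per_locus: dict[str, float] = {}
    prod_keep = 1.0
    for loc, freqs in freqs_per_locus.items():
        if not freqs:
            logger.warning("P_E: locus %s has no data, excluded", loc)
            continue
        per_locus[loc] = _exclusion_single_locus(freqs)
        prod_keep *= 1.0 - per_locus[loc]
    return per_locus, 1.0 - prod_keep


# ---------------------------------------------------------------------------
# selfing classification


@dataclass
class SelfingCall:
    key: tuple[str, str, str, str]
    call: str  # "selfed" | "outcrossed" | "ambiguous"
    compatible: bool
    likelihood_ratio: float  # L(self) / L(outcross), inf when L_out = 0
    posterior: float  # P(selfed | genotypes, prior)
    n_informative_loci: int


def _p_offspring_given_selfing(mother: AllelePair, seed: AllelePair) -> float:
    """P(seed genotype | both gametes from the mother)."""
    gametes = {}
    for a in mother:
        gametes[a] = gametes.get(a, 0.0) + 0.5
    a, b = seed
    if a == b:
        return gametes.get(a, 0.0) ** 2
    return 2.0 * gametes.get(a, 0.0) * gametes.get(b, 0.0)


def _p_offspring_given_outcross(
    mother: AllelePair, seed: AllelePair, pollen: dict[str, float]
) -> float:
    """P(seed genotype | maternal gamete x random pollen-pool gamete)."""
    gametes = {}
    for a in mother:
        gametes[a] = gametes.get(a, 0.0) + 0.5
    prob = 0.0
    a, b = seed
    pairs = [(a, b)] if a == b else [(a, b), (b, a)]
    for mat, pat in pairs:
        prob += gametes.get(mat, 0.0) * pollen.get(pat, 0.0)
    return prob


def classify_selfing(
    mother: Genotype,
    seed: Genotype,
    pollen_freqs: dict[str, dict[str, float]],
    key: tuple[str, str, str, str] = ("", "", "", ""),
    prior_selfing: float = 0.1,
    threshold: float = 0.90,
) -> SelfingCall:
    """Classify one seed as selfed / outcrossed / ambiguous.

    A seed is *compatible* with selfing when, at every locus where both
    genotypes are non-missing, its genotype can be formed from two
    maternal gametes.  Incompatible seeds are called outcrossed outright.
    Compatible seeds get a posterior from the multilocus likelihood ratio
    of selfing vs outcrossing (pollen-pool frequencies), under the given
    prior selfing rate; calls use the posterior threshold symmetrically.
    """
    if not 0.0 <= prior_selfing <= 1.0:
        raise ValueError("prior_selfing must be in [0, 1]")
    log_lr = 0.0
    l_self = 1.0
    l_out = 1.0
    n_informative = 0
    compatible = True
    for loc, mp in mother.items():
        sp = seed.get(loc)
        if mp is None or sp is None:
            continue
        n_informative += 1
        ps = _p_offspring_given_selfing(mp, sp)
        po = _p_offspring_given_outcross(mp, sp, pollen_freqs.get(loc, {}))
        if ps == 0.0:
            compatible = False
        l_self *= ps
        l_out *= po
    if n_informative == 0:
        return SelfingCall(key, "ambiguous", True, 1.0, prior_selfing, 0)
    if not compatible:
        return SelfingCall(key, "outcrossed", False, 0.0, 0.0, n_informative)
    if l_self == 0.0 and l_out == 0.0:
        return SelfingCall(key, "ambiguous", True, float("nan"), prior_selfing, n_informative)
    lr = float("inf") if l_out == 0.0 else l_self / l_out
    num = prior_selfing * l_self
    den = num + (1.0 - prior_selfing) * l_out
    posterior = 1.0 if den == 0.0 else num / den
    if posterior >= threshold:
        call = "selfed"
    elif posterior <= 1.0 - threshold:
        call = "outcrossed"
    else:
        call = "ambiguous"
    return SelfingCall(key, call, True, lr, posterior, n_informative)


def classify_dataset_selfing(
    ds: Dataset,
    pollen_freqs: dict[str, dict[str, float]],
    prior_selfing: float = 0.1,
    threshold: float = 0.90,
) -> list[SelfingCall]:
    return [
        classify_selfing(
            ds.mothers[(s.site_id, s.mother_id)], s.genotype, pollen_freqs,
            key=s.key, prior_selfing=prior_selfing, threshold=threshold,
        )
        for s in ds.seeds
    ]


# ---------------------------------------------------------------------------
# Model A / B / C construction


@dataclass(frozen=True)
class ModelSpec:
    """Which seeds enter the AMOVA: A, B, or C (see module docstring)."""

    model: str  # "A" | "B" | "C"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("A", "B", "C"):
            raise ValueError(f"model must be A, B or C, got {self.model!r}")


def build_model_dataset(
    ds: Dataset,
    haplotypes: Sequence[PollenHaplotype],
    selfing_calls: Optional[Sequence[SelfingCall]],
    spec: ModelSpec,
) -> list[PollenHaplotype]:
    """Filter pollen haplotypes according to a model specification.

    Model C passes everything; B keeps one random seed per fruit; A drops
    selfed seeds first, then keeps one random seed per fruit (fruits left
    empty are dropped).  Sampling uses the spec's RNG seed and is
    reproducible.
    """
    if spec.model == "C":
        return list(haplotypes)
    if not ds.has_fruit_ids():
        raise ValueError(f"Model {spec.model} requires fruit identifiers")
    rng = np.random.default_rng(spec.seed)
    pool = list(haplotypes)
    if spec.model == "A":
        if selfing_calls is None:
            raise ValueError("Model A requires selfing calls")
        selfed = {c.key for c in selfing_calls if c.call == "selfed"}
        pool = [h for h in pool if h.key not in selfed]
    by_fruit: dict[tuple[str, str, str], list[PollenHaplotype]] = {}
    for h in pool:
        by_fruit.setdefault((h.site_id, h.mother_id, h.fruit_id), []).append(h)
    chosen: list[PollenHaplotype] = []
    # deterministic fruit order -> reproducible selection
    for fruit_key in sorted(by_fruit):
        members = by_fruit[fruit_key]
        chosen.append(members[rng.integers(len(members))])
    n_dropped = len({(h.site_id, h.mother_id, h.fruit_id) for h in haplotypes}) - len(by_fruit)
    if n_dropped:
        logger.info("Model %s: %d fruit(s) left no eligible seed", spec.model, n_dropped)
    return chosen


def estimated_selfing_fraction(calls: Sequence[SelfingCall]) -> float:
    """Fraction of seeds called selfed (ambiguous counts as not selfed)."""
    if not calls:
        return float("nan")
    return sum(c.call == "selfed" for c in calls) / len(calls)
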