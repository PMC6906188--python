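"""Infer the haploid paternal gamete of each seed by subtracting the mother.

At each locus the paternal contribution is forced (seed homozygous, or
exactly one seed allele absent from the mother), ambiguous (mother and
seed share the same heterozygous genotype), impossible (no seed allele in
the mother), or unavailable (missing data).  Ambiguous loci are resolved
with the posterior over the two maternal-transmission hypotheses weighted
by allele frequencies in the overall pollen pool: with seed = mother =
(a, b), P(paternal = a) = p_a / (p_a + p_b).

``infer_pollen_pool`` runs two passes: pollen frequencies are first
estimated from unambiguous assignments only, then used to resolve the
ambiguous loci (hard assignment, MAP or posterior sampling).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .genotypes import AllelePair, Dataset, allele_frequencies

UNAMBIGUOUS = "unambiguous"
RESOLVED = "resolved"
MISMATCH = "mismatch"
MISSING = "missing"


@dataclass
class PollenHaplotype:
    """Inferred haploid paternal multilocus gamete of one seed."""

    site_id: str
    mother_id: str
    fruit_id: str
    seed_id: str
    alleles: dict[str, Optional[str]]
    status: dict[str, str]
    #: posterior weight of the chosen allele, resolved loci only (in [0.5, 1])
    weight: dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.site_id, self.mother_id, self.fruit_id, self.seed_id)


@dataclass
class InferenceReport:
    policy: str
    status_counts: dict[str, dict[str, int]]  # locus -> status -> count
    uniform_fallback_loci: list[str]          # loci with no unambiguous assignment
    zero_frequency_flags: list[tuple[tuple[str, str, str, str], str]]

    def total(self, status: str) -> int:
        return sum(c.get(status, 0) for c in self.status_counts.values())


def infer_locus_gamete(
    mother: Optional[AllelePair],
    seed: Optional[AllelePair],
    pollen_freqs: Optional[dict[str, float]],
    policy: str = "map",
    rng: Optional[np.random.Generator] = None,
) -> tuple[Optional[str], str, Optional[float]]:
    """Single-locus paternal allele, its status, and the posterior weight.

    ``pollen_freqs=None`` defers ambiguous resolution (first pass): the
    status is still ``resolved`` but the allele is None.  Zero combined
    pollen frequency for an ambiguous pair resolves uniformly (weight 0.5).
    """
    if mother is None or seed is None:
        return None, MISSING, None
    mset = set(mother)
    a, b = seed
    in_mother = [x in mset for x in (a, b)]
    if not any(in_mother):
        return None, MISMATCH, None
    if a == b:
        return a, UNAMBIGUOUS, None
    if in_mother[0] != in_mother[1]:
        return (b if in_mother[0] else a), UNAMBIGUOUS, None
    # both seed alleles carried by a heterozygous mother (a, b)
    if pollen_freqs is None:
        return None, RESOLVED, None
    pa = pollen_freqs.get(a, 0.0)
    pb = pollen_freqs.get(b, 0.0)
    post_a = 0.5 if pa + pb == 0 else pa / (pa + pb)
    if policy == "map":
        if post_a > 0.5:
            return a, RESOLVED, post_a
        if post_a < 0.5:
            return b, RESOLVED, 1.0 - post_a
        return min(a, b), RESOLVED, 0.5  # deterministic tie-break
    if policy == "sample":
        if rng is None:
            raise ValueError("policy 'sample' requires an rng")
        if rng.random() < post_a:
            return a, RESOLVED, post_a
        return b, RESOLVED, 1.0 - post_a
    raise ValueError(f"unknown policy {policy!r}")


def infer_pollen_pool(
    ds: Dataset,
    policy: str = "sample",
    rng: Optional[Union[int, np.random.Generator]] = None,
    reference: str = "site",
    refine_passes: int = 0,
) -> tuple[list[PollenHaplotype], InferenceReport]:
    """Infer one pollen haplotype per seed (two-pass procedure).

    Pass 1 collects unambiguous paternal alleles and estimates per-locus
    pollen-pool frequencies; pass 2 resolves the ambiguous loci against
    those frequencies.  ``refine_passes`` adds optional EM-style
    re-estimation rounds using all assigned alleles.

    ``reference`` selects the frequency pool used for resolution:
    ``"site"`` (default) estimates pollen frequencies per site, falling
    back to the overall pool at site/locus combinations without
    unambiguous data; ``"overall"`` pools the whole dataset.  The site
    reference matters for downstream testing: when pollen pools differ
    among sites, resolving against overall frequencies biases ambiguous
    assignments in a mother-genotype-dependent direction and measurably
    inflates the type-I error of the within-site permutation test; the
    site-level reference restores within-site exchangeability.

    The default resolution policy draws the ambiguous allele from its
    posterior (bit-reproducible given the rng seed).  Deterministic MAP
    assignment is available but gives every ambiguous seed of a
    heterozygous mother the same allele, which badly inflates the
    type-I error of the within-site permutation test.  Use "map" for
    single-seed lookups, not for differentiation testing.
    """
    if reference not in ("site", "overall"):
        raise ValueError(f"unknown reference {reference!r}")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    locus_names = ds.locus_names
    # pass 1: forced assignments only, tallied overall and per site
    unambiguous: dict[str, list[str]] = {loc: [] for loc in locus_names}
    unambiguous_by_site: dict[str, dict[str, list[str]]] = {
        site: {loc: [] for loc in locus_names} for site in ds.sites()
    }
    for s in ds.seeds:
        mother = ds.mothers[(s.site_id, s.mother_id)]
        for loc in locus_names:
            allele, status, _ = infer_locus_gamete(
                mother.get(loc), s.genotype.get(loc), None
            )
            if status == UNAMBIGUOUS:
                unambiguous[loc].append(allele)
                unambiguous_by_site[s.site_id][loc].append(allele)

    uniform_fallback: list[str] = []
    locus_alleles = {l.name: l.alleles for l in ds.loci}
    overall: dict[str, dict[str, float]] = {}
    for loc in locus_names:
        f = allele_frequencies(unambiguous[loc])
        if not f:
            alleles = locus_alleles[loc]
            f = {a: 1.0 / len(alleles) for a in alleles}
            uniform_fallback.append(loc)
        overall[loc] = f

    def site_freqs(seed_record) -> dict[str, dict[str, float]]:
        if reference == "overall":
            return overall
        by_site = unambiguous_by_site[seed_record.site_id]
        return {
            loc: (allele_frequencies(by_site[loc]) or overall[loc])
            for loc in locus_names
        }

    def run_pass(freq_for_seed):
        haplotypes: list[PollenHaplotype] = []
        counts: dict[str, collections.Counter] = {
            loc: collections.Counter() for loc in locus_names
        }
        zero_flags: list[tuple[tuple[str, str, str, str], str]] = []
        freq_cache: dict[str, dict[str, dict[str, float]]] = {}
        for s in ds.seeds:
            mother = ds.mothers[(s.site_id, s.mother_id)]
            current_freqs = freq_cache.setdefault(s.site_id, freq_for_seed(s))
            alleles: dict[str, Optional[str]] = {}
            status: dict[str, str] = {}
            weight: dict[str, float] = {}
            for loc in locus_names:
                al, st, w = infer_locus_gamete(
                    mother.get(loc), s.genotype.get(loc), current_freqs[loc],
                    policy=policy, rng=rng,
                )
                if st == MISMATCH:
                    al = None  # tolerant policy: record as missing, keep the seed
                alleles[loc] = al
                status[loc] = st
                if st == RESOLVED:
                    weight[loc] = w
                    if w == 0.5 and loc not in uniform_fallback:
                        sp = s.genotype.get(loc)
                        if sp and current_freqs[loc].get(sp[0], 0.0) + current_freqs[loc].get(sp[1], 0.0) == 0:
                            zero_flags.append((s.key, loc))
                counts[loc][st] += 1
            haplotypes.append(
                PollenHaplotype(s.site_id, s.mother_id, s.fruit_id, s.seed_id,
                                alleles, status, weight)
            )
        return haplotypes, counts, zero_flags

    haplotypes, counts, zero_flags = run_pass(site_freqs)
    for _ in range(refine_passes):
        by_site_assigned: dict[str, list[PollenHaplotype]] = {}
        for h in haplotypes:
            by_site_assigned.setdefault(h.site_id, []).append(h)
        refined_overall = {
            loc: allele_frequencies(h.alleles[loc] for h in haplotypes) or overall[loc]
            for loc in locus_names
        }

        def refined(seed_record, _overall=refined_overall):
            if reference == "overall":
                return _overall
            hs = by_site_assigned.get(seed_record.site_id, [])
            return {
                loc: (allele_frequencies(h.alleles[loc] for h in hs) or _overall[loc])
                for loc in locus_names
            }

        haplotypes, counts, zero_flags = run_pass(refined)

    report = InferenceReport(
        policy=policy,
        status_counts={loc: dict(counts[loc]) for loc in locus_names},
        uniform_fallback_loci=uniform_fallback,
        zero_frequency_flags=zero_flags,
    )
    return haplotypes, report


def pollen_pool_frequencies(
    haplotypes: list[PollenHaplotype], locus_names: list[str]
) -> dict[str, dict[str, float]]:
    """Per-locus allele frequencies of an inferred pollen pool."""
    return {
        loc: allele_frequencies(h.alleles.get(loc) for h in haplotypes)
        for loc in locus_names
    }


def haplotypes_to_frame(
    haplotypes: list[PollenHaplotype], locus_names: list[str]
) -> pd.DataFrame:
    """One row per seed: ids, per-locus paternal allele, per-locus status."""
    rows = []
    for h in haplotypes:
        row: dict[str, object] = {
            "site": h.site_id, "mother": h.mother_id,
            "fruit": h.fruit_id, "seed": h.seed_id,
        }
        for loc in locus_names:
            row[loc] = h.alleles.get(loc) if h.alleles.get(loc) is not None else ""
            row[f"{loc}.status"] = h.status.get(loc, MISSING)
        rows.append(row)
    return pd.DataFrame(rows)


def write_haplotype_table(
    haplotypes: list[PollenHaplotype], locus_names: list[str], path: Union[str, Path]
) -> None:
    haplotypes_to_frame(haplotypes, locus_names).to_csv(path, index=False)
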