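"""Generate mother/seed genotype datasets with hierarchical pollen structure.

The generator follows a hierarchical Dirichlet (Balding-Nichols style)
construction: per locus, global allele frequencies are drawn from a
symmetric Dirichlet; each site's pollen pool is a Dirichlet perturbation
of the global pool with fixation parameter F_CT; each mother's pollen
pool perturbs her site's pool with parameter F_SC (concentration
parent * (1-F)/F, so the expected fixation index of subpools relative to
their parent is F).  Mother genotypes are drawn in Hardy-Weinberg
proportions from site-level frequencies, which yields mild adult
structure without a separate parameter.  Seeds combine one maternal
gamete with a paternal gamete from the mother's pollen pool; whole
fruits may share a single paternal draw (correlated paternity) and each
seed may instead be selfed (paternal gamete re-drawn from the mother).

The per-seed truth (pools, paternal gametes, selfing flags) is returned
alongside the dataset so inference can be validated exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genotypes import Dataset, Genotype, LocusDef, SeedRecord

DIVERSITY_ALLELE_RANGE = {"high": (10, 17), "low": (4, 6)}


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one simulated sampling design.

    Defaults mirror the sampling scheme the simulation harness targets:
    18 sites x 4 mothers x 5 fruits x 2 seeds (720 seeds) typed at 11
    microsatellite loci.
    """

    n_sites: int = 18
    mothers_per_site: int = 4
    fruits_per_mother: int = 5
    seeds_per_fruit: int = 2
    n_loci: int = 11
    alleles_per_locus: Optional[int] = None  # None: drawn from diversity range
    diversity: str = "high"
    f_ct: float = 0.0
    f_sc: float = 0.0
    selfing_rate: float = 0.0
    fruit_paternity_correlation: float = 0.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        for f in ("n_sites", "mothers_per_site", "fruits_per_mother",
                  "seeds_per_fruit", "n_loci"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        for f in ("f_ct", "f_sc"):
            v = getattr(self, f)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{f} must be in [0, 1)")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")
        if not 0.0 <= self.fruit_paternity_correlation <= 1.0:
            raise ValueError("fruit_paternity_correlation must be in [0, 1]")
        if self.diversity not in DIVERSITY_ALLELE_RANGE:
            raise ValueError(f"diversity must be one of {list(DIVERSITY_ALLELE_RANGE)}")

    @property
    def n_seeds(self) -> int:
        return (self.n_sites * self.mothers_per_site
                * self.fruits_per_mother * self.seeds_per_fruit)


@dataclass
class SimulationTruth:
    """Ground truth retained from a simulation run."""

    global_freqs: dict[str, dict[str, float]]
    site_pools: dict[str, dict[str, dict[str, float]]]          # site -> locus -> freqs
    mother_pools: dict[tuple[str, str], dict[str, dict[str, float]]]
    paternal_gametes: dict[tuple[str, str, str, str], dict[str, str]]
    selfing_flags: dict[tuple[str, str, str, str], bool] = field(default_factory=dict)
    shared_fruit_flags: dict[tuple[str, str, str], bool] = field(default_factory=dict)


def draw_subpool(
    parent_freqs: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet subpool around ``parent_freqs`` with fixation parameter F.

    Concentration is parent * (1-F)/F (total (1-F)/F regardless of allele
    count), giving E[subpool] = parent and an expected Wright fixation
    index of F across many subpools.  F = 0 returns the parent unchanged.
    """
    parent = np.asarray(parent_freqs, dtype=float)
    if not 0.0 <= F < 1.0:
        raise ValueError("F must be in [0, 1)")
    if F == 0.0:
        return parent.copy()
    alpha = parent * (1.0 - F) / F
    draws = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-300)), 0.0)
    total = draws.sum()
    if total == 0.0:  # numerically degenerate parent: fall back to parent
        return parent.copy()
    return draws / total


def _draw_gamete(freqs: np.ndarray, labels: list[str], rng: np.random.Generator) -> str:
    return labels[rng.choice(len(labels), p=freqs)]


def simulate_dataset(sc: SimulationScenario) -> tuple[Dataset, SimulationTruth]:
    """Generate a (Dataset, truth) pair under the scenario.

    All randomness derives from the scenario seed through spawned
    sub-streams (frequencies, mother genotypes, mating), so components
    can be re-drawn independently without disturbing each other.
    """
    ss = np.random.SeedSequence(sc.seed)
    rng_freq, rng_geno, rng_mating = (np.random.default_rng(c) for c in ss.spawn(3))

    lo, hi = DIVERSITY_ALLELE_RANGE[sc.diversity]
    locus_names = [f"L{i + 1:02d}" for i in range(sc.n_loci)]
    site_ids = [f"S{i + 1:02d}" for i in range(sc.n_sites)]

    labels: dict[str, list[str]] = {}
    global_freqs: dict[str, np.ndarray] = {}
    for loc in locus_names:
        k = sc.alleles_per_locus or int(rng_freq.integers(lo, hi + 1))
        # labels mimic microsatellite fragment sizes (opaque strings)
        labels[loc] = [str(100 + 2 * i) for i in range(k)]
        global_freqs[loc] = rng_freq.dirichlet(np.ones(k))

    site_pools: dict[str, dict[str, np.ndarray]] = {}
    for site in site_ids:
        site_pools[site] = {
            loc: draw_subpool(global_freqs[loc], sc.f_ct, rng_freq)
            for loc in locus_names
        }

    mothers: dict[tuple[str, str], Genotype] = {}
    mother_pools: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    seeds: list[SeedRecord] = []
    truth = SimulationTruth(
        global_freqs={
            loc: dict(zip(labels[loc], map(float, global_freqs[loc])))
            for loc in locus_names
        },
        site_pools={
            site: {loc: dict(zip(labels[loc], map(float, p)))
                   for loc, p in pools.items()}
            for site, pools in site_pools.items()
        },
        mother_pools={},
        paternal_gametes={},
    )

    for site in site_ids:
        for m in range(sc.mothers_per_site):
            mother_id = f"M{m + 1:02d}"
            key = (site, mother_id)
            geno: Genotype = {}
            for loc in locus_names:
                p = site_pools[site][loc]
                pair = (
                    _draw_gamete(p, labels[loc], rng_geno),
                    _draw_gamete(p, labels[loc], rng_geno),
                )
                geno[loc] = tuple(sorted(pair))
            mothers[key] = geno
            mother_pools[key] = {
                loc: draw_subpool(site_pools[site][loc], sc.f_sc, rng_freq)
                for loc in locus_names
            }
            truth.mother_pools[key] = {
                loc: dict(zip(labels[loc], map(float, mother_pools[key][loc])))
                for loc in locus_names
            }

            for f in range(sc.fruits_per_mother):
                fruit_id = f"F{f + 1:02d}"
                shared = rng_mating.random() < sc.fruit_paternity_correlation
                truth.shared_fruit_flags[(site, mother_id, fruit_id)] = shared
                fruit_gamete: Optional[dict[str, str]] = None
                if shared:
                    fruit_gamete = {
                        loc: _draw_gamete(mother_pools[key][loc], labels[loc], rng_mating)
                        for loc in locus_names
                    }
                for s in range(sc.seeds_per_fruit):
                    seed_id = f"X{s + 1:02d}"
                    skey = (site, mother_id, fruit_id, seed_id)
                    selfed = rng_mating.random() < sc.selfing_rate
                    if selfed:
                        paternal = {
                            loc: geno[loc][rng_mating.integers(2)]
                            for loc in locus_names
                        }
                    elif shared:
                        paternal = dict(fruit_gamete)
                    else:
                        paternal = {
                            loc: _draw_gamete(mother_pools[key][loc], labels[loc], rng_mating)
                            for loc in locus_names
                        }
                    seed_geno: Genotype = {}
                    for loc in locus_names:
                        maternal = geno[loc][rng_mating.integers(2)]
                        seed_geno[loc] = tuple(sorted((maternal, paternal[loc])))
                    truth.paternal_gametes[skey] = paternal
                    truth.selfing_flags[skey] = selfed
                    seeds.append(SeedRecord(site, mother_id, fruit_id, seed_id, seed_geno))

    loci = [LocusDef(loc, tuple(labels[loc])) for loc in locus_names]
    return Dataset(loci=loci, mothers=mothers, seeds=seeds), truth


# ---------------------------------------------------------------------------
# presets

_CT_LEVELS = {"ct0": 0.0, "ctlow": 0.01, "cthigh": 0.05}
_SC_LEVELS = {"sc0": 0.0, "sclow": 0.01, "schigh": 0.08}


def scenario_presets(base_seed: int = 1000) -> dict[str, SimulationScenario]:
    """Factorial grid: {high, low diversity} x F_CT {0, .01, .05} x F_SC {0, .01, .08}.

    18 named, deterministically seeded scenarios in the study's sampling
    shape.  The differentiation levels bracket the empirically observed
    Phi range (~0.03-0.09) and are overridable via dataclasses.replace.
    """
    presets: dict[str, SimulationScenario] = {}
    i = 0
    for div in ("high", "low"):
        for ct_name, f_ct in _CT_LEVELS.items():
            for sc_name, f_sc in _SC_LEVELS.items():
                name = f"{div}-{ct_name}-{sc_name}"
                presets[name] = SimulationScenario(
                    diversity=div, f_ct=f_ct, f_sc=f_sc,
                    seed=base_seed + i, name=name,
                )
                i += 1
    return presets


def study_scenario(seed: int = 2024) -> SimulationScenario:
    """A scenario emulating the empirical study's stated conditions.

    ~10% selfing, within-fruit correlated paternity, and hierarchical
    differentiation in the observed range (F_SC ~ 0.08, F_CT ~ 0.03).
    """
    return SimulationScenario(
        f_ct=0.03, f_sc=0.08, selfing_rate=0.10,
        fruit_paternity_correlation=0.5, seed=seed, name="study-like",
    )


def replace(sc: SimulationScenario, **kwargs) -> SimulationScenario:
    """Return a copy of the scenario with fields replaced."""
    return dataclasses.replace(sc, **kwargs)
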