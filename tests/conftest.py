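import numpy as np
import pytest

import pollenflow as pf


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset with hierarchical structure and its truth."""
    sc = pf.SimulationScenario(
        n_sites=6, mothers_per_site=3, fruits_per_mother=3, seeds_per_fruit=2,
        n_loci=6, f_ct=0.05, f_sc=0.08, seed=101,
    )
    ds, truth = pf.simulate_dataset(sc)
    return ds, truth


@pytest.fixture(scope="session")
def study_shaped_dataset():
    """Null-structured dataset in the study's sampling shape (720 seeds)."""
    sc = pf.SimulationScenario(seed=2023)
    ds, truth = pf.simulate_dataset(sc)
    return ds, truth


@pytest.fixture(scope="session")
def toy_haplotypes():
    """2 sites x 2 mothers x 2 gametes at one locus; mothers fixed for
    alternative alleles.  Hand-computed AMOVA: SSD (0, 2, 0), components
    (-0.25, 0.5, 0), Phi_SC = 1, Phi_CT = -1."""
    haps = []
    for s in ("s1", "s2"):
        for m, allele in (("m1", "1"), ("m2", "2")):
            for i in range(2):
                haps.append(
                    pf.PollenHaplotype(s, m, "f1", f"x{i}", {"L": allele},
                                       {"L": "unambiguous"})
                )
    return haps


def make_haplotypes(codes, sites, mothers, n_loci):
    """Build PollenHaplotype objects from integer allele codes."""
    haps = []
    for i, row in enumerate(np.atleast_2d(codes)):
        alleles = {f"L{j}": (str(row[j]) if row[j] >= 0 else None)
                   for j in range(n_loci)}
        status = {f"L{j}": ("unambiguous" if row[j] >= 0 else "missing")
                  for j in range(n_loci)}
        haps.append(pf.PollenHaplotype(str(sites[i]), str(mothers[i]), "f", str(i),
                                       alleles, status))
    return haps
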