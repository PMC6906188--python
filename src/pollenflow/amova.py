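"""Two-level nested AMOVA on pollen haplotypes.

Haplotypes are grouped as gametes within mothers (subpopulations) within
sites (groups).  Squared inter-gamete distance is the count of loci at
which two haplotypes carry different alleles; loci missing in either
member contribute zero.  The total sum of squared deviations is
partitioned into among-site, among-mother-within-site, and within-mother
components via the standard pairwise-distance identities

    SSD_total          = (1/N)   * sum_{i<j} d2_ij
    SSD_within_mothers = sum_k (1/n_k) * sum_{i<j in mother k} d2_ij
    T_g                = (1/N_g) * sum_{i<j in site g} d2_ij
    SSD_among_mothers  = sum_g T_g - SSD_within_mothers
    SSD_among_sites    = SSD_total - sum_g T_g

Variance components for the unbalanced design use the method-of-moments
coefficients

    n'   = (N - sum_g sum_{k in g} n_k^2 / N_g) / (S - G)
    n''  = (sum_g sum_{k in g} n_k^2 / N_g - sum_k n_k^2 / N) / (G - 1)
    n''' = (N - sum_g N_g^2 / N) / (G - 1)

with sigma2_c = SSD_w/(N-S), sigma2_b = (MSD_b - sigma2_c)/n', and
sigma2_a = (MSD_a - sigma2_c - n''*sigma2_b)/n'''.  Phi-statistics:
Phi_CT = s_a/total, Phi_SC = s_b/(s_b + s_c), Phi_ST = (s_a + s_b)/total.
Small negative components and Phi values are reported as-is, never
truncated: they are the expected behaviour in the absence of
differentiation.

Significance is assessed by stratified permutation: Phi_SC by permuting
seeds among mothers within the same site, Phi_CT by permuting whole
mothers (with their seeds) among sites.  p = (#{perm >= obs} + 1)/(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .gametes import PollenHaplotype


@dataclass
class AmovaResult:
    ssd_among_sites: float
    ssd_among_mothers: float
    ssd_within_mothers: float
    ssd_total: float
    df_among_sites: int
    df_among_mothers: int
    df_within_mothers: int
    msd_among_sites: float
    msd_among_mothers: float
    msd_within_mothers: float
    n_prime: float
    n_double_prime: float
    n_triple_prime: float
    sigma2_a: float
    sigma2_b: float
    sigma2_c: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    negative_component: bool = False
    zero_total_variance: bool = False
    p_ct: Optional[float] = None
    p_sc: Optional[float] = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class DegenerateDesignError(ValueError):
    """Raised when a stratum has no degrees of freedom or coefficient <= 0."""


# ---------------------------------------------------------------------------
# distances


def encode_haplotypes(
    haplotypes: Sequence[PollenHaplotype], locus_names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer-code haplotypes: (codes[N, L] with -1 = missing, sites, mothers).

    Mother labels are globally unique (site-qualified) so that nesting is
    unambiguous.
    """
    allele_index: dict[str, dict[str, int]] = {loc: {} for loc in locus_names}
    codes = np.full((len(haplotypes), len(locus_names)), -1, dtype=np.int64)
    for i, h in enumerate(haplotypes):
        for j, loc in enumerate(locus_names):
            a = h.alleles.get(loc)
            if a is None:
                continue
            idx = allele_index[loc].setdefault(a, len(allele_index[loc]))
            codes[i, j] = idx
    sites = np.asarray([h.site_id for h in haplotypes], dtype=object)
    mothers = np.asarray(
        [f"{h.site_id}::{h.mother_id}" for h in haplotypes], dtype=object
    )
    return codes, sites, mothers


def amova_distance(
    h1: PollenHaplotype,
    h2: PollenHaplotype,
    locus_names: Sequence[str],
    rescale_missing: bool = False,
) -> float:
    """Squared distance between two haplotypes (count of differing loci).

    Loci missing in either haplotype contribute 0; with
    ``rescale_missing`` the count is rescaled by L / shared loci.
    Returns NaN when no locus is shared.
    """
    diff = 0
    shared = 0
    for loc in locus_names:
        a, b = h1.alleles.get(loc), h2.alleles.get(loc)
        if a is None or b is None:
            continue
        shared += 1
        if a != b:
            diff += 1
    if shared == 0:
        return float("nan")
    if rescale_missing:
        return diff * len(locus_names) / shared
    return float(diff)


def distance_matrix(codes: np.ndarray, rescale_missing: bool = False) -> np.ndarray:
    """Pairwise squared-distance matrix from integer-coded haplotypes."""
    valid = codes >= 0
    n, L = codes.shape
    D = np.zeros((n, n))
    shared = np.zeros((n, n))
    for j in range(L):  # per-locus accumulation keeps memory at O(N^2)
        c = codes[:, j]
        v = valid[:, j]
        both = np.logical_and.outer(v, v)
        D += np.not_equal.outer(c, c) & both
        shared += both
    if rescale_missing:
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(shared > 0, D * L / shared, np.nan)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# SSD partition and components


def _check_nesting(sites: np.ndarray, mothers: np.ndarray) -> None:
    seen: dict = {}
    for s, m in zip(sites, mothers):
        if m in seen and seen[m] != s:
            raise ValueError(f"mother {m!r} appears in sites {seen[m]!r} and {s!r}")
        seen[m] = s


def ssd_partition(
    D: np.ndarray, sites: Sequence, mothers: Sequence
) -> dict[str, float]:
    """Partition total SSD into among-site / among-mother / within-mother."""
    sites = np.asarray(sites, dtype=object)
    mothers = np.asarray(mothers, dtype=object)
    _check_nesting(sites, mothers)
    N = len(sites)
    if D.shape != (N, N):
        raise ValueError("distance matrix / label length mismatch")
    site_ids = pd_unique(sites)
    mother_ids = pd_unique(mothers)
    G, S = len(site_ids), len(mother_ids)
    if G < 2:
        raise DegenerateDesignError("need at least 2 sites for the among-site stratum")
    if S <= G:
        raise DegenerateDesignError("need more mothers than sites")

    ssd_total = D.sum() / (2.0 * N)
    ssd_within = 0.0
    for m in mother_ids:
        idx = np.flatnonzero(mothers == m)
        ssd_within += D[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    t_sum = 0.0
    for g in site_ids:
        idx = np.flatnonzero(sites == g)
        t_sum += D[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return {
        "ssd_total": float(ssd_total),
        "ssd_within_mothers": float(ssd_within),
        "ssd_among_mothers": float(t_sum - ssd_within),
        "ssd_among_sites": float(ssd_total - t_sum),
        "df_among_sites": G - 1,
        "df_among_mothers": S - G,
        "df_within_mothers": N - S,
    }


def pd_unique(values: np.ndarray) -> list:
    """Unique labels in order of first appearance."""
    out, seen = [], set()
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def design_coefficients(
    sites: Sequence, mothers: Sequence
) -> tuple[float, float, float]:
    """Unbalanced-design coefficients (n', n'', n''')."""
    sites = np.asarray(sites, dtype=object)
    mothers = np.asarray(mothers, dtype=object)
    N = len(sites)
    site_ids = pd_unique(sites)
    mother_ids = pd_unique(mothers)
    G, S = len(site_ids), len(mother_ids)
    n_k = np.array([(mothers == m).sum() for m in mother_ids], dtype=float)
    site_of_mother = np.array(
        [sites[np.flatnonzero(mothers == m)[0]] for m in mother_ids], dtype=object
    )
    N_g = np.array([(sites == g).sum() for g in site_ids], dtype=float)
    sum_nk2_over_Ng = sum(
        (n_k[site_of_mother == g] ** 2).sum() / N_g[i]
        for i, g in enumerate(site_ids)
    )
    n_prime = (N - sum_nk2_over_Ng) / (S - G)
    n_dprime = (sum_nk2_over_Ng - (n_k**2).sum() / N) / (G - 1)
    n_tprime = (N - (N_g**2).sum() / N) / (G - 1)
    if n_prime <= 0:
        raise DegenerateDesignError("n' <= 0: degenerate mother-within-site stratum")
    if n_tprime <= 0:
        raise DegenerateDesignError("n''' <= 0: degenerate site stratum")
    return float(n_prime), float(n_dprime), float(n_tprime)


def variance_components(
    ssd: dict[str, float], coeffs: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Method-of-moments variance components (sigma2_a, sigma2_b, sigma2_c)."""
    n_p, n_dp, n_tp = coeffs
    sigma2_c = ssd["ssd_within_mothers"] / ssd["df_within_mothers"]
    msd_b = ssd["ssd_among_mothers"] / ssd["df_among_mothers"]
    msd_a = ssd["ssd_among_sites"] / ssd["df_among_sites"]
    sigma2_b = (msd_b - sigma2_c) / n_p
    sigma2_a = (msd_a - sigma2_c - n_dp * sigma2_b) / n_tp
    return float(sigma2_a), float(sigma2_b), float(sigma2_c)


def phi_statistics(
    sigma2_a: float, sigma2_b: float, sigma2_c: float
) -> tuple[float, float, float]:
    """(Phi_CT, Phi_SC, Phi_ST) from variance components; NaN if total is 0."""
    total = sigma2_a + sigma2_b + sigma2_c
    if total == 0:
        return float("nan"), float("nan"), float("nan")
    phi_ct = sigma2_a / total
    phi_sc = sigma2_b / (sigma2_b + sigma2_c) if sigma2_b + sigma2_c != 0 else float("nan")
    phi_st = (sigma2_a + sigma2_b) / total
    return phi_ct, phi_sc, phi_st


def phi_ratio(phi_sc: float, phi_ct: float) -> tuple[float, float]:
    """Fractions of the additive total Phi_ST = Phi_SC + Phi_CT.

    Returns (within_fraction, among_fraction): the shares of total
    mother-to-mother (different sites) pollen-pool differentiation
    attributable to the within-site and among-site levels.
    """
    total = phi_sc + phi_ct
    if total == 0:
        return float("nan"), float("nan")
    return phi_sc / total, phi_ct / total


def amova(
    D: np.ndarray, sites: Sequence, mothers: Sequence
) -> AmovaResult:
    """Full nested AMOVA from a precomputed squared-distance matrix."""
    ssd = ssd_partition(D, sites, mothers)
    coeffs = design_coefficients(sites, mothers)
    s_a, s_b, s_c = variance_components(ssd, coeffs)
    phi_ct, phi_sc, phi_st = phi_statistics(s_a, s_b, s_c)
    total = s_a + s_b + s_c
    return AmovaResult(
        ssd_among_sites=ssd["ssd_among_sites"],
        ssd_among_mothers=ssd["ssd_among_mothers"],
        ssd_within_mothers=ssd["ssd_within_mothers"],
        ssd_total=ssd["ssd_total"],
        df_among_sites=ssd["df_among_sites"],
        df_among_mothers=ssd["df_among_mothers"],
        df_within_mothers=ssd["df_within_mothers"],
        msd_among_sites=ssd["ssd_among_sites"] / ssd["df_among_sites"],
        msd_among_mothers=ssd["ssd_among_mothers"] / ssd["df_among_mothers"],
        msd_within_mothers=ssd["ssd_within_mothers"] / ssd["df_within_mothers"],
        n_prime=coeffs[0], n_double_prime=coeffs[1], n_triple_prime=coeffs[2],
        sigma2_a=s_a, sigma2_b=s_b, sigma2_c=s_c,
        phi_ct=phi_ct, phi_sc=phi_sc, phi_st=phi_st,
        negative_component=(s_a < 0 or s_b < 0 or s_c < 0),
        zero_total_variance=(total == 0),
    )


# ---------------------------------------------------------------------------
# stratified permutation tests


def _int_codes(values: np.ndarray) -> tuple[np.ndarray, list]:
    ids = pd_unique(values)
    lookup = {v: i for i, v in enumerate(ids)}
    return np.array([lookup[v] for v in values], dtype=np.int64), ids


def permutation_test_within(
    D: np.ndarray,
    sites: Sequence,
    mothers: Sequence,
    n_perm: int = 999,
    rng: Optional[Union[int, np.random.Generator]] = None,
    return_null: bool = False,
):
    """p-value for Phi_SC: permute seeds among mothers within each site.

    Per-mother haplotype counts and all site memberships are preserved;
    only the within-mother SSD changes, so the permutation distribution of
    Phi_SC is computed from that single term.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sites = np.asarray(sites, dtype=object)
    mothers = np.asarray(mothers, dtype=object)
    _check_nesting(sites, mothers)

    obs = amova(D, sites, mothers)
    ssd = ssd_partition(D, sites, mothers)
    n_p, _, _ = design_coefficients(sites, mothers)
    N = len(sites)
    mcodes, mother_ids = _int_codes(mothers)
    n_k = np.bincount(mcodes).astype(float)
    inv_nk = 1.0 / n_k
    df_w = ssd["df_within_mothers"]
    df_b = ssd["df_among_mothers"]
    t_sum = ssd["ssd_among_mothers"] + ssd["ssd_within_mothers"]  # sum_g T_g

    # within-site pair list
    scodes, site_ids = _int_codes(sites)
    I_list, J_list = [], []
    for g in range(len(site_ids)):
        idx = np.flatnonzero(scodes == g)
        if len(idx) < 2:
            continue
        ii, jj = np.triu_indices(len(idx), k=1)
        I_list.append(idx[ii])
        J_list.append(idx[jj])
    I = np.concatenate(I_list)
    J = np.concatenate(J_list)
    dpair = D[I, J]

    null = np.empty(n_perm)
    chunk = 256
    for start in range(0, n_perm, chunk):
        P = min(chunk, n_perm - start)
        perm_labels = np.tile(mcodes, (P, 1))
        for g in range(len(site_ids)):
            idx = np.flatnonzero(scodes == g)
            if len(idx) < 2:
                continue  # single-mother or single-seed site: no freedom
            order = np.argsort(rng.random((P, len(idx))), axis=1)
            perm_labels[:, idx] = mcodes[idx][order]
        li = perm_labels[:, I]
        same = li == perm_labels[:, J]
        ssd_w = np.where(same, dpair[None, :] * inv_nk[li], 0.0).sum(axis=1)
        sigma2_c = ssd_w / df_w
        sigma2_b = ((t_sum - ssd_w) / df_b - sigma2_c) / n_p
        with np.errstate(invalid="ignore", divide="ignore"):
            null[start:start + P] = sigma2_b / (sigma2_b + sigma2_c)

    p = (np.sum(null >= obs.phi_sc) + 1) / (n_perm + 1)
    if return_null:
        return float(p), obs, null
    return float(p), obs


def permutation_test_among(
    D: np.ndarray,
    sites: Sequence,
    mothers: Sequence,
    n_perm: int = 999,
    rng: Optional[Union[int, np.random.Generator]] = None,
    return_null: bool = False,
):
    """p-value for Phi_CT: permute whole mothers (with their seeds) among sites.

    The number of mothers per site is preserved; site totals, design
    coefficients and the among-level SSDs are recomputed per permutation
    from mother-level block sums of the distance matrix.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sites = np.asarray(sites, dtype=object)
    mothers = np.asarray(mothers, dtype=object)
    _check_nesting(sites, mothers)

    obs = amova(D, sites, mothers)
    ssd = ssd_partition(D, sites, mothers)
    N = len(sites)
    mcodes, mother_ids = _int_codes(mothers)
    scodes, site_ids = _int_codes(sites)
    K, G = len(mother_ids), len(site_ids)
    S = K
    n_k = np.bincount(mcodes).astype(float)
    site_of_mother = np.empty(K, dtype=np.int64)
    for k in range(K):
        site_of_mother[k] = scodes[np.flatnonzero(mcodes == k)[0]]

    # mother-level block sums: C[k, l] = sum_{i in k, j in l} D_ij
    A = np.zeros((N, K))
    A[np.arange(N), mcodes] = 1.0
    C = A.T @ D @ A

    ssd_total = ssd["ssd_total"]
    ssd_w = ssd["ssd_within_mothers"]
    df_a, df_b, df_w = (
        ssd["df_among_sites"], ssd["df_among_mothers"], ssd["df_within_mothers"],
    )
    sigma2_c = ssd_w / df_w
    sum_nk2 = (n_k**2).sum()

    null = np.empty(n_perm)
    template = site_of_mother.copy()
    for b in range(n_perm):
        assign = template[rng.permutation(K)]
        Z = np.zeros((G, K))
        Z[assign, np.arange(K)] = 1.0
        N_g = Z @ n_k
        pair_sum_g = 0.5 * np.einsum("gk,kl,gl->g", Z, C, Z)
        t_sum = (pair_sum_g / N_g).sum()
        nk2_over_Ng = ((Z @ (n_k**2)) / N_g).sum()
        n_p = (N - nk2_over_Ng) / (S - G)
        n_dp = (nk2_over_Ng - sum_nk2 / N) / (G - 1)
        n_tp = (N - (N_g**2).sum() / N) / (G - 1)
        msd_b = (t_sum - ssd_w) / df_b
        msd_a = (ssd_total - t_sum) / df_a
        s_b = (msd_b - sigma2_c) / n_p
        s_a = (msd_a - sigma2_c - n_dp * s_b) / n_tp
        total = s_a + s_b + sigma2_c
        null[b] = s_a / total if total != 0 else np.nan

    p = (np.sum(null >= obs.phi_ct) + 1) / (n_perm + 1)
    if return_null:
        return float(p), obs, null
    return float(p), obs


def amova_with_tests(
    haplotypes: Sequence[PollenHaplotype],
    locus_names: Sequence[str],
    n_perm: int = 999,
    rng: Optional[Union[int, np.random.Generator]] = None,
    rescale_missing: bool = False,
) -> AmovaResult:
    """Convenience wrapper: encode, build distances, AMOVA + both tests.

    Runs both permutation tests on the haplotypes as given.  For strict
    type-I control the within-site test wants site-referenced ambiguity
    resolution and the among-site test overall-referenced resolution
    (see ``infer_pollen_pool``); the pipeline handles that split.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    codes, sites, mothers = encode_haplotypes(haplotypes, locus_names)
    D = distance_matrix(codes, rescale_missing=rescale_missing)
    p_sc, result = permutation_test_within(D, sites, mothers, n_perm, rng)
    p_ct, _ = permutation_test_among(D, sites, mothers, n_perm, rng)
    result.p_sc = p_sc
    result.p_ct = p_ct
    return result
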