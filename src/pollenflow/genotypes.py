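"""Data model, I/O, and validation for codominant multilocus genotype tables.

Genotypes are unordered pairs of opaque allele labels (microsatellite
fragment sizes are treated as labels, never as numbers).  Individuals are
organised hierarchically: site -> mother -> fruit -> seed.  Mothers carry
no fruit/seed identifiers; every seed must reference a sampled mother.
"""

from __future__ import annotations

import collections
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

#: unordered allele pair (stored sorted) or None when the locus is missing
AllelePair = tuple[str, str]
#: a multilocus genotype: locus name -> allele pair or None
Genotype = dict[str, Optional[AllelePair]]

DEFAULT_MISSING = ("0", "", "NA", "?")


@dataclass(frozen=True)
class LocusDef:
    """A locus and the ordered set of allele labels observed at it."""

    name: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name!r} has no alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name!r} has duplicate allele labels")


@dataclass(frozen=True)
class SeedRecord:
    site_id: str
    mother_id: str
    fruit_id: str
    seed_id: str
    genotype: Genotype

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.site_id, self.mother_id, self.fruit_id, self.seed_id)


@dataclass
class Dataset:
    """A hierarchical mother/seed genotype collection with a locus registry."""

    loci: list[LocusDef]
    mothers: dict[tuple[str, str], Genotype]
    seeds: list[SeedRecord]

    def __post_init__(self) -> None:
        for s in self.seeds:
            if (s.site_id, s.mother_id) not in self.mothers:
                raise ValueError(
                    f"seed {s.key} references unknown mother "
                    f"({s.site_id}, {s.mother_id})"
                )
        keys = [s.key for s in self.seeds]
        if len(set(keys)) != len(keys):
            dup = [k for k, c in collections.Counter(keys).items() if c > 1]
            raise ValueError(f"duplicate seed keys: {dup[:5]}")

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    def sites(self) -> list[str]:
        out: list[str] = []
        for site, _ in self.mothers:
            if site not in out:
                out.append(site)
        return out

    def mothers_in_site(self, site_id: str) -> list[str]:
        return [m for (s, m) in self.mothers if s == site_id]

    def has_fruit_ids(self) -> bool:
        """True when fruit identifiers are informative (not all blank)."""
        return all(s.fruit_id not in ("", "0") for s in self.seeds)


@dataclass
class ValidationReport:
    """Mother-offspring consistency screen.

    A (seed, locus) combination is *impossible* when both genotypes are
    non-missing and the seed shares no allele with its mother there; the
    per-locus rate is impossible / non-missing comparisons.
    """

    impossible_rate: dict[str, float]
    missing_rate: dict[str, float]
    n_compared: dict[str, int]
    flagged: list[tuple[tuple[str, str, str, str], str]] = field(default_factory=list)

    @property
    def max_impossible_rate(self) -> float:
        return max(self.impossible_rate.values(), default=0.0)


# ---------------------------------------------------------------------------
# parsing / writing


def _norm_missing(value: str, missing: Sequence[str]) -> Optional[str]:
    v = value.strip()
    return None if v in missing else v


def _row_genotype(
    row: Mapping[str, str],
    locus_names: Sequence[str],
    dialect: str,
    missing: Sequence[str],
    rowno: int,
) -> Genotype:
    geno: Genotype = {}
    for loc in locus_names:
        if dialect == "wide":
            a = _norm_missing(str(row[f"{loc}.1"]), missing)
            b = _norm_missing(str(row[f"{loc}.2"]), missing)
        else:  # "ab": single column "a/b"
            raw = str(row[loc]).strip()
            if _norm_missing(raw, missing) is None:
                a = b = None
            else:
                parts = raw.split("/")
                if len(parts) != 2:
                    raise ValueError(
                        f"row {rowno}: malformed allele column {loc!r}: {raw!r}"
                    )
                a = _norm_missing(parts[0], missing)
                b = _norm_missing(parts[1], missing)
        # a half-called locus is unreliable fragment data: treat as missing
        geno[loc] = None if (a is None or b is None) else tuple(sorted((a, b)))
    return geno


def _locus_names_from_header(columns: Sequence[str], dialect: str) -> list[str]:
    meta = {"site", "mother", "fruit", "seed", "role"}
    if dialect == "wide":
        firsts = [c[:-2] for c in columns if c.endswith(".1")]
        seconds = {c[:-2] for c in columns if c.endswith(".2")}
        loci = [c for c in firsts if c in seconds]
        if not loci:
            raise ValueError("no locus columns found (expected '<locus>.1'/'<locus>.2')")
        return loci
    loci = [c for c in columns if c not in meta]
    if not loci:
        raise ValueError("no locus columns found")
    return loci


def read_genotype_table(
    path: Union[str, Path, io.TextIOBase],
    dialect: str = "wide",
    missing: Sequence[str] = DEFAULT_MISSING,
    sep: str = ",",
) -> Dataset:
    """Read a delimited genotype table into a :class:`Dataset`.

    One row per individual.  Metadata columns: ``site``, ``mother``,
    ``role`` (``mother``/``seed``) and, for seeds, ``fruit`` and ``seed``.
    Dialect ``wide`` expects two columns per locus (``<locus>.1``,
    ``<locus>.2``); dialect ``ab`` a single ``a/b`` column.  Alleles equal
    to a missing sentinel (default ``0`` or empty) mark the locus missing.
    """
    if dialect not in ("wide", "ab"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=sep)
    for col in ("site", "mother", "role"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    locus_names = _locus_names_from_header(df.columns, dialect)

    mothers: dict[tuple[str, str], Genotype] = {}
    seeds: list[SeedRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        rowno = i + 2  # header is row 1
        role = str(row["role"]).strip().lower()
        geno = _row_genotype(row, locus_names, dialect, missing, rowno)
        site, mother = str(row["site"]).strip(), str(row["mother"]).strip()
        if role == "mother":
            if (site, mother) in mothers:
                raise ValueError(f"row {rowno}: duplicate mother ({site}, {mother})")
            mothers[(site, mother)] = geno
        elif role == "seed":
            fruit = str(row.get("fruit", "")).strip()
            seed = str(row.get("seed", "")).strip()
            seeds.append(SeedRecord(site, mother, fruit, seed, geno))
        else:
            raise ValueError(f"row {rowno}: role must be 'mother' or 'seed', got {role!r}")

    for i, s in enumerate(seeds):
        if (s.site_id, s.mother_id) not in mothers:
            raise ValueError(
                f"seed {s.key} references unknown mother (data row ~{i + 2})"
            )

    observed: dict[str, set[str]] = {loc: set() for loc in locus_names}
    for geno in list(mothers.values()) + [s.genotype for s in seeds]:
        for loc, pair in geno.items():
            if pair is not None:
                observed[loc].update(pair)
    loci = [
        LocusDef(loc, tuple(sorted(observed[loc])) or ("<none>",))
        for loc in locus_names
    ]
    return Dataset(loci=loci, mothers=mothers, seeds=seeds)


def write_genotype_table(
    ds: Dataset,
    path: Union[str, Path],
    dialect: str = "wide",
    missing_code: str = "0",
    sep: str = ",",
) -> None:
    """Write a Dataset back to delimited text (inverse of the reader)."""
    rows = []
    for (site, mother), geno in ds.mothers.items():
        rows.append(_out_row(site, mother, "", "", "mother", geno, ds.locus_names, dialect, missing_code))
    for s in ds.seeds:
        rows.append(_out_row(s.site_id, s.mother_id, s.fruit_id, s.seed_id, "seed", s.genotype, ds.locus_names, dialect, missing_code))
    pd.DataFrame(rows).to_csv(path, index=False, sep=sep)


def _out_row(site, mother, fruit, seed, role, geno, locus_names, dialect, missing_code):
    row: dict[str, str] = {
        "site": site, "mother": mother, "fruit": fruit, "seed": seed, "role": role,
    }
    for loc in locus_names:
        pair = geno.get(loc)
        if dialect == "wide":
            row[f"{loc}.1"] = pair[0] if pair else missing_code
            row[f"{loc}.2"] = pair[1] if pair else missing_code
        else:
            row[loc] = f"{pair[0]}/{pair[1]}" if pair else missing_code
    return row


def to_genepop(ds: Dataset, path: Union[str, Path], title: str = "pollenflow export") -> None:
    """Export diploid genotypes (mothers + seeds) in GenePop format.

    Allele labels are mapped to 3-digit codes in label-sorted order; one
    POP block per site.  Intended for interoperability only.
    """
    codes: dict[str, dict[str, str]] = {}
    for locus in ds.loci:
        if len(locus.alleles) > 999:
            raise ValueError(f"locus {locus.name}: too many alleles for GenePop")
        codes[locus.name] = {a: f"{i + 1:03d}" for i, a in enumerate(locus.alleles)}

    lines = [title]
    lines.extend(ds.locus_names)
    by_site: dict[str, list[tuple[str, Genotype]]] = collections.defaultdict(list)
    for (site, mother), geno in ds.mothers.items():
        by_site[site].append((f"{site}_{mother}_M", geno))
    for s in ds.seeds:
        by_site[s.site_id].append(("_".join(s.key), s.genotype))
    for site in ds.sites():
        lines.append("POP")
        for name, geno in by_site[site]:
            gcols = []
            for loc in ds.locus_names:
                pair = geno.get(loc)
                if pair is None:
                    gcols.append("000000")
                else:
                    gcols.append(codes[loc][pair[0]] + codes[loc][pair[1]])
            lines.append(f"{name} , " + " ".join(gcols))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# validation and allele frequencies


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Screen every mother-offspring pair for impossible genotype combinations."""
    impossible: dict[str, int] = {loc: 0 for loc in ds.locus_names}
    compared: dict[str, int] = {loc: 0 for loc in ds.locus_names}
    missing: dict[str, int] = {loc: 0 for loc in ds.locus_names}
    flagged: list[tuple[tuple[str, str, str, str], str]] = []

    n_individuals = len(ds.mothers) + len(ds.seeds)
    for geno in list(ds.mothers.values()) + [s.genotype for s in ds.seeds]:
        for loc in ds.locus_names:
            if geno.get(loc) is None:
                missing[loc] += 1

    for s in ds.seeds:
        mother = ds.mothers[(s.site_id, s.mother_id)]
        for loc in ds.locus_names:
            mp, sp = mother.get(loc), s.genotype.get(loc)
            if mp is None or sp is None:
                continue
            compared[loc] += 1
            if not (set(sp) & set(mp)):
                impossible[loc] += 1
                flagged.append((s.key, loc))

    return ValidationReport(
        impossible_rate={
            loc: (impossible[loc] / compared[loc]) if compared[loc] else 0.0
            for loc in ds.locus_names
        },
        missing_rate={loc: missing[loc] / n_individuals for loc in ds.locus_names},
        n_compared=compared,
        flagged=flagged,
    )


Observation = Union[None, str, Sequence[str]]


def allele_frequencies(observations: Iterable[Observation]) -> dict[str, float]:
    """Allele frequencies from haploid gametes and/or diploid genotypes.

    Each observation is an allele label (haploid), a pair of labels
    (diploid), or None (missing, excluded from the denominator).  Returns
    an empty dict when nothing is observed.
    """
    counts: collections.Counter[str] = collections.Counter()
    for obs in observations:
        if obs is None:
            continue
        if isinstance(obs, str):
            counts[obs] += 1
        else:
            if len(obs) != 2:
                raise ValueError(f"diploid observation must have 2 alleles: {obs!r}")
            counts[obs[0]] += 1
            counts[obs[1]] += 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {a: c / total for a, c in sorted(counts.items())}


def dataset_allele_frequencies(ds: Dataset, which: str = "all") -> dict[str, dict[str, float]]:
    """Per-locus allele frequencies over mothers, seeds, or all individuals."""
    genos: list[Genotype] = []
    if which in ("all", "mothers"):
        genos += list(ds.mothers.values())
    if which in ("all", "seeds"):
        genos += [s.genotype for s in ds.seeds]
    return {
        loc: allele_frequencies(g.get(loc) for g in genos) for loc in ds.locus_names
    }
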