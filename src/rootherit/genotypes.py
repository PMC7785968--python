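"""SSR genotype panels, trait tables and per-locus allele frequencies.

Microsatellite (SSR) genotypes are codominant and multi-allelic: each
sample carries at most two sized alleles (fragment lengths in base pairs)
per locus.  The wide CSV dialect used here is GenAlEx-like: two integer
columns per locus (``<locus>_a1``, ``<locus>_a2``), with ``0`` or an empty
cell marking a missing allele.  A record with only one of its two allele
columns scored is treated as fully missing for that locus — capillary
dropout makes the single-allele call ambiguous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = 0  # sentinel allele length for a missing call


class FormatError(ValueError):
    """Malformed genotype or trait file."""


@dataclass
class GenotypePanel:
    """Sample x locus table of codominant allele-size pairs.

    Parameters
    ----------
    samples : list of str
        Unique sample identifiers, in input order.
    loci : list of str
        Unique locus identifiers, in input order.
    allele1, allele2 : ndarray of int, shape (n_samples, n_loci)
        Allele fragment lengths in base pairs; ``0`` encodes a missing
        call.  A call is either both-present or both-missing.
    populations : list of str or None
        Optional per-sample population labels carried through from input.
    """

    samples: list[str]
    loci: list[str]
    allele1: np.ndarray
    allele2: np.ndarray
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        self.allele1 = np.asarray(self.allele1, dtype=np.int64)
        self.allele2 = np.asarray(self.allele2, dtype=np.int64)
        n, L = len(self.samples), len(self.loci)
        if self.allele1.shape != (n, L) or self.allele2.shape != (n, L):
            raise ValueError("allele arrays must be (n_samples, n_loci)")
        if len(set(self.samples)) != n:
            raise FormatError("duplicate sample identifiers")
        if len(set(self.loci)) != L:
            raise FormatError("duplicate locus identifiers")
        if np.any(self.allele1 < 0) or np.any(self.allele2 < 0):
            raise ValueError("allele lengths must be non-negative integers")
        # enforce both-or-neither missing (single-allele records were
        # already collapsed to missing by the reader)
        half = (self.allele1 == MISSING) ^ (self.allele2 == MISSING)
        if np.any(half):
            raise ValueError("half-missing call; collapse to missing first")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci); True where the call is missing."""
        return self.allele1 == MISSING

    def call(self, sample: str, locus: str) -> tuple[int, int] | None:
        """Return the unordered allele pair for one cell, or None."""
        i = self.samples.index(sample)
        j = self.loci.index(locus)
        if self.allele1[i, j] == MISSING:
            return None
        return (int(self.allele1[i, j]), int(self.allele2[i, j]))

    def sample_calls(self, sample: str) -> dict[str, tuple[int, int] | None]:
        """Mapping locus -> allele pair (or None) for one sample."""
        i = self.samples.index(sample)
        out: dict[str, tuple[int, int] | None] = {}
        for j, loc in enumerate(self.loci):
            if self.allele1[i, j] == MISSING:
                out[loc] = None
            else:
                out[loc] = (int(self.allele1[i, j]), int(self.allele2[i, j]))
        return out

    def all_missing_samples(self) -> list[str]:
        """Samples with no scored locus (retained but flagged on read)."""
        mask = self.missing_mask.all(axis=1)
        return [s for s, m in zip(self.samples, mask) if m]

    def subset(self, samples: list[str]) -> "GenotypePanel":
        idx = [self.samples.index(s) for s in samples]
        pops = [self.populations[i] for i in idx] if self.populations else None
        return GenotypePanel(
            samples=list(samples),
            loci=list(self.loci),
            allele1=self.allele1[idx],
            allele2=self.allele2[idx],
            populations=pops,
        )


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele relative frequencies from observed gene copies.

    ``freqs[locus]`` maps allele length -> frequency (> 0, summing to 1);
    ``n_alleles[locus]`` is the number of distinct observed alleles.
    """

    freqs: dict[str, dict[int, float]]
    n_alleles: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.n_alleles = {}
        for locus, table in self.freqs.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {total}")
            if any(p <= 0 for p in table.values()):
                raise ValueError(f"non-positive frequency at {locus}")
            self.n_alleles[locus] = len(table)


def allele_frequencies(panel: GenotypePanel) -> AlleleFrequencyTable:
    """Estimate per-locus allele frequencies from all non-missing calls.

    Each diploid call contributes two gene copies.  Loci with zero
    non-missing calls are dropped with a warning.
    """
    if panel.n_samples == 0:
        raise ValueError("empty panel")
    freqs: dict[str, dict[int, float]] = {}
    for j, locus in enumerate(panel.loci):
        ok = panel.allele1[:, j] != MISSING
        if not ok.any():
            warnings.warn(f"locus {locus} has no scored calls; dropped")
            continue
        copies = np.concatenate([panel.allele1[ok, j], panel.allele2[ok, j]])
        alleles, counts = np.unique(copies, return_counts=True)
        total = counts.sum()
        freqs[locus] = {int(a): c / total for a, c in zip(alleles, counts)}
    return AlleleFrequencyTable(freqs=freqs)


def read_genotypes(path, dialect: str = "wide") -> GenotypePanel:
    """Read a wide-format SSR genotype CSV.

    Header must be ``sample[,population],<locus>_a1,<locus>_a2,...``; the
    population column is optional.  Missing alleles are coded ``0`` or left
    empty.  Samples missing every locus are retained but logged.
    """
    if dialect != "wide":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str).fillna("")
    cols = list(df.columns)
    if not cols or cols[0] != "sample":
        raise FormatError("first column must be 'sample'")
    has_pop = len(cols) > 1 and cols[1] == "population"
    allele_cols = cols[2:] if has_pop else cols[1:]
    loci: list[str] = []
    for k in range(0, len(allele_cols), 2):
        pair = allele_cols[k : k + 2]
        if len(pair) != 2:
            raise FormatError("odd number of allele columns")
        base1, suf1 = pair[0].rsplit("_", 1) if "_" in pair[0] else (pair[0], "")
        base2, suf2 = pair[1].rsplit("_", 1) if "_" in pair[1] else (pair[1], "")
        if suf1 != "a1" or suf2 != "a2" or base1 != base2:
            raise FormatError(f"locus columns {pair} must be <locus>_a1,<locus>_a2")
        if base1 in loci:
            raise FormatError(f"more than two allele columns for locus {base1}")
        loci.append(base1)

    def parse_allele(v: str) -> int:
        v = v.strip()
        if v == "":
            return MISSING
        try:
            f = float(v)
        except ValueError as exc:
            raise ValueError(f"non-integer allele {v!r}") from exc
        if f != int(f) or f < 0:
            raise ValueError(f"non-integer allele {v!r}")
        return int(f)

    n = len(df)
    a1 = np.zeros((n, len(loci)), dtype=np.int64)
    a2 = np.zeros((n, len(loci)), dtype=np.int64)
    for j in range(len(loci)):
        c1 = allele_cols[2 * j]
        c2 = allele_cols[2 * j + 1]
        v1 = df[c1].map(parse_allele).to_numpy()
        v2 = df[c2].map(parse_allele).to_numpy()
        # single-allele records are ambiguous dropout: treat as missing
        half = (v1 == MISSING) ^ (v2 == MISSING)
        v1[half] = MISSING
        v2[half] = MISSING
        a1[:, j] = v1
        a2[:, j] = v2

    panel = GenotypePanel(
        samples=df["sample"].tolist(),
        loci=loci,
        allele1=a1,
        allele2=a2,
        populations=df["population"].tolist() if has_pop else None,
    )
    empty = panel.all_missing_samples()
    if empty:
        log.warning("samples with all loci missing: %s", ", ".join(empty))
    return panel


def write_genotypes(panel: GenotypePanel, path) -> None:
    """Write a panel back to the wide CSV dialect (missing coded 0)."""
    data: dict[str, list] = {"sample": panel.samples}
    if panel.populations is not None:
        data["population"] = panel.populations
    for j, locus in enumerate(panel.loci):
        data[f"{locus}_a1"] = panel.allele1[:, j].tolist()
        data[f"{locus}_a2"] = panel.allele2[:, j].tolist()
    pd.DataFrame(data).to_csv(path, index=False)


@dataclass
class TraitTable:
    """Sample x trait phenotypes with orchard and agroecological-region labels.

    Orchard/region labels on the trait table are the grouping source of
    truth for the analysis; every orchard must map to exactly one region.
    """

    samples: list[str]
    orchard: list[str]
    region: list[str]
    values: pd.DataFrame  # index = samples, columns = traits, NaN = missing

    def __post_init__(self) -> None:
        n = len(self.samples)
        if len(set(self.samples)) != n:
            raise FormatError("duplicate sample identifiers")
        if len(self.orchard) != n or len(self.region) != n:
            raise ValueError("orchard/region label length mismatch")
        mapping: dict[str, str] = {}
        for o, r in zip(self.orchard, self.region):
            if o in mapping and mapping[o] != r:
                raise FormatError(f"orchard {o} mapped to regions {mapping[o]} and {r}")
            mapping[o] = r
        self.values = self.values.astype(float)
        self.values.index = pd.Index(self.samples)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def trait_vector(self, trait: str) -> pd.Series:
        return self.values[trait]

    def non_missing_counts(self) -> pd.Series:
        return self.values.notna().sum(axis=0)

    def samples_in_region(self, region: str) -> list[str]:
        return [s for s, r in zip(self.samples, self.region) if r == region]

    def subset(self, samples: list[str]) -> "TraitTable":
        idx = [self.samples.index(s) for s in samples]
        return TraitTable(
            samples=list(samples),
            orchard=[self.orchard[i] for i in idx],
            region=[self.region[i] for i in idx],
            values=self.values.iloc[idx].copy(),
        )


def read_traits(path) -> TraitTable:
    """Read a trait CSV with header ``sample,orchard,region,<trait1>,...``.

    All-missing trait columns are skipped with a warning; per-trait
    non-missing counts are logged.
    """
    df = pd.read_csv(path)
    required = ["sample", "orchard", "region"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"trait CSV must start with columns {required}")
    values = df.drop(columns=required).astype(float)
    keep = []
    for c in values.columns:
        if values[c].notna().sum() == 0:
            warnings.warn(f"trait {c} has no values; skipped")
        else:
            keep.append(c)
    values = values[keep]
    table = TraitTable(
        samples=df["sample"].astype(str).tolist(),
        orchard=df["orchard"].astype(str).tolist(),
        region=df["region"].astype(str).tolist(),
        values=values,
    )
    for trait, count in table.non_missing_counts().items():
        log.info("trait %s: %d non-missing", trait, count)
    return table


def write_traits(table: TraitTable, path) -> None:
    out = pd.DataFrame(
        {"sample": table.samples, "orchard": table.orchard, "region": table.region}
    )
    out = pd.concat([out, table.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)
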