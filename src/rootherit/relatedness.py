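"""Ritland method-of-moments pairwise relatedness from codominant markers.

For a locus l with observed alleles i of population frequency p_i and a
pair of diploid genotypes (a,b) and (c,d), define the allele-sharing score

    S_i = 1/4 (d_ai + d_bi)(d_ci + d_di)

(d is the Kronecker delta).  The single-locus estimator is

    r_l = 2/(n_l - 1) * ( sum_i S_i / p_i - 1 )

with n_l the number of distinct alleles observed at the locus.  The
multilocus estimate weights loci by w_l = n_l - 1:

    r = sum_l w_l r_l / sum_l w_l,

skipping loci missing in either sample or monomorphic in the panel
(n_l = 1 carries no information and has weight 0).  The estimator is
unbiased but high-variance: single-locus values range well below 0 and
above 1, and the resulting matrix need not be positive semidefinite.
Negative estimates are retained untruncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencyTable, GenotypePanel, allele_frequencies

log = logging.getLogger(__name__)


@dataclass
class RelatednessMatrix:
    """Symmetric n x n marker relatedness with the diagonal set to one.

    The diagonal is fixed at 1 by convention (self-relatedness), not
    estimated.  ``locus_support[i, j]`` counts the loci contributing to
    each pairwise estimate.
    """

    samples: list[str]
    values: np.ndarray
    locus_support: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.all(np.diag(self.values) == 1.0):
            raise ValueError("diagonal must be exactly 1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal values (all unordered pairs)."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.values[iu]

    def subset(self, samples: list[str]) -> "RelatednessMatrix":
        idx = np.array([self.samples.index(s) for s in samples])
        return RelatednessMatrix(
            samples=list(samples),
            values=self.values[np.ix_(idx, idx)],
            locus_support=self.locus_support[np.ix_(idx, idx)],
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.samples, columns=self.samples).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "RelatednessMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("row and column sample IDs differ")
        values = df.to_numpy(dtype=float)
        return cls(
            samples=list(df.index.astype(str)),
            values=values,
            locus_support=np.zeros_like(values, dtype=int),
        )


def ritland_pair(
    calls_x: dict[str, tuple[int, int] | None],
    calls_y: dict[str, tuple[int, int] | None],
    freqs: AlleleFrequencyTable,
) -> tuple[float, int]:
    """Multilocus Ritland relatedness for one pair of samples.

    ``calls_*`` map locus -> unordered allele pair or None (missing).
    Returns (estimate, number of loci used).  Raises if no locus is usable
    (missing in either sample or monomorphic everywhere).
    """
    num = 0.0
    den = 0.0
    used = 0
    for locus, table in freqs.freqs.items():
        gx = calls_x.get(locus)
        gy = calls_y.get(locus)
        n_l = len(table)
        if gx is None or gy is None or n_l < 2:
            continue
        a, b = gx
        c, d = gy
        total = 0.0
        for allele, p in table.items():
            s_i = 0.25 * ((a == allele) + (b == allele)) * ((c == allele) + (d == allele))
            if s_i:
                total += s_i / p
        r_l = (2.0 / (n_l - 1)) * (total - 1.0)
        w_l = n_l - 1
        num += w_l * r_l
        den += w_l
        used += 1
    if used == 0:
        raise ValueError("no usable locus for this pair")
    return num / den, used


def _pair_freq_tables(panel: GenotypePanel, i: int, j: int) -> AlleleFrequencyTable:
    """Allele frequencies with the focal pair's gene copies removed."""
    keep = [k for k in range(panel.n_samples) if k not in (i, j)]
    sub = GenotypePanel(
        samples=[panel.samples[k] for k in keep],
        loci=list(panel.loci),
        allele1=panel.allele1[keep],
        allele2=panel.allele2[keep],
    )
    return allele_frequencies(sub)


def relatedness_matrix(
    panel: GenotypePanel,
    freqs: AlleleFrequencyTable | None = None,
    exclude_focal_pairs: bool = False,
) -> RelatednessMatrix:
    """Pairwise Ritland relatedness over all unordered pairs of a panel.

    Reference allele frequencies are computed from the full panel
    (including the focal pair) unless ``exclude_focal_pairs`` is set, in
    which case each pair's own gene copies are removed from the frequency
    estimate (slower; SPaGeDi-style option).  Pairs with no usable locus
    are imputed with the mean of the estimated off-diagonal values, with a
    warning.  The diagonal is set to one.
    """
    n = panel.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")

    if exclude_focal_pairs:
        return _relatedness_matrix_naive(panel)

    if freqs is None:
        freqs = allele_frequencies(panel)

    num = np.zeros((n, n))
    den = np.zeros((n, n))
    support = np.zeros((n, n), dtype=int)
    for j, locus in enumerate(panel.loci):
        table = freqs.freqs.get(locus)
        if table is None:
            continue
        n_l = len(table)
        if n_l < 2:
            continue
        alleles = np.fromiter(table.keys(), dtype=np.int64)
        p = np.fromiter(table.values(), dtype=float)
        a1 = panel.allele1[:, j]
        a2 = panel.allele2[:, j]
        ok = a1 != MISSING
        # Q[i, k] = half the count of allele k in sample i's genotype, so
        # sum_i S_i / p_i over a pair is a row-by-row inner product
        Q = 0.5 * (
            (a1[:, None] == alleles[None, :]).astype(float)
            + (a2[:, None] == alleles[None, :])
        )
        A = (Q / p) @ Q.T
        r_l = (2.0 / (n_l - 1)) * (A - 1.0)
        w = float(n_l - 1)
        both = np.outer(ok, ok)
        num += np.where(both, w * r_l, 0.0)
        den += np.where(both, w, 0.0)
        support += both.astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        values = num / den
    iu = np.triu_indices(n, k=1)
    estimated = np.isfinite(values[iu])
    if not estimated.all():
        fill = float(np.mean(values[iu][estimated]))
        bad = ~np.isfinite(values)
        log.warning(
            "%d pairs with no usable locus; imputed off-diagonal mean %.4f",
            int(bad[iu].sum()),
            fill,
        )
        values[bad] = fill
    values = 0.5 * (values + values.T)  # symmetric up to float noise
    np.fill_diagonal(values, 1.0)
    np.fill_diagonal(support, panel.n_loci)
    return RelatednessMatrix(samples=list(panel.samples), values=values, locus_support=support)


def _relatedness_matrix_naive(panel: GenotypePanel) -> RelatednessMatrix:
    """Per-pair loop with focal-pair-excluded allele frequencies."""
    n = panel.n_samples
    calls = [panel.sample_calls(s) for s in panel.samples]
    values = np.full((n, n), np.nan)
    support = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            freqs_ij = _pair_freq_tables(panel, i, j)
            try:
                r, used = ritland_pair(calls[i], calls[j], freqs_ij)
            except ValueError:
                continue
            values[i, j] = values[j, i] = r
            support[i, j] = support[j, i] = used
    iu = np.triu_indices(n, k=1)
    estimated = np.isfinite(values[iu])
    if not estimated.all():
        fill = float(np.mean(values[iu][estimated]))
        log.warning("pairs with no usable locus imputed to %.4f", fill)
        values[~np.isfinite(values)] = fill
    np.fill_diagonal(values, 1.0)
    np.fill_diagonal(support, panel.n_loci)
    return RelatednessMatrix(samples=list(panel.samples), values=values, locus_support=support)


@dataclass
class LocusContributions:
    """Per-locus weighted contribution matrices w_l * r_l and call masks.

    Permuting a locus's genotype calls across samples permutes that
    locus's contribution matrix symmetrically, so a marker-matrix
    permutation of the whole panel reduces to per-locus row/column
    shuffles of cached matrices — exactly the matrix a recompute from the
    permuted panel would give, at a fraction of the cost.
    """

    samples: list[str]
    n_loci_total: int
    wr: list[np.ndarray]  # per usable locus: (n, n) = w_l * r_l
    w: list[float]
    masks: list[np.ndarray]  # per usable locus: (n,) bool, call present

    @classmethod
    def from_panel(
        cls, panel: GenotypePanel, freqs: AlleleFrequencyTable | None = None
    ) -> "LocusContributions":
        if freqs is None:
            freqs = allele_frequencies(panel)
        wr, w, masks = [], [], []
        for j, locus in enumerate(panel.loci):
            table = freqs.freqs.get(locus)
            if table is None or len(table) < 2:
                continue
            n_l = len(table)
            alleles = np.fromiter(table.keys(), dtype=np.int64)
            p = np.fromiter(table.values(), dtype=float)
            a1 = panel.allele1[:, j]
            a2 = panel.allele2[:, j]
            Q = 0.5 * (
                (a1[:, None] == alleles[None, :]).astype(float)
                + (a2[:, None] == alleles[None, :])
            )
            A = (Q / p) @ Q.T
            wr.append(float(n_l - 1) * ((2.0 / (n_l - 1)) * (A - 1.0)))
            w.append(float(n_l - 1))
            masks.append(a1 != MISSING)
        return cls(
            samples=list(panel.samples),
            n_loci_total=panel.n_loci,
            wr=wr,
            w=w,
            masks=masks,
        )

    def assemble(
        self, rng: np.random.Generator | None = None
    ) -> RelatednessMatrix:
        """Combine locus contributions into the multilocus matrix.

        With an ``rng``, each locus is first independently shuffled across
        samples (the marker-matrix permutation null); the rng is consumed
        exactly as one ``permutation(n)`` per locus, in locus order.
        """
        n = len(self.samples)
        num = np.zeros((n, n))
        den = np.zeros((n, n))
        support = np.zeros((n, n), dtype=int)
        for wr_l, w_l, mask in zip(self.wr, self.w, self.masks):
            if rng is not None:
                order = rng.permutation(n)
                wr_l = wr_l[np.ix_(order, order)]
                mask = mask[order]
            both = np.outer(mask, mask)
            num += np.where(both, wr_l, 0.0)
            den += np.where(both, w_l, 0.0)
            support += both.astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = num / den
        iu = np.triu_indices(n, k=1)
        estimated = np.isfinite(values[iu])
        if not estimated.all():
            fill = float(np.mean(values[iu][estimated]))
            values[~np.isfinite(values)] = fill
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 1.0)
        np.fill_diagonal(support, self.n_loci_total)
        return RelatednessMatrix(
            samples=list(self.samples), values=values, locus_support=support
        )


def summarize_relatedness(
    m: RelatednessMatrix,
    regions: dict[str, str] | None = None,
    bins: int = 20,
) -> dict:
    """Distribution summary of the off-diagonal pairwise estimates.

    Returns min, quartiles, mean, max and histogram counts over the upper
    triangle; with a sample -> region mapping, adds the same per region
    (pairs with both members in the region).
    """

    def _summary(vals: np.ndarray) -> dict:
        counts, edges = np.histogram(vals, bins=bins)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {
            "n_pairs": int(vals.size),
            "min": float(vals.min()),
            "q1": float(q1),
            "median": float(med),
            "mean": float(vals.mean()),
            "q3": float(q3),
            "max": float(vals.max()),
            "hist_counts": counts.tolist(),
            "hist_edges": edges.tolist(),
        }

    out = {"all": _summary(m.offdiag())}
    if regions:
        for region in sorted(set(regions.values())):
            members = [s for s in m.samples if regions.get(s) == region]
            if len(members) >= 2:
                out[region] = _summary(m.subset(members).offdiag())
    return out
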