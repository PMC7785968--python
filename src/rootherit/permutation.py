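"""Triple-permutation significance test for rootstock-mediated heritability.

Three randomization strategies build null distributions of the posterior-
mean h^2, each destroying a different link in the genotype -> phenotype
chain while preserving its marginal structure:

PHENOTYPE           shuffle the trait vector across samples (design fixed);
MARKER_MATRIX       shuffle each SSR locus independently across samples
                    (allele frequencies preserved, multilocus identity
                    destroyed), then recompute relatedness and refit;
RELATEDNESS_MATRIX  apply one random sample permutation jointly to rows
                    and columns of the relatedness matrix (P M P'), which
                    preserves symmetry, the unit diagonal and the
                    eigenvalue spectrum.

The one-sided p-value is the proportion of permutations whose refitted
h^2 is strictly larger than the observed estimate; with n_perm
permutations p is a multiple of 1/n_perm and p = 0 is attainable.  A
trait is declared significant only when p < 0.05 simultaneously for all
three strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .genotypes import GenotypePanel, TraitTable
from .prediction import (
    GeneticPredictionModel,
    GibbsConfig,
    reduced_config,
)
from .relatedness import LocusContributions, RelatednessMatrix, relatedness_matrix

# cache per-locus contribution matrices for the marker-permutation null
# when the cache stays modest (n^2 * n_loci elements)
_CACHE_MAX_ELEMENTS = 50_000_000

ALPHA = 0.05


class Strategy(str, Enum):
    PHENOTYPE = "phenotype"
    MARKER_MATRIX = "marker_matrix"
    RELATEDNESS_MATRIX = "relatedness_matrix"


def permute_phenotype(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One full shuffle of the phenotype vector (without replacement)."""
    y = np.asarray(y)
    if len(y) < 2:
        raise ValueError("need at least 2 values to permute")
    return y[rng.permutation(len(y))]


def permute_marker_matrix(panel: GenotypePanel, rng: np.random.Generator) -> GenotypePanel:
    """Shuffle each locus's genotype calls independently across samples.

    Per-locus allele frequencies are invariant by construction; what is
    destroyed is the multilocus identity of each sample, and with it any
    genuine relatedness structure.
    """
    a1 = panel.allele1.copy()
    a2 = panel.allele2.copy()
    n = panel.n_samples
    for j in range(panel.n_loci):
        order = rng.permutation(n)
        a1[:, j] = a1[order, j]
        a2[:, j] = a2[order, j]
    return GenotypePanel(
        samples=list(panel.samples),
        loci=list(panel.loci),
        allele1=a1,
        allele2=a2,
        populations=list(panel.populations) if panel.populations else None,
    )


def permute_sample_rows(panel: GenotypePanel, rng: np.random.Generator) -> GenotypePanel:
    """Reassign whole multilocus genotypes to samples (one row shuffle).

    The marker-mode analogue of the joint relatedness-matrix relabeling:
    each sample keeps its phenotype but receives another sample's full
    genotype.
    """
    order = rng.permutation(panel.n_samples)
    return GenotypePanel(
        samples=list(panel.samples),
        loci=list(panel.loci),
        allele1=panel.allele1[order],
        allele2=panel.allele2[order],
        populations=list(panel.populations) if panel.populations else None,
    )


def permute_relatedness(m: RelatednessMatrix, rng: np.random.Generator) -> RelatednessMatrix:
    """Joint row/column permutation P M P' of the relatedness matrix."""
    order = rng.permutation(m.n_samples)
    return RelatednessMatrix(
        samples=list(m.samples),
        values=m.values[np.ix_(order, order)],
        locus_support=m.locus_support[np.ix_(order, order)],
    )


def permutation_pvalue(observed: float, nulls: np.ndarray) -> float:
    """Proportion of null h^2 values strictly larger than the observed."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("need at least one null value")
    return float(np.sum(nulls > observed) / nulls.size)


@dataclass
class PermutationReport:
    """Null distribution and p-value for one trait under one strategy."""

    trait: str
    strategy: Strategy
    observed_h2: float
    null_h2: np.ndarray
    observed_r: float
    seed: int | None

    @property
    def n_perm(self) -> int:
        return len(self.null_h2)

    @property
    def p_value(self) -> float:
        return permutation_pvalue(self.observed_h2, self.null_h2)


@dataclass
class SignificanceVerdict:
    """Combined verdict: significant iff all three p-values < 0.05."""

    trait: str
    p_values: dict[Strategy, float]

    @property
    def significant(self) -> bool:
        return all(p < ALPHA for p in self.p_values.values())


def run_significance(
    panel: GenotypePanel,
    m: RelatednessMatrix,
    traits: TraitTable,
    trait: str,
    config: GibbsConfig | None = None,
    n_perm: int = 50,
    seed: int | None = None,
    perm_config: GibbsConfig | None = None,
    mode: str = "relatedness",
) -> tuple[SignificanceVerdict, dict[Strategy, PermutationReport]]:
    """Observed fit plus the three permutation nulls for one trait.

    ``config`` governs the observed fit (full protocol by default);
    ``perm_config`` the permutation refits (default: the same config with
    chains shortened to 2,000 iterations / 1,000 burn-in).  One master
    seed spawns deterministic child seeds for the observed fit and every
    permutation, so the full report is reproducible from one integer.

    With ``mode="marker"`` the allele-dosage design replaces the
    relatedness design throughout; the third strategy then reassigns
    whole multilocus genotypes to samples, the design-side relabeling
    analogous to the joint matrix permutation.
    """
    cfg = config or GibbsConfig()
    pcfg = perm_config or reduced_config(cfg)

    ss = np.random.SeedSequence(seed)
    obs_seq, phen_seq, mark_seq, rel_seq = ss.spawn(4)

    source = m if mode == "relatedness" else panel
    model = GeneticPredictionModel.from_tables(source, traits, trait, mode=mode)
    res = model.fit(cfg, rng=np.random.default_rng(obs_seq))
    observed_h2 = res.h2_mean
    observed_r = res.r

    reports: dict[Strategy, PermutationReport] = {}

    # strategy 1: phenotype shuffles share the design, run as one batch
    rng = np.random.default_rng(phen_seq)
    Y = np.column_stack([permute_phenotype(model.y, rng) for _ in range(n_perm)])
    nulls_phen = model.fit_permuted_phenotypes(Y, pcfg, rng)
    reports[Strategy.PHENOTYPE] = PermutationReport(
        trait, Strategy.PHENOTYPE, observed_h2, nulls_phen, observed_r, seed
    )

    # strategy 2: per-locus shuffles, relatedness recomputed per permutation
    nulls_mark = np.empty(n_perm)
    cache = None
    if (
        mode == "relatedness"
        and panel.n_samples**2 * panel.n_loci <= _CACHE_MAX_ELEMENTS
    ):
        cache = LocusContributions.from_panel(panel)
    for b, child in enumerate(mark_seq.spawn(n_perm)):
        rng = np.random.default_rng(child)
        if mode == "relatedness":
            if cache is not None:
                src = cache.assemble(rng)
            else:
                src = relatedness_matrix(permute_marker_matrix(panel, rng))
        else:
            src = permute_marker_matrix(panel, rng)
        pm = GeneticPredictionModel.from_tables(src, traits, trait, mode=mode)
        nulls_mark[b] = pm.fit(pcfg, rng=rng).h2_mean
    reports[Strategy.MARKER_MATRIX] = PermutationReport(
        trait, Strategy.MARKER_MATRIX, observed_h2, nulls_mark, observed_r, seed
    )

    # strategy 3: joint row/column relabeling of the relatedness matrix
    nulls_rel = np.empty(n_perm)
    for b, child in enumerate(rel_seq.spawn(n_perm)):
        rng = np.random.default_rng(child)
        if mode == "relatedness":
            src = permute_relatedness(m, rng)
        else:
            src = permute_sample_rows(panel, rng)
        pm = GeneticPredictionModel.from_tables(src, traits, trait, mode=mode)
        nulls_rel[b] = pm.fit(pcfg, rng=rng).h2_mean
    reports[Strategy.RELATEDNESS_MATRIX] = PermutationReport(
        trait, Strategy.RELATEDNESS_MATRIX, observed_h2, nulls_rel, observed_r, seed
    )

    verdict = SignificanceVerdict(
        trait=trait,
        p_values={s: rep.p_value for s, rep in reports.items()},
    )
    return verdict, reports
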