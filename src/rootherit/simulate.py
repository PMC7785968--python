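"""Synthetic half-sib rootstock populations with known genetic ground truth.

The generator emulates the sampling design the analysis assumes: a set of
"plus-tree" donor mothers whose open-pollinated (OP) seed is raised in
nurseries and planted across orchards grouped into agroecological
regions.  Each tree's rootstock genotype is one maternal gamete from its
assigned donor plus one pollen gamete drawn from the panmictic pool, so
trees sharing a mother are paternal-unknown half sibs (expected additive
relatedness 0.25).  Donors are assigned to trees at random across
orchards, mimicking nurseries mixing seed lots.

Traits are additive: donor breeding values A ~ Normal(0, sigma_a^2), an
offspring inherits A/2 plus a Mendelian-sampling deviation
Normal(0, 3/4 sigma_a^2), and the phenotype is

    y = mu + region_shift + A + Normal(0, sigma_e^2)

with sigma_a^2 / (sigma_a^2 + sigma_e^2) equal to the configured true
h^2.  Region shifts are fixed effects excluded from the h^2 denominator
(the "within-environment" definition); the realized alternative including
them is recorded on the truth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel, TraitTable
from .relatedness import RelatednessMatrix


@dataclass
class SimulationConfig:
    """Population and trait-architecture settings.

    Defaults mirror the grafted-orchard study design: 3 agroecological
    regions holding 2 + 4 + 2 = 8 orchards of 30 trees (240 trees), 12
    plus-tree donors, and 13 SSR loci whose allele counts are drawn
    per-locus from {5..12} (set ``alleles_per_locus`` to fix them).
    ``trait_h2`` maps trait name -> true narrow-sense h^2.  Variances are
    on the phenotypic scale ``phenotypic_variance``; the region-shift SD
    is expressed in phenotypic-SD units.
    """

    n_regions: int = 3
    orchards_per_region: tuple[int, ...] = (2, 4, 2)
    trees_per_orchard: int = 30
    n_donors: int = 12
    n_loci: int = 13
    alleles_per_locus: int | None = None  # None -> per-locus draw from {5..12}
    trait_h2: dict[str, float] = field(default_factory=lambda: {"trait_1": 0.4})
    region_effect_sd: float = 0.5
    mu: float = 0.0
    phenotypic_variance: float = 1.0
    missing_genotype_rate: float = 0.0
    missing_phenotype_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.orchards_per_region) != self.n_regions:
            raise ValueError("orchards_per_region length must equal n_regions")
        for name, h2 in self.trait_h2.items():
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"true h2 for {name} must lie in [0, 1]")
        counts = [
            self.trees_per_orchard,
            self.n_donors,
            self.n_loci,
            *self.orchards_per_region,
        ]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        for rate in (self.missing_genotype_rate, self.missing_phenotype_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missing rates must lie in [0, 1]")
        if self.phenotypic_variance <= 0:
            raise ValueError("phenotypic variance must be positive")

    @property
    def n_trees(self) -> int:
        return self.trees_per_orchard * sum(self.orchards_per_region)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the simulator for recovery tests."""

    mothers: list[str]  # donor id per tree, aligned with samples
    samples: list[str]
    breeding_values: pd.DataFrame  # trees x traits
    donor_breeding_values: pd.DataFrame  # donors x traits
    true_h2: dict[str, float]
    realized_h2_with_region: dict[str, float]
    region_shifts: dict[str, float]
    allele_freqs: dict[str, dict[int, float]]

    def to_csv(self, path) -> None:
        out = pd.DataFrame({"tree": self.samples, "mother": self.mothers})
        for trait in self.breeding_values.columns:
            out[f"A_{trait}"] = self.breeding_values[trait].to_numpy()
        out.to_csv(path, index=False)


def _draw_locus_pools(cfg: SimulationConfig, rng: np.random.Generator):
    """Per-locus allele sizes and Dirichlet(1) frequencies."""
    pools = {}
    for l in range(cfg.n_loci):
        k = cfg.alleles_per_locus or int(rng.integers(5, 13))
        sizes = (100 + 4 * l + 2 * np.arange(k)).astype(int) + 50
        freqs = rng.dirichlet(np.ones(k))
        # keep every allele representable: renormalize away zeros
        freqs = np.clip(freqs, 1e-6, None)
        freqs = freqs / freqs.sum()
        pools[f"SSR{l + 1:02d}"] = (sizes, freqs)
    return pools


def simulate_population(
    cfg: SimulationConfig,
) -> tuple[GenotypePanel, TraitTable, SyntheticTruth]:
    """Generate a genotype panel, trait table and ground-truth record."""
    rng = np.random.default_rng(cfg.seed)
    pools = _draw_locus_pools(cfg, rng)
    loci = list(pools)
    n = cfg.n_trees
    sp2 = cfg.phenotypic_variance

    # orchard / region layout
    orchards: list[str] = []
    regions: list[str] = []
    region_names = [f"R{r + 1}" for r in range(cfg.n_regions)]
    o_idx = 0
    orchard_of_tree: list[str] = []
    region_of_tree: list[str] = []
    for r, n_orch in enumerate(cfg.orchards_per_region):
        for _ in range(n_orch):
            o_idx += 1
            name = f"O{o_idx}"
            orchards.append(name)
            regions.append(region_names[r])
            orchard_of_tree += [name] * cfg.trees_per_orchard
            region_of_tree += [region_names[r]] * cfg.trees_per_orchard
    samples = [f"T{i + 1:03d}" for i in range(n)]

    # donor mothers: HWE genotypes, random assignment across all orchards
    donors = [f"D{d + 1:02d}" for d in range(cfg.n_donors)]
    donor_a1 = np.zeros((cfg.n_donors, cfg.n_loci), dtype=np.int64)
    donor_a2 = np.zeros((cfg.n_donors, cfg.n_loci), dtype=np.int64)
    for j, locus in enumerate(loci):
        sizes, freqs = pools[locus]
        donor_a1[:, j] = rng.choice(sizes, size=cfg.n_donors, p=freqs)
        donor_a2[:, j] = rng.choice(sizes, size=cfg.n_donors, p=freqs)
    mother_idx = rng.integers(0, cfg.n_donors, size=n)

    # offspring genotype: maternal gamete + panmictic pollen gamete
    a1 = np.zeros((n, cfg.n_loci), dtype=np.int64)
    a2 = np.zeros((n, cfg.n_loci), dtype=np.int64)
    for j, locus in enumerate(loci):
        sizes, freqs = pools[locus]
        pick = rng.integers(0, 2, size=n)
        a1[:, j] = np.where(pick == 0, donor_a1[mother_idx, j], donor_a2[mother_idx, j])
        a2[:, j] = rng.choice(sizes, size=n, p=freqs)

    # region shifts (fixed effects, drawn once)
    shifts = rng.normal(0.0, cfg.region_effect_sd * np.sqrt(sp2), size=cfg.n_regions)
    region_shift = {name: float(s) for name, s in zip(region_names, shifts)}
    shift_vec = np.array([region_shift[r] for r in region_of_tree])

    # traits: donor A, half-sib transmission, environmental noise
    bv = {}
    donor_bv = {}
    values = {}
    realized_with_region = {}
    for trait, h2 in cfg.trait_h2.items():
        sa2 = h2 * sp2
        se2 = (1.0 - h2) * sp2
        A_donor = rng.normal(0.0, np.sqrt(sa2), size=cfg.n_donors)
        mendelian = rng.normal(0.0, np.sqrt(0.75 * sa2), size=n)
        A = 0.5 * A_donor[mother_idx] + mendelian
        e = rng.normal(0.0, np.sqrt(se2), size=n)
        y = cfg.mu + shift_vec + A + e
        bv[trait] = A
        donor_bv[trait] = A_donor
        values[trait] = y
        denom = sa2 + se2 + float(np.var(shift_vec, ddof=0))
        realized_with_region[trait] = sa2 / denom if denom > 0 else 0.0

    # missingness applied last
    if cfg.missing_genotype_rate > 0:
        mask = rng.random((n, cfg.n_loci)) < cfg.missing_genotype_rate
        a1[mask] = 0
        a2[mask] = 0
    value_df = pd.DataFrame(values, index=samples)
    if cfg.missing_phenotype_rate > 0:
        pmask = rng.random(value_df.shape) < cfg.missing_phenotype_rate
        value_df = value_df.mask(pmask)

    panel = GenotypePanel(samples=samples, loci=loci, allele1=a1, allele2=a2)
    traits = TraitTable(
        samples=samples,
        orchard=orchard_of_tree,
        region=region_of_tree,
        values=value_df,
    )
    truth = SyntheticTruth(
        mothers=[donors[i] for i in mother_idx],
        samples=samples,
        breeding_values=pd.DataFrame(bv, index=samples),
        donor_breeding_values=pd.DataFrame(donor_bv, index=donors),
        true_h2=dict(cfg.trait_h2),
        realized_h2_with_region=realized_with_region,
        region_shifts=region_shift,
        allele_freqs={
            locus: {int(s): float(f) for s, f in zip(*pools[locus])} for locus in loci
        },
    )
    return panel, traits, truth


def additive_relationship(truth: SyntheticTruth, a: str, b: str) -> float:
    """Expected additive relationship between two pedigree members.

    Donors are mutually unrelated founders; fathers are an untracked
    panmictic pollen pool; no inbreeding is modeled.
    """
    if a == b:
        return 1.0
    mothers = dict(zip(truth.samples, truth.mothers))
    a_is_tree = a in mothers
    b_is_tree = b in mothers
    if a_is_tree and b_is_tree:
        return 0.25 if mothers[a] == mothers[b] else 0.0
    if a_is_tree != b_is_tree:  # tree vs donor
        tree, donor = (a, b) if a_is_tree else (b, a)
        return 0.5 if mothers[tree] == donor else 0.0
    return 0.0  # two distinct donors


def pedigree_relatedness_oracle(truth: SyntheticTruth) -> RelatednessMatrix:
    """Numerator-relationship matrix over the simulated trees.

    Half sibs (shared mother) have expected additive relatedness 0.25,
    trees from different donors 0; the diagonal is 1 (no inbreeding).
    Serves as the independent oracle for marker-based estimates.
    """
    mother_idx = pd.factorize(np.array(truth.mothers))[0]
    same = mother_idx[:, None] == mother_idx[None, :]
    values = np.where(same, 0.25, 0.0)
    np.fill_diagonal(values, 1.0)
    n = len(truth.samples)
    return RelatednessMatrix(
        samples=list(truth.samples),
        values=values,
        locus_support=np.full((n, n), 0, dtype=int),
    )


def null_trait(
    cfg: SimulationConfig,
    seed: int | None = None,
    region_of_tree: list[str] | None = None,
    include_region_effect: bool = False,
) -> np.ndarray:
    """Pure-noise trait (true h^2 = 0) for calibration runs.

    Variance equals the configured phenotypic variance; an optional fixed
    region shift can be layered on when ``region_of_tree`` labels are
    supplied.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_trees if region_of_tree is None else len(region_of_tree)
    y = cfg.mu + rng.normal(0.0, np.sqrt(cfg.phenotypic_variance), size=n)
    if include_region_effect and region_of_tree is not None:
        names = sorted(set(region_of_tree))
        shifts = rng.normal(
            0.0, cfg.region_effect_sd * np.sqrt(cfg.phenotypic_variance), len(names)
        )
        table = dict(zip(names, shifts))
        y = y + np.array([table[r] for r in region_of_tree])
    return y
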