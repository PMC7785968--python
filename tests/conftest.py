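import numpy as np
import pytest

from rootherit.genotypes import AlleleFrequencyTable, GenotypePanel
from rootherit.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def study_like_population():
    """Default-scale population: 240 trees, 8 orchards, 3 regions, 13 loci."""
    cfg = SimulationConfig(seed=11, trait_h2={"t04": 0.4, "t00": 0.0})
    panel, traits, truth = simulate_population(cfg)
    return cfg, panel, traits, truth


@pytest.fixture(scope="session")
def dense_population():
    """300-tree population genotyped at 200 loci for tight relatedness."""
    cfg = SimulationConfig(
        seed=7,
        trait_h2={"t04": 0.4},
        n_loci=200,
        alleles_per_locus=8,
        trees_per_orchard=38,
        region_effect_sd=0.0,
    )
    panel, traits, truth = simulate_population(cfg)
    return cfg, panel, traits, truth


def paired_ritland(panel, freqs, n_pairs):
    """Ritland estimates for the pairs (i, i + n_pairs) of a pair panel,
    computed locus-vectorized (each pair touched directly, no full matrix)."""
    num = np.zeros(n_pairs)
    den = np.zeros(n_pairs)
    for j, locus in enumerate(panel.loci):
        table = freqs.freqs[locus]
        if len(table) < 2:
            continue
        alleles = np.fromiter(table.keys(), dtype=np.int64)
        p = np.fromiter(table.values(), dtype=float)
        w = len(table) - 1

        def dosage(a1, a2):
            return 0.5 * (
                (a1[:, None] == alleles[None, :]).astype(float)
                + (a2[:, None] == alleles[None, :])
            )

        q1 = dosage(panel.allele1[:n_pairs, j], panel.allele2[:n_pairs, j])
        q2 = dosage(panel.allele1[n_pairs:, j], panel.allele2[n_pairs:, j])
        r_l = (2.0 / w) * ((q1 / p * q2).sum(axis=1) - 1.0)
        num += w * r_l
        den += w
    return num / den


def make_pair_panel(kind: str, n_pairs: int, n_loci: int, seed: int):
    """Panel of 2*n_pairs samples where (i, i + n_pairs) form a known pair.

    kind: 'unrelated', 'half_sib', 'full_sib' or 'clone'.  Returns the
    panel together with the true per-locus allele-frequency table used to
    draw the genotypes.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_pairs
    a1 = np.zeros((n, n_loci), dtype=np.int64)
    a2 = np.zeros((n, n_loci), dtype=np.int64)
    freq_tables = {}
    loci = [f"L{j + 1:03d}" for j in range(n_loci)]
    for j, locus in enumerate(loci):
        k = 8
        sizes = 100 + 2 * np.arange(k)
        p = rng.dirichlet(np.ones(k))
        p = np.clip(p, 1e-6, None)
        p = p / p.sum()
        freq_tables[locus] = {int(s): float(f) for s, f in zip(sizes, p)}

        def gamete(size):
            return rng.choice(sizes, size=size, p=p)

        if kind == "unrelated":
            a1[:, j] = gamete(n)
            a2[:, j] = gamete(n)
        elif kind == "clone":
            g1, g2 = gamete(n_pairs), gamete(n_pairs)
            a1[:n_pairs, j] = g1
            a2[:n_pairs, j] = g2
            a1[n_pairs:, j] = g1
            a2[n_pairs:, j] = g2
        elif kind in ("half_sib", "full_sib"):
            m1, m2 = gamete(n_pairs), gamete(n_pairs)  # shared mother
            pick_a = rng.integers(0, 2, n_pairs)
            pick_b = rng.integers(0, 2, n_pairs)
            a1[:n_pairs, j] = np.where(pick_a == 0, m1, m2)
            a1[n_pairs:, j] = np.where(pick_b == 0, m1, m2)
            if kind == "half_sib":
                a2[:n_pairs, j] = gamete(n_pairs)
                a2[n_pairs:, j] = gamete(n_pairs)
            else:
                f1, f2 = gamete(n_pairs), gamete(n_pairs)  # shared father
                pick_a = rng.integers(0, 2, n_pairs)
                pick_b = rng.integers(0, 2, n_pairs)
                a2[:n_pairs, j] = np.where(pick_a == 0, f1, f2)
                a2[n_pairs:, j] = np.where(pick_b == 0, f1, f2)
        else:
            raise ValueError(kind)
    panel = GenotypePanel(
        samples=[f"S{i}" for i in range(n)], loci=loci, allele1=a1, allele2=a2
    )
    return panel, AlleleFrequencyTable(freqs=freq_tables)
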