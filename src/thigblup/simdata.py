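"""Synthetic genotypes and two-environment pseudo-phenotypes.

The generator emulates the data structure of a genotyped dairy-cow
population evaluated at two temperature-humidity-index (THI) levels: a
heat-comfort environment and a heat-stress environment. Pseudo-phenotypes
are breeding-value-scale records (one per animal per environment) built
from additive marker effects that are correlated across environments —
the genotype-by-environment signal the downstream bivariate GBLUP is
meant to pick up.

Defaults reproduce the scale of a ~1000-cow Holstein milk-yield
evaluation: 1013 animals, means 1.13 / 1.00 kg/day and phenotypic SDs
2.13 / 2.01 kg/day in the comfort / stress environments, with 80% of the
phenotypic variance additive-genetic (pseudo-phenotypes are prior-round
EBVs, hence high reliability) and a between-environment additive genetic
correlation of 0.99. Markers are simulated in linkage equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_ENV_LABELS,
    GenotypeMatrix,
    PseudoPhenotypeTable,
    TrueEffects,
)

__all__ = [
    "SimulationConfig",
    "compute_thi",
    "simulate_genotypes",
    "simulate_pseudo_phenotypes",
    "true_allele_frequencies",
]

#: spacing between adjacent marker positions within a chromosome (bp)
POSITION_STRIDE = 25_000


def compute_thi(temp, rh):
    """Temperature-humidity index from dry-bulb temperature and humidity.

    THI = (1.8*temp + 32) - (0.55 - 0.0055*rh) * (1.8*temp - 26)

    Parameters
    ----------
    temp : float or array
        Air temperature in degrees Celsius.
    rh : float or array
        Relative humidity in percent, in [0, 100].

    Returns
    -------
    float or ndarray
        The index value; 72 is the conventional comfort/heat-stress
        threshold for dairy cows.
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr < 0) or np.any(rh_arr > 100):
        raise ValueError("relative humidity must be in [0, 100] percent")
    t = np.asarray(temp, dtype=float)
    thi = (1.8 * t + 32.0) - (0.55 - 0.0055 * rh_arr) * (1.8 * t - 26.0)
    if np.isscalar(temp) and np.isscalar(rh):
        return float(thi)
    return thi


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic population.

    Attributes
    ----------
    n_animals, n_markers, n_chromosomes
        Population and panel size; markers are assigned round-robin to
        autosomes labelled "1".."n_chromosomes".
    maf_low, maf_high
        Bounds of the uniform distribution of the counted-allele
        frequency, both in (0, 0.5].
    missing_rate
        Probability of a missing call (missing completely at random).
    genetic_corr
        Correlation between the two environments' true marker effects.
    env_variances, noise_variances
        Per-environment additive-genetic and residual variance targets
        (trait units^2); phenotypic variance is their sum.
    trait_mean
        Per-environment phenotype means (trait units).
    seed
        Seed for all randomness; identical configs give identical data.
    """

    n_animals: int = 1013
    n_markers: int = 5000
    n_chromosomes: int = 29
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.0
    genetic_corr: float = 0.99
    env_variances: tuple[float, float] = (3.63, 3.23)
    noise_variances: tuple[float, float] = (0.91, 0.81)
    trait_mean: tuple[float, float] = (1.13, 1.00)
    env_labels: tuple[str, str] = DEFAULT_ENV_LABELS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (-1.0 <= self.genetic_corr <= 1.0):
            raise ValueError("genetic_corr must be in [-1, 1]")
        if any(v < 0 for v in self.env_variances) or any(
            v < 0 for v in self.noise_variances
        ):
            raise ValueError("variances must be non-negative")
        if self.n_animals < 2 or self.n_markers < 1 or self.n_chromosomes < 1:
            raise ValueError("need n_animals >= 2, n_markers >= 1, n_chromosomes >= 1")


def _marker_map(cfg: SimulationConfig) -> pd.DataFrame:
    """Round-robin chromosome assignment with fixed-stride positions."""
    idx = np.arange(cfg.n_markers)
    chrom = (idx % cfg.n_chromosomes) + 1
    pos = (idx // cfg.n_chromosomes + 1) * POSITION_STRIDE
    width = len(str(cfg.n_markers))
    return pd.DataFrame(
        {
            "marker_id": [f"SNP{i + 1:0{width}d}" for i in idx],
            "chromosome": chrom.astype(str),
            "position": pos.astype(np.int64),
        }
    )


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Draw an animals x markers dosage matrix under linkage equilibrium.

    Each marker gets an allele frequency p ~ U(maf_low, maf_high) and
    dosages Binomial(2, p) per animal (Hardy-Weinberg); missing calls
    are inserted at ``missing_rate``, completely at random.
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_markers)
    dosages = rng.binomial(2, p, size=(cfg.n_animals, cfg.n_markers)).astype(np.float64)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan
    width = len(str(cfg.n_animals))
    animal_ids = np.array(
        [f"A{i + 1:0{width}d}" for i in range(cfg.n_animals)], dtype=object
    )
    return GenotypeMatrix(dosages=dosages, animal_ids=animal_ids, marker_map=_marker_map(cfg))


def true_allele_frequencies(cfg: SimulationConfig):
    """The generating allele frequencies for a config (seed-determined).

    These are the p used by :func:`simulate_genotypes` for the same
    config, useful when downstream steps should center genotypes by the
    base-population frequencies rather than the observed ones (observed
    frequencies make the centered columns sum to zero, so the unblended
    relationship matrix is always singular; the generating frequencies
    avoid that).
    """
    from .datatypes import AlleleFrequencies

    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_markers)
    return AlleleFrequencies(
        p=p, marker_ids=_marker_map(cfg)["marker_id"].to_numpy()
    )


def _correlated_effect_pairs(rng: np.random.Generator, m: int, rho: float) -> np.ndarray:
    """Standardized effect pairs with correlation rho; exact rank-1 at |rho|=1."""
    z = rng.standard_normal((m, 2))
    if abs(rho) == 1.0:
        u = np.column_stack([z[:, 0], np.sign(rho) * z[:, 0]])
    else:
        u = np.column_stack([z[:, 0], rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]])
    return u


def simulate_pseudo_phenotypes(
    g: GenotypeMatrix, cfg: SimulationConfig
) -> tuple[PseudoPhenotypeTable, TrueEffects]:
    """Simulate breeding-value-scale records at both environments.

    Per-marker effect pairs are drawn from a bivariate normal with
    correlation ``genetic_corr`` and rescaled (one positive scalar per
    environment, so the correlation is untouched) so the realized total
    additive variance sum_i 2 p_i (1-p_i) u_i^2 equals ``env_variances``
    exactly, with p the observed allele frequencies of ``g``. The record
    for animal j in environment t is

        y_tj = trait_mean_t + sum_i (dosage_ji - 2 p_i) u_ti + e_tj,

    with independent Gaussian noise of variance ``noise_variances[t]``
    (missing dosages are mean-filled for the genetic term only).
    """
    obs = ~np.isnan(g.dosages)
    if not obs.any(axis=0).all():
        raise ValueError("genotype matrix has all-missing markers")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_919]))

    col_mean = np.nanmean(g.dosages, axis=0)
    p = col_mean / 2.0
    two_pq = 2.0 * p * (1.0 - p)

    u = _correlated_effect_pairs(rng, g.n_markers, cfg.genetic_corr)
    for t in range(2):
        target = cfg.env_variances[t]
        realized = float(two_pq @ (u[:, t] ** 2))
        if target == 0.0 or realized == 0.0:
            u[:, t] = 0.0
        else:
            u[:, t] *= np.sqrt(target / realized)

    filled = np.where(obs, g.dosages, col_mean)
    z = filled - 2.0 * p  # centered dosages
    genetic = z @ u  # (n_animals, 2)

    noise = rng.standard_normal((g.n_animals, 2)) * np.sqrt(
        np.asarray(cfg.noise_variances)
    )
    values = np.asarray(cfg.trait_mean) + genetic + noise

    records = pd.DataFrame(
        {
            "animal_id": np.repeat(g.animal_ids, 2),
            "env": np.tile(np.asarray(cfg.env_labels, dtype=object), g.n_animals),
            "value": values.ravel(),
        }
    )
    pheno = PseudoPhenotypeTable(data=records, env_labels=cfg.env_labels)
    truth = TrueEffects(marker_ids=g.marker_ids, effects=u, env_labels=cfg.env_labels)
    return pheno, truth
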