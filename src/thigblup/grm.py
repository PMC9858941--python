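"""Genomic relationship matrix (VanRaden method 1) and allele frequencies.

G = Z Z' / (2 * sum_i p_i (1 - p_i)), with Z the dosage matrix centered
by twice the allele frequencies. A small ridge ``blend_epsilon * I`` is
added to the diagonal so G is invertible for REML and the mixed-model
equations (no pedigree is in scope, so pedigree blending is not used).
Frequencies are the observed post-QC ones.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AlleleFrequencies, GenotypeMatrix, GRM

__all__ = ["allele_frequencies", "vanraden_g", "centered_dosages"]


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """Counted-allele frequency per marker: p = sum(dosage)/(2 n_observed)."""
    obs = ~np.isnan(g.dosages)
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = g.marker_ids[n_obs == 0]
        raise ValueError(f"markers with no observed calls: {list(bad[:5])}")
    total = np.where(obs, g.dosages, 0.0).sum(axis=0)
    return AlleleFrequencies(p=total / (2.0 * n_obs), marker_ids=g.marker_ids.copy())


def centered_dosages(g: GenotypeMatrix, freq: AlleleFrequencies) -> np.ndarray:
    """Z = M - 2P: dosages centered by twice the allele frequency."""
    if g.has_missing():
        raise ValueError("genotypes must be imputed (no missing) before centering")
    if not np.array_equal(g.marker_ids, freq.marker_ids):
        raise ValueError("frequency table does not match the genotype marker set")
    return g.dosages - 2.0 * freq.p


def vanraden_g(
    g: GenotypeMatrix,
    freq: AlleleFrequencies | None = None,
    blend_epsilon: float = 1e-6,
) -> GRM:
    """Build the genomic relationship matrix, method 1.

    Parameters
    ----------
    g
        Imputed genotype matrix (no missing entries).
    freq
        Allele frequencies used both for centering and for the
        2*sum(p(1-p)) denominator; computed from ``g`` when omitted.
    blend_epsilon
        Ridge added to the diagonal; 0 disables blending.

    Raises
    ------
    ValueError
        If any marker is monomorphic (p outside (0,1)) or the
        denominator is zero.
    """
    if freq is None:
        freq = allele_frequencies(g)
    p = freq.p
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        bad = g.marker_ids[(p <= 0.0) | (p >= 1.0)]
        raise ValueError(f"monomorphic markers (p not in (0,1)): {list(bad[:5])}")
    scale = 2.0 * float(np.sum(p * (1.0 - p)))
    if scale <= 0.0:
        raise ValueError("zero denominator: all markers monomorphic")
    z = centered_dosages(g, freq)
    mat = (z @ z.T) / scale
    mat = 0.5 * (mat + mat.T)  # enforce exact symmetry
    if blend_epsilon:
        mat[np.diag_indices_from(mat)] += blend_epsilon
    return GRM(
        matrix=mat,
        animal_ids=g.animal_ids.copy(),
        scale=scale,
        blend_epsilon=float(blend_epsilon),
    )
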