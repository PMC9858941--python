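"""Back-solving SNP effects from GEBVs and per-SNP explained variance.

For each environment the marker effects are recovered from the animal
solutions by

    u_hat = D Z' (Z D Z')^-1 a_hat,

with Z the column-centered dosage matrix (M - 2P, the same centering
used to build the relationship matrix, so Z D Z' is proportional to the
unblended G) and D a diagonal marker-weight matrix (identity here: a
single pass, no iterative reweighting). Each marker's explained
additive variance is 2 p (1 - p) u_hat^2, reported also as a percentage
of the environment's summed SNP variance — a comparison metric, not a
significance test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .datatypes import AlleleFrequencies, GEBVTable, GenotypeMatrix, SNPEffectTable
from .grm import centered_dosages

__all__ = ["backsolve_snp_effects", "explained_variance", "snp_effects_from_gebv"]


def backsolve_snp_effects(
    gebv: GEBVTable,
    g: GenotypeMatrix,
    freq: AlleleFrequencies,
    weights: np.ndarray | None = None,
) -> SNPEffectTable:
    """Recover per-marker effects for both environments from GEBVs.

    Parameters
    ----------
    gebv
        Animal solutions covering every animal in ``g``.
    g
        Imputed genotype matrix (no missing entries).
    freq
        Allele frequencies used for centering (must be the ones used to
        build the relationship matrix behind ``gebv``).
    weights
        Positive per-marker weights (the diagonal of D); all ones by
        default.

    Notes
    -----
    When Z D Z' is singular (e.g. more animals than effective markers)
    the Moore-Penrose pseudoinverse is used and the result is flagged
    via ``pseudo_inverse_used``.
    """
    z = centered_dosages(g, freq)
    n, m = z.shape
    if weights is None:
        d = np.ones(m)
    else:
        d = np.asarray(weights, float)
        if d.shape != (m,) or np.any(d <= 0):
            raise ValueError("weights must be positive, one per marker")

    a_mat = np.column_stack(
        [gebv.vector(env, g.animal_ids) for env in gebv.env_labels]
    )  # raises on animal mismatch

    zd = z * d
    k = zd @ z.T  # Z D Z', (n, n)
    flagged = False
    try:
        cf = sla.cho_factor(k, check_finite=False)
        t = sla.cho_solve(cf, a_mat, check_finite=False)
    except (sla.LinAlgError, np.linalg.LinAlgError):
        t = np.linalg.pinv(k) @ a_mat
        flagged = True
    u = d[:, None] * (z.T @ t)  # (m, 2)

    data = g.marker_map[["marker_id", "chromosome", "position"]].copy()
    for j, env in enumerate(gebv.env_labels):
        data[f"u_{env}"] = u[:, j]
    return SNPEffectTable(
        data=data, env_labels=gebv.env_labels, pseudo_inverse_used=flagged
    )


def explained_variance(
    effects: SNPEffectTable, freq: AlleleFrequencies
) -> SNPEffectTable:
    """Fill per-marker explained additive variance and its percentage.

    var_i = 2 p_i (1 - p_i) u_i^2 per environment; pct_i normalizes the
    variances to sum to 100 within each environment. Raises if an
    environment's effects are all zero (percentages undefined).
    """
    if not np.array_equal(effects.data["marker_id"].to_numpy(), freq.marker_ids):
        raise ValueError("frequency table does not match the effect table marker set")
    if np.any(freq.p <= 0.0) or np.any(freq.p >= 1.0):
        raise ValueError("allele frequencies must be strictly inside (0, 1)")
    two_pq = 2.0 * freq.p * (1.0 - freq.p)
    data = effects.data.copy()
    for env in effects.env_labels:
        u = data[f"u_{env}"].to_numpy()
        var = two_pq * u**2
        total = var.sum()
        if total <= 0.0:
            raise ValueError(
                f"all SNP effects are zero in environment {env!r}; "
                "percentage of explained variance is undefined"
            )
        data[f"var_{env}"] = var
        data[f"pct_{env}"] = 100.0 * var / total
    return SNPEffectTable(
        data=data,
        env_labels=effects.env_labels,
        pseudo_inverse_used=effects.pseudo_inverse_used,
    )


def snp_effects_from_gebv(
    gebv: GEBVTable,
    g: GenotypeMatrix,
    freq: AlleleFrequencies,
    weights: np.ndarray | None = None,
) -> SNPEffectTable:
    """Back-solve effects and fill explained variances in one call."""
    return explained_variance(backsolve_snp_effects(gebv, g, freq, weights), freq)
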