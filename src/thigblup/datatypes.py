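"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Genotypes are allele dosages of the counted allele (0/1/2), stored as
  ``float64`` with ``NaN`` marking missing calls; after imputation dosages
  may be fractional.
* The two environments are labelled ``env_labels = (env1, env2)``; the
  defaults follow the heat-comfort / heat-stress THI levels ("THI59",
  "THI74") used throughout dairy heat-stress work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_ENV_LABELS: tuple[str, str] = ("THI59", "THI74")

#: chromosome labels treated as sex chromosomes by QC
SEX_CHROMOSOMES: frozenset[str] = frozenset({"X", "Y"})


@dataclass
class GenotypeMatrix:
    """Animals x markers allele-dosage matrix with its marker map.

    Parameters
    ----------
    dosages
        ``(n_animals, n_markers)`` float array; entries in {0, 1, 2} or
        ``NaN`` (missing); fractional after mean imputation.
    animal_ids
        Unique animal identifiers, one per row.
    marker_map
        DataFrame indexed 0..m-1 with columns ``marker_id`` (unique),
        ``chromosome`` (string label, may include "X"/"Y") and
        ``position`` (1-based bp, strictly increasing within chromosome).
    """

    dosages: np.ndarray
    animal_ids: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D animals x markers array")
        n, m = self.dosages.shape
        if len(self.animal_ids) != n:
            raise ValueError(f"{len(self.animal_ids)} animal ids for {n} rows")
        if len(self.marker_map) != m:
            raise ValueError(f"marker map has {len(self.marker_map)} rows for {m} markers")
        for col in ("marker_id", "chromosome", "position"):
            if col not in self.marker_map.columns:
                raise ValueError(f"marker map lacks required column {col!r}")
        if self.marker_map["marker_id"].duplicated().any():
            raise ValueError("marker ids are not unique")
        if pd.Index(self.animal_ids).duplicated().any():
            raise ValueError("animal ids are not unique")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.marker_map["marker_id"].to_numpy()

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def subset(self, animal_idx=None, marker_idx=None) -> "GenotypeMatrix":
        """Row/column subset preserving order of the given indices."""
        ai = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(ai, mi)],
            animal_ids=self.animal_ids[ai],
            marker_map=self.marker_map.iloc[mi].reset_index(drop=True),
        )


@dataclass
class AlleleFrequencies:
    """Per-marker frequency of the counted allele, from observed calls."""

    p: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.p.shape != self.marker_ids.shape:
            raise ValueError("p and marker_ids differ in length")


@dataclass
class GRM:
    """Genomic relationship matrix (VanRaden method 1) with its metadata."""

    matrix: np.ndarray
    animal_ids: np.ndarray
    scale: float
    blend_epsilon: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        n = len(self.animal_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM matrix shape does not match animal ids")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)


@dataclass
class PseudoPhenotypeTable:
    """Long-format per-animal breeding values at the two environments.

    ``data`` columns: ``animal_id``, ``env``, ``value`` (optionally
    ``trait``). Each animal has at most one record per environment.
    """

    data: pd.DataFrame
    env_labels: tuple[str, str] = DEFAULT_ENV_LABELS

    def __post_init__(self) -> None:
        for col in ("animal_id", "env", "value"):
            if col not in self.data.columns:
                raise ValueError(f"phenotype table lacks column {col!r}")
        if self.data.duplicated(["animal_id", "env"]).any():
            raise ValueError("duplicate (animal, environment) records")
        extra = set(self.data["env"].unique()) - set(self.env_labels)
        if extra:
            raise ValueError(f"unknown environment labels: {sorted(extra)}")

    def pivot(self) -> pd.DataFrame:
        """Wide animals x env table (NaN where a record is absent)."""
        wide = self.data.pivot(index="animal_id", columns="env", values="value")
        return wide.reindex(columns=list(self.env_labels))

    def complete_case_ids(self) -> np.ndarray:
        wide = self.pivot()
        return wide.index[wide.notna().all(axis=1)].to_numpy()


@dataclass
class VarianceComponents:
    """REML estimates for the bivariate model.

    ``G0`` is the 2x2 additive-genetic covariance between the two
    environment-traits, ``R0`` the residual one; both in trait units^2.
    """

    G0: np.ndarray
    R0: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    env_labels: tuple[str, str] = DEFAULT_ENV_LABELS
    loglik_path: list = field(default_factory=list, repr=False)

    @property
    def genetic_correlation(self) -> float:
        d = np.sqrt(self.G0[0, 0] * self.G0[1, 1])
        return float(self.G0[0, 1] / d) if d > 0 else float("nan")

    @property
    def residual_correlation(self) -> float:
        d = np.sqrt(self.R0[0, 0] * self.R0[1, 1])
        return float(self.R0[0, 1] / d) if d > 0 else float("nan")


@dataclass
class GEBVTable:
    """Genomic breeding values per animal per environment.

    ``data`` columns: ``animal_id``, ``env``, ``gebv``; every animal in
    the GRM appears under both environments (animals without records get
    values through genomic relationships).
    """

    data: pd.DataFrame
    fixed_means: tuple[float, float]
    env_labels: tuple[str, str] = DEFAULT_ENV_LABELS

    def vector(self, env: str, animal_ids: np.ndarray) -> np.ndarray:
        """GEBVs for ``env`` ordered as ``animal_ids``."""
        sub = self.data[self.data["env"] == env].set_index("animal_id")["gebv"]
        missing = [a for a in animal_ids if a not in sub.index]
        if missing:
            raise ValueError(f"GEBV table lacks animals: {missing[:5]}...")
        return sub.reindex(animal_ids).to_numpy()


@dataclass
class SNPEffectTable:
    """Back-solved SNP effects and their explained additive variance.

    ``data`` columns: ``marker_id``, ``chromosome``, ``position`` plus,
    per environment label E, ``u_E`` (effect per allele copy), and once
    the variance step ran, ``var_E`` = 2p(1-p)u^2 and ``pct_E``
    (percentage of the environment's summed SNP variance).
    """

    data: pd.DataFrame
    env_labels: tuple[str, str] = DEFAULT_ENV_LABELS
    pseudo_inverse_used: bool = False

    def col(self, kind: str, env: str) -> str:
        return f"{kind}_{env}"


@dataclass
class TrueEffects:
    """Simulated ground-truth marker effects (for recovery tests)."""

    marker_ids: np.ndarray
    effects: np.ndarray  # (m, 2), trait units per allele copy
    env_labels: tuple[str, str] = DEFAULT_ENV_LABELS
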