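"""Genotype quality control: call-rate, MAF and Hardy-Weinberg filters.

Filter order mirrors common dairy-chip practice: animals first (call
rate), then markers — sex-chromosome removal, marker call rate, minor
allele frequency, and deviation from Hardy-Weinberg expectation, each
marker counted under the first rule that removes it. Frequencies for the
MAF and HWE rules are computed from observed (pre-imputation) calls on
the surviving animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import SEX_CHROMOSOMES, GenotypeMatrix

__all__ = ["QCReport", "filter_animals", "filter_markers", "impute_missing", "run_qc"]

RULE_ORDER = ("animal_call_rate", "sex_chromosome", "marker_call_rate", "maf", "hwe")


@dataclass
class QCReport:
    """Survivor counts and per-rule removal counts."""

    n_animals_in: int
    n_animals_out: int
    n_markers_in: int
    n_markers_out: int
    removed_by_rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rule in RULE_ORDER:
            self.removed_by_rule.setdefault(rule, 0)
        removed_animals = self.removed_by_rule["animal_call_rate"]
        removed_markers = sum(
            self.removed_by_rule[r] for r in RULE_ORDER if r != "animal_call_rate"
        )
        if self.n_animals_out != self.n_animals_in - removed_animals:
            raise ValueError("animal counts inconsistent with removals")
        if self.n_markers_out != self.n_markers_in - removed_markers:
            raise ValueError("marker counts inconsistent with removals")

    def to_dict(self) -> dict:
        return {
            "n_animals_in": self.n_animals_in,
            "n_animals_out": self.n_animals_out,
            "n_markers_in": self.n_markers_in,
            "n_markers_out": self.n_markers_out,
            "removed_by_rule": dict(self.removed_by_rule),
        }


def filter_animals(g: GenotypeMatrix, min_call_rate: float = 0.90) -> GenotypeMatrix:
    """Remove animals whose fraction of non-missing calls is below threshold.

    The rule is strict ("less than"): an animal at exactly the threshold
    is retained. Survivor order is preserved.
    """
    obs = ~np.isnan(g.dosages)
    call_rate = obs.mean(axis=1)
    keep = call_rate >= min_call_rate
    if not keep.any():
        raise ValueError("all animals removed by the call-rate filter")
    return g.subset(animal_idx=np.flatnonzero(keep))


def _observed_freq(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(p, n_observed) per marker from non-missing calls."""
    obs = ~np.isnan(dosages)
    n_obs = obs.sum(axis=0)
    total = np.where(obs, dosages, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = total / (2.0 * n_obs)
    return p, n_obs


def filter_markers(
    g: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.02,
    max_hwe_dev: float = 0.15,
    drop_sex_chromosomes: bool = True,
    sex_labels: frozenset = SEX_CHROMOSOMES,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the marker filters in fixed order and report removals.

    Rules, each strict and each marker counted once under the first rule
    that removes it:

    1. sex-chromosome markers (all of them, when enabled);
    2. call rate < ``min_call_rate``;
    3. minor allele frequency < ``min_maf``;
    4. Hardy-Weinberg deviation |het_obs - 2p(1-p)| > ``max_hwe_dev``.
    """
    m = g.n_markers
    removed = dict.fromkeys(RULE_ORDER, 0)
    alive = np.ones(m, dtype=bool)

    if drop_sex_chromosomes:
        on_sex = g.marker_map["chromosome"].astype(str).isin(sex_labels).to_numpy()
        removed["sex_chromosome"] = int(on_sex.sum())
        alive &= ~on_sex

    obs = ~np.isnan(g.dosages)
    call_rate = obs.mean(axis=0)
    low_call = alive & (call_rate < min_call_rate)
    removed["marker_call_rate"] = int(low_call.sum())
    alive &= ~low_call

    p, n_obs = _observed_freq(g.dosages)
    maf = np.minimum(p, 1.0 - p)
    low_maf = alive & (n_obs > 0) & (maf < min_maf)
    removed["maf"] = int(low_maf.sum())
    alive &= ~low_maf

    het_obs = np.where(obs, g.dosages == 1.0, False).sum(axis=0) / np.maximum(n_obs, 1)
    hwe_dev = np.abs(het_obs - 2.0 * p * (1.0 - p))
    bad_hwe = alive & (hwe_dev > max_hwe_dev)
    removed["hwe"] = int(bad_hwe.sum())
    alive &= ~bad_hwe

    if not alive.any():
        raise ValueError("all markers removed by QC filters")

    out = g.subset(marker_idx=np.flatnonzero(alive))
    report = QCReport(
        n_animals_in=g.n_animals,
        n_animals_out=g.n_animals,
        n_markers_in=m,
        n_markers_out=out.n_markers,
        removed_by_rule=removed,
    )
    return out, report


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker's mean observed dosage (2p).

    Produces fractional dosages; observed entries are untouched. Raises
    if any marker has no observed call.
    """
    obs = ~np.isnan(g.dosages)
    if not obs.any(axis=0).all():
        bad = g.marker_ids[~obs.any(axis=0)]
        raise ValueError(f"markers with no observed calls: {list(bad[:5])}")
    if obs.all():
        return g
    col_mean = np.nanmean(g.dosages, axis=0)
    filled = np.where(obs, g.dosages, col_mean)
    return GenotypeMatrix(
        dosages=filled, animal_ids=g.animal_ids, marker_map=g.marker_map.copy()
    )


def run_qc(
    g: GenotypeMatrix,
    min_animal_call_rate: float = 0.90,
    min_marker_call_rate: float = 0.90,
    min_maf: float = 0.02,
    max_hwe_dev: float = 0.15,
    drop_sex_chromosomes: bool = True,
    impute: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC pass: animal filter, marker filters, optional imputation."""
    n_in = g.n_animals
    g2 = filter_animals(g, min_call_rate=min_animal_call_rate)
    g3, report = filter_markers(
        g2,
        min_call_rate=min_marker_call_rate,
        min_maf=min_maf,
        max_hwe_dev=max_hwe_dev,
        drop_sex_chromosomes=drop_sex_chromosomes,
    )
    removed = dict(report.removed_by_rule)
    removed["animal_call_rate"] = n_in - g2.n_animals
    full = QCReport(
        n_animals_in=n_in,
        n_animals_out=g2.n_animals,
        n_markers_in=g.n_markers,
        n_markers_out=g3.n_markers,
        removed_by_rule=removed,
    )
    if impute:
        g3 = impute_missing(g3)
    return g3, full
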