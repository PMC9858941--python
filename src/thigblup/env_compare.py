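"""Two-environment comparison: top-k SNP quadrants, gene annotation,
direct genomic breeding values and reranking.

The comparison mirrors how genotype-by-environment signal is read off a
bi-trait genomic evaluation:

* the k markers with the largest percentage of explained additive
  variance are selected per environment; the truncation point T is the
  k-th largest percentage, and each marker falls in one of four
  quadrants (top in both, top in one only, top in neither);
* markers that differ between environments can be annotated against
  user-supplied gene intervals;
* direct genomic breeding values DBV = Z u_hat are recomputed from
  genotypes and SNP solutions alone, and animal rankings across
  environments are compared by Spearman correlation on the top 10%,
  top 40% and all animals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    AlleleFrequencies,
    GenotypeMatrix,
    SNPEffectTable,
)
from .grm import centered_dosages

__all__ = [
    "TopKComparison",
    "DBVTable",
    "RankCorrelationReport",
    "GeneIntervalSet",
    "top_k",
    "annotate_markers",
    "compute_dbv",
    "rank_correlations",
    "manhattan_table",
    "quadrant_table",
]

QUADRANTS = ("both", "only_env1", "only_env2", "neither")


def _chrom_sort_key(labels: pd.Series) -> pd.Series:
    """Numeric-aware chromosome ordering (1..29 before X, Y)."""
    num = pd.to_numeric(labels, errors="coerce")
    return pd.Series(
        list(zip(num.isna(), num.fillna(np.inf), labels.astype(str))),
        index=labels.index,
    )


@dataclass
class GeneIntervalSet:
    """Named 1-based inclusive genomic intervals."""

    data: pd.DataFrame  # columns: gene, chromosome, start, end

    def __post_init__(self) -> None:
        for col in ("gene", "chromosome", "start", "end"):
            if col not in self.data.columns:
                raise ValueError(f"gene table lacks column {col!r}")
        if (self.data["start"] > self.data["end"]).any():
            raise ValueError("gene intervals with start > end")
        if (self.data["start"] <= 0).any():
            raise ValueError("gene coordinates must be positive (1-based)")


@dataclass
class TopKComparison:
    """Top-k truncation-point comparison between the two environments."""

    k: int
    T_env1: float
    T_env2: float
    quadrant: pd.Series  # per marker_id, label in QUADRANTS
    n_common: int
    n_different: int
    per_chromosome: pd.DataFrame  # env, chromosome, n_top_snps, summed_pct
    env_labels: tuple[str, str]


@dataclass
class DBVTable:
    """Direct genomic breeding values, one row per genotyped animal."""

    data: pd.DataFrame  # animal_id + one dbv column per environment
    env_labels: tuple[str, str]


@dataclass
class RankCorrelationReport:
    """Spearman reranking summary per selection fraction.

    ``data`` columns: fraction, n_selected, spearman_rho,
    n_not_retained (animals top in env1 but not in env2's top set),
    plus the symmetric env2-selected columns, and a ``flagged`` marker
    for undefined correlations (constant DBVs).
    """

    data: pd.DataFrame
    env_labels: tuple[str, str]


def _top_indices(df: pd.DataFrame, pct_col: str, k: int) -> np.ndarray:
    """Indices of the k best markers: pct desc, chromosome asc, position asc."""
    order = df.assign(_ck=_chrom_sort_key(df["chromosome"])).sort_values(
        [pct_col, "_ck", "position"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return order.index.to_numpy()[:k]


def top_k(effects: SNPEffectTable, k: int = 50) -> TopKComparison:
    """Select the top-k markers per environment and assign quadrants.

    The truncation point per environment is the percentage of explained
    variance of the k-th selected marker. Quadrant labels follow set
    membership (identical to threshold comparison except for exact ties
    at T, which are broken deterministically by chromosome then
    position; a warning is emitted when such ties exist).
    """
    env1, env2 = effects.env_labels
    df = effects.data
    for env in (env1, env2):
        if f"pct_{env}" not in df.columns:
            raise ValueError("explained variance must be computed before top_k")
    if len(df) < k:
        raise ValueError(f"table has {len(df)} markers; need at least k={k}")

    sel = {}
    T = {}
    for env in (env1, env2):
        idx = _top_indices(df, f"pct_{env}", k)
        sel[env] = set(df.loc[idx, "marker_id"])
        T[env] = float(df.loc[idx[-1], f"pct_{env}"])
        n_at_t = int((df[f"pct_{env}"] == T[env]).sum())
        if n_at_t > 1 and (df[f"pct_{env}"] >= T[env]).sum() > k:
            warnings.warn(
                f"tie at the k-th explained-variance value in {env}; "
                "broken by (chromosome, position)",
                stacklevel=2,
            )

    in1 = df["marker_id"].isin(sel[env1])
    in2 = df["marker_id"].isin(sel[env2])
    label = np.where(
        in1 & in2, "both",
        np.where(in1, "only_env1", np.where(in2, "only_env2", "neither")),
    )
    quadrant = pd.Series(label, index=df["marker_id"].to_numpy(), name="quadrant")

    n_common = int((in1 & in2).sum())
    n_different = int((in1 ^ in2).sum())

    rows = []
    for env, mask in ((env1, in1), (env2, in2)):
        top = df[mask]
        agg = top.groupby("chromosome", sort=False).agg(
            n_top_snps=("marker_id", "size"), summed_pct=(f"pct_{env}", "sum")
        )
        agg = agg.reset_index()
        agg.insert(0, "env", env)
        rows.append(agg)
    per_chrom = pd.concat(rows, ignore_index=True)
    per_chrom = per_chrom.assign(_ck=_chrom_sort_key(per_chrom["chromosome"]))
    per_chrom = per_chrom.sort_values(["env", "_ck"]).drop(columns="_ck")
    per_chrom = per_chrom.reset_index(drop=True)

    return TopKComparison(
        k=k,
        T_env1=T[env1],
        T_env2=T[env2],
        quadrant=quadrant,
        n_common=n_common,
        n_different=n_different,
        per_chromosome=per_chrom,
        env_labels=effects.env_labels,
    )


def _format_distance(bp: int) -> str:
    return f"{round(bp / 1000)} kb"


def annotate_markers(
    markers: pd.DataFrame,
    genes: GeneIntervalSet,
    window: int = 600_000,
) -> pd.DataFrame:
    """Attach the containing or nearest gene (within ``window`` bp).

    ``markers`` needs columns marker_id, chromosome, position. A marker
    inside an interval gets relation "within" and distance 0; otherwise
    the nearest gene start/end within the window is reported with the
    distance and an "upstream" (before the gene start) or "downstream"
    (after the gene end) label on the forward axis — gene strand is not
    modelled. Markers with no gene in range stay unannotated (gene is
    NA); this is a valid outcome, not an error.
    """
    gdf = genes.data
    out = markers.copy()
    out["gene"] = pd.NA
    out["distance_bp"] = pd.NA
    out["relation"] = pd.NA
    out["annotation"] = pd.NA

    for i, row in out.iterrows():
        cand = gdf[gdf["chromosome"].astype(str) == str(row["chromosome"])]
        if cand.empty:
            continue
        pos = int(row["position"])
        start = cand["start"].to_numpy()
        end = cand["end"].to_numpy()
        inside = (start <= pos) & (pos <= end)
        if inside.any():
            # deterministic choice among overlapping genes: smallest interval
            j = np.flatnonzero(inside)
            j = j[np.argmin((end - start)[j])]
            out.loc[i, ["gene", "distance_bp", "relation", "annotation"]] = [
                cand.iloc[j]["gene"], 0, "within", "within",
            ]
            continue
        dist = np.where(pos < start, start - pos, pos - end)
        j = int(np.argmin(dist))
        if dist[j] <= window:
            rel = "upstream" if pos < start[j] else "downstream"
            out.loc[i, ["gene", "distance_bp", "relation", "annotation"]] = [
                cand.iloc[j]["gene"],
                int(dist[j]),
                rel,
                f"{_format_distance(int(dist[j]))} {rel}",
            ]
    return out


def compute_dbv(
    g: GenotypeMatrix, effects: SNPEffectTable, freq: AlleleFrequencies
) -> DBVTable:
    """Direct genomic breeding values DBV = Z u_hat per environment.

    ``g`` must be imputed and is centered with the same frequencies used
    in back-solving, so on a full-rank unblended system DBV reproduces
    the GEBVs exactly.
    """
    gm = set(g.marker_ids)
    em = set(effects.data["marker_id"])
    if gm != em:
        diff = sorted(gm ^ em)
        raise ValueError(
            f"marker sets differ between genotypes and effects: {diff[:10]}"
            + ("..." if len(diff) > 10 else "")
        )
    eff = effects.data.set_index("marker_id").loc[g.marker_ids]
    z = centered_dosages(g, freq)
    data = pd.DataFrame({"animal_id": g.animal_ids})
    for env in effects.env_labels:
        data[f"dbv_{env}"] = z @ eff[f"u_{env}"].to_numpy()
    return DBVTable(data=data, env_labels=effects.env_labels)


def _rank_stats(dbv_df, env_sel, env_other, fractions):
    """Selection by env_sel's DBV; Spearman between both envs' values."""
    n = len(dbv_df)
    rows = []
    ranked = dbv_df.sort_values(
        [f"dbv_{env_sel}", "animal_id"], ascending=[False, True], kind="mergesort"
    )
    ranked_other = dbv_df.sort_values(
        [f"dbv_{env_other}", "animal_id"], ascending=[False, True], kind="mergesort"
    )
    for f in fractions:
        n_sel = max(1, math.ceil(f * n))
        top = ranked.head(n_sel)
        top_other = set(ranked_other.head(n_sel)["animal_id"])
        x = top[f"dbv_{env_sel}"].to_numpy()
        y_ = top[f"dbv_{env_other}"].to_numpy()
        flagged = bool(np.ptp(x) == 0 or np.ptp(y_) == 0 or n_sel < 2)
        rho = float("nan") if flagged else float(sps.spearmanr(x, y_).statistic)
        n_lost = int(sum(a not in top_other for a in top["animal_id"]))
        rows.append((f, n_sel, rho, n_lost, flagged))
    return rows


def rank_correlations(
    dbv: DBVTable, fractions: tuple[float, ...] = (0.10, 0.40, 1.00)
) -> RankCorrelationReport:
    """Spearman reranking of animals between the two environments.

    For each fraction f, the ceil(f*n) animals with the highest
    environment-1 DBV are selected and the correlation between their
    DBVs in the two environments is reported, along with how many of
    them fall outside environment 2's own top set. The symmetric
    selection by environment 2 is reported in the ``*_env2sel`` columns.
    Constant DBVs make rho undefined; such rows are flagged, not raised.
    """
    if len(dbv.data) < 10:
        raise ValueError("need at least 10 animals for reranking analysis")
    env1, env2 = dbv.env_labels
    primary = _rank_stats(dbv.data, env1, env2, fractions)
    secondary = _rank_stats(dbv.data, env2, env1, fractions)
    data = pd.DataFrame(
        {
            "fraction": [r[0] for r in primary],
            "n_selected": [r[1] for r in primary],
            "spearman_rho": [r[2] for r in primary],
            "n_not_retained": [r[3] for r in primary],
            "flagged": [r[4] for r in primary],
            "spearman_rho_env2sel": [r[2] for r in secondary],
            "n_not_retained_env2sel": [r[3] for r in secondary],
        }
    )
    return RankCorrelationReport(data=data, env_labels=dbv.env_labels)


def manhattan_table(effects: SNPEffectTable) -> pd.DataFrame:
    """Long-format plot-ready table with genome-wide cumulative positions."""
    df = effects.data
    chroms = df[["chromosome"]].drop_duplicates()
    chroms = chroms.assign(_ck=_chrom_sort_key(chroms["chromosome"]))
    chrom_order = chroms.sort_values("_ck")["chromosome"].tolist()
    offsets = {}
    running = 0
    for c in chrom_order:
        offsets[c] = running
        running += int(df.loc[df["chromosome"] == c, "position"].max())
    rows = []
    for env in effects.env_labels:
        part = df[["marker_id", "chromosome", "position", f"pct_{env}"]].copy()
        part = part.rename(columns={f"pct_{env}": "pct_var"})
        part["cumulative_position"] = part["position"] + part["chromosome"].map(offsets)
        part["env"] = env
        rows.append(part)
    return pd.concat(rows, ignore_index=True)


def quadrant_table(cmp: TopKComparison, effects: SNPEffectTable) -> pd.DataFrame:
    """Scatter-ready table: per marker, both pct values and the quadrant."""
    env1, env2 = effects.env_labels
    df = effects.data[["marker_id", f"pct_{env1}", f"pct_{env2}"]].copy()
    df = df.rename(columns={f"pct_{env1}": "pct_env1", f"pct_{env2}": "pct_env2"})
    df["quadrant"] = df["marker_id"].map(cmp.quadrant)
    return df
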