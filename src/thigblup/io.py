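"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
* dosage TSV: header row of marker names, first column of animal IDs,
  entries 0/1/2 (or fractional after imputation), ``NA`` for missing;
  accompanied by a marker-map TSV (marker_id, chromosome, position);
* PLINK-style .ped/.map pair (alleles A/B coding, "0 0" for missing);
* phenotype CSV: animal_id, trait, environment, value;
* GRM TSV with animal IDs plus a JSON sidecar (scale, blend epsilon);
* variance components and QC reports as JSON; effects/GEBV/DBV as TSV;
* gene intervals as BED (0-based half-open, converted to 1-based
  inclusive) or a 4-column TSV (gene, chromosome, start, end).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GEBVTable,
    GRM,
    GenotypeMatrix,
    PseudoPhenotypeTable,
    SNPEffectTable,
    TrueEffects,
    VarianceComponents,
)
from .env_compare import DBVTable, GeneIntervalSet, RankCorrelationReport, TopKComparison
from .genotype_qc import QCReport

__all__ = [
    "write_dosage_tsv", "read_dosage_tsv",
    "write_ped_map", "read_ped_map",
    "write_phenotypes_csv", "read_phenotypes_csv",
    "write_true_effects_tsv",
    "write_grm", "read_grm",
    "write_variance_components", "read_variance_components",
    "write_gebv_tsv", "read_gebv_tsv",
    "write_effects_tsv", "read_effects_tsv",
    "write_qc_report",
    "read_gene_bed", "read_gene_table",
    "write_comparison_summary",
]


# -- genotypes ---------------------------------------------------------------

def write_dosage_tsv(g: GenotypeMatrix, matrix_path, map_path) -> None:
    df = pd.DataFrame(g.dosages, index=g.animal_ids, columns=g.marker_ids)
    df.index.name = "animal_id"
    df.to_csv(matrix_path, sep="\t", na_rep="NA", float_format="%.6g")
    g.marker_map.to_csv(map_path, sep="\t", index=False)


def read_dosage_tsv(matrix_path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA"])
    marker_map = pd.read_csv(map_path, sep="\t", dtype={"chromosome": str})
    if list(df.columns) != list(marker_map["marker_id"]):
        raise ValueError("dosage matrix columns do not match the marker map")
    return GenotypeMatrix(
        dosages=df.to_numpy(float),
        animal_ids=df.index.to_numpy(object),
        marker_map=marker_map,
    )


def write_ped_map(g: GenotypeMatrix, ped_path, map_path) -> None:
    """PLINK .ped/.map pair; dosage 0/1/2 -> 'A A'/'A B'/'B B', missing '0 0'."""
    codes = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(g.animal_ids):
            row = g.dosages[i]
            geno = [
                "0 0" if np.isnan(v) else codes.get(float(round(v)), "0 0")
                for v in row
            ]
            fh.write(f"FAM1 {aid} 0 0 0 -9 " + " ".join(geno) + "\n")
    with open(map_path, "w") as fh:
        for _, r in g.marker_map.iterrows():
            fh.write(f"{r['chromosome']} {r['marker_id']} 0 {r['position']}\n")


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chromosome", "marker_id", "cm", "position"], dtype={"chromosome": str},
    )
    marker_map = mp[["marker_id", "chromosome", "position"]].copy()
    animal_ids, rows = [], []
    code = {("A", "A"): 0.0, ("A", "B"): 1.0, ("B", "A"): 1.0, ("B", "B"): 2.0}
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            animal_ids.append(parts[1])
            alleles = parts[6:]
            row = [
                code.get((alleles[2 * j], alleles[2 * j + 1]), np.nan)
                for j in range(len(alleles) // 2)
            ]
            rows.append(row)
    return GenotypeMatrix(
        dosages=np.asarray(rows, float),
        animal_ids=np.asarray(animal_ids, object),
        marker_map=marker_map,
    )


# -- phenotypes and effects --------------------------------------------------

def write_phenotypes_csv(
    pheno: PseudoPhenotypeTable, path, trait: str = "trait"
) -> None:
    df = pheno.data.copy()
    if "trait" not in df.columns:
        df.insert(1, "trait", trait)
    df = df.rename(columns={"env": "environment"})
    df.to_csv(path, index=False)


def read_phenotypes_csv(path, env_labels=None) -> PseudoPhenotypeTable:
    df = pd.read_csv(path).rename(columns={"environment": "env"})
    labels = tuple(env_labels) if env_labels else tuple(pd.unique(df["env"]))
    if len(labels) != 2:
        raise ValueError(f"expected exactly two environments, found {labels}")
    return PseudoPhenotypeTable(
        data=df[["animal_id", "env", "value"]].copy(), env_labels=labels
    )


def write_true_effects_tsv(truth: TrueEffects, path) -> None:
    df = pd.DataFrame(
        {
            "marker_id": truth.marker_ids,
            f"u_true_{truth.env_labels[0]}": truth.effects[:, 0],
            f"u_true_{truth.env_labels[1]}": truth.effects[:, 1],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# -- GRM ---------------------------------------------------------------------

def write_grm(grm: GRM, matrix_path, sidecar_path) -> None:
    df = pd.DataFrame(grm.matrix, index=grm.animal_ids, columns=grm.animal_ids)
    df.index.name = "animal_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.10g")
    Path(sidecar_path).write_text(
        json.dumps({"scale": grm.scale, "blend_epsilon": grm.blend_epsilon}, indent=2)
    )


def read_grm(matrix_path, sidecar_path) -> GRM:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = json.loads(Path(sidecar_path).read_text())
    return GRM(
        matrix=df.to_numpy(float),
        animal_ids=df.index.to_numpy(object),
        scale=float(meta["scale"]),
        blend_epsilon=float(meta["blend_epsilon"]),
    )


# -- model outputs -----------------------------------------------------------

def write_variance_components(vc: VarianceComponents, path) -> None:
    payload = {
        "env_labels": list(vc.env_labels),
        "G0": np.asarray(vc.G0).tolist(),
        "R0": np.asarray(vc.R0).tolist(),
        "genetic_correlation": vc.genetic_correlation,
        "residual_correlation": vc.residual_correlation,
        "loglik": vc.loglik,
        "n_iter": vc.n_iter,
        "converged": vc.converged,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_variance_components(path) -> VarianceComponents:
    d = json.loads(Path(path).read_text())
    return VarianceComponents(
        G0=np.asarray(d["G0"], float),
        R0=np.asarray(d["R0"], float),
        loglik=float(d["loglik"]),
        n_iter=int(d["n_iter"]),
        converged=bool(d["converged"]),
        env_labels=tuple(d["env_labels"]),
    )


def write_gebv_tsv(gebv: GEBVTable, path) -> None:
    df = gebv.data.copy()
    df.attrs = {}
    df.to_csv(path, sep="\t", index=False)


def read_gebv_tsv(path, fixed_means=(float("nan"), float("nan")), env_labels=None) -> GEBVTable:
    df = pd.read_csv(path, sep="\t")
    labels = tuple(env_labels) if env_labels else tuple(pd.unique(df["env"]))
    return GEBVTable(data=df, fixed_means=tuple(fixed_means), env_labels=labels)


def write_effects_tsv(effects: SNPEffectTable, path) -> None:
    effects.data.to_csv(path, sep="\t", index=False)


def read_effects_tsv(path, env_labels=None) -> SNPEffectTable:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if env_labels is None:
        env_labels = tuple(
            c[len("u_"):] for c in df.columns if c.startswith("u_") and not c.startswith("u_true")
        )
    return SNPEffectTable(data=df, env_labels=tuple(env_labels))


def write_qc_report(report: QCReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


# -- gene intervals ----------------------------------------------------------

def read_gene_bed(path) -> GeneIntervalSet:
    """BED (0-based half-open): chrom, start, end, name -> 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chromosome", "start", "end", "gene"],
        usecols=[0, 1, 2, 3], dtype={0: str},
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return GeneIntervalSet(data=df[["gene", "chromosome", "start", "end"]])


def read_gene_table(path) -> GeneIntervalSet:
    """4-column TSV (gene, chromosome, start, end), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return GeneIntervalSet(data=df[["gene", "chromosome", "start", "end"]])


# -- comparison summary ------------------------------------------------------

def write_comparison_summary(
    cmp: TopKComparison, report: RankCorrelationReport, path
) -> None:
    payload = {
        "k": cmp.k,
        "env_labels": list(cmp.env_labels),
        "truncation_points": {
            cmp.env_labels[0]: cmp.T_env1,
            cmp.env_labels[1]: cmp.T_env2,
        },
        "n_common": cmp.n_common,
        "n_different": cmp.n_different,
        "rank_correlations": report.data.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
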