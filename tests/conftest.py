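import numpy as np
import pandas as pd
import pytest

import thigblup as tg

ENV1, ENV2 = tg.DEFAULT_ENV_LABELS


def make_genotypes(dosages, chromosomes=None, positions=None, animal_ids=None):
    """Hand-built GenotypeMatrix from a nested list (None -> missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in dosages]
    )
    n, m = arr.shape
    if chromosomes is None:
        chromosomes = ["1"] * m
    if positions is None:
        positions = [(i + 1) * 1000 for i in range(m)]
    if animal_ids is None:
        animal_ids = [f"A{i+1}" for i in range(n)]
    mm = pd.DataFrame(
        {
            "marker_id": [f"M{i+1}" for i in range(m)],
            "chromosome": [str(c) for c in chromosomes],
            "position": positions,
        }
    )
    return tg.GenotypeMatrix(
        dosages=arr, animal_ids=np.array(animal_ids, object), marker_map=mm
    )


def make_phenotypes(animal_ids, y1, y2):
    rec = pd.DataFrame(
        {
            "animal_id": list(animal_ids) * 2,
            "env": [ENV1] * len(animal_ids) + [ENV2] * len(animal_ids),
            "value": list(y1) + list(y2),
        }
    )
    return tg.PseudoPhenotypeTable(data=rec)


@pytest.fixture(scope="session")
def pipeline():
    """Moderate simulated dataset run through the full pipeline once."""
    cfg = tg.SimulationConfig(
        n_animals=300, n_markers=800, seed=3, genetic_corr=0.9,
        env_variances=(1.0, 1.0), noise_variances=(0.25, 0.25), trait_mean=(0.5, 0.4),
    )
    g = tg.simulate_genotypes(cfg)
    pheno, truth = tg.simulate_pseudo_phenotypes(g, cfg)
    freq = tg.allele_frequencies(g)
    G = tg.vanraden_g(g, freq)
    vc = tg.fit_greml(pheno, G)
    gebv = tg.solve_mme(pheno, G, vc)
    effects = tg.snp_effects_from_gebv(gebv, g, freq)
    dbv = tg.compute_dbv(g, effects, freq)
    return {
        "cfg": cfg, "g": g, "pheno": pheno, "truth": truth, "freq": freq,
        "G": G, "vc": vc, "gebv": gebv, "effects": effects, "dbv": dbv,
    }
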