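"""Parameter-recovery experiments on synthetic data.

Each experiment regenerates datasets from scratch under the generator's
default study conditions (scaled down where a design is replicated many
times), runs the corresponding inference, and reports a recovery rate.
Problem sizes: replicated designs use 2 wells x 5 depths x 2 replicates
(20 samples) and 128 taxa with 99-draw nulls and 199-permutation Mantel
tests, which keeps a full battery within a few minutes on one CPU while
leaving each single test well powered.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .community import rarefy, relative_abundance
from .dissimilarity import env_delta_matrix, forward_select_distance
from .envstats import forward_select_aicc
from .simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_env_and_biomass,
    simulate_richness_regression,
    simulate_well_logs,
)
from .turnover import bnti

#: Candidate covariates offered to the distance-matrix forward selection.
DELTA_CANDIDATES = (
    "FeII_umol_g",
    "pH",
    "mica_pct",
    "anorthoclase_pct",
    "organic_C_pct",
    "porosity",
)

REPLICATED_DESIGN = dict(
    n_wells=2, depths_per_well=5, replicates_per_depth=2, n_taxa=128
)


def _seeds(master_seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(master_seed).spawn(n)]


def _between_facies_values(result, facies: pd.Series) -> np.ndarray:
    ids = result.sample_ids
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pair = {facies[ids[i]], facies[ids[j]]}
            if pair == {"oxidized", "reduced"}:
                out.append(result.bnti.iloc[i, j])
    return np.asarray(out)


def strong_selection_bnti(seed: int, n_seeds: int = 50,
                          n_null: int = 99, n_perm: int = 199) -> dict:
    """Selection signal and driver recovery under strong niche selection.

    For each replicate dataset: betaNTI across all sample pairs, the
    median betaNTI between oxidized and reduced samples, and whether
    Mantel forward selection over the environmental delta matrices picks
    the redox-axis variable (Fe(II)) first.
    """
    medians = []
    redox_first = 0
    for s in _seeds(seed, n_seeds):
        config = SimulationConfig(seed=s, **REPLICATED_DESIGN)
        dataset = simulate_dataset(config)
        rel = relative_abundance(rarefy(dataset.otu_table, seed=s))
        result = bnti(rel, dataset.tree, n_null=n_null, seed=s)
        facies = dataset.metadata.facies()
        medians.append(float(np.nanmedian(_between_facies_values(result, facies))))
        meta = dataset.metadata.subset(result.sample_ids)
        candidates = {v: env_delta_matrix(meta, v) for v in DELTA_CANDIDATES}
        selection = forward_select_distance(
            result.to_distance_matrix(), candidates, n_perm=n_perm, seed=s
        )
        redox_first += bool(selection.selected) and (
            selection.selected[0] == "FeII_umol_g"
        )
    return {
        "median_between_facies_bnti": medians[0],
        "median_between_facies_bnti_all": medians,
        "redox_first_rate": redox_first / n_seeds,
        "n_seeds": n_seeds,
    }


def neutral_bnti_fraction(seed: int, n_seeds: int = 20, n_null: int = 99) -> dict:
    """Fraction of pairs with |betaNTI| < 2 under neutral assembly
    (infinite niche breadth), pooled over replicate datasets."""
    inside = 0
    total = 0
    for s in _seeds(seed, n_seeds):
        config = SimulationConfig(
            seed=s, selection_strength=math.inf, **REPLICATED_DESIGN
        )
        dataset = simulate_dataset(config)
        rel = relative_abundance(rarefy(dataset.otu_table, seed=s))
        result = bnti(rel, dataset.tree, n_null=n_null, seed=s)
        z = result.bnti.to_numpy()[np.triu_indices(len(result.sample_ids), 1)]
        z = z[np.isfinite(z)]
        inside += int((np.abs(z) < 2).sum())
        total += len(z)
    return {"fraction_abs_bnti_lt_2": inside / total, "n_pairs": total,
            "n_seeds": n_seeds}


def richness_recovery_rate(seed: int, n_reps: int = 100, n_samples: int = 18,
                           n_decoys: int = 6, r_squared: float = 0.65) -> dict:
    """How often AICc forward selection recovers both planted richness
    predictors (pH and the mineral) among decoy candidates."""
    both = 0
    clean = 0
    for s in _seeds(seed, n_reps):
        response, candidates, truth = simulate_richness_regression(
            seed=s, n_samples=n_samples, n_decoys=n_decoys, r_squared=r_squared
        )
        result = forward_select_aicc(response, candidates)
        recovered = set(truth) <= set(result.selected)
        both += recovered
        clean += recovered and set(result.selected) == set(truth)
    return {
        "both_recovered_rate": both / n_reps,
        "exact_model_rate": clean / n_reps,
        "n_reps": n_reps,
    }


def biomass_fold_rate(seed: int, n_seeds: int = 100) -> dict:
    """How often the realized transition/reduced median biomass ratio
    falls in the 10-20x band the generator targets (fold 15)."""
    hits = 0
    folds = []
    for s in _seeds(seed, n_seeds):
        config = SimulationConfig(seed=s)
        logs = simulate_well_logs(config, seed=s)
        metadata, _ = simulate_env_and_biomass(config, logs, seed=s + 1)
        frame = metadata.frame
        fold = (
            frame.loc[frame.facies == "transition", "copies_per_g"].median()
            / frame.loc[frame.facies == "reduced", "copies_per_g"].median()
        )
        folds.append(float(fold))
        hits += 10.0 <= fold <= 20.0
    return {"within_band_rate": hits / n_seeds, "first_fold": folds[0],
            "n_seeds": n_seeds}
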