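"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a vertically structured aquitard sampled by a
few boreholes: an oxidized facies below a stratigraphic contact, a thin
redox transition band, and a reduced facies beneath it. On top of that
geometry it simulates

* a Yule phylogeny over the taxon pool,
* phylogenetically conserved niche optima (Brownian motion on the tree)
  on a single redox axis,
* multinomial community sampling with a Gaussian niche filter, so that
  finite niche breadth plus conserved optima produces a betaNTI signal
  and the infinite-breadth limit recovers neutral assembly,
* facies-structured geochemistry (Fe(II) and pH higher in the reduced
  facies, one mineral trending with elevation),
* a biomass hotspot at the transition (configurable fold over the
  reduced facies, lognormal within facies), and
* a richness covariate generated from a linear model in pH and one
  mineral.

Every draw descends from a single integer seed through
``numpy.random.SeedSequence`` spawning, so full dataset generation is
bit-reproducible, and a truth record retains everything needed to score
downstream inference (per-taxon optima, true facies, true surfaces,
true regression coefficients).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (
    OtuTable,
    SampleMetadata,
    ValidationError,
    WellLog,
    write_metadata,
    write_otu_table,
    write_tree,
    write_well_logs,
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults describe the study conditions the analysis expects:
    4 wells x 5 depths x 4 replicates (~80 samples), 256 taxa, reads per
    sample at the rarefaction depth of 1000, a 10-20x biomass hotspot at
    the transition (target fold 15), and surfaces in the 96-100 m
    elevation range.
    """

    seed: int = 0
    n_taxa: int = 256
    n_wells: int = 4
    depths_per_well: int = 5
    replicates_per_depth: int = 4
    reads_per_sample: int = 1000
    # niche model
    selection_strength: float = 0.15  # sigma of the Gaussian niche on [0, 1]
    niche_conservatism: float = 1.0  # Brownian-motion rate for optima
    abundance_lognormal_sd: float = 1.5  # metacommunity rank-abundance spread
    # biomass profile (log10 copies/g)
    biomass_fold_transition: float = 15.0
    biomass_fold_oxidized: float = 4.0
    biomass_log10_reduced: float = 6.8
    biomass_log10_sd: float = 0.15
    # richness linear model: richness ~ pH + anorthoclase
    richness_intercept: float = 600.0
    richness_coef_ph: float = -40.0
    richness_coef_mineral: float = 12.0
    richness_noise_sd: float = 14.4  # population R^2 = 0.65 under defaults
    # well-log geometry (meters)
    contact_elev: float = 98.5
    transition_elev: float = 97.3
    surface_trend: tuple[float, float] = (0.005, -0.003)  # dz/dx, dz/dy
    surface_noise_sd: float = 0.15
    well_spacing_m: float = 20.0
    band_halfwidth: float = 0.25
    sample_span_m: float = 0.9  # samples at rel elevations +/- this span

    def __post_init__(self):
        positive = (
            "n_taxa", "n_wells", "depths_per_well", "replicates_per_depth",
            "reads_per_sample", "niche_conservatism", "biomass_fold_transition",
            "biomass_fold_oxidized", "biomass_log10_sd", "richness_noise_sd",
            "well_spacing_m", "sample_span_m",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.selection_strength <= 0:
            raise ValidationError("selection_strength must be positive (inf = neutral)")
        if self.contact_elev <= self.transition_elev:
            raise ValidationError("contact must lie above the transition")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Phylogeny and niches
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int, birth_rate: float = 1.0) -> TreeNode:
    """Yule (pure-birth) tree with ``n_taxa`` extant tips.

    Lineages split at rate ``birth_rate`` each; after the pool reaches
    ``n_taxa`` one further exponential waiting time is appended so every
    pendant branch has positive length. The tree is ultrametric.
    """
    if n_taxa < 2:
        raise ValidationError("a tree needs at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None, length=None)
    start: dict[int, float] = {}
    active: list[TreeNode] = []
    t = 0.0
    for _ in range(2):  # the root split defines time zero
        child = TreeNode(length=None)
        root.append(child)
        start[id(child)] = 0.0
        active.append(child)
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        parent = active.pop(rng.integers(k))
        parent.length = t - start.pop(id(parent))
        for _ in range(2):
            child = TreeNode(length=None)
            parent.append(child)
            start[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    width = len(str(n_taxa))
    for i, node in enumerate(active):
        node.length = t_end - start[id(node)]
    for i, tip in enumerate(root.tips()):
        tip.name = f"OTU{i + 1:0{width}d}"
    return root


def assign_niche_optima(tree: TreeNode, rate: float, seed: int) -> pd.Series:
    """Per-taxon redox optima evolved by Brownian motion along the tree.

    The ancestral value is 0; each branch adds a Normal(0, rate * length)
    increment, so closely related taxa carry correlated optima — the
    condition under which tip-shuffle null models detect selection.
    """
    if rate <= 0:
        raise ValidationError("Brownian rate must be positive")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        length = node.length or 0.0
        values[id(node)] = values[id(node.parent)] + rng.normal(
            0.0, math.sqrt(rate * length)
        )
    tips = list(tree.tips())
    return pd.Series({t.name: values[id(t)] for t in tips}, name="optimum")


def rescale_optima(optima: pd.Series) -> pd.Series:
    """Min-max rescale optima onto the [0, 1] redox axis."""
    lo, hi = optima.min(), optima.max()
    if hi == lo:
        return pd.Series(np.full(len(optima), 0.5), index=optima.index)
    return (optima - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def simulate_base_abundance(n_taxa: int, sd: float, seed: int) -> np.ndarray:
    """Lognormal metacommunity base abundances (mean-normalized).

    Emulates the steep rank-abundance structure of real communities so
    that a finite read depth samples only part of the taxon pool; drawn
    independently of the phylogeny.
    """
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(0.0, sd, n_taxa))
    return base / base.sum()


def simulate_communities(
    tree: TreeNode,
    optima: pd.Series,
    redox_axis: pd.Series,
    config: SimulationConfig,
    seed: int,
    base_abundance: np.ndarray | None = None,
) -> OtuTable:
    """Multinomial community sampling under a Gaussian niche filter.

    Taxon i's sampling probability in sample s is proportional to
    base_i * exp(-(E_s - o_i)^2 / (2 sigma^2)) where E_s is the
    sample's redox axis value and o_i the taxon's optimum. sigma = inf
    recovers the neutral, environment-independent model, in which every
    sample draws from the same metacommunity distribution (equal
    expected relative abundances across samples). Column sums equal
    ``reads_per_sample`` exactly.
    """
    sigma = config.selection_strength
    if not sigma > 0:
        raise ValidationError("selection strength sigma must be positive")
    rng = np.random.default_rng(seed)
    taxa = [t.name for t in tree.tips()]
    o = optima.loc[taxa].to_numpy(dtype=float)
    base = (
        np.ones(len(o)) if base_abundance is None
        else np.asarray(base_abundance, dtype=float)
    )
    if len(base) != len(o) or (base < 0).any() or base.sum() <= 0:
        raise ValidationError("base abundance must be non-negative over all taxa")
    counts = np.zeros((len(taxa), len(redox_axis)), dtype=np.int64)
    for j, e in enumerate(redox_axis.to_numpy(dtype=float)):
        if math.isinf(sigma):
            w = base.copy()
        else:
            w = base * np.exp(-((e - o) ** 2) / (2.0 * sigma**2))
        total = w.sum()
        if total <= 0:  # numerically empty niche: fall back to the closest taxon
            w = np.zeros(len(o))
            w[np.argmin(np.abs(e - o))] = 1.0
            total = 1.0
        counts[:, j] = rng.multinomial(config.reads_per_sample, w / total)
    return OtuTable(tuple(taxa), tuple(str(s) for s in redox_axis.index), counts)


# ---------------------------------------------------------------------------
# Well logs, environment, biomass
# ---------------------------------------------------------------------------

def simulate_well_logs(config: SimulationConfig, seed: int | None = None) -> list[WellLog]:
    """Well logs with smooth planar surface trends plus noise.

    Both surfaces share the configured plan trend and a common per-well
    vertical wobble (the two picks track each other stratigraphically);
    a smaller independent component (one third of the noise sd) perturbs
    the thickness between them. The contact is checked to remain above
    the transition; a configuration that makes them cross raises.
    """
    if config.n_wells < 1:
        raise ValidationError("need at least one well")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    side = math.ceil(math.sqrt(config.n_wells))
    logs = []
    ax, ay = config.surface_trend
    for w in range(config.n_wells):
        x = (w % side) * config.well_spacing_m
        y = (w // side) * config.well_spacing_m
        wobble = rng.normal(0, config.surface_noise_sd)
        thickness = rng.normal(0, config.surface_noise_sd / 3.0)
        contact = config.contact_elev + ax * x + ay * y + wobble
        transition = config.transition_elev + ax * x + ay * y + wobble + thickness
        if contact <= transition:
            raise ValidationError(
                f"configuration lets surfaces cross at well {w}: "
                f"contact {contact:.3f} <= transition {transition:.3f}"
            )
        logs.append(
            WellLog(
                well_id=f"W{w + 1:02d}",
                x_m=x,
                y_m=y,
                surface_elev_m=115.0,
                hr_contact_elev_m=round(contact, 3),
                transition_elev_m=round(transition, 3),
            )
        )
    return logs


#: Facies-conditional means for the geochemical covariates.
FACIES_MEANS = {
    "FeII_umol_g": {"oxidized": 3.0, "transition": 15.0, "reduced": 30.0},
    "pH": {"oxidized": 7.4, "transition": 7.8, "reduced": 8.2},
    "clinochlore_pct": {"oxidized": 3.0, "transition": 2.5, "reduced": 2.0},
}

FACIES_SDS = {"FeII_umol_g": 2.0, "pH": 0.15, "clinochlore_pct": 0.4}

#: Elevation trends (slope per meter relative to the transition elevation).
ELEVATION_TRENDS = {
    "mica_pct": (10.0, 1.5, 0.5),  # intercept, slope, noise sd
    "quartz_pct": (40.0, -2.0, 1.0),
    "montmorillonite_pct": (5.0, 0.8, 0.4),
}


def simulate_env_and_biomass(
    config: SimulationConfig,
    well_logs: list[WellLog],
    seed: int | None = None,
    noise_scale: float = 1.0,
) -> tuple[SampleMetadata, dict]:
    """Sample metadata: facies labels, geochemistry, biomass, richness.

    Depth bands sit at fixed elevations relative to each well's
    transition pick; facies labels follow the true surfaces (band
    half-width from the config). Geochemical and mineral covariates are
    drawn once per depth band and shared by its replicates (one
    geochemistry sample per depth in the field design); biomass and
    richness are drawn per replicate, since every replicate is its own
    DNA extract and sequenced community. ``noise_scale=0`` collapses
    every covariate onto its configured group mean or trend.

    Returns the metadata plus a truth record (facies, redox axis value,
    expected biomass and richness coefficients).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    offsets = np.linspace(config.sample_span_m, -config.sample_span_m,
                          config.depths_per_well)
    rows = []
    truth_rows = []
    fe_means = FACIES_MEANS["FeII_umol_g"]
    log10_means = {
        "reduced": config.biomass_log10_reduced,
        "transition": config.biomass_log10_reduced
        + math.log10(config.biomass_fold_transition),
        "oxidized": config.biomass_log10_reduced
        + math.log10(config.biomass_fold_oxidized),
    }
    for log in well_logs:
        for d, off in enumerate(offsets):
            z = log.transition_elev_m + off
            if z > log.hr_contact_elev_m:
                raise ValidationError(
                    f"sample elevation {z:.2f} above the contact in {log.well_id}"
                )
            if abs(off) <= config.band_halfwidth:
                facies = "transition"
            elif off > 0:
                facies = "oxidized"
            else:
                facies = "reduced"
            env = {}
            for var, means in FACIES_MEANS.items():
                env[var] = means[facies] + noise_scale * rng.normal(
                    0, FACIES_SDS[var]
                )
            for var, (b0, b1, sd) in ELEVATION_TRENDS.items():
                env[var] = b0 + b1 * off + noise_scale * rng.normal(0, sd)
            env["anorthoclase_pct"] = 5.0 + noise_scale * rng.normal(0, 1.0)
            env["organic_C_pct"] = abs(0.2 + noise_scale * rng.normal(0, 0.05))
            env["porosity"] = 0.35 + noise_scale * rng.normal(0, 0.03)
            env["tortuosity"] = 1.6 + noise_scale * rng.normal(0, 0.1)
            for r in range(config.replicates_per_depth):
                sid = f"{log.well_id}_D{d + 1}_R{r + 1}"
                per_sample = {
                    "copies_per_g": 10 ** (
                        log10_means[facies]
                        + noise_scale * rng.normal(0, config.biomass_log10_sd)
                    ),
                    "richness": (
                        config.richness_intercept
                        + config.richness_coef_ph * env["pH"]
                        + config.richness_coef_mineral * env["anorthoclase_pct"]
                        + noise_scale * rng.normal(0, config.richness_noise_sd)
                    ),
                }
                rows.append(
                    {
                        "sample_id": sid,
                        "well_id": log.well_id,
                        "facies": facies,
                        "elevation_m": round(z, 3),
                        "rel_elevation_m": round(off, 3),
                        **env,
                        **per_sample,
                    }
                )
                truth_rows.append({"sample_id": sid, "true_facies": facies})
    frame = pd.DataFrame(rows).set_index("sample_id")
    # redox axis: Fe(II) min-max scaled over the configured facies means
    lo, hi = fe_means["oxidized"], fe_means["reduced"]
    redox = ((frame["FeII_umol_g"] - lo) / (hi - lo)).clip(0.0, 1.0)
    truth = {
        "facies": frame["facies"].to_dict(),
        "redox_axis": redox.to_dict(),
        "biomass_log10_means": log10_means,
        "richness_coefficients": {
            "intercept": config.richness_intercept,
            "pH": config.richness_coef_ph,
            "anorthoclase_pct": config.richness_coef_mineral,
        },
    }
    return SampleMetadata(frame), truth


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A complete synthetic study with its ground truth."""

    config: SimulationConfig
    otu_table: OtuTable
    tree: TreeNode
    metadata: SampleMetadata
    well_logs: list[WellLog]
    truth: dict


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a full dataset (tree, communities, metadata, well logs).

    All randomness descends from ``config.seed``; repeated calls with
    the same config are bit-identical.
    """
    config = config or SimulationConfig()
    s_tree, s_opt, s_logs, s_env, s_comm, s_base = _spawn_seeds(config.seed, 6)
    tree = simulate_tree(config.n_taxa, s_tree)
    optima_raw = assign_niche_optima(tree, config.niche_conservatism, s_opt)
    optima = rescale_optima(optima_raw)
    well_logs = simulate_well_logs(config, s_logs)
    metadata, truth = simulate_env_and_biomass(config, well_logs, s_env)
    redox = pd.Series(truth["redox_axis"]).loc[list(metadata.sample_ids)]
    base = simulate_base_abundance(config.n_taxa, config.abundance_lognormal_sd,
                                   s_base)
    table = simulate_communities(tree, optima, redox, config, s_comm, base)
    truth = dict(truth)
    truth["optima"] = optima.to_dict()
    truth["optima_raw"] = optima_raw.to_dict()
    truth["selection_strength"] = config.selection_strength
    truth["surfaces"] = {
        log.well_id: {
            "hr_contact_elev_m": log.hr_contact_elev_m,
            "transition_elev_m": log.transition_elev_m,
        }
        for log in well_logs
    }
    return SyntheticDataset(
        config=config,
        otu_table=table,
        tree=tree,
        metadata=metadata,
        well_logs=well_logs,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write all artifacts in their interchange formats plus the truth
    record and a provenance file carrying the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_otu_table(dataset.otu_table, out / "otu_table.tsv")
    write_tree(dataset.tree, out / "tree.nwk")
    write_metadata(dataset.metadata, out / "metadata.csv")
    write_well_logs(dataset.well_logs, out / "well_logs.csv")
    pd.DataFrame(
        {
            "sample_id": list(dataset.truth["facies"]),
            "true_facies": list(dataset.truth["facies"].values()),
            "redox_axis": [dataset.truth["redox_axis"][s]
                           for s in dataset.truth["facies"]],
        }
    ).to_csv(out / "truth_samples.csv", index=False)
    pd.Series(dataset.truth["optima"], name="optimum").rename_axis("otu_id").to_csv(
        out / "truth_optima.csv"
    )
    provenance = {
        "seed": dataset.config.seed,
        "config": dataclasses.asdict(dataset.config),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))


# ---------------------------------------------------------------------------
# Focused regression fixture for the richness model
# ---------------------------------------------------------------------------

def simulate_richness_regression(
    seed: int,
    n_samples: int = 18,
    n_decoys: int = 6,
    r_squared: float = 0.65,
    coef_ph: float = -40.0,
    coef_mineral: float = 12.0,
) -> tuple[pd.Series, pd.DataFrame, tuple[str, str]]:
    """A richness-style regression problem with planted predictors.

    pH is facies-structured (three group means, within-group noise) and
    the mineral is independent; the response is linear in both with
    Gaussian noise calibrated so the population R^2 equals
    ``r_squared``. Decoy covariates are independent noise. Returns
    (response, candidate frame, names of the two true predictors).
    """
    rng = np.random.default_rng(seed)
    facies = rng.choice(["oxidized", "transition", "reduced"], size=n_samples)
    ph = np.array([FACIES_MEANS["pH"][f] for f in facies]) + rng.normal(
        0, FACIES_SDS["pH"], n_samples
    )
    mineral = 5.0 + rng.normal(0, 1.0, n_samples)
    # population variances of the two signal components under this design
    ph_var = np.var(list(FACIES_MEANS["pH"].values())) + FACIES_SDS["pH"] ** 2
    signal_var = coef_ph**2 * ph_var + coef_mineral**2 * 1.0
    noise_sd = math.sqrt(signal_var * (1 - r_squared) / r_squared)
    response = (
        600.0 + coef_ph * ph + coef_mineral * mineral
        + rng.normal(0, noise_sd, n_samples)
    )
    candidates = pd.DataFrame({"pH": ph, "anorthoclase_pct": mineral})
    for k in range(n_decoys):
        candidates[f"decoy_{k + 1}"] = rng.normal(0, 1.0, n_samples)
    index = [f"S{i + 1:02d}" for i in range(n_samples)]
    candidates.index = index
    return (
        pd.Series(response, index=index, name="richness"),
        candidates,
        ("pH", "anorthoclase_pct"),
    )
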