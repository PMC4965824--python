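"""Phylogenetic community turnover: betaMNTD, its null model, and betaNTI.

betaMNTD (beta mean nearest taxon distance) measures, for a pair of
communities, the abundance-weighted mean phylogenetic distance from each
taxon to its closest relative in the other community, averaged over both
directions. Standardizing the observed value against a null distribution
obtained by shuffling taxa across the tips of the phylogeny yields
betaNTI, the beta nearest taxon index. |betaNTI| > 2 indicates community
turnover governed by deterministic ecological selection: betaNTI > +2
implies variable selection (environments select for phylogenetically
divergent taxa), betaNTI < -2 homogeneous selection.

The null shuffles the assignment of taxon identities to tree tips
uniformly over the full taxon pool of the table (a "regional pool"
randomization), leaving abundance vectors untouched, so null draws are
comparable across sample pairs. For small pools an exhaustive mode
enumerates every tip permutation, giving the exact null moments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .io import ValidationError, _validate_tree

#: Maximum pool size for exhaustive enumeration of tip permutations.
EXHAUSTIVE_LIMIT = 8


def cophenetic(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distance matrix."""
    _validate_tree(tree)
    return tree.tip_tip_distances()


def beta_mntd(
    f1: np.ndarray,
    f2: np.ndarray,
    coph: np.ndarray,
    weighted: bool = True,
) -> float:
    """betaMNTD for one pair of communities.

    Parameters
    ----------
    f1, f2
        Relative-abundance vectors over the same taxa ordering as
        ``coph``. Taxa with zero abundance in a sample do not contribute
        to that sample's side of the average.
    coph
        Square cophenetic distance matrix over the taxa.
    weighted
        Abundance-weighted (default) or presence/absence (uniform
        weights over present taxa).
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    coph = np.asarray(coph, dtype=float)
    s1 = f1 > 0
    s2 = f2 > 0
    if not s1.any() or not s2.any():
        raise ValidationError("betaMNTD undefined for an empty community")
    if not weighted:
        f1 = s1 / s1.sum()
        f2 = s2 / s2.sum()
    else:
        f1 = f1 / f1.sum()
        f2 = f2 / f2.sum()
    # nearest-taxon distance from every taxon to the other community
    near_to_2 = coph[:, s2].min(axis=1)
    near_to_1 = coph[:, s1].min(axis=1)
    return 0.5 * (float(f1 @ near_to_2) + float(f2 @ near_to_1))


def _all_pairs_beta_mntd(F: np.ndarray, coph: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs at once.

    ``F`` is taxa x samples with columns summing to 1. Returns a square
    samples x samples matrix. Vectorized: for each sample m we need
    ``M[i, m] = min_{j in support(m)} coph[i, j]``, after which
    ``betaMNTD(k, m) = 0.5 * (F[:,k] @ M[:,m] + F[:,m] @ M[:,k])``.
    """
    n_taxa, n_samples = F.shape
    support = F > 0
    M = np.empty((n_taxa, n_samples))
    for m in range(n_samples):
        M[:, m] = coph[:, support[:, m]].min(axis=1)
    cross = F.T @ M  # cross[k, m] = sum_i F[i,k] * M[i,m]
    out = 0.5 * (cross + cross.T)
    np.fill_diagonal(out, 0.5 * (np.diag(cross) + np.diag(cross)))
    return out


def taxa_shuffle_null(
    F: np.ndarray,
    coph: np.ndarray,
    n_null: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """Null betaMNTD distributions under tip-label shuffling.

    Each randomization permutes the assignment of taxa to tips over the
    full pool (equivalently, jointly permutes the rows and columns of the
    cophenetic matrix) and recomputes betaMNTD for every sample pair.
    Returns an array of shape (n_null, n_samples, n_samples); in
    exhaustive mode the first axis runs over all pool-size! permutations.
    """
    F = np.asarray(F, dtype=float)
    coph = np.asarray(coph, dtype=float)
    n_taxa = F.shape[0]
    if n_taxa < 2:
        raise ValidationError("taxa pool must contain at least 2 taxa")
    if exhaustive:
        if n_taxa > EXHAUSTIVE_LIMIT:
            raise ValidationError(
                f"exhaustive null limited to pools of <= {EXHAUSTIVE_LIMIT} taxa "
                f"({math.factorial(n_taxa)} permutations otherwise)"
            )
        perms = [np.array(p) for p in itertools.permutations(range(n_taxa))]
    else:
        if n_null < 1:
            raise ValidationError("n_null must be >= 1")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n_taxa) for _ in range(n_null)]
    out = np.empty((len(perms), F.shape[1], F.shape[1]))
    for r, perm in enumerate(perms):
        out[r] = _all_pairs_beta_mntd(F, coph[np.ix_(perm, perm)])
    return out


@dataclass(frozen=True)
class BntiResult:
    """Observed betaMNTD, null moments and betaNTI for every sample pair.

    ``degenerate`` flags pairs whose null distribution has zero standard
    deviation (e.g. a star phylogeny); their betaNTI is NaN, never +/-inf.
    """

    sample_ids: tuple[str, ...]
    beta_mntd_obs: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    bnti: pd.DataFrame
    degenerate: pd.DataFrame
    n_null: int

    def pairs(self) -> pd.DataFrame:
        """Long format: one row per unordered sample pair."""
        rows = []
        ids = self.sample_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                rows.append(
                    {
                        "sample_a": a,
                        "sample_b": b,
                        "beta_mntd_obs": self.beta_mntd_obs.loc[a, b],
                        "null_mean": self.null_mean.loc[a, b],
                        "null_sd": self.null_sd.loc[a, b],
                        "bnti": self.bnti.loc[a, b],
                        "degenerate": bool(self.degenerate.loc[a, b]),
                    }
                )
        return pd.DataFrame(rows)

    def to_distance_matrix(self, fill_degenerate: float = 0.0) -> DistanceMatrix:
        """Square betaNTI matrix for distance-matrix consumers.

        Degenerate pairs (flagged NaN in ``bnti``) are written as
        ``fill_degenerate`` because square-matrix consumers (Mantel,
        ordination) cannot take NaN; the ``degenerate`` flags remain the
        authoritative record of which pairs were unscored.
        """
        data = self.bnti.to_numpy(copy=True)
        data[self.degenerate.to_numpy()] = fill_degenerate
        np.fill_diagonal(data, 0.0)
        return DistanceMatrix(data, ids=list(self.sample_ids))


def bnti(
    rel_abund: pd.DataFrame,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
    exhaustive: bool = False,
) -> BntiResult:
    """betaNTI for every pair of samples in a relative-abundance table.

    Parameters
    ----------
    rel_abund
        taxa x samples relative abundances (index = taxa ids, which must
        all be tips of ``tree``).
    tree
        Rooted phylogeny with branch lengths.
    n_null
        Number of tip-shuffle randomizations (ignored in exhaustive mode).
    weighted
        Abundance-weighted betaMNTD (default) or presence/absence.
    exhaustive
        Enumerate all tip permutations (small pools only) for an exact null.
    """
    coph_dm = cophenetic(tree)
    taxa = [str(t) for t in rel_abund.index]
    missing = set(taxa) - set(coph_dm.ids)
    if missing:
        raise ValidationError(f"taxa absent from tree: {sorted(missing)[:5]} ...")
    coph = pd.DataFrame(coph_dm.data, index=coph_dm.ids, columns=coph_dm.ids).loc[
        taxa, taxa
    ].to_numpy()
    F = rel_abund.to_numpy(dtype=float)
    if (F.sum(axis=0) <= 0).any():
        raise ValidationError("every sample must contain at least one taxon")
    F = F / F.sum(axis=0, keepdims=True)
    if not weighted:
        F = (F > 0).astype(float)
        F = F / F.sum(axis=0, keepdims=True)
    obs = _all_pairs_beta_mntd(F, coph)
    nulls = taxa_shuffle_null(F, coph, n_null=n_null, seed=seed, exhaustive=exhaustive)
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1) if nulls.shape[0] > 1 else np.zeros_like(obs)
    degenerate = null_sd <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - null_mean) / null_sd
    z[degenerate] = np.nan
    np.fill_diagonal(degenerate, False)
    ids = [str(c) for c in rel_abund.columns]

    def frame(a):
        return pd.DataFrame(a, index=ids, columns=ids)

    return BntiResult(
        sample_ids=tuple(ids),
        beta_mntd_obs=frame(obs),
        null_mean=frame(null_mean),
        null_sd=frame(null_sd),
        bnti=frame(z),
        degenerate=frame(degenerate),
        n_null=nulls.shape[0],
    )


#: Classification labels for pairwise betaNTI values.
VARIABLE_SELECTION = "variable_selection"
HOMOGENEOUS_SELECTION = "homogeneous_selection"
NOT_DISTINGUISHED = "not_distinguished"
DEGENERATE = "degenerate"


def classify_selection(result: BntiResult, threshold: float = 2.0) -> pd.DataFrame:
    """Label each pair by the inferred assembly process.

    |betaNTI| > threshold implies ecological selection: positive values
    are variable selection, negative homogeneous selection. Pairs inside
    the threshold are not distinguished from stochastic assembly;
    degenerate-null pairs are labelled as such.
    """
    z = result.bnti.to_numpy()
    labels = np.full(z.shape, NOT_DISTINGUISHED, dtype=object)
    labels[z > threshold] = VARIABLE_SELECTION
    labels[z < -threshold] = HOMOGENEOUS_SELECTION
    labels[result.degenerate.to_numpy()] = DEGENERATE
    np.fill_diagonal(labels, NOT_DISTINGUISHED)
    return pd.DataFrame(labels, index=result.bnti.index, columns=result.bnti.columns)
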