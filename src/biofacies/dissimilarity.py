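"""Distance-matrix statistics: Bray-Curtis, environmental deltas,
Mantel and partial Mantel permutation tests, forward selection over
distance matrices, and NMDS ordination.

Entries within a distance matrix are non-independent, so relationships
between matrices are tested by Mantel permutation: the Pearson
correlation of the vectorized upper triangles is compared against the
distribution obtained by jointly permuting the rows and columns of the
second matrix. The partial variant conditions on a third matrix via the
first-order partial correlation. Forward selection adds, at each step,
the candidate matrix with the strongest (partial) correlation with the
response and stops at the first candidate that is not significant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .io import SampleMetadata, ValidationError

#: Largest n for exhaustive Mantel permutation enumeration.
EXHAUSTIVE_LIMIT = 7


def bray_curtis(rel_abund: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples of a relative-abundance
    table (taxa x samples); values lie in [0, 1]."""
    X = rel_abund.to_numpy(dtype=float).T
    if (X.sum(axis=1) <= 0).any():
        empty = [str(c) for c, s in zip(rel_abund.columns, X.sum(axis=1)) if s <= 0]
        raise ValidationError(f"all-zero samples: {empty}")
    condensed = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(c) for c in rel_abund.columns])


def env_delta_matrix(metadata: SampleMetadata, variable: str) -> DistanceMatrix:
    """Between-sample absolute differences in one covariate."""
    values = metadata.env(variable).to_numpy(dtype=float)
    delta = np.abs(values[:, None] - values[None, :])
    return DistanceMatrix(delta, ids=list(metadata.sample_ids))


def _triangle(dm: DistanceMatrix) -> np.ndarray:
    data = dm.data
    iu = np.triu_indices(data.shape[0], k=1)
    return data[iu]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise ValidationError("zero variance in a distance-matrix triangle")
    return float(a @ b) / denom


@dataclass(frozen=True)
class MantelResult:
    """Outcome of a (partial) Mantel permutation test."""

    statistic: float
    p_value: float
    n_perm: int
    tail: str
    conditioning: tuple[str, ...] = ()


def _check_pair(d1: DistanceMatrix, d2: DistanceMatrix) -> None:
    if tuple(d1.ids) != tuple(d2.ids):
        raise ValidationError("distance matrices must share the same ids in order")
    if d1.shape[0] < 4:
        raise ValidationError("Mantel tests need at least 4 samples")


def _tail_count(perm_stats: np.ndarray, observed: float, tail: str) -> int:
    eps = 1e-12
    if tail == "positive":
        return int(np.sum(perm_stats >= observed - eps))
    if tail == "negative":
        return int(np.sum(perm_stats <= observed + eps))
    if tail == "two-sided":
        return int(np.sum(np.abs(perm_stats) >= abs(observed) - eps))
    raise ValueError(f"unknown tail: {tail!r}")


def _permutations(n: int, n_perm: int, seed, exhaustive: bool):
    if exhaustive:
        if n > EXHAUSTIVE_LIMIT:
            raise ValidationError(
                f"exhaustive Mantel limited to n <= {EXHAUSTIVE_LIMIT}"
            )
        return [np.array(p) for p in itertools.permutations(range(n))], True
    rng = np.random.default_rng(seed)
    return [rng.permutation(n) for _ in range(n_perm)], False


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "positive",
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test between two distance matrices.

    The statistic is the Pearson correlation of the off-diagonal upper
    triangles. Significance is assessed by permuting the sample labels
    of ``d2`` (rows and columns jointly). In sampled mode the p-value
    uses the (count + 1)/(n_perm + 1) convention so it is never zero; in
    exhaustive mode it is the exact fraction over all n! relabelings
    (which include the identity, so it is still positive). The default
    tail is ``positive``: larger environmental change implying larger
    community turnover.
    """
    _check_pair(d1, d2)
    x = _triangle(d1)
    n = d1.shape[0]
    data2 = d2.data
    r_obs = _pearson(x, _triangle(d2))
    perms, exact = _permutations(n, n_perm, seed, exhaustive)
    iu = np.triu_indices(n, k=1)
    stats = np.empty(len(perms))
    for k, perm in enumerate(perms):
        stats[k] = _pearson(x, data2[np.ix_(perm, perm)][iu])
    count = _tail_count(stats, r_obs, tail)
    if exact:
        p = count / len(perms)
    else:
        p = (count + 1) / (len(perms) + 1)
    return MantelResult(statistic=r_obs, p_value=p, n_perm=len(perms), tail=tail)


def partial_correlation(r12: float, r1c: float, r2c: float) -> float:
    """First-order partial correlation r_12.c."""
    if abs(r1c) >= 1 - 1e-12 or abs(r2c) >= 1 - 1e-12:
        raise ValidationError(
            "partial correlation undefined: conditioning matrix perfectly "
            "correlated with an input"
        )
    return (r12 - r1c * r2c) / math.sqrt((1 - r1c**2) * (1 - r2c**2))


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    dc: DistanceMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "positive",
    exhaustive: bool = False,
    conditioning_label: str = "conditioning",
) -> MantelResult:
    """Partial Mantel test of d1 vs d2 controlling for dc.

    The permutation scheme relabels ``d2`` and recomputes the full
    partial statistic (r_12 and r_2c both change under the relabeling).
    """
    _check_pair(d1, d2)
    _check_pair(d1, dc)
    n = d1.shape[0]
    x = _triangle(d1)
    c = _triangle(dc)
    r1c = _pearson(x, c)
    data2 = d2.data
    iu = np.triu_indices(n, k=1)

    def stat(y: np.ndarray) -> float:
        return partial_correlation(_pearson(x, y), r1c, _pearson(y, c))

    r_obs = stat(_triangle(d2))
    perms, exact = _permutations(n, n_perm, seed, exhaustive)
    stats = np.empty(len(perms))
    for k, perm in enumerate(perms):
        stats[k] = stat(data2[np.ix_(perm, perm)][iu])
    count = _tail_count(stats, r_obs, tail)
    p = count / len(perms) if exact else (count + 1) / (len(perms) + 1)
    return MantelResult(
        statistic=r_obs,
        p_value=p,
        n_perm=len(perms),
        tail=tail,
        conditioning=(conditioning_label,),
    )


@dataclass(frozen=True)
class DistanceSelectionResult:
    """Forward-selection path over candidate distance matrices.

    ``steps`` lists accepted (variable, statistic, p) triples in order;
    ``rejected`` is the first non-significant candidate (or None if the
    pool was exhausted).
    """

    steps: tuple[tuple[str, float, float], ...]
    rejected: tuple[str, float, float] | None
    alpha: float

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.steps)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": i + 1, "variable": v, "statistic": r, "p_value": p,
             "accepted": True}
            for i, (v, r, p) in enumerate(self.steps)
        ]
        if self.rejected is not None:
            v, r, p = self.rejected
            rows.append(
                {"step": len(self.steps) + 1, "variable": v, "statistic": r,
                 "p_value": p, "accepted": False}
            )
        return pd.DataFrame(rows)


def _sum_matrices(mats: list[DistanceMatrix]) -> DistanceMatrix:
    total = np.zeros_like(mats[0].data)
    for m in mats:
        total = total + m.data
    return DistanceMatrix(total, ids=list(mats[0].ids))


def forward_select_distance(
    response: DistanceMatrix,
    candidates: dict[str, DistanceMatrix],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "positive",
) -> DistanceSelectionResult:
    """Mantel-based forward selection of environmental delta matrices.

    Step 1 picks the candidate with the largest Mantel correlation with
    the response; subsequent steps pick the largest partial correlation
    conditioning on the elementwise sum of the already-selected
    matrices. Selection stops at the first best candidate whose
    permutation p-value is >= alpha (reported as ``rejected``); if no
    first candidate is significant the selection is empty.
    """
    if not candidates:
        raise ValidationError("at least one candidate matrix required")
    remaining = dict(candidates)
    selected: list[tuple[str, float, float]] = []
    chosen_mats: list[DistanceMatrix] = []
    child_seeds = np.random.SeedSequence(seed).spawn(len(candidates))
    step = 0
    while remaining:
        step_seed = int(child_seeds[step].generate_state(1)[0] % (2**31))
        results = {}
        for name, dm in remaining.items():
            try:
                if not chosen_mats:
                    res = mantel(response, dm, n_perm=n_perm, seed=step_seed,
                                 tail=tail)
                else:
                    res = partial_mantel(
                        response, dm, _sum_matrices(chosen_mats),
                        n_perm=n_perm, seed=step_seed, tail=tail,
                    )
            except ValidationError:
                # undefined partial (perfectly correlated conditioning):
                # the candidate cannot be evaluated at this step
                continue
            results[name] = res
        if not results:
            break
        best = max(results, key=lambda k: results[k].statistic)
        res = results[best]
        if res.p_value >= alpha:
            return DistanceSelectionResult(
                steps=tuple(selected),
                rejected=(best, res.statistic, res.p_value),
                alpha=alpha,
            )
        selected.append((best, res.statistic, res.p_value))
        chosen_mats.append(remaining.pop(best))
        step += 1
    return DistanceSelectionResult(steps=tuple(selected), rejected=None, alpha=alpha)


@dataclass(frozen=True)
class NmdsResult:
    """Nonmetric multidimensional scaling ordination."""

    coordinates: pd.DataFrame
    stress: float
    n_dims: int
    seed: int


def nmds(
    d: DistanceMatrix,
    n_dims: int = 2,
    n_starts: int = 8,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> NmdsResult:
    """NMDS by iterative majorization with monotone regression.

    Minimizes Kruskal stress-1 over ``n_starts`` random starts and
    returns the best configuration. A visualization aid: only the stress
    value carries a contract, not the (rotation/reflection-arbitrary)
    coordinates.
    """
    n = d.shape[0]
    if n_dims >= n - 1:
        raise ValidationError("n_dims must be < n_samples - 1")
    model = MDS(
        n_components=n_dims,
        metric_mds=False,
        metric="precomputed",
        n_init=n_starts,
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
        init="random",
    )
    coords = model.fit_transform(d.data)
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"NMDS{i+1}" for i in range(n_dims)]
    )
    return NmdsResult(coordinates=frame, stress=float(model.stress_),
                      n_dims=n_dims, seed=seed)
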