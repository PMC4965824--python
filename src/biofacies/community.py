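"""OTU-table preprocessing and facies set-overlap summaries.

Rarefaction equalizes sampling effort by drawing, without replacement,
a fixed number of reads from every sample; samples shallower than the
target depth are excluded and reported, never up-sampled. Downstream
beta-diversity analyses consume the rarefied relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FACIES_CODES, OtuTable, SampleMetadata, ValidationError


@dataclass(frozen=True)
class RarefiedTable:
    """An OtuTable subsampled to a common depth, with provenance.

    ``excluded`` lists samples whose total count fell below ``depth``.
    """

    table: OtuTable
    depth: int
    seed: int
    excluded: tuple[str, ...]

    @property
    def taxa_ids(self):
        return self.table.taxa_ids

    @property
    def sample_ids(self):
        return self.table.sample_ids

    @property
    def counts(self):
        return self.table.counts


def rarefy(table: OtuTable, depth: int = 1000, seed: int = 0) -> RarefiedTable:
    """Subsample each sample's reads to ``depth`` without replacement.

    Deterministic given ``seed``; a single draw per sample (not an
    average over draws). Errors if no sample reaches the depth.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep = totals >= depth
    if not keep.any():
        raise ValidationError(f"no sample has >= {depth} reads")
    kept_ids = tuple(s for s, k in zip(table.sample_ids, keep) if k)
    excluded = tuple(s for s, k in zip(table.sample_ids, keep) if not k)
    cols = []
    for j, k in enumerate(keep):
        if not k:
            continue
        col = table.counts[:, j]
        if col.sum() == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    counts = np.column_stack(cols) if cols else np.zeros((len(table.taxa_ids), 0), int)
    sub = OtuTable(table.taxa_ids, kept_ids, counts)
    return RarefiedTable(table=sub, depth=depth, seed=seed, excluded=excluded)


def relative_abundance(rarefied: RarefiedTable) -> pd.DataFrame:
    """Per-sample relative abundances (each column sums to 1)."""
    if not isinstance(rarefied, RarefiedTable):
        raise TypeError("relative_abundance requires a RarefiedTable")
    frame = rarefied.table.to_frame().astype(float) / rarefied.depth
    return frame


def richness(rarefied: RarefiedTable) -> pd.Series:
    """Number of taxa with count > 0 in each sample."""
    if not isinstance(rarefied, RarefiedTable):
        raise TypeError("richness requires a RarefiedTable")
    return pd.Series(
        (rarefied.counts > 0).sum(axis=0), index=list(rarefied.sample_ids)
    )


@dataclass(frozen=True)
class FaciesVenn:
    """Three-set OTU overlap counts across the oxidized (A), transition
    (B) and reduced (C) facies.

    Stores the marginals, pairwise intersections, triple intersection and
    union; disjoint region counts are derived properties. The
    inclusion-exclusion identity is enforced exactly on construction.
    """

    n_a: int
    n_b: int
    n_c: int
    n_ab: int
    n_ac: int
    n_bc: int
    n_abc: int
    n_union: int

    def __post_init__(self):
        expected = (
            self.n_a + self.n_b + self.n_c
            - self.n_ab - self.n_ac - self.n_bc + self.n_abc
        )
        if expected != self.n_union:
            raise ValidationError(
                f"inclusion-exclusion violated: union {self.n_union} != {expected}"
            )
        for name, value in self.regions().items():
            if value < 0:
                raise ValidationError(f"negative Venn region {name}: {value}")

    @property
    def only_a(self) -> int:
        return self.n_a - self.n_ab - self.n_ac + self.n_abc

    @property
    def only_b(self) -> int:
        return self.n_b - self.n_ab - self.n_bc + self.n_abc

    @property
    def only_c(self) -> int:
        return self.n_c - self.n_ac - self.n_bc + self.n_abc

    def regions(self) -> dict[str, int]:
        """The seven disjoint regions of the Venn diagram."""
        return {
            "only_a": self.n_a - self.n_ab - self.n_ac + self.n_abc,
            "only_b": self.n_b - self.n_ab - self.n_bc + self.n_abc,
            "only_c": self.n_c - self.n_ac - self.n_bc + self.n_abc,
            "ab_only": self.n_ab - self.n_abc,
            "ac_only": self.n_ac - self.n_abc,
            "bc_only": self.n_bc - self.n_abc,
            "abc": self.n_abc,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "oxidized": self.n_a,
            "transition": self.n_b,
            "reduced": self.n_c,
            "oxidized_transition": self.n_ab,
            "oxidized_reduced": self.n_ac,
            "transition_reduced": self.n_bc,
            "all_three": self.n_abc,
            "union": self.n_union,
            **{f"region_{k}": v for k, v in self.regions().items()},
        }
        return pd.DataFrame({"count": rows})


def facies_venn(rarefied: RarefiedTable, metadata: SampleMetadata) -> FaciesVenn:
    """OTU presence overlap across the three facies.

    An OTU belongs to a facies if it has a count > 0 in at least one
    sample of that facies.
    """
    meta = metadata.subset(rarefied.sample_ids)
    facies = meta.facies()
    present: dict[str, np.ndarray] = {}
    counts = rarefied.counts
    for code in FACIES_CODES:
        cols = [j for j, s in enumerate(rarefied.sample_ids) if facies[s] == code]
        present[code] = (counts[:, cols] > 0).any(axis=1) if cols else np.zeros(
            counts.shape[0], bool
        )
    a, b, c = (present[code] for code in FACIES_CODES)
    return FaciesVenn(
        n_a=int(a.sum()),
        n_b=int(b.sum()),
        n_c=int(c.sum()),
        n_ab=int((a & b).sum()),
        n_ac=int((a & c).sum()),
        n_bc=int((b & c).sum()),
        n_abc=int((a & b & c).sum()),
        n_union=int((a | b | c).sum()),
    )


def venn_from_marginals(
    n_a: int, n_b: int, n_c: int, n_ab: int, n_ac: int, n_bc: int, n_union: int
) -> FaciesVenn:
    """Solve the triple intersection from marginals by inclusion-exclusion.

    Given per-facies totals, pairwise intersections and the union, the
    triple intersection is the unique value satisfying
    ``|A∪B∪C| = |A|+|B|+|C| - |AB| - |AC| - |BC| + |ABC|``. Errors if any
    implied disjoint region would be negative.
    """
    values = (n_a, n_b, n_c, n_ab, n_ac, n_bc, n_union)
    if any(v < 0 for v in values):
        raise ValidationError("Venn marginals must be non-negative")
    n_abc = n_union - (n_a + n_b + n_c) + (n_ab + n_ac + n_bc)
    return FaciesVenn(n_a, n_b, n_c, n_ab, n_ac, n_bc, n_abc, n_union)
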