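"""Readers and writers for the pipeline's external artifacts.

All tabular formats are plain text: OTU tables are tab-delimited
(taxa rows x sample columns), trees are Newick, and metadata, well
logs, distance matrices and facies grids are CSV. Every reader
validates its input fully before constructing an object, so a
validation failure never yields a partially built table or log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode


class ValidationError(ValueError):
    """Raised when an external artifact violates its contract."""


#: The three biogeochemical facies within the fine-grained aquitard unit.
FACIES_CODES = ("oxidized", "transition", "reduced")

#: Columns every sample-metadata table must carry.
CORE_COLUMNS = ("well_id", "facies", "elevation_m", "rel_elevation_m")

#: Recognised environmental covariates (units in docs/methods.md).
KNOWN_COVARIATES = (
    "pH",
    "FeII_umol_g",
    "organic_C_pct",
    "mica_pct",
    "quartz_pct",
    "montmorillonite_pct",
    "anorthoclase_pct",
    "clinochlore_pct",
    "porosity",
    "tortuosity",
    "euler_index",
    "surface_area_per_volume",
    "fragmentation",
    "linear_density",
    "copies_per_g",
    "richness",
)

WELL_LOG_COLUMNS = (
    "well_id",
    "x_m",
    "y_m",
    "surface_elev_m",
    "hr_contact_elev_m",
    "transition_elev_m",
)


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OtuTable:
    """Integer counts of taxa (rows) per sample (columns)."""

    taxa_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D taxa x samples matrix")
        if counts.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxa_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(set(self.taxa_ids)) != len(self.taxa_ids):
            raise ValidationError("duplicate taxa ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.issubdtype(counts.dtype, np.floating) and np.all(
                counts == np.floor(counts)
            ):
                counts = counts.astype(np.int64)
            else:
                raise ValidationError("counts must be integers")
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "taxa_ids", tuple(str(t) for t in self.taxa_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.taxa_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OtuTable":
        return cls(
            taxa_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
            counts=frame.to_numpy(),
        )


def read_otu_table(path: str | Path, format: str = "tsv") -> OtuTable:
    """Read an OTU count table.

    ``tsv`` expects taxa rows x sample columns with a header row of
    sample ids and the taxa ids in the first column. ``biom`` expects a
    BIOM 1.0 JSON document (dense or sparse), which is transposed into
    the same taxa x samples orientation on read.
    """
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if frame.index.has_duplicates:
            raise ValidationError(f"{path}: duplicated taxa ids")
        if any(str(c).endswith(tuple(f".{k}" for k in range(1, 10))) for c in frame.columns):
            # pandas mangles duplicate headers into name.1, name.2, ...
            raw = path.read_text().splitlines()[0].split("\t")[1:]
            if len(set(raw)) != len(raw):
                raise ValidationError(f"{path}: duplicated sample ids")
        return OtuTable.from_frame(frame)
    if format == "biom":
        doc = json.loads(Path(path).read_text())
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        counts = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                counts[int(i), int(j)] = v
        else:
            counts[:] = np.asarray(doc["data"])
        return OtuTable(tuple(taxa), tuple(samples), counts)
    raise ValueError(f"unknown OTU table format: {format!r}")


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_frame().rename_axis("otu_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _validate_tree(tree: TreeNode) -> TreeNode:
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if any(n is None or n == "" for n in names):
        raise ValidationError("tree has unlabeled tips")
    if len(set(names)) != len(names):
        raise ValidationError("tree tip labels are not unique")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(f"missing branch length above {node.name!r}")
        if node.length < 0:
            raise ValidationError(f"negative branch length above {node.name!r}")
    return tree


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    return _validate_tree(tree)


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample facies labels, elevations and environmental covariates.

    Wraps a DataFrame indexed by sample id. Missing covariate values are
    permitted in storage (empty CSV cells -> NaN) but any operation that
    needs a covariate fails loudly, naming the offending samples, rather
    than silently dropping them.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        frame = self.frame
        if frame.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        missing = [c for c in CORE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        bad = set(frame["facies"]) - set(FACIES_CODES)
        if bad:
            raise ValidationError(f"unknown facies labels: {sorted(bad)}")
        unknown = [
            c for c in frame.columns
            if c not in CORE_COLUMNS and c not in KNOWN_COVARIATES
        ]
        if unknown:
            raise ValidationError(f"covariates outside declared schema: {unknown}")
        self.frame = frame

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.frame.index)

    def facies(self) -> pd.Series:
        return self.frame["facies"]

    def env(self, variable: str) -> pd.Series:
        """A covariate for all samples; errors listing samples with gaps."""
        if variable not in self.frame.columns:
            raise ValidationError(f"covariate {variable!r} not in metadata")
        values = self.frame[variable]
        gaps = values.index[values.isna()].tolist()
        if gaps:
            raise ValidationError(f"covariate {variable!r} missing for samples {gaps}")
        return values

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        ids = list(sample_ids)
        unknown = [s for s in ids if s not in self.frame.index]
        if unknown:
            raise ValidationError(f"samples absent from metadata: {unknown}")
        return SampleMetadata(self.frame.loc[ids].copy())


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, index_col=0)
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.rename_axis("sample_id").to_csv(path)


# ---------------------------------------------------------------------------
# Well logs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellLog:
    """One borehole's plan position and stratigraphic surface picks.

    ``hr_contact_elev_m`` is the unconformity at the top of the oxidized
    facies; ``transition_elev_m`` is the redox-transition elevation. All
    elevations are meters above the site datum.
    """

    well_id: str
    x_m: float
    y_m: float
    surface_elev_m: float
    hr_contact_elev_m: float
    transition_elev_m: float

    def __post_init__(self):
        for name in ("x_m", "y_m", "surface_elev_m", "hr_contact_elev_m",
                     "transition_elev_m"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"well {self.well_id}: {name} not finite")
        if not self.hr_contact_elev_m > self.transition_elev_m:
            raise ValidationError(
                f"well {self.well_id}: transition elevation "
                f"{self.transition_elev_m} is not below the contact "
                f"{self.hr_contact_elev_m}"
            )


def read_well_logs(path: str | Path) -> list[WellLog]:
    frame = pd.read_csv(path)
    missing = [c for c in WELL_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"well log missing columns: {missing}")
    return [
        WellLog(
            well_id=str(row.well_id),
            x_m=float(row.x_m),
            y_m=float(row.y_m),
            surface_elev_m=float(row.surface_elev_m),
            hr_contact_elev_m=float(row.hr_contact_elev_m),
            transition_elev_m=float(row.transition_elev_m),
        )
        for row in frame.itertuples()
    ]


def write_well_logs(logs: Sequence[WellLog], path: str | Path) -> None:
    pd.DataFrame([log.__dict__ for log in logs]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Distance matrices and grids
# ---------------------------------------------------------------------------

def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Square CSV with ids as header row and first column."""
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index.astype(str)) != list(frame.columns.astype(str)):
        raise ValidationError(f"{path}: row and column ids differ")
    return DistanceMatrix(frame.to_numpy(dtype=float), ids=[str(i) for i in frame.index])


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).rename_axis(
        "sample_id"
    ).to_csv(path)


GRID_COLUMNS = ("x", "y", "z", "facies", "log10_copies_per_g")


def read_grid(path: str | Path) -> pd.DataFrame:
    """Long-format facies/biomass grid: x, y, z, facies, log10_copies_per_g."""
    frame = pd.read_csv(path)
    missing = [c for c in GRID_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"grid missing columns: {missing}")
    return frame


def write_grid(frame: pd.DataFrame, path: str | Path) -> None:
    frame.loc[:, list(GRID_COLUMNS)].to_csv(path, index=False)
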