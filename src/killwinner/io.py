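"""Table formats, validation and pipeline configuration.

Pipeline inputs are plain text: a counts TSV (taxa x samples, first column
``taxon_id``), a metadata TSV (one row per composition sample), a densities CSV
(one row per bottle x timepoint) and an optional taxonomy TSV (taxon_id,
order). Counts may alternatively be supplied as a Matrix Market triplet file
with sidecar taxon/sample index files.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .synthetic import TREATMENT_SOURCE, TREATMENTS, SyntheticDataset

METADATA_COLUMNS = ["sample_id", "experiment", "treatment", "dilution_factor",
                    "replicate", "timepoint"]
DENSITY_COLUMNS = ["bottle_id", "experiment", "treatment", "dilution_factor",
                   "replicate", "timepoint", "cells_per_ml"]


@dataclass(frozen=True)
class PipelineConfig:
    """Fixed constants of the analysis, with the study's defaults."""

    depth: int = 3188
    n_norm: int = 1000
    n_perm: int = 1000
    n_sub: int = 100
    alpha: float = 0.05
    duration_h: float = 12.0
    seed: int = 0
    replicate_mode: str = "pooled"
    subtraction_order: str = "pv_minus_p"
    perm_mode: str = "within_taxon"
    allow_partial: bool = False

    def __post_init__(self) -> None:
        for name in ("depth", "n_norm", "n_perm", "n_sub"):
            if getattr(self, name) < 1:
                raise SchemaError(f"{name} must be >= 1")
        if not 0 < self.alpha < 1:
            raise SchemaError("alpha must lie in (0, 1)")
        if self.duration_h <= 0:
            raise SchemaError("duration_h must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_dataset(dataset: SyntheticDataset, out_dir,
                  taxonomy: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write a dataset as the standard pipeline input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "densities": out / "densities.csv",
        "truth": out / "truth.tsv",
    }
    dataset.counts.to_csv(paths["counts"], sep="\t")
    dataset.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    dataset.densities.to_csv(paths["densities"], index=False)
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    if taxonomy is not None:
        paths["taxonomy"] = out / "taxonomy.tsv"
        taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)
    return paths


def read_counts(path) -> pd.DataFrame:
    """Read a counts table: TSV (taxa x samples) or Matrix Market triplets.

    The MTX dialect expects ``<stem>.mtx`` plus ``<stem>_taxa.txt`` and
    ``<stem>_samples.txt`` index files, one identifier per line.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense())
        taxa = Path(str(path)[: -len(".mtx")] + "_taxa.txt").read_text().split()
        samples = Path(str(path)[: -len(".mtx")] + "_samples.txt").read_text().split()
        if mat.shape != (len(taxa), len(samples)):
            raise SchemaError("MTX dimensions do not match the index files")
        df = pd.DataFrame(mat, index=pd.Index(taxa, name="taxon_id"), columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "taxon_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise SchemaError(f"duplicate taxon ids: {dup}")
    if df.columns.duplicated().any():
        raise SchemaError("duplicate sample ids in counts")
    vals = df.to_numpy()
    if (vals < 0).any():
        raise SchemaError("negative read counts")
    if not np.allclose(vals, np.rint(vals)):
        bad = df.columns[np.where(~np.isclose(vals, np.rint(vals)))[1]][0]
        raise SchemaError(f"non-integer counts (first offending sample: {bad})")
    return df.astype(np.int64)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise SchemaError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"duplicate sample ids in metadata: {dup}")
    ok = set(TREATMENTS) | {TREATMENT_SOURCE}
    bad = set(meta["treatment"]) - ok
    if bad:
        raise SchemaError(f"unknown treatments: {sorted(bad)}")
    d = meta["dilution_factor"]
    bad_d = meta[(~d.isna()) & ((d <= 0) | (d > 1))]
    if len(bad_d):
        raise SchemaError(
            f"dilution factors outside (0, 1] for samples: {bad_d['sample_id'].tolist()}"
        )
    if not set(meta["timepoint"]) <= {"T0", "T12"}:
        raise SchemaError("timepoint must be T0 or T12")
    design_cols = ["experiment", "treatment", "dilution_factor", "replicate", "timepoint"]
    dup = meta[meta.duplicated(design_cols, keep=False)]
    if len(dup):
        raise SchemaError(f"duplicate design cells for samples: {dup['sample_id'].tolist()}")
    return meta


def read_densities(path) -> pd.DataFrame:
    dens = pd.read_csv(path)
    missing = set(DENSITY_COLUMNS) - set(dens.columns)
    if missing:
        raise SchemaError(f"density table missing columns: {sorted(missing)}")
    if (dens["cells_per_ml"] <= 0).any():
        bad = dens.loc[dens["cells_per_ml"] <= 0, "bottle_id"].tolist()
        raise SchemaError(f"non-positive densities for bottles: {bad}")
    return dens


def read_tables(counts_path, metadata_path, densities_path, taxonomy_path=None,
                allow_partial: bool = False):
    """Read and cross-validate the full pipeline input set."""
    counts = read_counts(counts_path)
    metadata = read_metadata(metadata_path)
    densities = read_densities(densities_path)
    unknown = set(counts.columns) - set(metadata["sample_id"])
    if unknown:
        raise SchemaError(f"samples in counts absent from metadata: {sorted(unknown)}")
    validate_design(metadata, allow_partial=allow_partial)
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t")
        if {"taxon_id", "order"} - set(taxonomy.columns):
            raise SchemaError("taxonomy must have columns taxon_id, order")
    return counts, metadata, densities, taxonomy


def validate_design(metadata: pd.DataFrame, allow_partial: bool = False) -> None:
    """Check the dilution-design cardinalities per experiment.

    Each experiment needs exactly one T0 source sample and, unless
    ``allow_partial``, a complete treatments x dilution factors x replicates
    grid of T12 samples (a failed sample makes a partial grid).
    """
    for exp, grp in metadata.groupby("experiment"):
        src = grp[grp["treatment"] == TREATMENT_SOURCE]
        if len(src) != 1:
            raise SchemaError(f"experiment {exp!r} has {len(src)} T0 source samples, expected 1")
        t12 = grp[grp["timepoint"] == "T12"]
        expected = (t12["treatment"].nunique() * t12["dilution_factor"].nunique()
                    * t12["replicate"].nunique())
        if len(t12) != expected and not allow_partial:
            raise SchemaError(
                f"experiment {exp!r} has {len(t12)} T12 samples but the full design "
                f"needs {expected}; pass allow_partial to accept"
            )
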