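"""Tab-separated file formats and pipeline configuration.

All tables are UTF-8 TSV with '.' decimals: the study's objects are small
tabular matrices and need no binary container.  OTU tables are written with
OTUs as rows (first column ``OTU_ID``) and samples as columns, the layout
sequencing pipelines conventionally emit; in memory they are transposed into
the samples x OTUs :class:`~snowcat.diversity.OtuTable`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diversity import OtuTable
from .msc import MscGeometry

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_table",
    "write_table",
    "FluxConfig",
    "DiversityConfig",
    "RegressionConfig",
    "PipelineConfig",
]


def write_otu_table(table: OtuTable, path) -> None:
    out = table.counts.T
    out.index.name = "OTU_ID"
    out.to_csv(path, sep="\t")


def read_otu_table(path, metadata=None) -> OtuTable:
    """Read an OTU TSV (rows = OTUs, columns = samples) and join metadata.

    Malformed cells are reported by OTU id and sample id; duplicate ids and
    samples missing from the metadata raise with the offending keys named.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "OTU_ID":
        raise ValueError(f"{path}: first column must be 'OTU_ID', got {raw.columns[0]!r}")
    raw = raw.set_index("OTU_ID")
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate OTU ids {dupes[:5]}")
    if raw.columns.duplicated().any():
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
    if bad.to_numpy().any():
        otu_idx, sample_idx = np.argwhere(bad.to_numpy())[0]
        otu = raw.index[otu_idx]
        sample = raw.columns[sample_idx]
        raise ValueError(
            f"{path}: count for OTU {otu!r} in sample {sample!r} is not a "
            f"non-negative integer: {raw.iloc[otu_idx, sample_idx]!r}"
        )
    counts = numeric.astype(np.int64).T  # samples x OTUs

    if metadata is None:
        meta = pd.DataFrame(
            {"fraction": "unknown", "depth_m": np.nan, "replicate": 0},
            index=counts.index,
        )
    else:
        meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
        missing = counts.index.difference(meta.index)
        if len(missing):
            raise ValueError(
                f"metadata missing join keys for samples: {list(missing)[:5]}"
            )
    return OtuTable(counts, meta.loc[counts.index].copy())


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    out = taxonomy.copy()
    out.index.name = "OTU_ID"
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t").set_index("OTU_ID")
    for col in ("family", "genus"):
        if col not in tax.columns:
            raise ValueError(f"{path}: taxonomy must contain a {col!r} column")
    return tax


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t").set_index("sample_id")
    return meta


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluxConfig:
    leucine_factor: float = 1.55
    isotope_dilution: float = 1.0
    pge: float = 0.08
    rq: float = 1.0
    cell_carbon_fg: float = 12.0


@dataclass(frozen=True)
class DiversityConfig:
    rarefy_depth: int | str = "min"
    k_families: int = 20
    nmds_restarts: int = 20
    nmds_max_iter: int = 300
    shannon_base: float | None = None  # None = natural log


@dataclass(frozen=True)
class RegressionConfig:
    exclude_fractions: tuple[str, ...] = ("fast",)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline."""

    seed: int = 0
    geometry: MscGeometry = field(default_factory=MscGeometry)
    flux: FluxConfig = field(default_factory=FluxConfig)
    diversity: DiversityConfig = field(default_factory=DiversityConfig)
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    fast_dilution: float = 2.0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict = {}
        blocks = {
            "geometry": MscGeometry,
            "flux": FluxConfig,
            "diversity": DiversityConfig,
            "regression": RegressionConfig,
        }
        for key, block_cls in blocks.items():
            if key in data:
                block = data.pop(key)
                if key == "regression" and "exclude_fractions" in block:
                    block["exclude_fractions"] = tuple(block["exclude_fractions"])
                kwargs[key] = block_cls(**block)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def sha256(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def file_sha256(path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()
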