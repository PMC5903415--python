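"""Core data containers for structural-covariance analyses.

A study is represented by a :class:`CorticalDataset`: a participants x regions
morphometry table (cortical thickness, in mm), per-participant metadata (age in
decimal years, sex), per-region metadata (hemisphere, 3-D anatomical centroid,
unit-sphere projection used by the spin test, optional community labels), and
optionally a set of magnetization-transfer (MT) maps keyed by cortical depth.

Everything is stored as plain pandas objects and serialized as delimited text,
so datasets round-trip through ``write_dataset`` / ``read_dataset`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegionSet",
    "CorticalDataset",
    "write_dataset",
    "read_dataset",
]

_REGION_COLUMNS = ["hemisphere", "cx", "cy", "cz", "sx", "sy", "sz"]


@dataclass
class RegionSet:
    """Region metadata: hemisphere, anatomical centroid, sphere projection.

    ``sphere`` rows are unit vectors on the (per-hemisphere) projection sphere;
    paired left/right regions are mirror images in the sagittal (x = 0) plane.
    ``module`` holds planted (or detected) community labels, 1-based.
    """

    hemisphere: np.ndarray          # (n,) array of "left"/"right"
    centroid: np.ndarray            # (n, 3) anatomical coordinates, mm
    sphere: np.ndarray              # (n, 3) unit vectors
    module: np.ndarray | None = None  # (n,) integer labels, optional
    region_id: np.ndarray = field(default=None)  # (n,) string ids

    def __post_init__(self) -> None:
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.sphere = np.asarray(self.sphere, dtype=float)
        n = len(self.hemisphere)
        if self.centroid.shape != (n, 3) or self.sphere.shape != (n, 3):
            raise ValueError("centroid and sphere must be (n, 3) arrays")
        norms = np.linalg.norm(self.sphere, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("sphere coordinates must have unit norm")
        if self.module is not None:
            self.module = np.asarray(self.module, dtype=int)
            if self.module.shape != (n,):
                raise ValueError("module labels must be length n")
        if self.region_id is None:
            self.region_id = np.array([f"r{i:03d}" for i in range(n)], dtype=object)
        else:
            self.region_id = np.asarray(self.region_id, dtype=object)

    @property
    def n_regions(self) -> int:
        return len(self.hemisphere)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "hemisphere": self.hemisphere,
                "cx": self.centroid[:, 0],
                "cy": self.centroid[:, 1],
                "cz": self.centroid[:, 2],
                "sx": self.sphere[:, 0],
                "sy": self.sphere[:, 1],
                "sz": self.sphere[:, 2],
            },
            index=pd.Index(self.region_id, name="region_id"),
        )
        if self.module is not None:
            df["module"] = self.module
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionSet":
        missing = [c for c in _REGION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"region table missing columns: {missing}")
        return cls(
            hemisphere=df["hemisphere"].to_numpy(),
            centroid=df[["cx", "cy", "cz"]].to_numpy(float),
            sphere=df[["sx", "sy", "sz"]].to_numpy(float),
            module=df["module"].to_numpy(int) if "module" in df.columns else None,
            region_id=df.index.to_numpy(object),
        )


@dataclass
class CorticalDataset:
    """Participants x regions morphometry with participant and region metadata."""

    values: pd.DataFrame                  # participants x regions (CT, mm)
    participants: pd.DataFrame            # index participant_id; columns age, sex
    regions: pd.DataFrame                 # index region_id; see _REGION_COLUMNS
    mt: dict[str, pd.DataFrame] = field(default_factory=dict)  # depth -> table

    def __post_init__(self) -> None:
        if "age" not in self.participants.columns:
            raise ValueError("participant table must have an 'age' column")
        if not self.values.index.equals(self.participants.index):
            raise ValueError("values rows and participant table rows do not match")
        if self.values.shape[1] != self.regions.shape[0] or not (
            self.values.columns.astype(str) == self.regions.index.astype(str)
        ).all():
            raise ValueError(
                "dimension mismatch: value matrix has "
                f"{self.values.shape[1]} region columns but region table has "
                f"{self.regions.shape[0]} rows (ids must match in order)"
            )
        bad = self.participants.index[self.participants["age"].isna()]
        if len(bad):
            raise ValueError(f"participant(s) lacking age: {list(bad)}")
        for depth, table in self.mt.items():
            if table.shape != self.values.shape:
                raise ValueError(f"MT map at depth {depth!r} has mismatched shape")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def ages(self) -> np.ndarray:
        return self.participants["age"].to_numpy(float)

    @property
    def centroids(self) -> np.ndarray:
        return self.regions[["cx", "cy", "cz"]].to_numpy(float)

    @property
    def region_set(self) -> RegionSet:
        return RegionSet.from_frame(self.regions)

    def subset(self, participant_ids) -> "CorticalDataset":
        """Row-subset (e.g. one sex, one window) preserving region metadata."""
        return CorticalDataset(
            values=self.values.loc[participant_ids],
            participants=self.participants.loc[participant_ids],
            regions=self.regions,
            mt={d: t.loc[participant_ids] for d, t in self.mt.items()},
        )


def write_dataset(dataset: CorticalDataset, path, ground_truth=None) -> Path:
    """Write a dataset as delimited text under directory ``path``.

    Layout: ``values.csv`` (participants x regions), ``participants.csv``,
    ``regions.csv``, optional ``mt_<depth>.csv`` per depth and
    ``ground_truth.json`` (key-value record of the generating model).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    fmt = "%.17g"  # guarantees bit-exact float64 round-trips through text
    dataset.values.to_csv(path / "values.csv", float_format=fmt)
    dataset.participants.to_csv(path / "participants.csv", float_format=fmt)
    dataset.regions.to_csv(path / "regions.csv", float_format=fmt)
    for depth, table in dataset.mt.items():
        table.to_csv(path / f"mt_{_depth_slug(depth)}.csv", float_format=fmt)
    if dataset.mt:
        (path / "mt_depths.json").write_text(json.dumps(list(dataset.mt)))
    if ground_truth is not None:
        (path / "ground_truth.json").write_text(ground_truth.to_json())
    return path


def read_dataset(path) -> CorticalDataset:
    """Read a dataset written by :func:`write_dataset`; validates consistency."""
    path = Path(path)
    kw = dict(index_col=0, float_precision="round_trip")
    try:
        values = pd.read_csv(path / "values.csv", **kw)
        participants = pd.read_csv(path / "participants.csv", **kw)
        regions = pd.read_csv(path / "regions.csv", **kw)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"malformed dataset directory {path}: {exc}") from exc
    mt: dict[str, pd.DataFrame] = {}
    depth_file = path / "mt_depths.json"
    if depth_file.exists():
        for depth in json.loads(depth_file.read_text()):
            mt[depth] = pd.read_csv(path / f"mt_{_depth_slug(depth)}.csv", **kw)
    return CorticalDataset(values=values, participants=participants,
                           regions=regions, mt=mt)


def _depth_slug(depth: str) -> str:
    return str(depth).replace("%", "pct").replace(" ", "_")
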