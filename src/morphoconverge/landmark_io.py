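"""Reading, writing and validation of 3D landmark data.

Supported on-disk formats:

* CSV, *wide* dialect: one row per specimen, columns ``specimen_id, x1, y1,
  z1, x2, ...`` (landmark names may replace the numeric suffix).
* CSV, *long* dialect: one row per landmark, columns ``specimen_id,
  landmark, x, y, z``.
* TPS: ``LM3=k`` records followed by ``k`` coordinate lines, with optional
  ``ID=`` and ``SCALE=`` lines.
* pts: plain-text ``name x y z`` lines (IDAV-style point export); names
  containing spaces must be quoted.

Landmark indices are 1-based in every file and error message (the
convention of the field); internally everything is 0-based.
"""

from __future__ import annotations

import logging
import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAGE_LEVELS = ("DE", "DL", "wild")
PERIOD_LEVELS = ("historic", "modern")

_PLANES = {"x": 0, "y": 1, "z": 2}


class LandmarkError(ValueError):
    """Raised for malformed landmark files or inconsistent datasets."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's ordered set of 3D landmarks."""

    specimen_id: str
    coords: np.ndarray  # (k, 3) float
    landmark_names: tuple[str, ...] = ()
    units: str = "mm"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise LandmarkError(
                f"specimen {self.specimen_id!r}: coords must be (k, 3), "
                f"got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            bad = np.argwhere(~np.isfinite(coords))[0]
            raise LandmarkError(
                f"specimen {self.specimen_id!r}: non-finite coordinate at "
                f"landmark {bad[0] + 1}"
            )
        object.__setattr__(self, "coords", coords)
        names = tuple(self.landmark_names) or tuple(
            f"LM{i + 1}" for i in range(coords.shape[0])
        )
        if len(names) != coords.shape[0]:
            raise LandmarkError(
                f"specimen {self.specimen_id!r}: {len(names)} landmark names "
                f"for {coords.shape[0]} landmarks"
            )
        object.__setattr__(self, "landmark_names", names)

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SymmetryMap:
    """Bilateral pairing of landmarks for object symmetry.

    ``pairs`` and ``midline`` are 0-based internally and must partition
    ``range(k)`` with no overlap.
    """

    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]
    reflection_plane: str = "x"

    def __post_init__(self) -> None:
        if self.reflection_plane not in _PLANES:
            raise LandmarkError(
                f"reflection_plane must be one of {sorted(_PLANES)}, "
                f"got {self.reflection_plane!r}"
            )
        object.__setattr__(
            self, "pairs", tuple((int(a), int(b)) for a, b in self.pairs)
        )
        object.__setattr__(self, "midline", tuple(int(i) for i in self.midline))
        seen: set[int] = set()
        for idx in [i for p in self.pairs for i in p] + list(self.midline):
            if idx < 0:
                raise LandmarkError(f"negative landmark index {idx + 1}")
            if idx in seen:
                raise LandmarkError(
                    f"landmark {idx + 1} appears more than once in symmetry map"
                )
            seen.add(idx)

    @property
    def k(self) -> int:
        return 2 * len(self.pairs) + len(self.midline)

    @property
    def axis(self) -> int:
        return _PLANES[self.reflection_plane]

    def validate_for(self, k: int) -> None:
        indices = sorted(
            [i for p in self.pairs for i in p] + list(self.midline)
        )
        if any(i >= k for i in indices):
            bad = next(i for i in indices if i >= k)
            raise LandmarkError(
                f"symmetry index {bad + 1} out of range for k={k}"
            )
        if indices != list(range(k)):
            missing = sorted(set(range(k)) - set(indices))
            raise LandmarkError(
                "symmetry map does not partition landmarks; missing 1-based "
                f"indices {[i + 1 for i in missing]}"
            )

    def relabel_permutation(self) -> np.ndarray:
        """Index permutation swapping left and right landmark labels."""
        perm = np.arange(self.k)
        for left, right in self.pairs:
            perm[left], perm[right] = right, left
        return perm


@dataclass
class LandmarkDataset:
    """n landmark configurations sharing a schema, plus design factors."""

    coords: np.ndarray  # (n, k, 3)
    specimen_ids: tuple[str, ...]
    landmark_names: tuple[str, ...]
    lineage: np.ndarray  # (n,) str
    period: np.ndarray  # (n,) str
    symmetry: SymmetryMap | None = None
    units: str = "mm"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n, k = self.coords.shape[0], self.coords.shape[1]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise LandmarkError(f"coords must be (n, k, 3), got {self.coords.shape}")
        if n < 2:
            raise LandmarkError(f"dataset needs n >= 2 specimens, got {n}")
        if k < 4:
            raise LandmarkError(f"dataset needs k >= 4 landmarks, got {k}")
        self.specimen_ids = tuple(str(s) for s in self.specimen_ids)
        if len(set(self.specimen_ids)) != n:
            dup = pd.Series(self.specimen_ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise LandmarkError(f"duplicated specimen_id {dup!r}")
        self.landmark_names = tuple(self.landmark_names)
        if len(self.landmark_names) != k:
            raise LandmarkError("landmark_names length does not match k")
        self.lineage = np.asarray(self.lineage, dtype=object)
        self.period = np.asarray(self.period, dtype=object)
        if self.lineage.shape != (n,) or self.period.shape != (n,):
            raise LandmarkError("factor arrays must have one entry per specimen")
        if not np.all(np.isfinite(self.coords)):
            bad = int(np.argwhere(~np.isfinite(self.coords))[0][0])
            raise LandmarkError(
                f"non-finite coordinates for specimen {self.specimen_ids[bad]!r}"
            )
        if self.symmetry is not None:
            self.symmetry.validate_for(k)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def configurations(self) -> list[LandmarkConfiguration]:
        return [
            LandmarkConfiguration(sid, self.coords[i], self.landmark_names, self.units)
            for i, sid in enumerate(self.specimen_ids)
        ]

    def cell_counts(self) -> pd.DataFrame:
        return (
            pd.DataFrame({"lineage": self.lineage, "period": self.period})
            .value_counts()
            .unstack(fill_value=0)
        )

    def subset(self, mask: np.ndarray) -> "LandmarkDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return LandmarkDataset(
            coords=self.coords[idx],
            specimen_ids=tuple(self.specimen_ids[i] for i in idx),
            landmark_names=self.landmark_names,
            lineage=self.lineage[idx],
            period=self.period[idx],
            symmetry=self.symmetry,
            units=self.units,
        )


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------


def _wide_columns(names: Sequence[str]) -> list[str]:
    cols = ["specimen_id"]
    for name in names:
        cols += [f"{name}_x", f"{name}_y", f"{name}_z"]
    return cols


def read_landmarks_csv(path: str | Path, schema: str = "long") -> list[LandmarkConfiguration]:
    """Read landmark coordinates from CSV in the wide or long dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema not in ("wide", "long"):
        raise ValueError(f"schema must be 'wide' or 'long', got {schema!r}")
    df = pd.read_csv(path, dtype={"specimen_id": str})
    if schema == "wide":
        return _parse_wide(df)
    return _parse_long(df)


def _coerce_numeric(values: pd.Series, specimen: str, landmark: str) -> np.ndarray:
    out = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
    if np.any(pd.isna(values.to_numpy())) or not np.all(np.isfinite(out)):
        raise LandmarkError(
            f"specimen {specimen!r}: missing or non-numeric coordinate at "
            f"landmark {landmark}"
        )
    return out


def _parse_wide(df: pd.DataFrame) -> list[LandmarkConfiguration]:
    if "specimen_id" not in df.columns:
        raise LandmarkError("wide CSV must have a 'specimen_id' column")
    coord_cols = [c for c in df.columns if c != "specimen_id"]
    if len(coord_cols) % 3 != 0:
        raise LandmarkError(
            f"wide CSV has {len(coord_cols)} coordinate columns, not a multiple of 3"
        )
    names = []
    for j in range(0, len(coord_cols), 3):
        trip = coord_cols[j : j + 3]
        suffixes = [c.rsplit("_", 1)[-1] for c in trip]
        if suffixes != ["x", "y", "z"]:
            raise LandmarkError(
                f"wide CSV columns {trip} are not an x/y/z triplet"
            )
        names.append(trip[0].rsplit("_", 1)[0])
    configs = []
    for _, row in df.iterrows():
        sid = str(row["specimen_id"])
        coords = np.empty((len(names), 3))
        for i, name in enumerate(names):
            for d, ax in enumerate("xyz"):
                val = row[f"{name}_{ax}"]
                if pd.isna(val):
                    raise LandmarkError(
                        f"specimen {sid!r}: missing coordinate {ax} at "
                        f"landmark {i + 1} ({name})"
                    )
                try:
                    coords[i, d] = float(val)
                except (TypeError, ValueError):
                    raise LandmarkError(
                        f"specimen {sid!r}: non-numeric coordinate {val!r} at "
                        f"landmark {i + 1} ({name})"
                    ) from None
        configs.append(LandmarkConfiguration(sid, coords, tuple(names)))
    return configs


def _parse_long(df: pd.DataFrame) -> list[LandmarkConfiguration]:
    required = {"specimen_id", "landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise LandmarkError(
            f"long CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    order = df["specimen_id"].drop_duplicates().tolist()
    first = df[df["specimen_id"] == order[0]]
    names = tuple(str(x) for x in first["landmark"].tolist())
    if len(set(names)) != len(names):
        raise LandmarkError("duplicated landmark name within a specimen")
    configs = []
    for sid in order:
        block = df[df["specimen_id"] == sid]
        got = tuple(str(x) for x in block["landmark"].tolist())
        if sorted(got) != sorted(names):
            missing = sorted(set(names) - set(got))
            raise LandmarkError(
                f"specimen {sid!r}: missing landmark(s) {missing or got}"
            )
        block = block.set_index("landmark").loc[list(names)]
        coords = np.column_stack(
            [_coerce_numeric(block[ax], str(sid), "column " + ax) for ax in "xyz"]
        )
        configs.append(LandmarkConfiguration(str(sid), coords, names))
    return configs


def write_landmarks_csv(
    configs: Iterable[LandmarkConfiguration] | LandmarkDataset,
    path: str | Path,
    schema: str = "long",
) -> None:
    """Write configurations to CSV (inverse of :func:`read_landmarks_csv`)."""
    if isinstance(configs, LandmarkDataset):
        configs = configs.configurations()
    configs = list(configs)
    if schema == "wide":
        names = configs[0].landmark_names
        rows = []
        for c in configs:
            row: dict[str, object] = {"specimen_id": c.specimen_id}
            for name, xyz in zip(c.landmark_names, c.coords):
                row[f"{name}_x"], row[f"{name}_y"], row[f"{name}_z"] = xyz
            rows.append(row)
        pd.DataFrame(rows, columns=_wide_columns(names)).to_csv(path, index=False)
    elif schema == "long":
        rows = []
        for c in configs:
            for name, (x, y, z) in zip(c.landmark_names, c.coords):
                rows.append(
                    {"specimen_id": c.specimen_id, "landmark": name, "x": x, "y": y, "z": z}
                )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"schema must be 'wide' or 'long', got {schema!r}")


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a TPS file with LM3/ID/SCALE records."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    configs: list[LandmarkConfiguration] = []
    i, record = 0, 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise LandmarkError(
                f"TPS record {record + 1}: expected LM3= line, got {line!r}"
            )
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise LandmarkError(
                f"TPS record {record + 1}: bad landmark count in {line!r}"
            ) from None
        i += 1
        coords = np.empty((k, 3))
        for j in range(k):
            if i >= len(lines):
                raise LandmarkError(
                    f"TPS record {record + 1}: file ends after {j} of {k} landmarks"
                )
            parts = lines[i].split()
            if len(parts) != 3:
                raise LandmarkError(
                    f"TPS record {record + 1}: landmark count mismatch — "
                    f"LM3={k} but line {j + 1} is {lines[i]!r}"
                )
            try:
                coords[j] = [float(p) for p in parts]
            except ValueError:
                raise LandmarkError(
                    f"TPS record {record + 1}: non-numeric coordinate in {lines[i]!r}"
                ) from None
            i += 1
        sid, scale = f"record_{record + 1}", 1.0
        while i < len(lines) and lines[i] and "=" in lines[i] and not lines[i].upper().startswith("LM3="):
            key, _, value = lines[i].partition("=")
            key = key.strip().upper()
            if key == "ID":
                sid = value.strip()
            elif key == "SCALE":
                scale = float(value.strip())
            i += 1
        configs.append(LandmarkConfiguration(sid, coords * scale))
        record += 1
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration] | LandmarkDataset, path: str | Path) -> None:
    if isinstance(configs, LandmarkDataset):
        configs = configs.configurations()
    out = []
    for c in configs:
        out.append(f"LM3={c.k}")
        out.extend(" ".join(f"{v:.17g}" for v in pt) for pt in c.coords)
        out.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# pts
# ---------------------------------------------------------------------------


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_pts(path: str | Path) -> LandmarkConfiguration:
    """Read a plain-text ``name x y z`` point export."""
    path = Path(path)
    names: list[str] = []
    coords: list[list[float]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        tokens = shlex.split(line)
        if len(tokens) < 4 or not all(_is_number(t) for t in tokens[-3:]):
            # header / count-declaration line
            if coords:
                raise LandmarkError(f"malformed pts line {raw!r}")
            continue
        names.append(" ".join(tokens[:-3]))
        coords.append([float(t) for t in tokens[-3:]])
    if len(coords) < 4:
        raise LandmarkError(
            f"pts file {path.name}: fewer than 4 points ({len(coords)})"
        )
    return LandmarkConfiguration(path.stem, np.asarray(coords), tuple(names))


def write_pts(config: LandmarkConfiguration, path: str | Path) -> None:
    lines = []
    for name, (x, y, z) in zip(config.landmark_names, config.coords):
        quoted = f'"{name}"' if " " in name else name
        lines.append(f"{quoted} {x:.17g} {y:.17g} {z:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# metadata / symmetry tables and dataset assembly
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = {"specimen_id", "lineage", "period"}
    if not required.issubset(df.columns):
        raise LandmarkError(
            f"metadata must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return df


def read_symmetry_table(path: str | Path, reflection_plane: str = "x") -> tuple[list[tuple[int, int]], list[int]]:
    """Read a bilateral-pairing table.

    Columns ``left, right`` carry 1-based landmark indices; a row with an
    empty ``right`` declares a midline landmark. Returns 0-based pairs and
    midline lists.
    """
    df = pd.read_csv(path)
    if "left" not in df.columns or "right" not in df.columns:
        raise LandmarkError("symmetry table must have 'left' and 'right' columns")
    pairs: list[tuple[int, int]] = []
    midline: list[int] = []
    for _, row in df.iterrows():
        left = int(row["left"])
        if pd.isna(row["right"]):
            midline.append(left - 1)
        else:
            pairs.append((left - 1, int(row["right"]) - 1))
    return pairs, midline


def write_symmetry_table(symmetry: SymmetryMap, path: str | Path) -> None:
    rows = [{"left": a + 1, "right": b + 1} for a, b in symmetry.pairs]
    rows += [{"left": i + 1, "right": None} for i in symmetry.midline]
    pd.DataFrame(rows, columns=["left", "right"]).to_csv(path, index=False)


def write_metadata(dataset: LandmarkDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "specimen_id": dataset.specimen_ids,
            "lineage": dataset.lineage,
            "period": dataset.period,
        }
    ).to_csv(path, index=False)


def assemble_dataset(
    configs: Sequence[LandmarkConfiguration],
    metadata: pd.DataFrame,
    symmetry: SymmetryMap | None = None,
    allowed_lineages: Sequence[str] | None = LINEAGE_LEVELS,
    allowed_periods: Sequence[str] | None = PERIOD_LEVELS,
) -> LandmarkDataset:
    """Join coordinates with design factors into a validated dataset.

    Specimens without a metadata row are dropped with a warning; metadata
    rows without coordinates are ignored (the dataset is sized by the
    coordinates). Assembly is stable under metadata row order.
    """
    if not configs:
        raise LandmarkError("no landmark configurations supplied")
    names = configs[0].landmark_names
    k = configs[0].k
    for c in configs:
        if c.k != k or c.landmark_names != names:
            raise LandmarkError(
                f"specimen {c.specimen_id!r} has a different landmark schema"
            )
    meta = metadata.drop_duplicates(subset="specimen_id").set_index("specimen_id")
    kept, dropped = [], []
    for c in configs:
        (kept if c.specimen_id in meta.index else dropped).append(c)
    if dropped:
        logger.warning(
            "dropping %d specimen(s) lacking metadata: %s",
            len(dropped),
            [c.specimen_id for c in dropped],
        )
    if not kept:
        raise LandmarkError("no specimens shared between coordinates and metadata")
    lineage = np.array([meta.loc[c.specimen_id, "lineage"] for c in kept], dtype=object)
    period = np.array([meta.loc[c.specimen_id, "period"] for c in kept], dtype=object)
    for value, allowed, what in (
        (lineage, allowed_lineages, "lineage"),
        (period, allowed_periods, "period"),
    ):
        if allowed is not None:
            unknown = sorted(set(value) - set(allowed))
            if unknown:
                raise LandmarkError(
                    f"unknown {what} level(s) {unknown}; allowed: {list(allowed)}"
                )
    dataset = LandmarkDataset(
        coords=np.stack([c.coords for c in kept]),
        specimen_ids=tuple(c.specimen_id for c in kept),
        landmark_names=names,
        lineage=lineage,
        period=period,
        symmetry=symmetry,
        units=kept[0].units,
    )
    counts = dataset.cell_counts()
    logger.info("assembled %d specimens, %d landmarks; cells:\n%s", dataset.n, k, counts)
    return dataset


# ---------------------------------------------------------------------------
# bundled HDF5 dataset artifact (lossless round-trip container)
# ---------------------------------------------------------------------------


def save_dataset_h5(dataset: LandmarkDataset, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=dataset.coords)
        str_dt = h5py.string_dtype("utf-8")
        f.create_dataset("specimen_ids", data=list(dataset.specimen_ids), dtype=str_dt)
        f.create_dataset("landmark_names", data=list(dataset.landmark_names), dtype=str_dt)
        f.create_dataset("lineage", data=[str(x) for x in dataset.lineage], dtype=str_dt)
        f.create_dataset("period", data=[str(x) for x in dataset.period], dtype=str_dt)
        f.attrs["units"] = dataset.units
        if dataset.symmetry is not None:
            f.create_dataset("symmetry/pairs", data=np.asarray(dataset.symmetry.pairs, dtype=int).reshape(-1, 2))
            f.create_dataset("symmetry/midline", data=np.asarray(dataset.symmetry.midline, dtype=int))
            f.attrs["reflection_plane"] = dataset.symmetry.reflection_plane


def load_dataset_h5(path: str | Path) -> LandmarkDataset:
    import h5py

    with h5py.File(path, "r") as f:
        symmetry = None
        if "symmetry" in f:
            symmetry = SymmetryMap(
                pairs=tuple(map(tuple, f["symmetry/pairs"][()])),
                midline=tuple(f["symmetry/midline"][()]),
                reflection_plane=f.attrs.get("reflection_plane", "x"),
            )
        return LandmarkDataset(
            coords=f["coords"][()],
            specimen_ids=tuple(s.decode() for s in f["specimen_ids"][()]),
            landmark_names=tuple(s.decode() for s in f["landmark_names"][()]),
            lineage=np.array([s.decode() for s in f["lineage"][()]], dtype=object),
            period=np.array([s.decode() for s in f["period"][()]], dtype=object),
            symmetry=symmetry,
            units=f.attrs.get("units", "mm"),
        )
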