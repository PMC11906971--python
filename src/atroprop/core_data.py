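"""Domain types and plain-text I/O for parcellated regional data.

Everything downstream operates on *parcellated* tables: one scalar per
cortical region, per subject, per visit.  Region identity is carried as an
ordered list of string ids, and every multi-input operation in the package
verifies id agreement instead of silently reindexing.  Missing regional
values are represented as NaN and exposed through ``missing_mask``.

File formats are delimited text only (TSV by default, comma accepted):
the pipeline starts strictly after image processing, parcellation and site
harmonization.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("HC", "FHAD", "AD")
SEXES = ("M", "F")

#: fixed column schema for longitudinal scan tables
META_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education_y",
    "bmi",
    "apoe4",
    "site",
    "visit",
]

REGION_PREFIX = "region_"


class RegionAlignmentError(ValueError):
    """Raised when two inputs disagree on region identity or order."""


def check_same_regions(a: Sequence[str], b: Sequence[str], what: str = "inputs") -> None:
    """Require two ordered region-id lists to be identical.

    Downstream operations call this rather than reindexing, so a misaligned
    deformation map can never be correlated against a connectome row for a
    different region.
    """
    a = list(a)
    b = list(b)
    if a != b:
        n = min(len(a), len(b))
        first_bad = next(
            (i for i in range(n) if a[i] != b[i]), n if len(a) != len(b) else None
        )
        raise RegionAlignmentError(
            f"region ids of {what} disagree (lengths {len(a)} vs {len(b)}; "
            f"first difference at index {first_bad})"
        )


def _as_id_array(region_ids: Iterable) -> np.ndarray:
    ids = np.asarray([str(r) for r in region_ids], dtype=object)
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        dup = dup[dup > 1].index.tolist()
        raise ValueError(f"duplicate region ids: {dup[:5]}")
    return ids


def default_region_ids(R: int) -> list[str]:
    width = max(3, len(str(R - 1)))
    return [f"{REGION_PREFIX}{i:0{width}d}" for i in range(R)]


@dataclass
class RegionalMap:
    """One scalar per cortical region.

    ``values`` may hold NaN for regions with no data; all non-missing values
    must be finite.  ``measure_label`` tags the units (e.g. ``"dbm"`` for the
    unitless log-Jacobian-like deformation scale, ``"w"`` for control-SD
    units, ``"beta"`` for deformation units per year, ``"suvr"``,
    ``"receptor_z"``).
    """

    region_ids: Sequence[str]
    values: np.ndarray
    measure_label: str = ""

    def __post_init__(self) -> None:
        self.region_ids = _as_id_array(self.region_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.region_ids):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.region_ids)} region ids"
            )
        bad = np.isinf(self.values)
        if bad.any():
            raise ValueError(
                f"non-finite (infinite) values at regions "
                f"{list(np.asarray(self.region_ids)[bad][:5])}"
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray, measure_label: str | None = None) -> "RegionalMap":
        return RegionalMap(
            list(self.region_ids),
            values,
            self.measure_label if measure_label is None else measure_label,
        )


@dataclass
class Connectome:
    """Binary symmetric structural connectivity with 3-D region coordinates (mm)."""

    region_ids: Sequence[str]
    adjacency: np.ndarray
    coordinates: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.region_ids = _as_id_array(self.region_ids)
        A = np.asarray(self.adjacency)
        R = len(self.region_ids)
        if A.shape != (R, R):
            raise ValueError(f"adjacency shape {A.shape} does not match {R} regions")
        if not np.array_equal(A, A.T):
            bad = np.argwhere(A != A.T)
            raise ValueError(
                f"adjacency is not symmetric (e.g. entry {tuple(bad[0])})"
            )
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be binary (0/1)")
        if np.any(np.diag(A) != 0):
            warnings.warn("nonzero adjacency diagonal forced to 0", stacklevel=2)
            A = A.copy()
            np.fill_diagonal(A, 0)
        self.adjacency = A.astype(np.int8)
        C = np.asarray(self.coordinates, dtype=float)
        if C.shape != (R, 3):
            raise ValueError(f"coordinates shape {C.shape}, expected ({R}, 3)")
        if not np.isfinite(C).all():
            raise ValueError("coordinates must be finite")
        self.coordinates = C

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def density(self) -> float:
        R = self.n_regions
        return float(self.adjacency.sum() / (R * (R - 1)))


@dataclass
class NetworkPartition:
    """Assignment of every region to exactly one of a small set of networks
    (canonically the 7 resting-state networks of the Yeo parcellation)."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.mapping.values():
            seen.setdefault(lab, None)
        return list(seen)

    def check_covers(self, region_ids: Sequence[str]) -> None:
        missing = [r for r in region_ids if str(r) not in self.mapping]
        if missing:
            raise ValueError(f"partition misses regions {missing[:5]}")

    def indices_by_label(self, region_ids: Sequence[str]) -> dict[str, np.ndarray]:
        self.check_covers(region_ids)
        out: dict[str, list[int]] = {lab: [] for lab in self.labels}
        for i, r in enumerate(region_ids):
            out[self.mapping[str(r)]].append(i)
        return {lab: np.asarray(ix, dtype=int) for lab, ix in out.items()}


@dataclass
class ReceptorAtlas:
    """Receptor/transporter density maps, one or more PET tracer studies per
    target, each weighted by its sample size."""

    entries: Mapping[str, Sequence[tuple[RegionalMap, float]]]

    def __post_init__(self) -> None:
        self.entries = {k: list(v) for k, v in self.entries.items()}
        ref_ids: list[str] | None = None
        for target, maps in self.entries.items():
            if not maps:
                raise ValueError(f"target {target!r} has no tracer maps")
            for m, w in maps:
                if w <= 0:
                    raise ValueError(f"non-positive weight {w} for target {target!r}")
                if ref_ids is None:
                    ref_ids = list(m.region_ids)
                else:
                    check_same_regions(ref_ids, m.region_ids, f"receptor atlas ({target})")

    @property
    def targets(self) -> list[str]:
        return list(self.entries)

    @property
    def region_ids(self) -> list[str]:
        first = next(iter(self.entries.values()))
        return list(first[0][0].region_ids)


@dataclass
class CategoricalTestResult:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("test statistic must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass
class LongitudinalDataset:
    """Scan-level longitudinal records with a shared regional value matrix.

    ``meta`` has one row per scan with columns :data:`META_COLUMNS`;
    ``values`` is the (n_scans, R) matrix of regional measurements aligned
    with ``region_ids``.  Rows are kept sorted by (subject_id, visit).
    """

    meta: pd.DataFrame
    values: np.ndarray
    region_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.region_ids = _as_id_array(self.region_ids)
        meta = self.meta.reset_index(drop=True)
        missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
        if missing_cols:
            raise ValueError(f"meta is missing columns {missing_cols}")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape != (len(meta), len(self.region_ids)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"({len(meta)} scans, {len(self.region_ids)} regions)"
            )
        bad_group = ~meta["group"].isin(GROUPS)
        if bad_group.any():
            raise ValueError(
                f"unknown group labels {sorted(meta.loc[bad_group, 'group'].unique())}"
            )
        dup = meta.duplicated(subset=["subject_id", "visit"])
        if dup.any():
            rows = meta.index[dup].tolist()
            raise ValueError(f"duplicate (subject, visit) pairs at rows {rows[:5]}")
        ngroups = meta.groupby("subject_id")["group"].nunique()
        conflicted = ngroups[ngroups > 1].index.tolist()
        if conflicted:
            raise ValueError(
                f"subjects with conflicting group labels: {conflicted[:5]}"
            )
        order = np.lexsort((meta["visit"].to_numpy(), meta["subject_id"].to_numpy()))
        meta = meta.iloc[order].reset_index(drop=True)
        vals = vals[order]
        for sid, sub in meta.groupby("subject_id"):
            ages = sub.sort_values("visit")["age"].to_numpy()
            if len(ages) > 1 and not np.all(np.diff(ages) > 0):
                raise ValueError(
                    f"age_at_scan not strictly increasing with visit for subject {sid!r}"
                )
        self.meta = meta
        self.values = vals

    # -- convenience ----------------------------------------------------
    @property
    def n_scans(self) -> int:
        return len(self.meta)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_subjects(self) -> int:
        return self.meta["subject_id"].nunique()

    def subjects(self) -> pd.DataFrame:
        """One row per subject with baseline metadata."""
        return (
            self.meta.sort_values(["subject_id", "visit"])
            .groupby("subject_id", as_index=False)
            .first()
        )

    def scan_counts(self) -> pd.DataFrame:
        counts = self.meta.groupby("subject_id").size().rename("n_scans")
        groups = self.meta.groupby("subject_id")["group"].first()
        return pd.concat([groups, counts], axis=1).reset_index()

    def select(self, mask: np.ndarray) -> "LongitudinalDataset":
        mask = np.asarray(mask, dtype=bool)
        return LongitudinalDataset(
            self.meta.loc[mask].reset_index(drop=True),
            self.values[mask],
            list(self.region_ids),
        )

    def baseline(self) -> "LongitudinalDataset":
        return self.select((self.meta["visit"] == 0).to_numpy())

    def restrict_group(self, *groups: str) -> "LongitudinalDataset":
        return self.select(self.meta["group"].isin(groups).to_numpy())

    def to_frame(self) -> pd.DataFrame:
        region_df = pd.DataFrame(self.values, columns=list(self.region_ids))
        return pd.concat([self.meta.reset_index(drop=True), region_df], axis=1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, accepting tabs or commas, with
    round-trip-exact float parsing."""
    with open(path) as fh:
        first = fh.readline()
    sep = "," if first.count(",") > first.count("\t") else "\t"
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_longitudinal_table(
    path: str | Path, schema_config: Mapping[str, str] | None = None
) -> LongitudinalDataset:
    """Load a scan-level table (one row per scan, ``region_*`` value columns).

    ``schema_config`` optionally maps file column names onto the fixed schema,
    e.g. ``{"subj": "subject_id"}``.  Validation failures are hard errors that
    name the offending row or cell.
    """
    df = _read_table(path)
    if schema_config:
        df = df.rename(columns=dict(schema_config))
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.astype(
        {"age": float, "education_y": float, "bmi": float, "visit": int}
    )
    region_cols = [c for c in df.columns if c.startswith(REGION_PREFIX)]
    if not region_cols:
        raise ValueError(f"{path}: no '{REGION_PREFIX}*' columns found")
    vals = np.empty((len(df), len(region_cols)))
    for j, col in enumerate(region_cols):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in cell "
                f"(row {row}, column {col!r})"
            )
        vals[:, j] = coerced.to_numpy()
    return LongitudinalDataset(df[META_COLUMNS], vals, region_cols)


def save_longitudinal_table(dataset: LongitudinalDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def save_map(regional_map: RegionalMap, path: str | Path) -> None:
    """Write a two-column (region_id, value) TSV; missing values as empty."""
    with open(path, "w") as fh:
        fh.write(f"region_id\t{regional_map.measure_label or 'value'}\n")
        for rid, v in zip(regional_map.region_ids, regional_map.values):
            fh.write(f"{rid}\t{'' if np.isnan(v) else format(v, '.17g')}\n")


def load_map(path: str | Path) -> RegionalMap:
    df = _read_table(path)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns, got {df.shape[1]}")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValueError(
            f"{path}: duplicate region ids {ids[ids.duplicated()].tolist()[:5]}"
        )
    return RegionalMap(ids.tolist(), df.iloc[:, 1].to_numpy(dtype=float), df.columns[1])


def load_connectome(
    adjacency_path: str | Path, coords_path: str | Path
) -> Connectome:
    """Load a dense binary adjacency matrix and a region-id keyed coordinate
    table; asymmetry is a hard failure, a nonzero diagonal is zeroed with a
    warning."""
    raw = Path(adjacency_path).read_text()
    delim = "," if "," in raw.splitlines()[0] else None
    A = np.loadtxt(io.StringIO(raw), delimiter=delim)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{adjacency_path}: adjacency must be square, got {A.shape}")
    if not np.array_equal(A, A.T):
        bad = np.argwhere(A != A.T)[0]
        raise ValueError(
            f"{adjacency_path}: asymmetric adjacency (A[{bad[0]},{bad[1]}] != "
            f"A[{bad[1]},{bad[0]}])"
        )
    coords = _read_table(coords_path)
    if coords.shape[1] != 4:
        raise ValueError(
            f"{coords_path}: expected columns (region_id, x, y, z), got "
            f"{list(coords.columns)}"
        )
    ids = coords.iloc[:, 0].astype(str).tolist()
    xyz = coords.iloc[:, 1:4].to_numpy(dtype=float)
    return Connectome(ids, A, xyz)


def save_connectome(conn: Connectome, adjacency_path: str | Path, coords_path: str | Path) -> None:
    np.savetxt(adjacency_path, conn.adjacency, fmt="%d", delimiter="\t")
    df = pd.DataFrame(conn.coordinates, columns=["x", "y", "z"])
    df.insert(0, "region_id", list(conn.region_ids))
    df.to_csv(coords_path, sep="\t", index=False, float_format="%.17g")


def load_partition(path: str | Path) -> NetworkPartition:
    df = _read_table(path)
    return NetworkPartition(
        dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    )


def save_partition(partition: NetworkPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tnetwork\n")
        for rid, lab in partition.mapping.items():
            fh.write(f"{rid}\t{lab}\n")
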