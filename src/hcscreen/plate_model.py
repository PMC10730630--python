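"""Domain model of a high-content screen.

A screen is a set of 384-well plates imaged in replicate.  Each well holds one
condition (a compound, an siRNA, or a control) and is imaged as F fields in C
fluorescence channels.  Downstream stages all operate on a single container,
the :class:`FeatureTable`, indexed by (plate, replicate, well) and carrying one
feature vector per well, which moves through three states:
``raw`` → ``spatially_corrected`` → ``aligned``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

N_ROWS = 16
N_COLS = 24
ROW_LETTERS = "ABCDEFGHIJKLMNOP"

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


class ControlRole(str, enum.Enum):
    """Role of a well: vehicle-only baseline, known perturbant, or tested sample."""

    negative = "negative"
    positive = "positive"
    sample = "sample"


@dataclass(frozen=True, order=True)
class WellAddress:
    """Position on a 384-well plate: row letter A–P, column 1–24."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS:
            raise ValueError(f"row must be one of A..P, got {self.row!r}")
        if not 1 <= self.column <= N_COLS:
            raise ValueError(f"column must be in 1..{N_COLS}, got {self.column}")

    @classmethod
    def parse(cls, name: str) -> "WellAddress":
        """Parse 'A1' or 'A01' (exporter dialects differ); case-insensitive."""
        m = _WELL_RE.match(name.strip())
        if m is None:
            raise ValueError(f"cannot parse well name {name!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column:02d}"

    @property
    def row_index(self) -> int:
        """0-based row index (A → 0)."""
        return ROW_LETTERS.index(self.row)

    @property
    def col_index(self) -> int:
        """0-based column index (1 → 0)."""
        return self.column - 1


@dataclass
class PlateLayout:
    """One plate of one replicate: well → (condition, role), plus imaging geometry.

    Wells absent from ``wells`` are empty (not dispensed, not imaged); a 384-well
    screen need not fill every position.
    """

    plate_id: str
    replicate_id: str
    wells: dict[WellAddress, tuple[str, ControlRole]] = field(default_factory=dict)
    fields_per_well: int = 4
    channels: int = 2

    def __post_init__(self) -> None:
        if self.fields_per_well < 1 or self.channels < 1:
            raise ValueError("fields_per_well and channels must be positive")

    def wells_with_role(self, role: ControlRole) -> list[WellAddress]:
        return [w for w, (_, r) in self.wells.items() if r == role]

    @property
    def n_wells(self) -> int:
        return len(self.wells)


class TableState(str, enum.Enum):
    raw = "raw"
    spatially_corrected = "spatially_corrected"
    aligned = "aligned"


_STATE_ORDER = [TableState.raw, TableState.spatially_corrected, TableState.aligned]

INDEX_COLS = ["plate_id", "replicate_id", "well"]


@dataclass
class FeatureTable:
    """Per-well feature matrix of a whole screen.

    ``data`` is a DataFrame indexed by (plate_id, replicate_id, well-string)
    with numeric feature columns f_0001..f_D.  Values must be finite.
    """

    data: pd.DataFrame
    state: TableState = TableState.raw

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex) or list(self.data.index.names) != INDEX_COLS:
            raise ValueError(f"FeatureTable index must be a MultiIndex {INDEX_COLS}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            bad = int(np.sum(~np.isfinite(values)))
            raise ValueError(f"FeatureTable contains {bad} non-finite values")

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def advance_state(self, new_state: TableState) -> None:
        """Enforce the one-way raw → spatially_corrected → aligned transition."""
        if _STATE_ORDER.index(new_state) != _STATE_ORDER.index(self.state) + 1:
            raise ValueError(f"illegal state transition {self.state.value} → {new_state.value}")
        self.state = new_state

    @staticmethod
    def feature_columns(n_features: int) -> list[str]:
        width = max(4, len(str(n_features)))
        return [f"f_{i + 1:0{width}d}" for i in range(n_features)]

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        index: Iterable[tuple[str, str, str]],
        state: TableState = TableState.raw,
    ) -> "FeatureTable":
        values = np.asarray(values, dtype=float)
        idx = pd.MultiIndex.from_tuples(list(index), names=INDEX_COLS)
        df = pd.DataFrame(values, index=idx, columns=cls.feature_columns(values.shape[1]))
        return cls(df, state=state)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "state", self.state.value)
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        # round_trip parsing keeps serialized intermediates bit-identical
        df = pd.read_csv(path, index_col=INDEX_COLS, float_precision="round_trip")
        state = TableState.raw
        if "state" in df.columns:
            states = df.pop("state").unique()
            if len(states) != 1:
                raise ValueError(f"inconsistent state column in {path}: {states}")
            state = TableState(states[0])
        return cls(df.astype(float), state=state)


# ---------------------------------------------------------------------------
# Plate-map I/O


def read_platemap(path, fields_per_well: int = 4, channels: int = 2) -> list[PlateLayout]:
    """Read a plate-map CSV with columns plate_id, replicate_id, well, condition_id, role."""
    df = pd.read_csv(path, dtype=str)
    required = {"plate_id", "replicate_id", "well", "condition_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate map {path} missing columns: {sorted(missing)}")
    layouts: dict[tuple[str, str], PlateLayout] = {}
    for row in df.itertuples(index=False):
        key = (row.plate_id, row.replicate_id)
        layout = layouts.setdefault(
            key,
            PlateLayout(row.plate_id, row.replicate_id, {}, fields_per_well, channels),
        )
        addr = WellAddress.parse(row.well)
        if addr in layout.wells:
            raise ValueError(f"duplicate well {addr} on plate {row.plate_id}/{row.replicate_id}")
        layout.wells[addr] = (row.condition_id, ControlRole(row.role))
    return list(layouts.values())


def write_platemap(layouts: Iterable[PlateLayout], path) -> None:
    rows = [
        {
            "plate_id": lay.plate_id,
            "replicate_id": lay.replicate_id,
            "well": str(well),
            "condition_id": cond,
            "role": role.value,
        }
        for lay in layouts
        for well, (cond, role) in sorted(lay.wells.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Bookkeeping operations


def expected_image_count(layout: PlateLayout) -> int:
    """Number of single-channel image files a complete plate acquisition yields.

    One file per well × field × channel; e.g. a full 384-well plate imaged with
    4 fields and 4 channels produces 6144 files.
    """
    return layout.n_wells * layout.fields_per_well * layout.channels


ManifestEntry = tuple[str, str, str, int, int]  # plate, replicate, well, field, channel


def expected_manifest(layouts: Iterable[PlateLayout]) -> list[ManifestEntry]:
    return [
        (lay.plate_id, lay.replicate_id, str(well), f, c)
        for lay in layouts
        for well in sorted(lay.wells)
        for f in range(1, lay.fields_per_well + 1)
        for c in range(1, lay.channels + 1)
    ]


def validate_screen(
    layouts: list[PlateLayout], image_manifest: Iterable[ManifestEntry]
) -> list[str]:
    """Compare an image-tree manifest against what the layouts require.

    Returns a human-readable report of missing and extra entries; empty iff the
    tree is complete with no duplicates.  Raises if plates disagree on imaging
    geometry (fields/channels must be shared across a screen).
    """
    if layouts:
        f0, c0 = layouts[0].fields_per_well, layouts[0].channels
        for lay in layouts:
            if (lay.fields_per_well, lay.channels) != (f0, c0):
                raise ValueError(
                    f"plate {lay.plate_id}/{lay.replicate_id} has F={lay.fields_per_well}, "
                    f"C={lay.channels}; screen expects F={f0}, C={c0}"
                )
    expected = expected_manifest(layouts)
    expected_set = set(expected)
    seen: dict[ManifestEntry, int] = {}
    for entry in image_manifest:
        seen[entry] = seen.get(entry, 0) + 1
    report: list[str] = []
    for entry in expected:
        n = seen.get(entry, 0)
        if n == 0:
            report.append(f"missing: {_fmt_entry(entry)}")
        elif n > 1:
            report.append(f"extra: {_fmt_entry(entry)} appears {n} times")
    for entry in sorted(seen):
        if entry not in expected_set:
            report.append(f"extra: unexpected {_fmt_entry(entry)}")
    return report


def _fmt_entry(entry: ManifestEntry) -> str:
    plate, rep, well, fld, ch = entry
    return f"plate={plate} replicate={rep} well={well} field={fld} channel={ch}"


def split_channel_blocks(n_features: int, channels: int) -> list[slice]:
    """Column slices of the per-channel feature blocks of a profile.

    Deep profiles are the concatenation of one embedding block per channel
    (block width 512 for the default encoder); block width is inferred as
    D / C so reduced-width tables work identically.
    """
    if n_features % channels:
        raise ValueError(f"{n_features} features do not divide into {channels} channel blocks")
    w = n_features // channels
    return [slice(i * w, (i + 1) * w) for i in range(channels)]
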