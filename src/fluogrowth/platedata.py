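"""Plate data model and readers/writers.

A 96-well plate-reader experiment is represented by two objects:

* :class:`PlateLayout` — what is in each well (strains and their fluorescent
  reporter channels, medium, condition label, replicate group, and whether the
  well is a sample, a medium-only blank, or empty), plus the measurement
  channels of the run (absorbance such as OD600, and fluorescence channels).
* :class:`PlateTimeSeries` — the measurements: one shared, strictly
  increasing time grid in hours and, per channel, a wells x timepoints matrix.

Time-series files are wide delimited tables (CSV or TSV), one file per
channel: first column is time, remaining columns are well ids.  Layouts are
YAML (or JSON) documents with top-level keys ``plate_id``, ``channels`` and
``wells``.  Missing reads are carried as NaN; each operation downstream
defines its own handling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import LayoutError, MergeError, ParseError

__all__ = [
    "ChannelDef",
    "PlateLayout",
    "PlateTimeSeries",
    "WellSpec",
    "canonical_well",
    "read_layout",
    "read_plate_timeseries",
    "well_sort_key",
    "write_layout",
    "write_plate_timeseries",
]

#: seconds/minutes/hours per hour, for the reader's input-unit dialect flag
_TIME_FACTORS = {"h": 1.0, "min": 60.0, "s": 3600.0}

_WELL_RE = re.compile(r"^([A-Za-z])\s*0*([0-9]+)$")

_ABSORBANCE = "absorbance"
_FLUORESCENCE = "fluorescence"


def canonical_well(well: str, n_rows: int = 8, n_cols: int = 12) -> str:
    """Canonicalize a well id to the form ``"A1".."H12"``.

    Accepts lowercase rows and zero-padded columns (``"a01"`` -> ``"A1"``).
    Raises :class:`ParseError` for malformed ids and :class:`LayoutError`
    for ids outside the declared plate dimensions.
    """
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ParseError(f"unknown well id {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    row_idx = ord(row) - ord("A")
    if not (0 <= row_idx < n_rows and 1 <= col <= n_cols):
        raise LayoutError(
            f"well {row}{col} outside plate dimensions {n_rows}x{n_cols}"
        )
    return f"{row}{col}"


def well_sort_key(well: str) -> tuple[int, int]:
    """Row-major sort key: A1..A12, B1.. (deterministic output ordering)."""
    m = _WELL_RE.match(well)
    if not m:
        raise ParseError(f"unknown well id {well!r}")
    return (ord(m.group(1).upper()) - ord("A"), int(m.group(2)))


@dataclass(frozen=True)
class ChannelDef:
    """One measurement channel of the run.

    ``kind`` is ``"absorbance"`` (e.g. OD600, dimensionless) or
    ``"fluorescence"`` (arbitrary units); fluorescence channels may carry
    their excitation/emission bands in nm.  Absorbance channels must not.
    """

    name: str
    kind: str
    excitation_nm: tuple[float, float] | None = None
    emission_nm: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in (_ABSORBANCE, _FLUORESCENCE):
            raise LayoutError(f"unknown channel kind {self.kind!r}")
        if self.kind == _ABSORBANCE and (
            self.excitation_nm is not None or self.emission_nm is not None
        ):
            raise LayoutError(
                f"absorbance channel {self.name!r} must not declare "
                "excitation/emission bands"
            )


@dataclass
class WellSpec:
    """Contents of one well.

    ``strains`` is a list of ``(strain_name, reporter_channel_or_None)``
    pairs; a blank well has no strains, only medium.  ``condition`` is a
    free-text grouping label (e.g. ``"NB 50%"`` or ``"vs PeWT"``) used by
    the metrics and fitness stages.
    """

    role: str = "sample"
    strains: list[tuple[str, str | None]] = field(default_factory=list)
    medium: str = ""
    condition: str = ""
    replicate_group: str = ""

    def validate(self, well: str) -> None:
        if self.role not in ("sample", "blank", "empty"):
            raise LayoutError(f"well {well}: unknown role {self.role!r}")
        if self.role == "blank" and self.strains:
            raise LayoutError(f"blank well {well} must have no strains")
        if self.role == "sample" and not self.strains:
            raise LayoutError(f"sample well {well} must have >=1 strain")
        reporters = [ch for _, ch in self.strains if ch is not None]
        if len(reporters) != len(set(reporters)):
            raise LayoutError(
                f"well {well}: more than one strain tagged with the same "
                "reporter channel"
            )


@dataclass
class PlateLayout:
    plate_id: str
    wells: dict[str, WellSpec]
    channels: list[ChannelDef] = field(default_factory=list)
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self):
        canon: dict[str, WellSpec] = {}
        for well, spec in self.wells.items():
            w = canonical_well(well, self.n_rows, self.n_cols)
            spec.validate(w)
            canon[w] = spec
        self.wells = {w: canon[w] for w in sorted(canon, key=well_sort_key)}

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, s in self.wells.items() if s.role == role]

    def blank_wells(self) -> list[str]:
        return self.wells_with_role("blank")

    def sample_wells(self) -> list[str]:
        return self.wells_with_role("sample")

    def channel(self, name: str) -> ChannelDef:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise LayoutError(f"layout {self.plate_id!r} has no channel {name!r}")

    def strain_for_channel(self, well: str, channel: str) -> str | None:
        """Name of the strain reporting on ``channel`` in ``well``, if any."""
        for name, ch in self.wells[well].strains:
            if ch == channel:
                return name
        return None


@dataclass
class PlateTimeSeries:
    """Per-channel wells x timepoints matrices on one shared time grid.

    ``data`` maps channel name to a 2-D float array with one row per entry
    of ``wells`` (canonical row-major order) and one column per entry of
    ``times_h``.  ``corrected`` records which channels have already been
    blank-corrected (re-correction is an error, see :mod:`.preprocess`).
    """

    times_h: np.ndarray
    wells: list[str]
    data: dict[str, np.ndarray]
    layout_ref: str = ""
    corrected: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.times_h.ndim != 1 or len(self.times_h) < 1:
            raise ParseError("time grid must be a 1-D sequence")
        if np.any(self.times_h < 0):
            raise ParseError("negative times not allowed")
        if np.any(np.diff(self.times_h) <= 0):
            raise ParseError("non-monotone time")
        order = sorted(range(len(self.wells)), key=lambda i: well_sort_key(self.wells[i]))
        self.wells = [self.wells[i] for i in order]
        for name, mat in self.data.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (len(self.wells), len(self.times_h)):
                raise ParseError(
                    f"channel {name!r}: matrix shape {mat.shape} does not "
                    f"match {len(self.wells)} wells x {len(self.times_h)} times"
                )
            self.data[name] = mat[order, :] if order != list(range(len(order))) else mat

    @property
    def channels(self) -> list[str]:
        return list(self.data)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[name]
        except KeyError:
            raise ParseError(f"no channel {name!r} in time series") from None

    def well_index(self, well: str) -> int:
        try:
            return self.wells.index(canonical_well(well))
        except ValueError:
            raise ParseError(f"well {well!r} not in time series") from None

    def trace(self, channel: str, well: str) -> np.ndarray:
        return self.channel(channel)[self.well_index(well), :]

    def merge(self, other: "PlateTimeSeries", tol: float = 1e-9) -> "PlateTimeSeries":
        """Combine channel fragments sharing a well set and time grid.

        Grids must agree within ``tol`` hours; the merge is order-independent
        up to channel ordering.
        """
        if self.wells != other.wells:
            raise MergeError("cannot merge: well sets differ")
        if len(self.times_h) != len(other.times_h) or np.max(
            np.abs(self.times_h - other.times_h)
        ) > tol:
            raise MergeError("cannot merge: time grids differ beyond tolerance")
        overlap = set(self.data) & set(other.data)
        if overlap:
            raise MergeError(f"cannot merge: duplicate channels {sorted(overlap)}")
        data = dict(self.data)
        data.update(other.data)
        return PlateTimeSeries(
            times_h=self.times_h.copy(),
            wells=list(self.wells),
            data=data,
            layout_ref=self.layout_ref or other.layout_ref,
            corrected=self.corrected | other.corrected,
        )

    def to_frame(self, channel: str) -> pd.DataFrame:
        df = pd.DataFrame(self.channel(channel).T, columns=self.wells)
        df.insert(0, "time_h", self.times_h)
        return df


def read_plate_timeseries(
    path,
    channel: str,
    time_unit: str = "h",
    layout_ref: str = "",
    n_rows: int = 8,
    n_cols: int = 12,
) -> PlateTimeSeries:
    """Read one channel's wide table into a single-channel PlateTimeSeries.

    The file is a delimited table (CSV or TSV, sniffed) whose first column is
    time in ``time_unit`` (``"h"``, ``"min"`` or ``"s"``) and remaining
    columns are well ids.  Well ids are canonicalized and ordered row-major.
    """
    if time_unit not in _TIME_FACTORS:
        raise ParseError(f"unknown time unit {time_unit!r}")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a time column plus >=1 well column")
    times = np.asarray(df.iloc[:, 0], dtype=float) / _TIME_FACTORS[time_unit]
    wells = [canonical_well(c, n_rows, n_cols) for c in df.columns[1:]]
    if len(set(wells)) != len(wells):
        raise ParseError(f"{path}: duplicate well columns")
    mat = np.asarray(df.iloc[:, 1:], dtype=float).T
    return PlateTimeSeries(
        times_h=times, wells=wells, data={channel: mat}, layout_ref=layout_ref
    )


def write_plate_timeseries(ts: PlateTimeSeries, channel: str, path) -> None:
    """Write one channel as ``time_h,A1,A2,...`` CSV ('.' decimal, UTF-8)."""
    ts.to_frame(channel).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# layout I/O


def _parse_band(value) -> tuple[float, float] | None:
    if value is None:
        return None
    lo, hi = value
    return (float(lo), float(hi))


def read_layout(path) -> PlateLayout:
    """Read a YAML or JSON plate layout.

    Role defaults: a well with strains is a ``sample``; a well with a medium
    but no strains is a ``blank``.  Validation errors (well outside plate,
    duplicate reporter channel, sample without strains) raise
    :class:`LayoutError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return layout_from_dict(doc)


def layout_from_dict(doc: dict) -> PlateLayout:
    if not isinstance(doc, dict) or "wells" not in doc:
        raise LayoutError("layout must be a mapping with a 'wells' key")
    channels = [
        ChannelDef(
            name=str(c["name"]),
            kind=str(c.get("kind", _FLUORESCENCE)),
            excitation_nm=_parse_band(c.get("excitation_nm")),
            emission_nm=_parse_band(c.get("emission_nm")),
        )
        for c in doc.get("channels", [])
    ]
    wells: dict[str, WellSpec] = {}
    for well, raw in doc["wells"].items():
        raw = raw or {}
        strains = [
            (str(s["name"]), None if s.get("channel") is None else str(s["channel"]))
            for s in raw.get("strains", [])
        ]
        role = raw.get("role")
        if role is None:
            role = "sample" if strains else ("blank" if raw.get("medium") else "empty")
        wells[str(well)] = WellSpec(
            role=str(role),
            strains=strains,
            medium=str(raw.get("medium", "")),
            condition=str(raw.get("condition", "")),
            replicate_group=str(raw.get("replicate_group", "")),
        )
    return PlateLayout(
        plate_id=str(doc.get("plate_id", "plate")),
        wells=wells,
        channels=channels,
        n_rows=int(doc.get("rows", 8)),
        n_cols=int(doc.get("cols", 12)),
    )


def layout_to_dict(layout: PlateLayout) -> dict:
    return {
        "plate_id": layout.plate_id,
        "rows": layout.n_rows,
        "cols": layout.n_cols,
        "channels": [
            {
                "name": c.name,
                "kind": c.kind,
                "excitation_nm": list(c.excitation_nm) if c.excitation_nm else None,
                "emission_nm": list(c.emission_nm) if c.emission_nm else None,
            }
            for c in layout.channels
        ],
        "wells": {
            w: {
                "role": s.role,
                "strains": [{"name": n, "channel": c} for n, c in s.strains],
                "medium": s.medium,
                "condition": s.condition,
                "replicate_group": s.replicate_group,
            }
            for w, s in layout.wells.items()
        },
    }


def write_layout(layout: PlateLayout, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(layout_to_dict(layout), fh, sort_keys=False)
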