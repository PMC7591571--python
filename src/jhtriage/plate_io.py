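"""Plate data model, layouts, and file I/O for dual-luciferase screening tables.

The screening assay reads two luminescence channels per well: firefly
luciferase (Fluc) driven by a juvenile-hormone response element, and Renilla
luciferase (Rluc) driven by a constitutive promoter as a viability reference.
Plates carry compound wells plus DMSO-only (positive) and 1 nM JH I
(negative) control wells used for per-plate normalization.

Plate tables are long-format CSV, one row per well, UTF-8, comma-separated,
with molar concentrations in scientific notation. Missing wells are absent
rows, never zero-luminescence rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ROLE_COMPOUND",
    "ROLE_POSITIVE",
    "ROLE_NEGATIVE",
    "ROLE_EMPTY",
    "PLATE_FORMATS",
    "WellAddress",
    "WellRecord",
    "Plate",
    "PlateLayout",
    "ValidationReport",
    "PlateError",
    "PlateFormatError",
    "PlateValidationError",
    "build_default_layout",
    "read_plate_table",
    "write_plate_table",
    "validate_plate",
    "write_screen_report",
]

ROLE_COMPOUND = "compound"
ROLE_POSITIVE = "positive_control"
ROLE_NEGATIVE = "negative_control"
ROLE_EMPTY = "empty"
ROLES = (ROLE_COMPOUND, ROLE_POSITIVE, ROLE_NEGATIVE, ROLE_EMPTY)

#: supported formats -> (n_rows, n_cols)
PLATE_FORMATS: dict[int, tuple[int, int]] = {384: (16, 24), 96: (8, 12)}

ROW_LETTERS = "ABCDEFGHIJKLMNOP"

REQUIRED_COLUMNS = ("plate_id", "row", "col", "role", "compound_id", "conc", "fluc", "rluc")


class PlateError(Exception):
    """Base class for plate-table problems."""


class PlateFormatError(PlateError):
    """Structural problem with a plate file (missing column, no records...)."""


class PlateValidationError(PlateError):
    """Content violates a plate invariant (duplicate well, negative RLU...)."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well position, e.g. row 'A', col 1 of plate 'P001' -> name 'A01'."""

    plate_id: str
    row: str
    col: int

    @property
    def name(self) -> str:
        return f"{self.row}{self.col:02d}"


@dataclass
class WellRecord:
    """One well's annotations and dual-channel luminescence readout (RLU)."""

    address: WellAddress
    role: str
    compound_id: Optional[str] = None
    conc: float = 0.0
    jh_conc: float = 0.0
    fluc: float = 0.0
    rluc: float = 0.0
    adherence_flag: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PlateValidationError(f"unknown well role {self.role!r}")
        if not (self.fluc >= 0 and self.rluc >= 0):
            raise PlateValidationError(
                f"negative luminescence in well {self.address.name} "
                f"of plate {self.address.plate_id}"
            )
        if self.role in (ROLE_POSITIVE, ROLE_NEGATIVE) and self.compound_id is not None:
            raise PlateValidationError(
                f"control well {self.address.name} must not carry a compound_id"
            )


def _check_address(address: WellAddress, fmt: int) -> None:
    n_rows, n_cols = PLATE_FORMATS[fmt]
    if address.row not in ROW_LETTERS[:n_rows] or not 1 <= address.col <= n_cols:
        raise PlateValidationError(
            f"address {address.name} out of bounds for {fmt}-well plate"
        )


@dataclass
class Plate:
    """A single assay plate: id, format (384 or 96) and its well records."""

    plate_id: str
    format: int
    wells: list[WellRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.format not in PLATE_FORMATS:
            raise PlateFormatError(f"unsupported plate format {self.format}")
        seen: set[tuple[str, int]] = set()
        for w in self.wells:
            _check_address(w.address, self.format)
            key = (w.address.row, w.address.col)
            if key in seen:
                raise PlateValidationError(
                    f"duplicate address {w.address.name} in plate {self.plate_id}"
                )
            seen.add(key)

    def wells_by_role(self, role: str) -> list[WellRecord]:
        return [w for w in self.wells if w.role == role]

    @property
    def well_map(self) -> dict[tuple[str, int], WellRecord]:
        return {(w.address.row, w.address.col): w for w in self.wells}


@dataclass
class PlateLayout:
    """Role map for a plate format: which address plays which role."""

    format: int
    roles: dict[tuple[str, int], str]

    def __post_init__(self) -> None:
        if self.format not in PLATE_FORMATS:
            raise PlateFormatError(f"unsupported plate format {self.format}")
        n_rows, n_cols = PLATE_FORMATS[self.format]
        if len(self.roles) != n_rows * n_cols:
            raise PlateValidationError(
                f"layout covers {len(self.roles)} wells, expected {n_rows * n_cols}"
            )
        counts = self.counts
        if counts.get(ROLE_POSITIVE, 0) < 1 or counts.get(ROLE_NEGATIVE, 0) < 1:
            raise PlateValidationError("layout must place both control roles")

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for role in self.roles.values():
            out[role] = out.get(role, 0) + 1
        return out

    def addresses(self, role: str) -> list[tuple[str, int]]:
        return sorted(k for k, v in self.roles.items() if v == role)


def build_default_layout(
    format: int,
    positive_col: Optional[int] = None,
    negative_col: Optional[int] = None,
) -> PlateLayout:
    """Default layout: controls in the two right-most columns.

    384-well: 320 compound wells (columns 1-20), 16 positive controls
    (column 23), 16 negative controls (column 24), columns 21-22 empty.
    96-well scales proportionally to 80 + 8 + 8 (compounds in columns 1-10,
    controls in 11 / 12, no empties). Edge-column controls are conventional
    HTS practice; no statistic here depends on control geometry.
    """
    if format not in PLATE_FORMATS:
        raise PlateFormatError(f"unsupported plate format {format}")
    n_rows, n_cols = PLATE_FORMATS[format]
    compound_cols = {384: 20, 96: 10}[format]
    pos_col = positive_col if positive_col is not None else n_cols - 1
    neg_col = negative_col if negative_col is not None else n_cols
    if pos_col == neg_col or not (1 <= pos_col <= n_cols and 1 <= neg_col <= n_cols):
        raise PlateValidationError("control columns must be distinct and in range")
    roles: dict[tuple[str, int], str] = {}
    for r in ROW_LETTERS[:n_rows]:
        for c in range(1, n_cols + 1):
            if c == pos_col:
                roles[(r, c)] = ROLE_POSITIVE
            elif c == neg_col:
                roles[(r, c)] = ROLE_NEGATIVE
            elif c <= compound_cols:
                roles[(r, c)] = ROLE_COMPOUND
            else:
                roles[(r, c)] = ROLE_EMPTY
    return PlateLayout(format=format, roles=roles)


def _infer_format(rows: Iterable[str], cols: Iterable[int]) -> int:
    if all(r in ROW_LETTERS[:8] for r in rows) and all(c <= 12 for c in cols):
        return 96
    return 384


def read_plate_table(path, format_hint: Optional[int] = None) -> list[Plate]:
    """Read a long-format plate CSV into validated :class:`Plate` objects.

    Required columns: plate_id, row, col, role, compound_id, conc, fluc,
    rluc. Optional: jh_conc, adherence_flag. Returns one plate per distinct
    plate_id, in file order.
    """
    try:
        df = pd.read_csv(
            path,
            dtype={"plate_id": str, "row": str, "compound_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise PlateFormatError(f"no records in {path}") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise PlateFormatError(f"no records in {path}")
    if "jh_conc" not in df.columns:
        df["jh_conc"] = 0.0
    if "adherence_flag" not in df.columns:
        df["adherence_flag"] = False

    plates: list[Plate] = []
    for plate_id, grp in df.groupby("plate_id", sort=False):
        fmt = format_hint or _infer_format(grp["row"], grp["col"].astype(int))
        wells = []
        for rec in grp.itertuples(index=False):
            cid = rec.compound_id
            if cid is None or (isinstance(cid, float) and math.isnan(cid)) or cid == "":
                cid = None
            if rec.fluc < 0 or rec.rluc < 0:
                raise PlateValidationError(
                    f"negative luminescence at {rec.row}{int(rec.col):02d} "
                    f"of plate {plate_id}"
                )
            wells.append(
                WellRecord(
                    address=WellAddress(str(plate_id), str(rec.row), int(rec.col)),
                    role=str(rec.role),
                    compound_id=cid,
                    conc=float(rec.conc),
                    jh_conc=float(rec.jh_conc),
                    fluc=float(rec.fluc),
                    rluc=float(rec.rluc),
                    adherence_flag=bool(rec.adherence_flag),
                )
            )
        plates.append(Plate(plate_id=str(plate_id), format=fmt, wells=wells))
    return plates


def plates_to_frame(plates: Iterable[Plate]) -> pd.DataFrame:
    rows = []
    for p in plates:
        for w in p.wells:
            rows.append(
                {
                    "plate_id": p.plate_id,
                    "row": w.address.row,
                    "col": w.address.col,
                    "role": w.role,
                    "compound_id": "" if w.compound_id is None else w.compound_id,
                    "conc": w.conc,
                    "jh_conc": w.jh_conc,
                    "fluc": w.fluc,
                    "rluc": w.rluc,
                    "adherence_flag": w.adherence_flag,
                }
            )
    return pd.DataFrame(rows)


def write_plate_table(plates: Sequence[Plate], path) -> None:
    """Write plates as long-format CSV (round-trips with read_plate_table)."""
    if not plates:
        raise PlateError("no plates to write")
    # %.17g round-trips float64 exactly through read_csv
    plates_to_frame(plates).to_csv(path, index=False, float_format="%.17g")


@dataclass
class ValidationReport:
    """Outcome of structural validation of one plate against a layout."""

    plate_id: str
    passed: bool
    issues: list[str] = field(default_factory=list)


def validate_plate(plate: Plate, layout: PlateLayout, min_controls: int = 2) -> ValidationReport:
    """Check a plate against a layout: role mismatches, stray or missing
    wells, and minimum control counts. Failures are reported, not raised."""
    issues: list[str] = []
    if plate.format != layout.format:
        issues.append(f"plate format {plate.format} != layout format {layout.format}")
    well_map = plate.well_map
    for key, w in well_map.items():
        expected = layout.roles.get(key)
        if expected is None:
            issues.append(f"address {w.address.name} absent from layout")
        elif expected != w.role and not (expected == ROLE_COMPOUND and w.role == ROLE_EMPTY):
            issues.append(
                f"role mismatch at {w.address.name}: plate={w.role}, layout={expected}"
            )
    for role, label in ((ROLE_POSITIVE, "positive"), (ROLE_NEGATIVE, "negative")):
        n_valid = sum(1 for w in plate.wells_by_role(role))
        if n_valid < min_controls:
            issues.append(
                f"fail: insufficient {label} controls ({n_valid} < {min_controls})"
            )
    return ValidationReport(plate_id=plate.plate_id, passed=not issues, issues=issues)


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_screen_report(records, path) -> None:
    """Write per-compound triage trajectories as TSV plus a JSON summary.

    One TSV row per compound: per-stage InH mean/SD, Rluc InH, pass flags,
    exclusion reason and final status. A sibling ``<path>.json`` carries
    per-stage hit counts.
    """
    records = list(records)
    if not records:
        raise PlateError("no screening records to report")
    path = Path(path)
    cols = [
        "compound_id",
        "analog_group",
        "stage1_inh",
        "stage1_sd",
        "stage2_inh",
        "stage2_sd",
        "stage3_inh_low",
        "stage3_sd_low",
        "stage4_inh_mid",
        "stage4_inh_low",
        "rluc_inh",
        "stage1_pass",
        "stage2_pass",
        "stage3_pass",
        "stage4_pass",
        "status",
        "exclusion_reason",
    ]
    lines = ["\t".join(cols)]
    for rec in records:
        row = [_fmt(v) for v in rec.report_row()]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")

    counts: dict[str, int] = {"n_compounds": len(records)}
    for stage in (1, 2, 3, 4):
        counts[f"stage{stage}_hits"] = sum(1 for r in records if r.passed.get(stage))
    counts["final_active"] = sum(1 for r in records if r.status == "active")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(counts, indent=2))
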