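"""Four-stage hit-triage cascade with an Rluc cytotoxicity counterscreen.

The screen narrows a compound library in four stages, all scored as InH (%)
of the 1 nM JH I reporter signal:

1. primary screen, single well at 5 uM: keep InH >= 26%;
2. confirmation, n = 4 replicates: drop mean InH < 20% or wells flagged for
   weakened cell adherence (a manual exclusion, carried as a boolean);
3. dose-response over a three-point series: keep InH > 10% at the lowest
   tested concentration, with an optional monotonicity sanity check;
4. analog/dose test at 0.05 / 0.5 / 5 uM: keep InH > 15% at 0.5 uM and
   > -10% at 0.05 uM.

Finally, a counterscreen on the constitutive Rluc channel removes
cytotoxic false positives: compounds losing more than 50% of the viability
signal at the highest tested dose are excluded. Plates are gated on the
fluc-channel Z' factor before any well is scored.

Boundary conventions follow the stated selection rules literally: stage 1
is inclusive ("at least 26%"), stage 2 excludes strictly-below-20, stages 3
and 4 require strict inequality, and the counterscreen excludes strictly
above 50%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .hts_stats import (
    InhibitionResult,
    PlateQC,
    ReplicateSummary,
    aggregate_replicates,
    plate_inhibition,
    plate_qc,
    plate_viability_inhibition,
)
from .plate_io import ROLE_COMPOUND, Plate, PlateLayout

__all__ = [
    "CascadeConfig",
    "ScreeningRecord",
    "CascadeResult",
    "stage1_select",
    "stage2_confirm",
    "stage3_dose_select",
    "stage4_analog_select",
    "counterscreen_cytotox",
    "run_cascade",
]

STATUS_ACTIVE = "active"
STATUS_EXCLUDED_CYTOTOXIC = "excluded_cytotoxic"
STATUS_EXCLUDED_ADHERENCE = "excluded_adherence"


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and concentrations of the four-stage triage.

    All concentrations in molar. Defaults are the screen's operating
    conditions: 1 nM JH I challenge, 5 uM primary-screen dose, the
    26/20/10/(15, -10) percent InH thresholds, and the >50% Rluc-loss
    cytotoxicity exclusion.
    """

    jh_conc: float = 1e-9
    stage1_conc: float = 5e-6
    stage1_min_inh: float = 26.0
    stage2_min_inh: float = 20.0
    stage2_n: int = 4
    stage3_min_inh: float = 10.0
    stage3_monotone_tol: float = 10.0
    stage3_check_monotone: bool = True
    stage4_concs: tuple[float, float, float] = (0.05e-6, 0.5e-6, 5e-6)
    stage4_min_inh_mid: float = 15.0
    stage4_min_inh_low: float = -10.0
    cytotox_max_rluc_inh: float = 50.0
    z_prime_min: float = 0.5
    apply_z_gate: bool = True

    def __post_init__(self) -> None:
        if self.jh_conc <= 0 or self.stage1_conc <= 0 or any(
            c <= 0 for c in self.stage4_concs
        ):
            raise ValueError("all concentrations must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "CascadeConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown cascade config key(s): {sorted(unknown)}")
        if "stage4_concs" in raw:
            raw["stage4_concs"] = tuple(float(c) for c in raw["stage4_concs"])
        return cls(**raw)


@dataclass
class ScreeningRecord:
    """One compound's trajectory through the cascade."""

    compound_id: str
    analog_group: Optional[str] = None
    stage1: Optional[ReplicateSummary] = None
    stage2: Optional[ReplicateSummary] = None
    stage3: Optional[dict[float, ReplicateSummary]] = None
    stage4: Optional[dict[float, ReplicateSummary]] = None
    rluc_inh: Optional[float] = None
    adherence: bool = False
    passed: dict[int, bool] = field(default_factory=dict)
    status: str = "excluded_stage1"
    exclusion_reason: Optional[str] = None

    def report_row(self) -> list:
        def ms(summary: Optional[ReplicateSummary]) -> tuple:
            if summary is None:
                return (None, None)
            return (summary.mean, summary.sd)

        s3_low = (None, None)
        if self.stage3:
            s3_low = ms(self.stage3[min(self.stage3)])
        s4_mid = s4_low = None
        if self.stage4:
            concs = sorted(self.stage4)
            if len(concs) >= 2:
                s4_low = self.stage4[concs[0]].mean
                s4_mid = self.stage4[concs[1]].mean
        return [
            self.compound_id,
            self.analog_group,
            *ms(self.stage1),
            *ms(self.stage2),
            *s3_low,
            s4_mid,
            s4_low,
            self.rluc_inh,
            *(self.passed.get(s) for s in (1, 2, 3, 4)),
            self.status,
            self.exclusion_reason,
        ]


@dataclass
class CascadeResult:
    records: list[ScreeningRecord]
    counts: dict[str, int]
    qc: list[PlateQC]

    @property
    def final_actives(self) -> list[str]:
        return [r.compound_id for r in self.records if r.status == STATUS_ACTIVE]


# ---------------------------------------------------------------------------
# stage selectors (operate on aggregated InH results)
# ---------------------------------------------------------------------------

def stage1_select(results: Iterable[InhibitionResult], config: CascadeConfig) -> list[str]:
    """Primary-screen selection: InH >= stage1_min_inh (inclusive)."""
    return [r.compound_id for r in results if r.mean >= config.stage1_min_inh]


def stage2_confirm(
    results: Iterable[InhibitionResult],
    config: CascadeConfig,
    adherence: Optional[Mapping[str, bool]] = None,
) -> tuple[list[str], dict[str, str]]:
    """Confirmation: keep mean replicate InH >= stage2_min_inh and no
    adherence flag. Returns (hits, exclusion reasons)."""
    adherence = adherence or {}
    hits: list[str] = []
    reasons: dict[str, str] = {}
    for r in results:
        if r.n < config.stage2_n:
            warnings.warn(
                f"{r.compound_id}: {r.n} replicates at stage 2 "
                f"(expected {config.stage2_n})",
                stacklevel=2,
            )
        if adherence.get(r.compound_id, False):
            reasons[r.compound_id] = "adherence"
        elif r.mean < config.stage2_min_inh:
            reasons[r.compound_id] = (
                f"mean InH {r.mean:.1f} < {config.stage2_min_inh}"
            )
        else:
            hits.append(r.compound_id)
    return hits, reasons


def _monotone(means: Sequence[float], tol: float) -> bool:
    return all(means[i + 1] >= means[i] - tol for i in range(len(means) - 1))


def stage3_dose_select(
    curves: Mapping[str, Sequence[tuple[float, float]]],
    config: CascadeConfig,
) -> tuple[list[str], dict[str, str]]:
    """Dose-response selection: InH at the lowest tested concentration must
    exceed stage3_min_inh (strict), and the dose series must be
    non-decreasing within ``stage3_monotone_tol`` percentage points (the
    monotonicity check can be disabled)."""
    hits: list[str] = []
    reasons: dict[str, str] = {}
    for cid, series in curves.items():
        series = sorted(series)
        if len(series) < 3:
            raise ValueError(
                f"{cid}: need >=3 concentrations for stage-3 selection, "
                f"got {len(series)}"
            )
        means = [m for _, m in series]
        if not means[0] > config.stage3_min_inh:
            reasons[cid] = (
                f"InH {means[0]:.1f} at lowest dose <= {config.stage3_min_inh}"
            )
        elif config.stage3_check_monotone and not _monotone(
            means, config.stage3_monotone_tol
        ):
            reasons[cid] = "non-monotone dose-response"
        else:
            hits.append(cid)
    return hits, reasons


def _lookup_conc(table: Mapping[float, ReplicateSummary], conc: float):
    for k, v in table.items():
        if np.isclose(k, conc, rtol=1e-6):
            return v
    return None


def stage4_analog_select(
    results: Mapping[str, Mapping[float, ReplicateSummary]],
    config: CascadeConfig,
) -> tuple[list[str], dict[str, str]]:
    """Analog/dose-test selection at the three stage-4 concentrations:
    InH > stage4_min_inh_mid at the middle dose and > stage4_min_inh_low at
    the lowest dose (both strict)."""
    low_c, mid_c, _ = sorted(config.stage4_concs)
    hits: list[str] = []
    reasons: dict[str, str] = {}
    for cid, table in results.items():
        low = _lookup_conc(table, low_c)
        mid = _lookup_conc(table, mid_c)
        if low is None or mid is None:
            raise ValueError(f"{cid}: missing a stage-4 concentration")
        if not mid.mean > config.stage4_min_inh_mid:
            reasons[cid] = (
                f"InH {mid.mean:.1f} at {mid_c:g} M <= {config.stage4_min_inh_mid}"
            )
        elif not low.mean > config.stage4_min_inh_low:
            reasons[cid] = (
                f"InH {low.mean:.1f} at {low_c:g} M <= {config.stage4_min_inh_low}"
            )
        else:
            hits.append(cid)
    return hits, reasons


def counterscreen_cytotox(
    rluc_results: Iterable[InhibitionResult], config: CascadeConfig
) -> tuple[list[str], dict[str, str]]:
    """Retain compounds with Rluc InH <= cytotox_max_rluc_inh; strictly
    greater means the apparent Fluc inhibition is a viability artifact."""
    retained: list[str] = []
    reasons: dict[str, str] = {}
    for r in rluc_results:
        if r.mean > config.cytotox_max_rluc_inh:
            reasons[r.compound_id] = "cytotoxic"
        else:
            retained.append(r.compound_id)
    return retained, reasons


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def _gate_plates(
    plates: Sequence[Plate], layout: PlateLayout, config: CascadeConfig
) -> tuple[list[Plate], list[PlateQC]]:
    kept, qcs = [], []
    for p in plates:
        qc = plate_qc(p, layout, "fluc", z_min=config.z_prime_min)
        qcs.append(qc)
        if qc.pass_flag or not config.apply_z_gate:
            kept.append(p)
        else:
            warnings.warn(
                f"plate {p.plate_id} failed QC (Z' = {qc.z_prime:.2f}); "
                "its wells are excluded",
                stacklevel=2,
            )
    return kept, qcs


def _collect_inh(
    plates: Sequence[Plate], layout: PlateLayout
) -> dict[tuple[str, float], list[float]]:
    """Pool per-plate-normalized InH values across plates by (compound, conc)."""
    pooled: dict[tuple[str, float], list[float]] = {}
    for p in plates:
        for r in plate_inhibition(p, layout, "fluc"):
            pooled.setdefault((r.compound_id, r.conc), []).extend(r.values)
    return pooled


def _as_results(
    pooled: Mapping[tuple[str, float], list[float]]
) -> list[InhibitionResult]:
    return [
        InhibitionResult(compound_id=cid, conc=conc, channel="fluc", values=tuple(v))
        for (cid, conc), v in pooled.items()
    ]


def run_cascade(
    plates_by_stage: Mapping[int, Sequence[Plate]],
    layouts: Mapping[int, PlateLayout],
    config: Optional[CascadeConfig] = None,
    analog_groups: Optional[Mapping[str, str]] = None,
) -> CascadeResult:
    """Run the full triage over per-stage plate sets.

    ``plates_by_stage`` maps stage number (1-4) to its plates; compounds are
    traced across stages by compound_id. Returns per-compound
    :class:`ScreeningRecord` trajectories, per-stage hit counts, and plate
    QC summaries. Final actives are stage-4 hits that survive the Rluc
    counterscreen (adherence exclusions happen at stage 2).
    """
    config = config or CascadeConfig()
    analog_groups = analog_groups or {}
    qcs: list[PlateQC] = []
    gated: dict[int, list[Plate]] = {}
    for stage in (1, 2, 3, 4):
        plates = list(plates_by_stage.get(stage, ()))
        layout = layouts[stage] if plates else None
        if plates:
            gated[stage], stage_qc = _gate_plates(plates, layout, config)
            qcs.extend(stage_qc)
        else:
            gated[stage] = []

    # ---- stage 1
    pooled1 = _collect_inh(gated[1], layouts.get(1))
    records: dict[str, ScreeningRecord] = {}
    stage1_results = []
    for (cid, conc), vals in pooled1.items():
        if not np.isclose(conc, config.stage1_conc, rtol=1e-6):
            continue
        rec = records.setdefault(
            cid, ScreeningRecord(compound_id=cid, analog_group=analog_groups.get(cid))
        )
        rec.stage1 = aggregate_replicates(vals, 1)
        stage1_results.append(
            InhibitionResult(cid, conc, "fluc", tuple(vals))
        )
    s1_hits = set(stage1_select(stage1_results, config))
    for cid, rec in records.items():
        rec.passed[1] = cid in s1_hits
        if not rec.passed[1]:
            rec.status = "excluded_stage1"
            rec.exclusion_reason = (
                f"InH {rec.stage1.mean:.1f} < {config.stage1_min_inh}"
            )

    # ---- stage 2 (confirmation on survivors)
    pooled2 = _collect_inh(gated[2], layouts.get(2))
    adherence: dict[str, bool] = {}
    for p in gated[2]:
        for w in p.wells:
            if w.role == ROLE_COMPOUND and w.compound_id and w.adherence_flag:
                adherence[w.compound_id] = True
    by_cid2: dict[str, list[float]] = {}
    for (cid, _conc), vals in pooled2.items():
        by_cid2.setdefault(cid, []).extend(vals)
    for cid in by_cid2:
        if cid not in records:
            warnings.warn(
                f"{cid}: stage-2 data without stage-1 lineage", stacklevel=2
            )
    stage2_results = [
        InhibitionResult(cid, config.stage1_conc, "fluc", tuple(v))
        for cid, v in by_cid2.items()
        if cid in s1_hits
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shortfall warnings handled per-record
        s2_hits_list, s2_reasons = stage2_confirm(stage2_results, config, adherence)
    s2_hits = set(s2_hits_list)
    for r in stage2_results:
        rec = records[r.compound_id]
        rec.stage2 = aggregate_replicates(r.values, config.stage2_n)
        rec.adherence = adherence.get(r.compound_id, False)
        rec.passed[2] = r.compound_id in s2_hits
        if not rec.passed[2]:
            reason = s2_reasons[r.compound_id]
            rec.status = (
                STATUS_EXCLUDED_ADHERENCE if reason == "adherence" else "excluded_stage2"
            )
            rec.exclusion_reason = reason

    # ---- stage 3 (dose-response on survivors)
    pooled3 = _collect_inh(gated[3], layouts.get(3))
    by_cid3: dict[str, dict[float, list[float]]] = {}
    for (cid, conc), vals in pooled3.items():
        by_cid3.setdefault(cid, {}).setdefault(conc, []).extend(vals)
    curves = {
        cid: [(conc, float(np.mean(v))) for conc, v in table.items()]
        for cid, table in by_cid3.items()
        if cid in s2_hits and len(table) >= 3
    }
    s3_hits_list, s3_reasons = stage3_dose_select(curves, config)
    s3_hits = set(s3_hits_list)
    for cid in list(curves) + [
        c for c in by_cid3 if c in s2_hits and len(by_cid3[c]) < 3
    ]:
        rec = records[cid]
        rec.stage3 = {
            conc: aggregate_replicates(v, config.stage2_n)
            for conc, v in by_cid3[cid].items()
        }
        if cid not in curves:
            rec.passed[3] = False
            rec.status = "excluded_stage3"
            rec.exclusion_reason = "insufficient dose series"
            continue
        rec.passed[3] = cid in s3_hits
        if not rec.passed[3]:
            rec.status = "excluded_stage3"
            rec.exclusion_reason = s3_reasons[cid]

    # ---- stage 4 (analog/dose test on survivors)
    pooled4 = _collect_inh(gated[4], layouts.get(4))
    by_cid4: dict[str, dict[float, list[float]]] = {}
    for (cid, conc), vals in pooled4.items():
        by_cid4.setdefault(cid, {}).setdefault(conc, []).extend(vals)
    stage4_tables = {
        cid: {
            conc: aggregate_replicates(v, 1) for conc, v in table.items()
        }
        for cid, table in by_cid4.items()
        if cid in s3_hits
    }
    s4_hits_list, s4_reasons = stage4_analog_select(stage4_tables, config)
    s4_hits = set(s4_hits_list)
    for cid, table in stage4_tables.items():
        rec = records[cid]
        rec.stage4 = table
        rec.passed[4] = cid in s4_hits
        if not rec.passed[4]:
            rec.status = "excluded_stage4"
            rec.exclusion_reason = s4_reasons[cid]

    # ---- Rluc cytotoxicity counterscreen at the highest stage-4 dose
    top_conc = max(config.stage4_concs)
    pooled_rluc: dict[str, list[float]] = {}
    for p in gated[4]:
        for r in plate_viability_inhibition(p, layouts.get(4)):
            if np.isclose(r.conc, top_conc, rtol=1e-6):
                pooled_rluc.setdefault(r.compound_id, []).extend(r.values)
    rluc_results = [
        InhibitionResult(cid, top_conc, "rluc", tuple(v))
        for cid, v in pooled_rluc.items()
        if cid in s4_hits
    ]
    retained_list, cyto_reasons = counterscreen_cytotox(rluc_results, config)
    retained = set(retained_list)
    for r in rluc_results:
        rec = records[r.compound_id]
        rec.rluc_inh = r.mean
        if r.compound_id in retained:
            rec.status = STATUS_ACTIVE
            rec.exclusion_reason = None
        else:
            rec.status = STATUS_EXCLUDED_CYTOTOXIC
            rec.exclusion_reason = cyto_reasons[r.compound_id]

    # ---- compounds that passed a stage but have no data for the next one
    for cid, rec in records.items():
        if rec.passed.get(1) and rec.stage2 is None:
            rec.status, rec.exclusion_reason = "excluded_stage2", "no stage-2 data"
        elif rec.passed.get(2) and rec.stage3 is None:
            rec.status, rec.exclusion_reason = "excluded_stage3", "no stage-3 data"
        elif rec.passed.get(3) and rec.stage4 is None:
            rec.status, rec.exclusion_reason = "excluded_stage4", "no stage-4 data"
        elif rec.passed.get(4) and rec.rluc_inh is None:
            rec.status, rec.exclusion_reason = "excluded_stage4", "no counterscreen data"

    counts = {
        "screened": len(records),
        "stage1_hits": len(s1_hits),
        "stage2_hits": len(s2_hits),
        "stage3_hits": len(s3_hits),
        "stage4_hits": len(s4_hits),
        "final_active": sum(1 for r in records.values() if r.status == STATUS_ACTIVE),
    }
    return CascadeResult(records=list(records.values()), counts=counts, qc=qcs)
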