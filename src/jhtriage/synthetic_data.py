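"""Synthetic dual-reporter screening data with known pharmacological truth.

The generator is phenomenological at the reporter level. Each compound
belongs to a latent class and perturbs the deterministic expected signal of
a well through minimal receptor-theory mechanisms:

* agonist occupancy follows a Hill curve, A = c^h / (c^h + EC50^h), with the
  JH I potency default EC50 = 3.7e-10 M and h = 1;
* competitive inhibitors shift the agonist EC50 by the Gaddum factor
  (1 + [I]/Ki), producing the parallel rightward shift of a surmountable
  antagonist;
* noncompetitive inhibitors divide the achievable span (Emax) by
  (1 + [I]/Ki), leaving the agonist EC50 in place;
* cytotoxic compounds scale BOTH channels by a viability factor
  v = 1 / (1 + ([I]/TC50)^h_tox) — the false-positive mode the Rluc
  counterscreen exists to catch;
* agonists add their own efficacy-scaled occupancy term.

Fluc reads (f0 + fmax_eff * A) * v; the constitutive Rluc reads r0 * v.
Measured wells multiply the expected signal by independent lognormal noise
with unit mean (CV parameterized per control/compound wells). All
randomness flows through a seeded numpy Generator: identical (config, seed)
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .plate_io import (
    ROLE_COMPOUND,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    Plate,
    PlateLayout,
    WellAddress,
    WellRecord,
    build_default_layout,
)

__all__ = [
    "CLASS_INACTIVE",
    "CLASS_AGONIST",
    "CLASS_COMPETITIVE",
    "CLASS_NONCOMPETITIVE",
    "CLASS_CYTOTOXIC",
    "CLASS_INHIBITOR_CYTOTOXIC",
    "CompoundModel",
    "SimulationConfig",
    "DEFAULT_CLASS_PROPORTIONS",
    "DEFAULT_POTENCY_RANGES",
    "AGONIST_SERIES",
    "INHIBITOR_SERIES",
    "expected_signal",
    "simulate_plate",
    "simulate_library",
    "simulate_screen",
    "simulate_antagonist_assay",
    "simulate_qpcr",
]

CLASS_INACTIVE = "inactive"
CLASS_AGONIST = "agonist"
CLASS_COMPETITIVE = "competitive_inhibitor"
CLASS_NONCOMPETITIVE = "noncompetitive_inhibitor"
CLASS_CYTOTOXIC = "cytotoxic"
CLASS_INHIBITOR_CYTOTOXIC = "inhibitor_and_cytotoxic"

LATENT_CLASSES = (
    CLASS_INACTIVE,
    CLASS_AGONIST,
    CLASS_COMPETITIVE,
    CLASS_NONCOMPETITIVE,
    CLASS_CYTOTOXIC,
    CLASS_INHIBITOR_CYTOTOXIC,
)

#: JH I concentration grid of the antagonist-mode assay (molar)
AGONIST_SERIES = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)
#: inhibitor concentrations of the antagonist-mode assay (molar)
INHIBITOR_SERIES = (0.0, 0.5e-6, 5e-6)


@dataclass(frozen=True)
class CompoundModel:
    """Ground-truth pharmacology of one library compound.

    ``ki`` (molar) is the inhibition constant of either inhibitor class;
    ``tc50``/``hill_tox`` parameterize viability loss; ``ec50_agonist`` and
    ``efficacy`` (fraction of the full JH response) describe agonists.
    """

    compound_id: str
    latent_class: str
    ki: Optional[float] = None
    ec50_agonist: Optional[float] = None
    efficacy: Optional[float] = None
    tc50: Optional[float] = None
    hill_tox: float = 1.0

    def __post_init__(self) -> None:
        if self.latent_class not in LATENT_CLASSES:
            raise ValueError(f"unknown latent class {self.latent_class!r}")
        needs_ki = self.latent_class in (
            CLASS_COMPETITIVE, CLASS_NONCOMPETITIVE, CLASS_INHIBITOR_CYTOTOXIC
        )
        needs_tox = self.latent_class in (CLASS_CYTOTOXIC, CLASS_INHIBITOR_CYTOTOXIC)
        if needs_ki and not (self.ki and self.ki > 0):
            raise ValueError(f"{self.compound_id}: inhibitor class requires ki > 0")
        if needs_tox and not (self.tc50 and self.tc50 > 0):
            raise ValueError(f"{self.compound_id}: cytotoxic class requires tc50 > 0")
        if self.latent_class == CLASS_AGONIST and not (
            self.ec50_agonist and self.ec50_agonist > 0 and self.efficacy is not None
        ):
            raise ValueError(
                f"{self.compound_id}: agonist class requires ec50_agonist and efficacy"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Assay-level simulation parameters.

    Defaults: JH I potency 3.7e-10 M (Hill 1); signal levels f0 = 50,
    fmax = 2000, r0 = 1000 RLU (arbitrary — InH is invariant to affine
    rescaling); control wells at 5% CV and compound wells at 10% CV of
    multiplicative lognormal noise.
    """

    ec50_jh: float = 3.7e-10
    hill_jh: float = 1.0
    f0: float = 50.0
    fmax: float = 2000.0
    r0: float = 1000.0
    control_cv: float = 0.05
    compound_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_cv < 0 or self.compound_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if self.ec50_jh <= 0 or self.hill_jh <= 0:
            raise ValueError("JH potency parameters must be > 0")


def _hill(c: float, ec50: float, h: float) -> float:
    if c <= 0:
        return 0.0
    return c ** h / (c ** h + ec50 ** h)


def expected_signal(
    model: Optional[CompoundModel],
    jh_conc: float,
    compound_conc: float,
    config: SimulationConfig,
) -> tuple[float, float]:
    """Deterministic (fluc_mean, rluc_mean) for a well; model=None means a
    compound-free (control) well."""
    if jh_conc < 0 or compound_conc < 0:
        raise ValueError("concentrations must be >= 0")
    ec50_eff = config.ec50_jh
    fmax_eff = config.fmax
    viability = 1.0
    agonist_term = 0.0
    if model is not None and compound_conc > 0:
        cls = model.latent_class
        if cls in (CLASS_COMPETITIVE, CLASS_INHIBITOR_CYTOTOXIC):
            ec50_eff = config.ec50_jh * (1.0 + compound_conc / model.ki)
        elif cls == CLASS_NONCOMPETITIVE:
            fmax_eff = config.fmax / (1.0 + compound_conc / model.ki)
        elif cls == CLASS_AGONIST:
            agonist_term = model.efficacy * _hill(
                compound_conc, model.ec50_agonist, config.hill_jh
            )
        if cls in (CLASS_CYTOTOXIC, CLASS_INHIBITOR_CYTOTOXIC):
            viability = 1.0 / (
                1.0 + (compound_conc / model.tc50) ** model.hill_tox
            )
    occupancy = min(1.0, _hill(jh_conc, ec50_eff, config.hill_jh) + agonist_term)
    fluc = (config.f0 + fmax_eff * occupancy) * viability
    rluc = config.r0 * viability
    return fluc, rluc


def _noise(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal factor with mean exactly 1."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def simulate_plate(
    library: Sequence[CompoundModel],
    layout: PlateLayout,
    config: SimulationConfig,
    plate_id: str = "P001",
    jh_conc: float = 1e-9,
    compound_conc: float = 5e-6,
    rng: Optional[np.random.Generator] = None,
) -> Plate:
    """One plate: compounds fill the layout's compound wells in address
    order; controls are compound-free (positive: no JH; negative: jh_conc).
    """
    compound_addrs = layout.addresses(ROLE_COMPOUND)
    if len(library) > len(compound_addrs):
        raise ValueError(
            f"library of {len(library)} exceeds {len(compound_addrs)} compound wells"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    wells: list[WellRecord] = []
    for (row, col), role in sorted(layout.roles.items()):
        addr = WellAddress(plate_id, row, col)
        if role == ROLE_POSITIVE:
            f, r = expected_signal(None, 0.0, 0.0, config)
            wells.append(
                WellRecord(addr, role, None, 0.0, 0.0,
                           f * _noise(rng, config.control_cv),
                           r * _noise(rng, config.control_cv))
            )
        elif role == ROLE_NEGATIVE:
            f, r = expected_signal(None, jh_conc, 0.0, config)
            wells.append(
                WellRecord(addr, role, None, 0.0, jh_conc,
                           f * _noise(rng, config.control_cv),
                           r * _noise(rng, config.control_cv))
            )
    for model, (row, col) in zip(library, compound_addrs):
        addr = WellAddress(plate_id, row, col)
        f, r = expected_signal(model, jh_conc, compound_conc, config)
        wells.append(
            WellRecord(addr, ROLE_COMPOUND, model.compound_id, compound_conc, jh_conc,
                       f * _noise(rng, config.compound_cv),
                       r * _noise(rng, config.compound_cv))
        )
    return Plate(plate_id=plate_id, format=layout.format, wells=wells)


#: default latent-class mix of a screening library (~3% active overall)
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    CLASS_INACTIVE: 0.970,
    CLASS_AGONIST: 0.005,
    CLASS_COMPETITIVE: 0.010,
    CLASS_NONCOMPETITIVE: 0.005,
    CLASS_CYTOTOXIC: 0.005,
    CLASS_INHIBITOR_CYTOTOXIC: 0.005,
}

#: log-uniform potency ranges (molar). Competitive Ki is anchored on the
#: JHSI48-like regime (cell EC50 ~3e-7 M at 1 nM JH implies Ki ~9e-8 M);
#: cytotoxic TC50 is potent enough that viability loss masquerades as Fluc
#: inhibition through all four stages and must be caught by the Rluc rule.
DEFAULT_POTENCY_RANGES: dict[str, tuple[float, float]] = {
    "competitive_ki": (1e-8, 1e-7),
    "noncompetitive_ki": (5e-8, 7.5e-7),
    "tc50": (2e-8, 1e-7),
    "ec50_agonist": (1e-9, 1e-7),
}


def simulate_library(
    n: int,
    class_proportions: Optional[Mapping[str, float]] = None,
    potency_ranges: Optional[Mapping[str, tuple[float, float]]] = None,
    seed: int = 0,
) -> tuple[list[CompoundModel], pd.DataFrame]:
    """Draw a compound library with recorded ground truth.

    Class counts are the rounded expectation of the proportions (largest-
    remainder); potencies are log-uniform over the configured ranges.
    Returns (models, truth table).
    """
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    for cls in props:
        if cls not in LATENT_CLASSES:
            raise ValueError(f"unknown latent class {cls!r}")
    total = sum(props.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"class proportions must sum to 1, got {total}")
    ranges = {**DEFAULT_POTENCY_RANGES, **(potency_ranges or {})}
    rng = np.random.default_rng(seed)

    classes = sorted(props)
    exact = {c: props[c] * n for c in classes}
    counts = {c: int(np.floor(exact[c])) for c in classes}
    for c in sorted(classes, key=lambda c: exact[c] - counts[c], reverse=True):
        if sum(counts.values()) >= n:
            break
        counts[c] += 1

    def log_uniform(lo_hi: tuple[float, float]) -> float:
        lo, hi = lo_hi
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    models: list[CompoundModel] = []
    assignments = [c for cls in classes for c in [cls] * counts[cls]]
    rng.shuffle(assignments)
    for i, cls in enumerate(assignments):
        cid = f"CMP{i + 1:05d}"
        kwargs: dict = {}
        if cls in (CLASS_COMPETITIVE, CLASS_INHIBITOR_CYTOTOXIC):
            kwargs["ki"] = log_uniform(ranges["competitive_ki"])
        if cls == CLASS_NONCOMPETITIVE:
            kwargs["ki"] = log_uniform(ranges["noncompetitive_ki"])
        if cls in (CLASS_CYTOTOXIC, CLASS_INHIBITOR_CYTOTOXIC):
            kwargs["tc50"] = log_uniform(ranges["tc50"])
        if cls == CLASS_AGONIST:
            kwargs["ec50_agonist"] = log_uniform(ranges["ec50_agonist"])
            kwargs["efficacy"] = float(rng.uniform(0.5, 1.0))
        models.append(CompoundModel(compound_id=cid, latent_class=cls, **kwargs))

    truth = pd.DataFrame(
        {
            "compound_id": [m.compound_id for m in models],
            "latent_class": [m.latent_class for m in models],
            "ki": [m.ki for m in models],
            "ec50_agonist": [m.ec50_agonist for m in models],
            "efficacy": [m.efficacy for m in models],
            "tc50": [m.tc50 for m in models],
            "hill_tox": [m.hill_tox for m in models],
        }
    )
    return models, truth


def _chunk(seq: Sequence, size: int) -> Iterable[Sequence]:
    for i in range(0, len(seq), size):
        yield seq[i : i + size]


def simulate_screen(
    library: Sequence[CompoundModel],
    config: SimulationConfig,
    jh_conc: float = 1e-9,
    stage1_conc: float = 5e-6,
    stage3_concs: Sequence[float] = (0.05e-6, 0.5e-6, 5e-6),
    stage2_n: int = 4,
    stage3_n: int = 4,
    stage4_n: int = 3,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[int, list[Plate]], dict[int, PlateLayout]]:
    """Plate sets for a full four-stage campaign over one library.

    Stage 1 (384-well, n=1 at 5 uM), stage 2 (96-well confirmation, n=4),
    stages 3/4 (384-well dose series; stage 4 reuses the same three
    concentrations with n=3). Each replicate goes on its own plate so that
    per-plate normalization is genuinely exercised.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layout384 = build_default_layout(384)
    layout96 = build_default_layout(96)
    cap384 = len(layout384.addresses(ROLE_COMPOUND))
    cap96 = len(layout96.addresses(ROLE_COMPOUND))
    plates: dict[int, list[Plate]] = {1: [], 2: [], 3: [], 4: []}

    for i, chunk in enumerate(_chunk(library, cap384)):
        plates[1].append(
            simulate_plate(chunk, layout384, config, f"S1_p{i:03d}",
                           jh_conc, stage1_conc, rng)
        )
    for rep in range(stage2_n):
        for i, chunk in enumerate(_chunk(library, cap96)):
            plates[2].append(
                simulate_plate(chunk, layout96, config, f"S2_r{rep}_p{i:03d}",
                               jh_conc, stage1_conc, rng)
            )
    for stage, concs, n_rep in (
        (3, stage3_concs, stage3_n),
        (4, stage3_concs, stage4_n),
    ):
        for ci, conc in enumerate(concs):
            for rep in range(n_rep):
                for i, chunk in enumerate(_chunk(library, cap384)):
                    plates[stage].append(
                        simulate_plate(
                            chunk, layout384, config,
                            f"S{stage}_c{ci}_r{rep}_p{i:03d}", jh_conc, conc, rng,
                        )
                    )
    layouts = {1: layout384, 2: layout96, 3: layout384, 4: layout384}
    return plates, layouts


def simulate_antagonist_assay(
    model: Optional[CompoundModel],
    config: SimulationConfig,
    agonist_concs: Sequence[float] = AGONIST_SERIES,
    inhibitor_concs: Sequence[float] = INHIBITOR_SERIES,
    n_replicates: int = 3,
    cv: float = 0.05,
    rng: Optional[np.random.Generator] = None,
):
    """Replicate reporter responses over the agonist x inhibitor grid.

    Returns an :class:`~jhtriage.antagonist_mode.AntagonistAssayData`.
    """
    from .antagonist_mode import AntagonistAssayData

    if rng is None:
        rng = np.random.default_rng(config.seed)
    responses: dict[tuple[float, float], np.ndarray] = {}
    for inh in inhibitor_concs:
        for ag in agonist_concs:
            f, _ = expected_signal(model, ag, inh, config)
            responses[(ag, inh)] = f * _noise(rng, cv, n_replicates)
    return AntagonistAssayData(
        agonist_concs=tuple(agonist_concs),
        inhibitor_concs=tuple(inhibitor_concs),
        responses=responses,
        compound_id=model.compound_id if model else None,
    )


def simulate_qpcr(
    model: Optional[CompoundModel],
    jh_conc: float,
    inhibitor_concs: Sequence[float],
    config: SimulationConfig,
    n_replicates: int = 10,
    ct_sd: float = 0.15,
    baseline_ct: float = 20.0,
    reference_ct: float = 15.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Ct table for target (JH-inducible) and reference (constitutive) genes.

    Relative target expression under the pharmacological model is the ratio
    of expected Fluc signals with/without compound at ``jh_conc``; each
    halving of expression costs one extra target cycle
    (Ct = baseline - log2(relative expression)). Replicate noise is normal
    on the Ct scale (default SD 0.15 cycles) for both genes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f_ref, _ = expected_signal(None, jh_conc, 0.0, config)
    rows = []
    for conc in inhibitor_concs:
        f, _ = expected_signal(model, jh_conc, conc, config)
        rel = f / f_ref
        ct_t = baseline_ct - float(np.log2(rel))
        for rep in range(n_replicates):
            rows.append(
                {
                    "sample_id": f"{model.compound_id if model else 'none'}_c{conc:g}_r{rep}",
                    "jh_conc": jh_conc,
                    "inhibitor_conc": conc,
                    "replicate": rep,
                    "ct_target": ct_t + float(rng.normal(0.0, ct_sd)),
                    "ct_reference": reference_ct + float(rng.normal(0.0, ct_sd)),
                }
            )
    return pd.DataFrame(rows)
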