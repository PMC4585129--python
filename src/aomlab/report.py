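"""End-to-end analysis pipeline and report tables.

Chains the study stages — energetics of the condition roster, tracer
activity (%13CO2 with compact letters), qPCR quantification and fold
changes, and the amendment log summary — into report tables mirroring
the study's presentation: a condition table with dG' and regime (em-dash
for conditions without methane), a per-clade fold-change table, and a
produced-13CO2 table with Welch-test letter groups.

Every value in the report files is computed by the corresponding library
module; ``full_run`` only orchestrates and serializes (full precision in
the JSON index, one decimal kJ/mol in the formatted table).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import qpcr as _qpcr
from . import tracer as _tracer
from .qpcr import StandardPoint, fit_standard_curve, quantify, welch_t
from .simulate import SimParams, generate_study
from .thermo import (
    EnergyThresholds,
    IncubationCondition,
    TABLE1_CONDITIONS,
    ThermoParams,
    UndefinedQuotientError,
    classify_energetic_regime,
    delta_g_prime,
    reaction_quotient,
)

__all__ = [
    "RunConfig",
    "read_conditions",
    "energetics_table",
    "format_energetics",
    "pct13co2_table",
    "final_pct13co2",
    "quantify_plates",
    "fold_change_table",
    "activity_letters",
    "amendment_summary",
    "full_run",
]

EM_DASH = "–"

CONDITION_CSV_COLUMNS = [
    "id",
    "sulfate_mM",
    "sulfide_mM",
    "methane_mM",
    "co2_mM",
    "methane_added",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    out_dir: str | Path = "results"
    alpha: float = 0.05
    thermo: ThermoParams = ThermoParams()
    thresholds: EnergyThresholds = EnergyThresholds()
    sim: SimParams | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def read_conditions(path: str | Path) -> list[IncubationCondition]:
    """Read a condition table CSV (the Table-1 dialect)."""
    df = pd.read_csv(path)
    missing = set(CONDITION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"condition CSV missing columns: {sorted(missing)}")
    conditions = []
    for i, row in df.iterrows():
        try:
            conditions.append(
                IncubationCondition(
                    id=str(row["id"]),
                    sulfate_mM=float(row["sulfate_mM"]),
                    sulfide_mM=float(row["sulfide_mM"]),
                    methane_mM=float(row["methane_mM"]),
                    co2_mM=float(row["co2_mM"]),
                    methane_added=bool(row["methane_added"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"condition CSV line {i + 2}: {exc}") from exc
    return conditions


def energetics_table(
    conditions: Sequence[IncubationCondition] = TABLE1_CONDITIONS,
    params: ThermoParams = ThermoParams(),
    thresholds: EnergyThresholds = EnergyThresholds(),
) -> pd.DataFrame:
    """One row per condition with Q, dG' (kJ/mol CH4) and regime.

    Conditions without methane get NaN energy and an empty regime (the
    report prints an em-dash).  A condition flagged methane_added but
    with zero dissolved methane yields a row-level error entry instead
    of aborting the table.
    """
    rows = []
    for cond in conditions:
        row = {
            "id": cond.id,
            "sulfate_mM": cond.sulfate_mM,
            "sulfide_mM": cond.sulfide_mM,
            "methane_mM": cond.methane_mM,
            "co2_mM": cond.co2_mM,
            "methane_added": cond.methane_added,
            "Q": math.nan,
            "delta_g_kj": math.nan,
            "regime": "",
            "error": "",
        }
        if cond.methane_added:
            try:
                row["Q"] = reaction_quotient(cond)
                row["delta_g_kj"] = delta_g_prime(cond, params)
                row["regime"] = classify_energetic_regime(
                    row["delta_g_kj"], thresholds
                )
            except UndefinedQuotientError as exc:
                row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "sulfate_mM",
            "sulfide_mM",
            "methane_mM",
            "co2_mM",
            "methane_added",
            "Q",
            "delta_g_kj",
            "regime",
            "error",
        ],
    )


def format_energetics(table: pd.DataFrame) -> pd.DataFrame:
    """Printable variant: dG' to one decimal, em-dash where undefined."""
    out = table.copy()
    out["delta_g_kj"] = [
        EM_DASH if math.isnan(v) else f"{v:.1f}" for v in table["delta_g_kj"]
    ]
    out["Q"] = [
        EM_DASH if math.isnan(v) else f"{v:.4f}" for v in table["Q"]
    ]
    return out


def pct13co2_table(
    gas: pd.DataFrame, label: _tracer.LabelState = _tracer.LabelState()
) -> pd.DataFrame:
    """Per-bottle produced 13CO2 (%) from a gas time-series table."""
    frames = []
    for bottle_id, sub in gas[gas["species"] == "CO2"].groupby(
        "bottle_id", sort=True
    ):
        sub = sub.sort_values("day")
        series = [
            _tracer.IsotopologueReading(
                "CO2", r.amount12_mmol, r.amount13_mmol, r.day
            )
            for r in sub.itertuples()
        ]
        pct = _tracer.percent_13co2(series, label)
        pct.insert(0, "bottle_id", bottle_id)
        frames.append(pct)
    return pd.concat(frames, ignore_index=True)


def final_pct13co2(
    gas: pd.DataFrame, label: _tracer.LabelState = _tracer.LabelState()
) -> pd.DataFrame:
    """Final produced 13CO2 (%) per bottle with its condition id."""
    table = pct13co2_table(gas, label)
    final = (
        table.sort_values("day").groupby("bottle_id", sort=True).tail(1)
    )
    final = final.copy()
    final["condition_id"] = [
        b.rsplit("_", 1)[0] for b in final["bottle_id"]
    ]
    return final[["condition_id", "bottle_id", "day", "pct_13co2"]].reset_index(
        drop=True
    )


def quantify_plates(plates: pd.DataFrame) -> pd.DataFrame:
    """Fit per-target standard curves and quantify all sample wells.

    Returns one row per sample well with both normalizations plus the
    curve diagnostics (slope, efficiency, R^2).
    """
    rows = []
    for target, sub in plates.groupby("target", sort=True):
        standards = sub[sub["well_type"] == "standard"]
        curve = fit_standard_curve(
            [
                StandardPoint(float(r.copies_per_ul), float(r.cq))
                for r in standards.itertuples()
            ]
        )
        samples = sub[sub["well_type"] == "sample"]
        for r in samples.itertuples():
            quant = quantify(
                float(r.cq),
                curve,
                template_ng=float(r.template_ng),
                extract_ng_per_ul=float(r.extract_ng_per_ul),
                elution_ul=float(r.elution_ul),
                sample_g_wet=float(r.sample_g_wet),
                clade=target,
                bottle_id=str(r.bottle_id),
                day=float(r.day),
            )
            rows.append(
                {
                    "clade": target,
                    "bottle_id": quant.bottle_id,
                    "day": quant.day,
                    "copies_per_g_wet": quant.copies_per_g_wet,
                    "copies_per_ng_dna": quant.copies_per_ng_dna,
                    "curve_slope": curve.slope,
                    "curve_efficiency": curve.efficiency,
                    "curve_r_squared": curve.r_squared,
                }
            )
    return pd.DataFrame(rows)


def fold_change_table(
    quants: pd.DataFrame, day_initial: float = 0.0, day_final: float = 344.0
) -> pd.DataFrame:
    """Per-bottle fold changes (day_final / day_initial) for every clade.

    Fold changes are invariant to the normalization chain when the DNA
    yield per sample is constant, so the per-g-wet values are used.
    """
    rows = []
    for (clade, bottle_id), sub in quants.groupby(
        ["clade", "bottle_id"], sort=True
    ):
        by_day = sub.set_index("day")
        if day_initial not in by_day.index or day_final not in by_day.index:
            continue
        initial = float(by_day.loc[day_initial, "copies_per_g_wet"])
        final = float(by_day.loc[day_final, "copies_per_g_wet"])
        ratio = final / initial
        rows.append(
            {
                "condition_id": bottle_id.rsplit("_", 1)[0],
                "bottle_id": bottle_id,
                "clade": clade,
                "ratio": ratio,
                "growth": ratio > 1.0,
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["condition_id", "clade", "bottle_id"], ignore_index=True
    )


def activity_letters(
    final_pct: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Welch tests on final %13CO2 and the letter display.

    Returns (pairwise p-value matrix as DataFrame, per-condition summary
    with mean, sd, letters and Holm-adjusted minimum p).
    """
    grouped = final_pct.groupby("condition_id", sort=True)["pct_13co2"]
    condition_ids = list(grouped.groups)
    values = {c: grouped.get_group(c).to_numpy() for c in condition_ids}
    n = len(condition_ids)
    p = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, pv = welch_t(values[condition_ids[i]], values[condition_ids[j]])
            p[i, j] = p[j, i] = pv
    letters = _qpcr.letter_groups(p, alpha)
    off_diag = p[np.triu_indices(n, k=1)]
    holm = _qpcr.holm_adjust(off_diag)
    holm_matrix = np.ones((n, n))
    holm_matrix[np.triu_indices(n, k=1)] = holm
    holm_matrix = np.minimum(holm_matrix, holm_matrix.T)
    summary = pd.DataFrame(
        {
            "condition_id": condition_ids,
            "n": [len(values[c]) for c in condition_ids],
            "mean_pct_13co2": [values[c].mean() for c in condition_ids],
            "sd_pct_13co2": [values[c].std(ddof=1) for c in condition_ids],
            "letters": letters,
        }
    )
    pmat = pd.DataFrame(p, index=condition_ids, columns=condition_ids)
    pmat_holm = pd.DataFrame(
        holm_matrix, index=condition_ids, columns=condition_ids
    )
    summary.attrs["holm"] = pmat_holm
    return pmat, summary


def amendment_summary(amendments: pd.DataFrame) -> pd.DataFrame:
    """Total reagent use per condition and reagent."""
    if amendments.empty:
        return pd.DataFrame(
            columns=["condition_id", "reagent", "n_additions", "total_mmol"]
        )
    df = amendments.copy()
    df["condition_id"] = [b.rsplit("_", 1)[0] for b in df["bottle_id"]]
    out = (
        df.groupby(["condition_id", "reagent"], sort=True)
        .agg(n_additions=("dose_mmol", "size"), total_mmol=("dose_mmol", "sum"))
        .reset_index()
    )
    return out


def full_run(cfg: RunConfig) -> dict:
    """Generate a study and emit the full report bundle.

    Writes the study CSVs, the energetics report, per-bottle fold
    changes, the %13CO2/letters table, the amendment summary and a
    machine-readable ``index.json``; deterministic given the seed.
    Returns the index as a dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim if cfg.sim is not None else SimParams(seed=cfg.seed)
    study = generate_study(sim)
    study_paths = study.write_csvs(out / "study")

    energetics = energetics_table(
        tuple(c.condition for c in study.conditions), cfg.thermo, cfg.thresholds
    )
    format_energetics(energetics).to_csv(out / "energetics.csv", index=False)

    quants = quantify_plates(study.qpcr_plates)
    quants.to_csv(out / "qpcr_quants.csv", index=False)
    folds = fold_change_table(quants, *[float(d) for d in sim.qpcr_days])
    folds.to_csv(out / "fold_changes.csv", index=False)

    label = _tracer.LabelState(
        label_start_day=sim.label_start_day,
        f13_ch4=sim.f13_ch4_label,
        natural_abundance=sim.natural_abundance,
    )
    pct = pct13co2_table(study.gas, label)
    pct.to_csv(out / "pct13co2.csv", index=False)
    final = final_pct13co2(study.gas, label)
    pmat, letters = activity_letters(final, cfg.alpha)
    letters.to_csv(out / "activity_letters.csv", index=False)
    pmat.to_csv(out / "pairwise_welch_p.csv")

    amend = amendment_summary(study.amendments)
    amend.to_csv(out / "amendment_summary.csv", index=False)

    fold_means = (
        folds.groupby(["condition_id", "clade"], sort=True)["ratio"]
        .mean()
        .unstack()
    )
    index = {
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "files": {
            "energetics": "energetics.csv",
            "fold_changes": "fold_changes.csv",
            "qpcr_quants": "qpcr_quants.csv",
            "pct13co2": "pct13co2.csv",
            "activity_letters": "activity_letters.csv",
            "pairwise_welch_p": "pairwise_welch_p.csv",
            "amendment_summary": "amendment_summary.csv",
            "study": {k: str(v.relative_to(out)) for k, v in study_paths.items()},
        },
        "energetics_kj_per_mol": {
            row["id"]: (None if math.isnan(row["delta_g_kj"]) else row["delta_g_kj"])
            for _, row in energetics.iterrows()
        },
        "regimes": {
            row["id"]: row["regime"] for _, row in energetics.iterrows()
        },
        "mean_fold_change": {
            cond: {clade: fold_means.loc[cond, clade] for clade in fold_means.columns}
            for cond in fold_means.index
        },
        "mean_pct_13co2": dict(
            zip(letters["condition_id"], letters["mean_pct_13co2"])
        ),
        "letters": dict(zip(letters["condition_id"], letters["letters"])),
    }
    (out / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True))
    return index
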