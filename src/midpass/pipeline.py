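"""End-to-end analysis pipeline.

Order of execution mirrors how the analysis is meant to be read: cohort
ingest, consecutive-interval pair construction, anchor-credibility screen,
then — for credible instruments only — the four MID estimators and the two
PASS estimators, pooled over all follow-up intervals (primary analysis)
and optionally per interval / per time point (secondary analysis).

Instruments failing the credibility gate get their MID/PASS cells marked
``withheld (anchor correlation below threshold)`` rather than silently
omitted, so a weakly anchored instrument is visible in the report.

Reports are written as one CSV per table plus a single deterministic JSON;
every stochastic step consumes a seed derived from the config seed, so a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import anchor as anchor_mod
from . import mid as mid_mod
from . import pass_state as pass_mod
from ._util import spawn_seeds
from .cohort import (
    DEFAULT_TIMEPOINTS,
    FollowUpRecord,
    Instrument,
    build_change_pairs,
    read_cohort,
)

logger = logging.getLogger(__name__)

WITHHELD = "withheld (anchor correlation below threshold)"


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the pipeline needs besides the dataset itself."""

    instruments: tuple[Instrument, ...]
    timepoint_labels: tuple[str, ...] = DEFAULT_TIMEPOINTS
    satisfied_max_level: int = 2
    credibility_threshold: float = 0.3
    n_boot_cutoff: int = 1000
    n_boot_auc: int = 2000
    n_boot_predictive: int = 1000
    n_boot_rho: int = 1000
    n_boot_pass_percentile: int = 1000
    seed: int = 0
    per_timepoint: bool = False
    cluster_bootstrap: bool = False
    missing_sentinels: tuple[str, ...] = ("", "NA")
    display_decimals: int = 1

    def __post_init__(self) -> None:
        if not self.instruments:
            raise ValueError("at least one instrument is required")
        if not 1 <= self.satisfied_max_level <= 6:
            raise ValueError("satisfied_max_level must be in [1, 6]")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from YAML (or JSON, a YAML subset).

        Expected shape::

            instruments:
              - {name: dash, scale_min: 0, scale_max: 100,
                 direction: higher_is_worse, resolution: 1}
            timepoint_labels: [6wk, 3mo, 6mo, 12mo, 24mo]
            satisfied_max_level: 2
            seed: 7
        """
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "instruments" not in raw:
            raise ValueError(f"{path}: config must define 'instruments'")
        instruments = tuple(
            Instrument(
                name=spec["name"],
                scale_min=float(spec["scale_min"]),
                scale_max=float(spec["scale_max"]),
                direction=spec["direction"],
                resolution=float(spec.get("resolution", 1.0)),
            )
            for spec in raw.pop("instruments")
        )
        tuple_fields = {"timepoint_labels", "missing_sentinels"}
        kwargs = {
            k: tuple(v) if k in tuple_fields else v for k, v in raw.items()
        }
        return cls(instruments=instruments, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisReport:
    """All result tables plus provenance; serialisable to CSV + JSON."""

    correlation_table: pd.DataFrame
    mid_roc_table: pd.DataFrame
    mid_other_table: pd.DataFrame
    pass_table: pd.DataFrame
    per_interval_mid: dict[str, pd.DataFrame] = field(default_factory=dict)
    per_timepoint_pass: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        def frame(df: pd.DataFrame) -> list[dict]:
            return json.loads(df.to_json(orient="records"))

        return {
            "correlations": frame(self.correlation_table),
            "mid_roc": frame(self.mid_roc_table),
            "mid_other": frame(self.mid_other_table),
            "pass": frame(self.pass_table),
            "per_interval_mid": {
                k: frame(v) for k, v in sorted(self.per_interval_mid.items())
            },
            "per_timepoint_pass": {
                k: frame(v) for k, v in sorted(self.per_timepoint_pass.items())
            },
            "provenance": self.provenance,
            "warnings": self.warnings,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.correlation_table.to_csv(out / "correlations.csv", index=False)
        self.mid_roc_table.to_csv(out / "mid_roc.csv", index=False)
        self.mid_other_table.to_csv(out / "mid_other.csv", index=False)
        self.pass_table.to_csv(out / "pass.csv", index=False)
        for label, df in self.per_interval_mid.items():
            df.to_csv(out / f"mid_interval_{label}.csv", index=False)
        for label, df in self.per_timepoint_pass.items():
            df.to_csv(out / f"pass_timepoint_{label}.csv", index=False)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
        with open(out / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write(self.summary_text())

    def summary_text(self, decimals: int | None = None) -> str:
        """Human-readable rounded summary (full precision stays in the CSVs)."""
        d = self.provenance.get("display_decimals", 1) if decimals is None else decimals

        def r(v):
            if isinstance(v, float):
                return round(v, d)
            return v

        lines = ["Anchor credibility (Spearman rho of anchor change vs outcome):"]
        for _, row in self.correlation_table.iterrows():
            lines.append(
                f"  {row.instrument}: rho_change={r(row.rho_change)} "
                f"({r(row.rho_change_ci_low)} to {r(row.rho_change_ci_high)}) "
                f"[{row.label}]"
                + ("" if row.credible else "  -> MID/PASS withheld")
            )
        lines.append("")
        lines.append("MID estimates (ROC method):")
        for _, row in self.mid_roc_table.iterrows():
            if row.status != "ok":
                lines.append(f"  {row.instrument}: {row.status}")
                continue
            lines.append(
                f"  {row.instrument}: MID={r(row.estimate)} "
                f"({r(row.ci_low)} to {r(row.ci_high)}), "
                f"sens={r(row.sensitivity)}, spec={r(row.specificity)}, "
                f"AUC={r(row.auc)} ({r(row.auc_ci_low)} to {r(row.auc_ci_high)}), "
                f"N={int(row.n_improved) + int(row.n_not_improved)} "
                f"({int(row.n_improved)}/{int(row.n_not_improved)})"
            )
        lines.append("")
        lines.append("MID estimates (other methods):")
        for _, row in self.mid_other_table.iterrows():
            if row.status != "ok":
                lines.append(f"  {row.instrument} [{row.method}]: {row.status}")
                continue
            lines.append(
                f"  {row.instrument} [{row.method}]: MID={r(row.estimate)} "
                f"({r(row.ci_low)} to {r(row.ci_high)})"
            )
        lines.append("")
        lines.append("PASS estimates:")
        for _, row in self.pass_table.iterrows():
            if row.status != "ok":
                lines.append(f"  {row.instrument} [{row.method}]: {row.status}")
                continue
            lines.append(
                f"  {row.instrument} [{row.method}]: PASS={r(row.estimate)} "
                f"({r(row.ci_low)} to {r(row.ci_high)})"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------

def _correlation_row(profile: anchor_mod.CorrelationProfile) -> dict:
    return {
        "instrument": profile.instrument_name,
        "rho_change": profile.rho_change,
        "rho_change_ci_low": profile.rho_change_ci[0],
        "rho_change_ci_high": profile.rho_change_ci[1],
        "rho_prescore": profile.rho_prescore,
        "rho_prescore_ci_low": profile.rho_prescore_ci[0],
        "rho_prescore_ci_high": profile.rho_prescore_ci[1],
        "rho_postscore": profile.rho_postscore,
        "rho_postscore_ci_low": profile.rho_postscore_ci[0],
        "rho_postscore_ci_high": profile.rho_postscore_ci[1],
        "n_pairs": profile.n_pairs,
        "credible": bool(profile.credible),
        "label": profile.label,
        "threshold": profile.threshold_used,
    }


def _mid_roc_row(instrument: str, outcome) -> dict:
    row = {
        "instrument": instrument,
        "status": "ok",
        "estimate": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "sensitivity": np.nan,
        "specificity": np.nan,
        "auc": np.nan,
        "auc_ci_low": np.nan,
        "auc_ci_high": np.nan,
        "n_improved": 0,
        "n_not_improved": 0,
    }
    if isinstance(outcome, str):
        row["status"] = outcome
    elif isinstance(outcome, Exception):
        row["status"] = f"error: {outcome}"
    else:
        aux = outcome.auxiliary
        row.update(
            estimate=outcome.estimate,
            ci_low=outcome.ci[0],
            ci_high=outcome.ci[1],
            sensitivity=aux["sensitivity"],
            specificity=aux["specificity"],
            auc=aux["auc"],
            auc_ci_low=aux["auc_ci"][0],
            auc_ci_high=aux["auc_ci"][1],
            n_improved=outcome.n_improved,
            n_not_improved=outcome.n_not_improved,
        )
    return row


def _mid_other_row(instrument: str, method: str, outcome) -> dict:
    row = {
        "instrument": instrument,
        "method": method,
        "status": "ok",
        "estimate": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "n_improved": 0,
        "n_not_improved": 0,
    }
    if isinstance(outcome, str):
        row["status"] = outcome
    elif isinstance(outcome, Exception):
        row["status"] = f"error: {outcome}"
    else:
        row.update(
            estimate=outcome.estimate,
            ci_low=outcome.ci[0],
            ci_high=outcome.ci[1],
            n_improved=outcome.n_improved,
            n_not_improved=outcome.n_not_improved,
        )
    return row


def _pass_row(instrument: str, method: str, outcome) -> dict:
    row = {
        "instrument": instrument,
        "method": method,
        "status": "ok",
        "estimate": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "sensitivity": np.nan,
        "specificity": np.nan,
        "auc": np.nan,
        "auc_ci_low": np.nan,
        "auc_ci_high": np.nan,
        "n_satisfied": 0,
    }
    if isinstance(outcome, str):
        row["status"] = outcome
    elif isinstance(outcome, Exception):
        row["status"] = f"error: {outcome}"
    else:
        aux = outcome.auxiliary
        row.update(
            estimate=outcome.estimate,
            ci_low=outcome.ci[0],
            ci_high=outcome.ci[1],
            n_satisfied=aux.get("n_satisfied", 0),
        )
        if method == pass_mod.METHOD_ROC:
            row.update(
                sensitivity=aux["sensitivity"],
                specificity=aux["specificity"],
                auc=aux["auc"],
                auc_ci_low=aux["auc_ci"][0],
                auc_ci_high=aux["auc_ci"][1],
            )
    return row


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def _analyse_mids(
    pairs, instrument: Instrument, config: AnalysisConfig, seed
) -> tuple[dict, list[dict]]:
    """One ROC row and three other-method rows for one instrument."""
    results = mid_mod.estimate_all_mids(
        pairs,
        instrument,
        n_boot_cutoff=config.n_boot_cutoff,
        n_boot_auc=config.n_boot_auc,
        n_boot_predictive=config.n_boot_predictive,
        seed=seed,
        cluster=config.cluster_bootstrap,
    )
    roc_row = _mid_roc_row(instrument.name, results[mid_mod.METHOD_ROC])
    other_rows = [
        _mid_other_row(instrument.name, method, results[method])
        for method in (
            mid_mod.METHOD_MEAN_DIFFERENCE,
            mid_mod.METHOD_MEAN_CHANGE,
            mid_mod.METHOD_PREDICTIVE,
        )
    ]
    return roc_row, other_rows


def _analyse_pass(
    records: Sequence[FollowUpRecord],
    instrument: Instrument,
    config: AnalysisConfig,
    seed,
) -> list[dict]:
    seeds = spawn_seeds(seed, 2)
    rows = []
    try:
        res = pass_mod.pass_roc(
            records,
            instrument,
            satisfied_max_level=config.satisfied_max_level,
            n_boot_cutoff=config.n_boot_cutoff,
            n_boot_auc=config.n_boot_auc,
            seed=seeds[0],
        )
    except pass_mod.InsufficientDataError as exc:
        res = exc
    rows.append(_pass_row(instrument.name, pass_mod.METHOD_ROC, res))
    try:
        res = pass_mod.pass_percentile(
            records,
            instrument,
            satisfied_max_level=config.satisfied_max_level,
            n_boot=config.n_boot_pass_percentile,
            seed=seeds[1],
        )
    except pass_mod.InsufficientDataError as exc:
        res = exc
    rows.append(_pass_row(instrument.name, pass_mod.METHOD_PERCENTILE, res))
    return rows


def run_analysis(
    dataset_path,
    config: AnalysisConfig,
    out_dir=None,
    per_timepoint: bool | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Run the full analysis on a cohort CSV.

    ``per_timepoint`` and ``seed`` override the corresponding config
    fields when given. When ``out_dir`` is set, tables are written as CSV
    plus ``report.json``, ``summary.txt`` and ``run.log``.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    if per_timepoint is not None:
        config = dataclasses.replace(config, per_timepoint=per_timepoint)

    log_handler = None
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(
            Path(out_dir) / "run.log", mode="w", encoding="utf-8"
        )
        log_handler.setFormatter(
            logging.Formatter("%(levelname)s %(name)s: %(message)s")
        )
        logging.getLogger("midpass").addHandler(log_handler)

    try:
        return _run(dataset_path, config, out_dir)
    finally:
        if log_handler is not None:
            logging.getLogger("midpass").removeHandler(log_handler)
            log_handler.close()


def _run(dataset_path, config: AnalysisConfig, out_dir) -> AnalysisReport:
    records = read_cohort(
        dataset_path,
        config.instruments,
        timepoint_labels=config.timepoint_labels,
        missing_sentinels=config.missing_sentinels,
    )

    root_seed = np.random.SeedSequence(config.seed)
    inst_seeds = root_seed.spawn(len(config.instruments))

    corr_rows, roc_rows, other_rows, pass_rows = [], [], [], []
    per_interval_mid: dict[str, pd.DataFrame] = {}
    per_timepoint_pass: dict[str, pd.DataFrame] = {}
    warnings: list[str] = []
    pair_counts: dict[str, int] = {}
    n_credible = 0

    for instrument, iseed in zip(config.instruments, inst_seeds):
        seeds = iseed.spawn(4)
        pairs = build_change_pairs(records, instrument)
        pair_counts[instrument.name] = len(pairs)
        if not pairs:
            warnings.append(f"{instrument.name}: no usable change pairs")
            roc_rows.append(
                _mid_roc_row(instrument.name, "error: no usable change pairs")
            )
            continue
        profile = anchor_mod.correlation_profile(
            pairs,
            instrument,
            threshold=config.credibility_threshold,
            n_boot=config.n_boot_rho,
            seed=seeds[0],
        )
        corr_rows.append(_correlation_row(profile))

        if not profile.credible:
            warnings.append(
                f"{instrument.name}: anchor correlation "
                f"{profile.rho_change:.2f} below threshold "
                f"{config.credibility_threshold}; MID/PASS withheld"
            )
            roc_rows.append(_mid_roc_row(instrument.name, WITHHELD))
            for method in (
                mid_mod.METHOD_MEAN_DIFFERENCE,
                mid_mod.METHOD_MEAN_CHANGE,
                mid_mod.METHOD_PREDICTIVE,
            ):
                other_rows.append(_mid_other_row(instrument.name, method, WITHHELD))
            for method in (pass_mod.METHOD_ROC, pass_mod.METHOD_PERCENTILE):
                pass_rows.append(_pass_row(instrument.name, method, WITHHELD))
            continue

        n_credible += 1
        roc_row, others = _analyse_mids(pairs, instrument, config, seeds[1])
        roc_rows.append(roc_row)
        other_rows.extend(others)
        pass_rows.extend(_analyse_pass(records, instrument, config, seeds[2]))

        if config.per_timepoint:
            n_tp = max(r.timepoint_index for r in records) + 1
            sub_seeds = seeds[3].spawn(2 * n_tp)
            _secondary_analyses(
                records,
                pairs,
                instrument,
                config,
                sub_seeds,
                per_interval_mid,
                per_timepoint_pass,
            )

    if n_credible == 0:
        warnings.insert(
            0,
            "NO CREDIBLE INSTRUMENTS: every anchor-change correlation fell "
            "below the credibility threshold; only the correlation table "
            "is reported",
        )
        logger.warning(warnings[0])

    report = AnalysisReport(
        correlation_table=pd.DataFrame(corr_rows),
        mid_roc_table=pd.DataFrame(roc_rows),
        mid_other_table=pd.DataFrame(other_rows),
        pass_table=pd.DataFrame(pass_rows),
        per_interval_mid=per_interval_mid,
        per_timepoint_pass=per_timepoint_pass,
        provenance={
            "config": _jsonable(config.to_dict()),
            "dataset": str(dataset_path),
            "n_records": len(records),
            "pair_counts": pair_counts,
            "seed": config.seed,
            "display_decimals": config.display_decimals,
        },
        warnings=warnings,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def _secondary_analyses(
    records,
    pairs,
    instrument,
    config,
    sub_seeds,
    per_interval_mid,
    per_timepoint_pass,
) -> None:
    """Per-interval MID and per-timepoint PASS (secondary analysis)."""
    labels = config.timepoint_labels
    intervals = sorted({p.interval for p in pairs})
    si = iter(sub_seeds)
    for interval in intervals:
        sub = [p for p in pairs if p.interval == interval]
        label = f"{labels[interval[0]]}_to_{labels[interval[1]]}"
        roc_row, others = _analyse_mids(sub, instrument, config, next(si))
        frame = pd.DataFrame([roc_row] + others)
        per_interval_mid[label] = (
            pd.concat([per_interval_mid[label], frame], ignore_index=True)
            if label in per_interval_mid
            else frame
        )
    timepoints = sorted({r.timepoint_index for r in records})
    for tp in timepoints:
        sub_records = [r for r in records if r.timepoint_index == tp]
        label = labels[tp]
        rows = _analyse_pass(sub_records, instrument, config, next(si))
        frame = pd.DataFrame(rows)
        per_timepoint_pass[label] = (
            pd.concat([per_timepoint_pass[label], frame], ignore_index=True)
            if label in per_timepoint_pass
            else frame
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
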