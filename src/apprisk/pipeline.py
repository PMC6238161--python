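"""Generate → score → evaluate orchestration.

The pipeline mirrors the intended decision-support pathway: a cohort table
of two-drug regimens (synthetic here, but any file with the same schema
works) is scored with four classifiers and each classifier is evaluated
against the recorded outcome by AUROC.

Score columns appended to the cohort table:

* ``qsp_readout`` — STN-elevation liability from the circuit model, with
  endogenous dopamine competing at D₂R (tone configurable, default 1.0);
* ``d2r_sum``     — summed D₂R occupancy of the two drugs (tone default 0);
* ``inv_k_sum``   — 1/K₁ + 1/K₂ at D₂R, dose independent;
* ``cpz_sum``     — summed chlorpromazine-equivalent daily dose.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .circuit import CircuitParams, default_circuit_params, stn_readout
from .cohort import (
    CohortConfig,
    PatientRecord,
    assign_outcomes,
    cohort_to_dataframe,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .evaluation import (
    CLASSIFIER_COLUMNS,
    evaluate_classifiers,
    results_to_dataframe,
)
from .pharmacology import (
    DrugTable,
    Regimen,
    cpz_equivalent_sum,
    default_drug_table,
    inv_k_sum,
    load_drug_table,
    sum_d2_occupancy,
)

__all__ = [
    "RunConfig",
    "load_run_config",
    "score_regimen",
    "score_cohort",
    "run_simulate",
    "run_score",
    "run_evaluate",
    "run_all",
]

log = logging.getLogger("apprisk")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (YAML-loadable)."""

    seed: int = 0
    drug_table_path: str | None = None  # None → bundled default table
    cohort: CohortConfig = field(default_factory=CohortConfig)
    circuit: CircuitParams | None = None  # None → bundled defaults
    se_method: str = "hanley"
    #: dopamine tone used inside the mechanistic readout
    qsp_dopamine_tone: float = 1.0
    #: tone used for the simple summed-occupancy comparator
    d2r_dopamine_tone: float = 0.0
    log_level: str = "INFO"

    def drug_table(self) -> DrugTable:
        if self.drug_table_path is None:
            return default_drug_table()
        return load_drug_table(self.drug_table_path)

    def circuit_params(self) -> CircuitParams:
        return self.circuit if self.circuit is not None else default_circuit_params()

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Read a YAML run configuration; an explicit ``seed`` overrides the file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_kwargs = dict(raw.get("cohort", {}))
    cfg_seed = int(raw.get("seed", 0)) if seed is None else int(seed)
    cohort_kwargs["seed"] = cfg_seed
    drug_table_path = (raw.get("paths") or {}).get("drug_table")
    if drug_table_path is not None and not Path(drug_table_path).exists():
        raise FileNotFoundError(f"drug table {drug_table_path} does not exist")
    circuit_raw = raw.get("circuit")
    ev = raw.get("evaluation", {})
    return RunConfig(
        seed=cfg_seed,
        drug_table_path=drug_table_path,
        cohort=CohortConfig(**cohort_kwargs),
        circuit=CircuitParams.from_dict(circuit_raw) if circuit_raw else None,
        se_method=ev.get("se_method", "hanley"),
        qsp_dopamine_tone=float(ev.get("qsp_dopamine_tone", 1.0)),
        d2r_dopamine_tone=float(ev.get("d2r_dopamine_tone", 0.0)),
        log_level=raw.get("log_level", "INFO"),
    )


def score_regimen(
    regimen: Regimen,
    circuit: CircuitParams,
    qsp_dopamine_tone: float = 1.0,
    d2r_dopamine_tone: float = 0.0,
) -> dict[str, float]:
    """All four classifier scores for one regimen."""
    return {
        "qsp_readout": stn_readout(regimen, circuit, qsp_dopamine_tone).liability_score,
        "d2r_sum": sum_d2_occupancy(regimen, d2r_dopamine_tone),
        "inv_k_sum": inv_k_sum(regimen),
        "cpz_sum": cpz_equivalent_sum(regimen),
    }


def score_cohort(records: list[PatientRecord], config: RunConfig) -> list[PatientRecord]:
    """Attach the four classifier scores to every record (in place)."""
    circuit = config.circuit_params()
    cache: dict[tuple, dict[str, float]] = {}
    for rec in records:
        key = (
            rec.regimen.drug_a.name,
            rec.regimen.dose_a,
            rec.regimen.drug_b.name,
            rec.regimen.dose_b,
        )
        if key not in cache:
            cache[key] = score_regimen(
                rec.regimen, circuit, config.qsp_dopamine_tone, config.d2r_dopamine_tone
            )
        rec.predictor_scores.update(cache[key])
    return records


def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate a cohort with outcomes and write it (plus provenance sidecar).

    When outcomes are linked to a predictor, the linked score is computed
    first; the written file carries only the base schema — scoring is the
    next pipeline stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = config.drug_table()
    records = generate_cohort(config.cohort, table)
    if config.cohort.link_delta > 0:
        log.info("computing linked predictor %s for outcome assignment", config.cohort.link_predictor)
        score_cohort(records, config)
    assign_outcomes(records, config.cohort)
    for rec in records:
        rec.predictor_scores = {}
    path = out_dir / "cohort.csv"
    write_cohort(path, records, config.cohort)
    log.info("wrote %d records to %s", len(records), path)
    return path


def run_score(
    cohort_path: str | Path, config: RunConfig, out_path: str | Path
) -> Path:
    """Score an existing cohort file; idempotent (re-scoring overwrites)."""
    table = config.drug_table()
    records = read_cohort(cohort_path, table)
    for rec in records:  # drop any stale scores before recomputing
        rec.predictor_scores = {}
    score_cohort(records, config)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    cohort_to_dataframe(records).to_csv(out_path, index=False, float_format="%.10g")
    log.info("scored %d records -> %s", len(records), out_path)
    return out_path


def run_evaluate(scored_path: str | Path, config: RunConfig, out_dir: str | Path) -> Path:
    """AUROC comparison table + ROC point files for a scored cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(scored_path)
    if "outcome" not in df.columns or df["outcome"].isna().any():
        raise ValueError("scored cohort must carry an outcome flag on every record")
    results = evaluate_classifiers(df, CLASSIFIER_COLUMNS, config.se_method)
    table = results_to_dataframe(results)
    table_path = out_dir / "roc_comparison.csv"
    table.to_csv(table_path, index=False, float_format="%.6g")
    for res in results:
        pts = pd.DataFrame(res.roc_points, columns=["fpr", "tpr"])
        pts.to_csv(out_dir / f"roc_points_{res.classifier_name}.csv", index=False)
    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "se_method": config.se_method,
        "n_records": int(len(df)),
    }
    (out_dir / "evaluation_meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    for res in results:
        log.info(
            "%s: AUC %.3f (SE %.3f, 95%% CI %.3f-%.3f, p=%.3g)",
            res.classifier_name, res.auc, res.se, res.ci_low, res.ci_high, res.p_vs_chance,
        )
    return table_path


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """simulate → score → evaluate in one call; returns the comparison table path."""
    out_dir = Path(out_dir)
    cohort_path = run_simulate(config, out_dir)
    scored_path = run_score(cohort_path, config, out_dir / "cohort_scored.csv")
    return run_evaluate(scored_path, config, out_dir)
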