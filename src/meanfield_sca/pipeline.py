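"""Per-participant analysis pipeline: preprocess -> fit -> classify -> BC.

Binds the modules into the workflow used on empirical cohorts: raw ESM item
panels are reduced to binary matrices and count series, the noise parameter
p (and graph parameter) is estimated by maximum likelihood, the fitted map's
equilibrium structure classifies each participant as stable or bistable
("expectancy for a transition"), and the bimodality coefficient is computed
on the same density series as the model-free comparison statistic. The
default fitted structure is the random graph with (p, p(e)) estimated
jointly; ``structure="auto"`` selects among the three structures by BIC.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import inference
from .bimodality import bimodality_coefficient
from .experiments import agreement
from .meanfield import classify
from .preprocess import ItemPanel, preprocess_panel

__all__ = [
    "PipelineConfig",
    "read_panels",
    "run_pipeline",
    "write_results",
    "read_results",
]

logger = logging.getLogger("meanfield_sca")

RESULT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serializable to/from YAML."""

    input_path: str
    scale: str = "binary"                 # {binary, tristate, continuous}
    structure: str = "random"             # {grid, random, smallworld, auto}
    gamma_size: int = 5
    p_max: float = 0.5
    collapse_with: str = "positive"
    dichotomizer: str = "median"
    missing_mode: str = "locf"
    reversed_items: tuple = ()
    delimiter: str = ","
    missing_marker: str = ""
    participant_col: str = "participant"
    occasion_col: str = "occasion"
    min_T: int = 5
    min_category_share: float = 0.05
    seed: int = 0
    output_dir: str = "results"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "reversed_items" in raw and raw["reversed_items"] is not None:
            raw["reversed_items"] = tuple(raw["reversed_items"])
        return cls(**raw)


def _read_one_csv(path: Path, cfg: PipelineConfig) -> pd.DataFrame:
    df = pd.read_csv(path, sep=cfg.delimiter,
                     na_values=[cfg.missing_marker] if cfg.missing_marker else None,
                     keep_default_na=True)
    if df.isna().all(axis=1).any():
        bad = int(df.isna().all(axis=1).idxmax())
        raise ValueError(f"{path}: row {bad + 2} is entirely unparseable")
    return df


def read_panels(cfg: PipelineConfig) -> list[ItemPanel]:
    """Read item panels from a wide CSV (or a directory of per-participant CSVs).

    A single file may carry a participant column (long-by-participant wide
    format); without it the file is one participant. Occasions are sorted by
    the occasion column when present, otherwise taken in file order.
    """
    panels_or_errors = list(iter_panels(cfg))
    bad = [e for kind, e in panels_or_errors if kind == "error"]
    if bad:
        raise ValueError("; ".join(e["error"] for e in bad))
    return [p for kind, p in panels_or_errors]


def iter_panels(cfg: PipelineConfig):
    """Yield ("ok", panel) or ("error", {participant, error}) per participant."""
    path = Path(cfg.input_path)

    def df_to_panel(df: pd.DataFrame, participant: str) -> ItemPanel:
        df = df.copy()
        if cfg.occasion_col in df.columns:
            df = df.sort_values(cfg.occasion_col)
            df = df.set_index(cfg.occasion_col)
        else:
            df.index = pd.RangeIndex(len(df))
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                try:
                    df[col] = pd.to_numeric(df[col])
                except ValueError as e:
                    raise ValueError(
                        f"participant {participant}: column {col!r} not numeric ({e})"
                    ) from e
        reversed_items = tuple(c for c in cfg.reversed_items if c in df.columns)
        return ItemPanel(participant=participant, data=df, scale=cfg.scale,
                         reversed_items=reversed_items)

    if path.is_dir():
        for f in sorted(path.glob("*.csv")):
            try:
                yield "ok", df_to_panel(_read_one_csv(f, cfg), f.stem)
            except ValueError as e:
                yield "error", {"participant": f.stem, "error": str(e)}
        return
    df = _read_one_csv(path, cfg)
    if cfg.participant_col in df.columns:
        for pid, grp in df.groupby(cfg.participant_col, sort=True):
            try:
                yield "ok", df_to_panel(grp.drop(columns=[cfg.participant_col]),
                                        str(pid))
            except ValueError as e:
                yield "error", {"participant": str(pid), "error": str(e)}
    else:
        yield "ok", df_to_panel(df, path.stem)


def _analyze_participant(panel: ItemPanel, cfg: PipelineConfig) -> dict:
    binary, report, y, rho = preprocess_panel(
        panel, collapse_with=cfg.collapse_with, dichotomizer=cfg.dichotomizer,
        missing=cfg.missing_mode, min_T=cfg.min_T,
        min_category_share=cfg.min_category_share)
    out = {"participant": panel.participant, "preprocess": report.to_dict()}
    if not report.included:
        return out
    if cfg.structure == "auto":
        comparison = inference.select_model(y, binary.n_items,
                                            gamma_size=cfg.gamma_size, p_max=cfg.p_max)
        fit_result = comparison.best
        out["model_comparison"] = {s: f.to_dict() for s, f in comparison.fits.items()}
    else:
        fit_result = inference.fit(y, cfg.structure, binary.n_items,
                                   gamma_size=cfg.gamma_size, p_max=cfg.p_max)
    out["fit"] = fit_result.to_dict()
    cls = classify(fit_result.spec())
    out["classification"] = {
        "p_hat": cls.p_hat, "equilibria": cls.equilibria_at_p_hat,
        "critical_point": cls.critical_point, "verdict": cls.verdict,
    }
    bc = bimodality_coefficient(rho)
    out["bc"] = bc.to_dict()
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full per-participant pipeline; returns the cohort report.

    Participant-level failures are aggregated under ``errors`` and do not
    abort the run. An empty input yields an empty report with a warning.
    """
    items = list(iter_panels(cfg))
    if not items:
        logger.warning("no input panels found at %s", cfg.input_path)
    participants, errors = [], []
    for kind, item in items:
        if kind == "error":
            logger.error("participant %s failed: %s", item["participant"],
                         item["error"])
            errors.append(item)
            continue
        panel = item
        try:
            participants.append(_analyze_participant(panel, cfg))
        except (ValueError, inference.NonConvergenceError) as e:
            logger.error("participant %s failed: %s", panel.participant, e)
            errors.append({"participant": panel.participant, "error": str(e)})

    analyzed = [p for p in participants if "classification" in p]
    verdicts = [int(p["classification"]["verdict"] == "bistable") for p in analyzed]
    bc_flags = [int(p["bc"]["bimodal"]) for p in analyzed]
    cohort: dict = {
        "n_participants": len(items),
        "n_included": len(analyzed),
        "n_excluded": sum(1 for p in participants if "classification" not in p),
        "n_errors": len(errors),
        "share_bistable": float(np.mean(verdicts)) if verdicts else None,
        "share_bc_bimodal": float(np.mean(bc_flags)) if bc_flags else None,
    }
    if verdicts:
        p_o, kappa = agreement(verdicts, bc_flags)
        cohort["verdict_bc_agreement"] = p_o
        cohort["verdict_bc_kappa"] = kappa
    return {
        "schema_version": RESULT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "participants": participants,
        "errors": errors,
        "cohort": cohort,
    }


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_results(report: dict, path) -> None:
    """Deterministic JSON: sorted keys, floats at 12 significant digits."""
    with open(path, "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True, default=float)


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
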