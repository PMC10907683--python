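"""Configuration-driven end-to-end pipeline.

Wires the computational stages in order — keyboard features, accelerometer
features, ICA of the self-report panel, modality alignment, and the
per-component mixed-effects fusion — recording row counts at every filter
so attrition is fully accounted for, and writing every intermediate
artifact plus a provenance log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import accel as accel_mod
from . import keyboard as keyboard_mod
from .fusion import (
    FIXED_TERMS,
    CorrectionSpec,
    align_modalities,
    enforce_week_identifiability,
    fit_component_model,
    forward_fit_random_effects,
    model_diagnostics,
)
from .ica import fit_ica, prepare_panel, restart_stability

logger = logging.getLogger("phenofuse")

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_frames", "validate_inputs"]


@dataclass
class PipelineConfig:
    """All pipeline knobs with their standard defaults.

    Defaults are the pipeline's published constants: 6 s session
    inactivity, 750-press daily volume filter, order-2 Butterworth at 4 Hz,
    [0.95, 1.05] g stationary band, 8% active-session rule, upright
    z < 0.1 / |x| <= 0.2, FastICA with logcosh (a1 = 1).
    """

    keypresses_csv: str = "keypresses.csv"
    accel_csv: str = "accel.csv"
    selfreport_csv: str = "selfreport.csv"
    output_dir: str = "output"
    q: int = 5
    inactivity_threshold_s: float = 6.0
    volume_threshold: int = 750
    sampling_rate_hz: float = 10.0
    cutoff_hz: float = 4.0
    filter_order: int = 2
    ica_seed: int = 0
    ica_tol: float = 1e-6
    ica_max_iter: int = 200
    stability_restarts: int = 0  # 0 disables the restart-stability report
    week_policy: str = "first-retained-day"  # 7-day blocks from first retained day
    identifiability_policy: str = "drop-week"
    fitting_method: str = "REML"
    forward_fit: bool = True  # forwards-fit the random-effects structure
    diagnostics: bool = True  # emit QQ/residual diagnostic tables

    def validate(self) -> None:
        for name in (
            "inactivity_threshold_s",
            "volume_threshold",
            "sampling_rate_hz",
            "cutoff_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.q < 1:
            raise ValueError("q must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def validate_inputs(
    keypresses: pd.DataFrame,
    accel: pd.DataFrame,
    selfreport: pd.DataFrame,
) -> dict:
    """Schema/positivity/duplicate checks on the three input tables.

    Returns ``{"errors": [...], "warnings": [...]}``; callers treat any
    error as fatal.
    """
    errors, warns = [], []
    kp_req = {"participant_id", "timestamp", "date", "key_class"}
    missing = kp_req - set(keypresses.columns)
    if missing:
        errors.append(f"keypresses: missing columns {sorted(missing)}")
    else:
        bad = set(keypresses["key_class"].unique()) - set(keyboard_mod.KEY_CLASSES)
        if bad:
            errors.append(f"keypresses: unknown key_class values {sorted(bad)}")
        extra = set(keypresses.columns) - kp_req - {"keyboard_dismissed", "session_index"}
        if extra:
            warns.append(f"keypresses: ignoring extra columns {sorted(extra)}")
    ac_req = {"participant_id", "session_index", "date", "x", "y", "z"}
    missing = ac_req - set(accel.columns)
    if missing:
        errors.append(f"accel: missing columns {sorted(missing)}")
    else:
        for c in ("x", "y", "z"):
            if not np.isfinite(accel[c].to_numpy(dtype=float)).all():
                errors.append(f"accel: non-finite values in {c}")
    sr_req = {"participant_id", "date"}
    missing = sr_req - set(selfreport.columns)
    if missing:
        errors.append(f"selfreport: missing columns {sorted(missing)}")
    else:
        dup = selfreport.duplicated(subset=["participant_id", "date"])
        if dup.any():
            row = selfreport[dup].iloc[0]
            errors.append(
                "selfreport: duplicate (participant, date) "
                f"({row['participant_id']}, {row['date']})"
            )
        items = [c for c in selfreport.columns if c not in sr_req]
        if not items:
            errors.append("selfreport: no item columns")
        for item in items:
            vals = selfreport[item].dropna()
            if (vals <= 0).any():
                errors.append(
                    f"selfreport: non-positive value in {item} "
                    "(Likert items must be >= 1 for the log transform)"
                )
                break
    return {"errors": errors, "warnings": warns}


def run_pipeline(config: PipelineConfig) -> dict:
    """Read the input CSVs and run the full analysis; write all artifacts."""
    config.validate()
    keypresses = pd.read_csv(config.keypresses_csv)
    accel = pd.read_csv(config.accel_csv)
    selfreport = pd.read_csv(config.selfreport_csv)
    return run_pipeline_frames(keypresses, accel, selfreport, config)


def run_pipeline_frames(
    keypresses: pd.DataFrame,
    accel: pd.DataFrame,
    selfreport: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
    write: bool = True,
) -> dict:
    """Run the pipeline on in-memory tables.

    Stages: keyboard daily features -> accelerometer daily rates -> panel
    ICA -> complete-case alignment -> feature standardization -> one nested
    mixed-effects model per component with family-wise Bonferroni
    correction -> diagnostics. Returns every intermediate plus a provenance
    record; with ``write=True`` all artifacts land in ``config.output_dir``.
    """
    config = config or PipelineConfig()
    config.validate()
    provenance: dict = {
        "phenofuse_version": __version__,
        "config": asdict(config),
        "attrition": {},
    }
    report = validate_inputs(keypresses, accel, selfreport)
    if report["errors"]:
        raise ValueError("input validation failed: " + "; ".join(report["errors"]))
    for w in report["warnings"]:
        logger.warning(w)

    def _stage(name):
        logger.info("stage: %s", name)

    _stage("keyboard")
    daily_kb = keyboard_mod.daily_keyboard_from_frame(
        keypresses,
        inactivity_threshold=config.inactivity_threshold_s,
        volume_threshold=config.volume_threshold,
    )
    provenance["attrition"]["keyboard_days_total"] = int(len(daily_kb))
    provenance["attrition"]["keyboard_days_included"] = int(daily_kb["included"].sum())

    _stage("accel")
    daily_ac = accel_mod.daily_accel_from_frame(
        accel,
        sampling_rate=config.sampling_rate_hz,
        cutoff=config.cutoff_hz,
        order=config.filter_order,
    )
    provenance["attrition"]["accel_days"] = int(len(daily_ac))

    _stage("ica")
    selfreport = selfreport.copy()
    selfreport["date"] = pd.to_datetime(selfreport["date"])
    conc = prepare_panel(selfreport)
    provenance["attrition"]["selfreport_days"] = int(conc.n)
    dec = fit_ica(
        conc,
        q=config.q,
        seed=config.ica_seed,
        tol=config.ica_tol,
        max_iter=config.ica_max_iter,
    )
    provenance["ica"] = dict(dec.meta)
    sources = conc.index_map.copy()
    for c in range(config.q):
        sources[f"IC_{c + 1}"] = dec.S[c]
    stability = None
    if config.stability_restarts >= 2:
        stability = restart_stability(
            conc, config.q, n_restarts=config.stability_restarts,
            base_seed=config.ica_seed, tol=config.ica_tol,
            max_iter=config.ica_max_iter,
        )
        provenance["ica"]["stability_clusters"] = stability.cluster_sizes()

    _stage("align")
    daily_kb = daily_kb.copy()
    daily_ac = daily_ac.copy()
    daily_kb["date"] = pd.to_datetime(daily_kb["date"])
    daily_ac["date"] = pd.to_datetime(daily_ac["date"])
    aligned = align_modalities(daily_kb, daily_ac, sources)
    provenance["attrition"]["aligned_days"] = int(len(aligned))
    aligned, exclusions = enforce_week_identifiability(
        aligned, policy=config.identifiability_policy
    )
    provenance["attrition"]["aligned_days_identifiable"] = int(len(aligned))
    provenance["attrition"]["excluded_units"] = int(len(exclusions))

    _stage("standardize")
    aligned_std, std_params = keyboard_mod.transform_and_standardize(
        aligned, features=FIXED_TERMS
    )

    _stage("fusion")
    spec = CorrectionSpec(n_ic=config.q)
    provenance["bonferroni_cf"] = spec.cf
    fits, lrt_tables, diagnostics = {}, {}, {}
    for c in range(config.q):
        comp = f"IC_{c + 1}"
        if config.forward_fit:
            lrt, _ = forward_fit_random_effects(aligned_std, comp)
            lrt_tables[comp] = lrt
        fit = fit_component_model(
            aligned_std, comp, method=config.fitting_method, correction=spec
        )
        fits[comp] = fit
        if config.diagnostics:
            diagnostics[comp] = model_diagnostics(fit, aligned_std)

    estimates = _estimates_table(fits)
    result = {
        "daily_keyboard": daily_kb,
        "daily_accel": daily_ac,
        "decomposition": dec,
        "sources": sources,
        "stability": stability,
        "aligned": aligned_std,
        "standardization": std_params,
        "exclusion_log": exclusions,
        "fits": fits,
        "lrt_tables": lrt_tables,
        "diagnostics": diagnostics,
        "model_estimates": estimates,
        "provenance": provenance,
        "items": conc.items,
    }
    if write:
        _write_outputs(result, config)
    return result


def _estimates_table(fits: dict) -> pd.DataFrame:
    rows = []
    for comp, fit in fits.items():
        frame = fit.summary_frame().reset_index()
        frame.insert(0, "component", comp)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def _write_outputs(result: dict, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["daily_keyboard"].to_csv(out / "daily_keyboard.csv", index=False)
    result["daily_accel"].to_csv(out / "daily_accel.csv", index=False)
    dec = result["decomposition"]
    pd.DataFrame(
        dec.A,
        index=result["items"],
        columns=[f"IC_{c + 1}" for c in range(dec.q)],
    ).rename_axis("item").to_csv(out / "mixing_matrix.csv")
    result["sources"].to_csv(out / "sources.csv", index=False)
    result["model_estimates"].to_csv(out / "model_estimates.csv", index=False)
    random_effects = {
        comp: {
            "sigma1_sq": fit.sigma1_sq,
            "sigma2_sq": fit.sigma2_sq,
            "sigma_sq": fit.sigma_sq,
            "loglike": fit.loglike,
            "lrt_table": (
                result["lrt_tables"][comp].to_dict(orient="records")
                if comp in result["lrt_tables"]
                else None
            ),
        }
        for comp, fit in result["fits"].items()
    }
    with open(out / "random_effects.json", "w") as fh:
        json.dump(random_effects, fh, indent=2)
    if result["stability"] is not None:
        rep = result["stability"]
        with open(out / "stability_report.json", "w") as fh:
            json.dump(
                {
                    "n_restarts": rep.n_restarts,
                    "n_converged": rep.n_converged,
                    "failed_seeds": rep.failed_seeds,
                    "cluster_sizes": {str(k): v for k, v in rep.cluster_sizes().items()},
                    "cluster_tightness": {
                        str(k): v for k, v in rep.cluster_tightness.items()
                    },
                },
                fh,
                indent=2,
            )
    with open(out / "provenance.json", "w") as fh:
        json.dump(result["provenance"], fh, indent=2, default=str)
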