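"""Dataset parsing, run configuration, and the end-to-end pipeline.

Trial files are one CSV per trial (``gait_pct,angle_rad,moment_Nm``) named
``<subject>_<speed>.csv`` next to a ``cohort.json`` of subject records. The
pipeline composes the package in order: simulate (or read) → segment →
summarize → PLS cross-validate → stepwise fit → stature reduction → report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import mechanics, models, segmentation, stature, synth
from .types import DomainError, GaitTrial, JointSummary, SubjectProfile

logger = logging.getLogger("anklemech")


class ParseError(DomainError):
    """Malformed dataset file."""


# ---------------------------------------------------------------------------
# Reading datasets
# ---------------------------------------------------------------------------


def read_cohort(path: Path) -> list[SubjectProfile]:
    records = json.loads(path.read_text())
    cohort = []
    for i, r in enumerate(records):
        try:
            cohort.append(
                SubjectProfile(
                    subject_id=r["subject_id"],
                    weight=float(r["weight_kg"]),
                    height=float(r["height_m"]),
                    preferred_speed=float(
                        r.get("preferred_speed_mps")
                        or stature.optimal_speed(float(r["height_m"]))
                    ),
                    singular_speed=float(
                        r.get("singular_speed_mps")
                        or 1.25
                        * (
                            r.get("preferred_speed_mps")
                            or stature.optimal_speed(float(r["height_m"]))
                        )
                    ),
                )
            )
        except (KeyError, DomainError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: record {i}: {exc}") from exc
    return cohort


def read_trial_csv(path: Path, subject_id: str, speed: float) -> GaitTrial:
    df = pd.read_csv(path)
    required = ["gait_pct", "angle_rad", "moment_Nm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    pct = df["gait_pct"].to_numpy(dtype=float)
    bad = np.where(np.diff(pct) <= 0)[0]
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based
        raise ParseError(
            f"{path}: gait_pct not strictly increasing at line {int(bad[0]) + 3}"
        )
    try:
        return GaitTrial(
            subject_id=subject_id,
            speed=speed,
            gait_pct=pct,
            angle=df["angle_rad"].to_numpy(dtype=float),
            moment=df["moment_Nm"].to_numpy(dtype=float),
        )
    except DomainError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_trials(path: str | Path) -> tuple[list[SubjectProfile], list[GaitTrial]]:
    """Read a dataset directory written by :func:`anklemech.synth.emit_dataset`."""
    root = Path(path)
    cohort_path = root / "cohort.json"
    if not cohort_path.exists():
        raise ParseError(f"missing cohort file {cohort_path}")
    cohort = read_cohort(cohort_path)
    known = {s.subject_id for s in cohort}
    trials = []
    for csv_path in sorted(root.glob("*.csv")):
        stem = csv_path.stem
        try:
            sid, speed_str = stem.rsplit("_", 1)
            speed = float(speed_str)
        except ValueError as exc:
            raise ParseError(
                f"{csv_path}: filename must be <subject>_<speed>.csv"
            ) from exc
        if sid not in known:
            raise ParseError(f"{csv_path}: unknown subject id {sid!r}")
        trials.append(read_trial_csv(csv_path, sid, speed))
    if not trials:
        logger.warning("no trial CSV files found under %s", root)
    return cohort, trials


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (all noise/threshold knobs)."""

    seed: int = 0
    n_subjects: int = 26
    noise_sd: float | tuple = synth.DEFAULT_NOISE_SD
    n_samples: int = 131
    c_pct: float = 30.0
    alpha: float = 0.05
    outlier_threshold: float = 3.0
    froude_opt: float = stature.FROUDE_OPT
    leg_coeff: float = stature.LEG_COEFF
    g: float = 9.81
    data_dir: str | None = None  # read instead of simulate when set
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.noise_sd, list):
            cfg.noise_sd = tuple(cfg.noise_sd)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if isinstance(d["noise_sd"], tuple):
            d["noise_sd"] = list(d["noise_sd"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def summarize_trials(
    trials: Sequence[GaitTrial], c_pct: float = 30.0
) -> list[JointSummary]:
    """Segment and summarize every trial, logging failures by stage."""
    out = []
    for t in trials:
        try:
            lm = segmentation.locate_landmarks(t, c_pct=c_pct)
            out.append(mechanics.summarize_trial(t, lm))
        except DomainError as exc:
            logger.warning(
                "dropping trial %s @ %.3f m/s: %s", t.subject_id, t.speed, exc
            )
    return out


def summaries_frame(summaries: Sequence[JointSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the report dictionary.

    The report carries a per-trial summary table, one model card per
    response (general-form fit + PLS-CV metrics), the stature-based
    reductions, and the error-comparison table (general-form vs
    stature-based vs cohort-average baseline). Deterministic for a fixed
    seed; written as JSON/CSV when ``config.out_dir`` is set.
    """
    if config.data_dir is not None:
        cohort, trials = read_trials(config.data_dir)
    else:
        cohort, _truths, trials = synth.simulate_study(
            config.seed,
            n_subjects=config.n_subjects,
            noise_sd=config.noise_sd,
            n_samples=config.n_samples,
        )
    summaries = summarize_trials(trials, c_pct=config.c_pct)
    if not summaries:
        raise DomainError("pipeline stage 'summarize': no usable trials")
    sf = summaries_frame(summaries)

    preferred = stature.nearest_preferred_trials(
        summaries, cohort, config.froude_opt, config.leg_coeff, config.g
    )
    mean_exc = stature.mean_excursions_at_preferred(preferred)
    subjects = {s.subject_id: s for s in cohort}

    model_cards: dict[str, dict] = {}
    stature_cards: dict[str, dict] = {}
    error_rows = []
    for response in models.RESPONSES:
        try:
            model, X, y, _groups = models.fit_response(
                summaries,
                cohort,
                response=response,
                alpha=config.alpha,
                outlier_threshold=config.outlier_threshold,
            )
        except DomainError as exc:
            raise DomainError(f"pipeline stage 'fit:{response}': {exc}") from exc
        model_cards[response] = model.to_dict()

        smodel = stature.reduce_model(
            model, mean_exc, config.froude_opt, config.leg_coeff, config.g
        )
        stature_cards[response] = smodel.to_dict()

        # error comparison: general-form and baseline over all usable rows
        # (excluding regression outliers); stature-based over the one
        # preferred-speed trial per subject.
        exclude = model.outlier_ids
        general_err = model.mean_pct_error
        baseline = models.baseline_mean_model(y)
        baseline_err = models.mean_pct_error(y, baseline.predict(X), exclude=exclude)
        pref_rows = [
            s
            for s in preferred.values()
            if not (response == "K_dl" and s.singular)
            and np.isfinite(models._summary_response(s, response))
        ]
        st_true = [models._summary_response(s, response) for s in pref_rows]
        st_pred = [
            smodel.predict(subjects[s.subject_id].weight, subjects[s.subject_id].height)
            for s in pref_rows
        ]
        stature_err = models.mean_pct_error(st_true, st_pred)
        error_rows.append(
            {
                "response": response,
                "general_form_pct": general_err,
                "stature_based_pct": stature_err,
                "average_value_pct": baseline_err,
            }
        )

    report = {
        "config": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
            }
        },
        "n_subjects": len(cohort),
        "n_trials": len(trials),
        "n_summaries": len(summaries),
        "cohort_means": {
            "K_df_Nm_per_rad": float(sf["K_df"].mean()),
            "K_dl_Nm_per_rad": float(sf.loc[~sf["singular"], "K_dl"].mean()),
            "K_pf_Nm_per_rad": float(sf["K_pf"].mean()),
            "E_loop_J": float(sf["E_loop"].mean()),
            "r2_df_pct": float(100 * sf["r2_df"].mean()),
            "r2_dl_pct": float(100 * sf["r2_dl"].dropna().mean()),
            "r2_pf_pct": float(100 * sf["r2_pf"].mean()),
            "speed_mps": float(sf["speed"].mean()),
        },
        "mean_excursions_at_preferred_rad": {
            "df": mean_exc.df,
            "dl_signed": mean_exc.dl_signed,
            "pf": mean_exc.pf,
        },
        "general_form_models": model_cards,
        "stature_based_models": stature_cards,
        "error_comparison": error_rows,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        sf.to_csv(out / "trial_summaries.csv", index=False)
        (out / "report.md").write_text(render_report_md(report))
    return report


def render_report_md(report: dict) -> str:
    """Human-readable digest of a pipeline report."""
    lines = [
        "# Ankle quasi-stiffness pipeline report",
        "",
        f"Subjects: {report['n_subjects']}; trials: {report['n_trials']}; "
        f"summarized: {report['n_summaries']} (seed {report['config']['seed']})",
        "",
        "## Cohort means",
        "",
        "| quantity | value |",
        "|---|---|",
    ]
    for k, v in report["cohort_means"].items():
        lines.append(f"| {k} | {v:.2f} |")
    lines += [
        "",
        "## General-form models",
        "",
        "| response | #terms | PLS-CV comps | PLS R^2 | predicted R^2 | OLS R^2 | error |",
        "|---|---|---|---|---|---|---|",
    ]
    for resp, card in report["general_form_models"].items():
        lines.append(
            f"| {resp} | {len(card['coefficients'])} | {card['n_components_cv']} | "
            f"{card['pls_r2_pct']:.1f}% | {card['pls_predicted_r2_pct']:.1f}% | "
            f"{card['ols_r2_pct']:.1f}% | {card['mean_pct_error']:.1f}% |"
        )
    lines += [
        "",
        "## Stature-based models (valid at the preferred speed)",
        "",
        "| response | formula | low confidence |",
        "|---|---|---|",
    ]
    for resp, card in report["stature_based_models"].items():
        lines.append(
            f"| {resp} | {card['formula']} | {card['low_confidence']} |"
        )
    lines += [
        "",
        "## Mean percent error by model family",
        "",
        "| response | general-form | stature-based | average-value |",
        "|---|---|---|---|",
    ]
    for row in report["error_comparison"]:
        lines.append(
            f"| {row['response']} | {row['general_form_pct']:.1f}% | "
            f"{row['stature_based_pct']:.1f}% | {row['average_value_pct']:.1f}% |"
        )
    lines.append("")
    return "\n".join(lines)
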