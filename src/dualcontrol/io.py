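"""Reading and writing the package's plain-text formats.

All trial logs are UTF-8 tab-separated files with Unix newlines; parameters
and manifests are flat YAML, fits and reports JSON.  Formats:

* two-step trial log: subject_id, trial, a1, s2, a2, reward, transition
* reward walk: four probability columns p00, p01, p10, p11 ((state, action))
* devaluation trial log: subject_id, phase, trial, condition, choice, outcome,
  with a YAML sidecar carrying the devalued-condition identity
* scores table: subject_id, deval_score, mb_score, omega_map
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import ScorePair
from .cohort import Cohort, CohortConfig
from .devaluation import DevalDesign, DevalSession, DevalTrial
from .errors import ValidationError
from .hybrid import PARAM_NAMES, HybridParams
from .twostep import COMMON, RewardWalk, TransitionStructure, TwoStepSession

TWOSTEP_COLUMNS = ["subject_id", "trial", "a1", "s2", "a2", "reward", "transition"]
DEVAL_COLUMNS = ["subject_id", "phase", "trial", "condition", "choice", "outcome"]
WALK_COLUMNS = ["p00", "p01", "p10", "p11"]


# -- two-step trial logs -----------------------------------------------------

def twostep_frame(sessions: list[TwoStepSession]) -> pd.DataFrame:
    rows = [
        (s.subject_id, tr.t, tr.a1, tr.s2, tr.a2, tr.r, tr.transition)
        for s in sessions
        for tr in s.trials
    ]
    return pd.DataFrame(rows, columns=TWOSTEP_COLUMNS)


def write_twostep_tsv(sessions: TwoStepSession | list[TwoStepSession], path) -> None:
    if isinstance(sessions, TwoStepSession):
        sessions = [sessions]
    twostep_frame(sessions).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _infer_structure(df: pd.DataFrame, p_common: float = 0.7) -> TransitionStructure:
    common_map = [None, None]
    for a1, s2 in df.loc[df["transition"] == COMMON, ["a1", "s2"]].itertuples(index=False):
        if common_map[a1] is None:
            common_map[a1] = int(s2)
        elif common_map[a1] != s2:
            raise ValidationError("inconsistent transition labels in trial log")
    if common_map[0] is None and common_map[1] is not None:
        common_map[0] = 1 - common_map[1]
    if common_map[1] is None and common_map[0] is not None:
        common_map[1] = 1 - common_map[0]
    if None in common_map:
        raise ValidationError("cannot infer transition structure: no common trials")
    return TransitionStructure(common_map=(common_map[0], common_map[1]), p_common=p_common)


def read_twostep_tsv(path, structure: TransitionStructure | None = None) -> list[TwoStepSession]:
    """Read a trial log; the transition structure is inferred from the
    common-trial labels when not supplied."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse trial log ({exc})") from exc
    missing = set(TWOSTEP_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if structure is None:
        structure = _infer_structure(df)
    sessions = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("trial")
        sessions.append(
            TwoStepSession.from_arrays(
                str(sid),
                grp["a1"].to_numpy(),
                grp["s2"].to_numpy(),
                grp["a2"].to_numpy(),
                grp["reward"].to_numpy(),
                structure=structure,
            )
        )
    return sessions


# -- reward walks ------------------------------------------------------------

def write_walk_tsv(walk: RewardWalk, path) -> None:
    pd.DataFrame(walk.probs, columns=WALK_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n", float_format="%.10g"
    )


def read_walk_tsv(path, sd_innovation: float = 0.025,
                  bounds: tuple[float, float] = (0.25, 0.75)) -> RewardWalk:
    df = pd.read_csv(path, sep="\t")
    return RewardWalk(probs=df[WALK_COLUMNS].to_numpy(), sd_innovation=sd_innovation, bounds=bounds)


# -- devaluation trial logs --------------------------------------------------

def deval_frame(sessions: list[DevalSession]) -> pd.DataFrame:
    rows = [
        (s.subject_id, tr.phase, tr.t, tr.condition, tr.choice, tr.outcome)
        for s in sessions
        for tr in s.trials
    ]
    return pd.DataFrame(rows, columns=DEVAL_COLUMNS)


def write_deval_tsv(sessions: DevalSession | list[DevalSession], path,
                    meta_path=None) -> None:
    if isinstance(sessions, DevalSession):
        sessions = [sessions]
    deval_frame(sessions).to_csv(path, sep="\t", index=False, lineterminator="\n")
    if meta_path is not None:
        meta = {s.subject_id: {"devalued_condition": s.devalued_condition} for s in sessions}
        with open(meta_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh)


def read_deval_tsv(path, meta_path=None, design: DevalDesign | None = None) -> list[DevalSession]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse trial log ({exc})") from exc
    missing = set(DEVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    meta = {}
    if meta_path is not None and Path(meta_path).exists():
        with open(meta_path, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}
    design = design if design is not None else DevalDesign()
    sessions = []
    for sid, grp in df.groupby("subject_id", sort=False):
        trials = [
            DevalTrial(t=int(row.trial), phase=str(row.phase), condition=str(row.condition),
                       choice=str(row.choice), outcome=str(row.outcome))
            for row in grp.itertuples(index=False)
        ]
        devalued = meta.get(str(sid), {}).get("devalued_condition", "unknown")
        sessions.append(
            DevalSession(subject_id=str(sid), devalued_condition=devalued,
                         trials=trials, design=design)
        )
    return sessions


# -- parameters --------------------------------------------------------------

def save_params_yaml(params: HybridParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_params_yaml(path) -> HybridParams:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    missing = set(PARAM_NAMES) - set(d)
    if missing:
        raise ValidationError(f"{path}: missing parameters {sorted(missing)}")
    return HybridParams(**{k: float(d[k]) for k in PARAM_NAMES})


# -- scores and reports ------------------------------------------------------

def write_scores_tsv(scores: list[ScorePair], path) -> None:
    df = pd.DataFrame(
        [
            {"subject_id": s.subject_id, "deval_score": s.deval_score,
             "mb_score": s.mb_score,
             "omega_map": "" if s.omega_map is None else s.omega_map}
            for s in scores
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_report_json(report_dict: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_dict, fh, indent=2)


# -- cohort directories ------------------------------------------------------

def config_hash(config: CohortConfig) -> str:
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(path, config: CohortConfig, extra: dict | None = None) -> None:
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort as a directory: per-subject TSVs, manifest, true parameters."""
    out = Path(out_dir)
    (out / "twostep").mkdir(parents=True, exist_ok=True)
    (out / "deval").mkdir(parents=True, exist_ok=True)
    for sub in cohort.subjects:
        write_twostep_tsv(sub.twostep, out / "twostep" / f"{sub.subject_id}.tsv")
        write_deval_tsv(
            sub.deval,
            out / "deval" / f"{sub.subject_id}.tsv",
            meta_path=out / "deval" / f"{sub.subject_id}.meta.yaml",
        )
    rows = [
        {"subject_id": s.subject_id, "trait": s.trait, "w": s.dual_params.w,
         "included": s.included, **s.hybrid_params.to_dict()}
        for s in cohort.subjects
    ]
    pd.DataFrame(rows).to_csv(out / "true_params.tsv", sep="\t", index=False, lineterminator="\n")
    write_manifest(
        out / "manifest.yaml",
        cohort.config,
        extra={"excluded_ids": cohort.excluded_ids},
    )


def read_cohort_sessions(cohort_dir) -> tuple[list[TwoStepSession], list[DevalSession], dict]:
    """Read back the trial logs of a cohort directory (manifest + TSVs)."""
    out = Path(cohort_dir)
    manifest_path = out / "manifest.yaml"
    if not manifest_path.exists():
        raise ValidationError(f"{cohort_dir}: no manifest.yaml (not a cohort directory)")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    p_common = manifest.get("config", {}).get("p_common", 0.7)
    twostep_files = sorted((out / "twostep").glob("*.tsv"))
    deval_files = sorted(p for p in (out / "deval").glob("*.tsv"))
    if not twostep_files or not deval_files:
        raise ValidationError(f"{cohort_dir}: empty cohort directory")
    two = []
    for f in twostep_files:
        sessions = read_twostep_tsv(f)
        for s in sessions:
            s.structure = TransitionStructure(s.structure.common_map, p_common)
        two.extend(sessions)
    dev = []
    for f in deval_files:
        dev.extend(read_deval_tsv(f, meta_path=f.with_suffix("").with_suffix(".meta.yaml")))
    return two, dev, manifest
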