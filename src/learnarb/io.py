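"""Readers, writers, configuration, seeding and the pipeline driver.

Session CSVs use one row per trial with a schema-version header comment;
configurations are YAML mirrors of :class:`~learnarb.task.TaskConfig`;
every pipeline run emits a JSON manifest (config snapshot, package version,
seeds, input hashes, stage timings and warnings) sufficient to reproduce
its deterministic outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .session import SESSION_COLUMNS, Session
from .task import TaskConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMA_VERSION", "write_session_csv", "read_sessions",
    "load_config", "save_config", "RunManifest", "spawn_seeds",
    "run_pipeline",
]

SCHEMA_VERSION = "learnarb-csv v1"

#: fraction of missing choices above which a session is flagged (the
#: deposited studies excluded participants missing more than 25% of trials;
#: the reader flags but does not enforce this)
MISSING_FLAG_THRESHOLD = 0.25


def spawn_seeds(seed: int, n: int) -> List[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# session CSV dialect
# ---------------------------------------------------------------------------

def write_session_csv(session: Session, path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION} session subject={session.subject_id}\n")
        session.trials[SESSION_COLUMNS].to_csv(fh, index=False,
                                               float_format="%.12g")
    return path


def _validate_session_df(df: pd.DataFrame, origin: str) -> None:
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{origin}: missing columns {missing}")
    for i, row in df.iterrows():
        line = i + 2  # header line + 1-based
        if row["observed_token"] not in ("orange", "blue"):
            raise ValueError(f"{origin} row {line}: bad token label "
                             f"{row['observed_token']!r}")
        if row["choice"] not in ("orange", "blue", ""):
            raise ValueError(f"{origin} row {line}: bad choice label "
                             f"{row['choice']!r}")
        if row["partner_box"] not in ("A", "B"):
            raise ValueError(f"{origin} row {line}: bad box label")
        if not 0 <= int(row["outcome"]) <= 99:
            raise ValueError(f"{origin} row {line}: outcome "
                             f"{row['outcome']} outside [0, 99]")
        if not 0.0 < float(row["trans_prob"]) < 1.0:
            raise ValueError(f"{origin} row {line}: transition probability "
                             "outside (0, 1)")


def read_sessions(path: Union[str, Path],
                  column_map: Optional[Dict[str, str]] = None) -> List[Session]:
    """Read one session CSV or a directory of them, with validation.

    ``column_map`` renames foreign column headers onto the native dialect,
    so externally deposited trial tables can be ingested without code
    changes.  Sessions missing more than 25% of choices load with a flag.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no session CSVs under {path}")
    sessions = []
    for f in files:
        df = pd.read_csv(f, comment="#", keep_default_na=False,
                         dtype={"choice": str})
        if column_map:
            df = df.rename(columns=column_map)
        _validate_session_df(df, f.name)
        s = Session(df, subject_id=f.stem)
        if s.missing_fraction > MISSING_FLAG_THRESHOLD:
            s.flags.append(
                f"missing {s.missing_fraction:.0%} of choices "
                f"(> {MISSING_FLAG_THRESHOLD:.0%} exclusion threshold)")
            logger.warning("%s: %s", f.name, s.flags[-1])
        sessions.append(s)
    return sessions


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def save_config(config: TaskConfig, path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"task": dataclasses.asdict(config)}, fh,
                       sort_keys=False)
    return path


def load_config(path: Union[str, Path]) -> TaskConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    section = raw.get("task", raw)
    fields = {f.name for f in dataclasses.fields(TaskConfig)}
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {k: tuple(v) if isinstance(v, list) else v
              for k, v in section.items()}
    return TaskConfig(**kwargs)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record emitted by every pipeline run."""

    config: dict
    package_version: str = _pkg_version
    seed: int = 0
    input_hashes: Dict[str, str] = field(default_factory=dict)
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    outputs: List[str] = field(default_factory=list)

    def write(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        return path


def file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: TaskConfig, out_dir: Union[str, Path],
                 model_mix: Dict[str, int], seed: int = 0,
                 with_oos: bool = False,
                 fit_models: Optional[Sequence[str]] = None) -> RunManifest:
    """Simulate a cohort, fit and classify it, and extract signatures.

    Writes per-subject session CSVs, a fit table, the cohort comparison
    (responsibilities, frequencies, exceedance, group labels), the
    signature report, and a manifest, under ``out_dir``.
    """
    from .fitting import FitConfig, cohort_compare, fit_cohort
    from .recovery import default_param_sampler
    from .signatures import signature_report

    if sum(model_mix.values()) <= 0:
        raise ValueError("pipeline requires at least one subject")
    out = Path(out_dir)
    (out / "sessions").mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), seed=seed)

    t0 = time.perf_counter()
    rng = np.random.default_rng([seed, 11])
    sessions = generate_cohort(config, model_mix, default_param_sampler, rng)
    for s in sessions:
        p = write_session_csv(s, out / "sessions" / f"{s.subject_id}.csv")
        manifest.input_hashes[p.name] = file_sha256(p)
    manifest.stage_seconds["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fits = fit_cohort(sessions, models=fit_models, config=FitConfig(),
                      seed=seed, with_oos=with_oos)
    fits.to_csv(out / "fits.csv", index=False)
    manifest.stage_seconds["fit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    lme = fits.pivot(index="subject_id", columns="model",
                     values="log_evidence")
    comp = cohort_compare(lme, seed=seed)
    comparison = comp.responsibilities.copy()
    comparison["group"] = comp.groups
    comparison.to_csv(out / "comparison.csv")
    pd.DataFrame({"frequency": comp.frequencies,
                  "exceedance": comp.exceedance}).to_csv(out / "bms.csv")
    manifest.stage_seconds["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = signature_report(sessions)
    report.to_csv(out / "signatures.csv", index=False)
    manifest.stage_seconds["signatures"] = time.perf_counter() - t0

    manifest.outputs = sorted(p.name for p in out.glob("*.csv"))
    manifest.write(out / "manifest.json")
    return manifest
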