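"""File readers/writers, run configuration and the end-to-end pipeline.

All interchange files are comma-delimited UTF-8 text with a header row and
'.' decimal separator. LFP files carry a time column ``t_s`` (seconds,
uniform step) followed by one voltage column per channel (microvolts);
trajectory files carry ``t_s, x_cm, y_cm``. Numeric output is serialised at
full double precision.

``run_pipeline`` chains simulate -> preprocess -> behaviour -> PAC -> stats
for a synthetic two-group study and writes per-trial MI tables, behaviour
summaries, group statistics, MI time courses and a manifest with content
hashes, so an identical configuration and seed reproduces identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import (
    ArenaSpec,
    Trajectory,
    align_lfp_to_trials,
    behavior_summary,
    extract_trials,
)
from .core import ConfigError, FormatError, TimeSeries
from .pac import comodulogram, mi_timecourse, zone_mi
from .preprocess import preprocess_chain
from .stats import anova_two_way, ttest_independent
from .synth import gen_group_dataset

__all__ = [
    "SCHEMA_VERSION",
    "read_timeseries",
    "write_timeseries",
    "read_trajectory",
    "write_trajectory",
    "write_session",
    "RunConfig",
    "RunManifest",
    "run_pipeline",
]

SCHEMA_VERSION = 1
_REL_TOL = 1e-6

log = logging.getLogger("pacfield")


def _region_for(name: str) -> str:
    low = name.lower()
    if "mpfc" in low or "pfc" in low:
        return "mPFC"
    if "bla" in low or "amyg" in low:
        return "BLA"
    return "other"


def read_timeseries(
    path: str | Path, fs_override: float | None = None
) -> dict[str, TimeSeries]:
    """Read a delimited LFP file into one TimeSeries per channel column.

    The first column is time in seconds and must step uniformly within a
    relative tolerance of 1e-6; otherwise a :class:`FormatError` names the
    first offending row (1-based, counting the header as row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse as delimited text: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus at least one channel")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(np.argmax(coerced.isna().to_numpy())) + 2  # header is row 1
            raise FormatError(
                f"{path}: non-numeric or missing cell in column {col!r}, row {row}"
            )
        df[col] = coerced
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 rows")
    dt = np.diff(t)
    dt0 = dt[0]
    if dt0 <= 0:
        raise FormatError(f"{path}: time not increasing at row 3")
    bad = np.abs(dt - dt0) > _REL_TOL * abs(dt0)
    if np.any(bad):
        row = int(np.argmax(bad)) + 3  # +2 header/0-base, +1 second element of diff
        raise FormatError(
            f"{path}: non-uniform sampling first detected at row {row} "
            f"(step {dt[row - 3]:.9g} s vs {dt0:.9g} s)"
        )
    fs = fs_override if fs_override is not None else 1.0 / dt0
    return {
        col: TimeSeries(
            df[col].to_numpy(dtype=float), fs, t0=float(t[0]), region=_region_for(col)
        )
        for col in df.columns[1:]
    }


def write_timeseries(path: str | Path, channels: dict[str, TimeSeries]) -> Path:
    """Write channels sharing a time base to a delimited file."""
    path = Path(path)
    first = next(iter(channels.values()))
    data = {"t_s": first.times}
    for name, ts in channels.items():
        if ts.fs != first.fs or len(ts) != len(first):
            raise ConfigError("all channels must share fs and length")
        data[name] = ts.samples
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    required = {"t_s", "x_cm", "y_cm"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: trajectory file needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return Trajectory(
        df["t_s"].to_numpy(float), df["x_cm"].to_numpy(float), df["y_cm"].to_numpy(float)
    )


def write_trajectory(path: str | Path, traj: Trajectory) -> Path:
    path = Path(path)
    pd.DataFrame({"t_s": traj.t, "x_cm": traj.x, "y_cm": traj.y}).to_csv(
        path, index=False
    )
    return path


def write_session(session, outdir: str | Path) -> dict[str, Path]:
    """Write one synthetic session: LFP pair, trajectory and JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lfp": write_timeseries(
            outdir / "lfp.csv",
            {"mpfc_uv": session.lfp_phase_region, "bla_uv": session.lfp_amp_region},
        ),
        "trajectory": write_trajectory(outdir / "trajectory.csv", session.trajectory),
    }
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "config": session.config.to_dict(),
        "group_label": session.group_label,
        "subject_id": session.subject_id,
        "traj_seed": session.traj_seed,
    }
    p = outdir / "session.json"
    p.write_text(json.dumps(sidecar, indent=2))
    paths["sidecar"] = p
    return paths


@dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic run."""

    n_subjects: int = 5
    trials_per_subject: int = 10
    chi_control: float = 0.8
    chi_cums: float = 0.3
    noise_sd: float = 10.0
    fs: float = 2000.0
    phase_band: str = "theta"
    amp_band: str = "high_gamma"
    n_bins: int = 18
    window_len: float = 1.0
    step: float = 0.1
    arena_side: float = 100.0
    arena_centre_side: float = 60.0
    seed: int = 0
    out_dir: str = "pacfield_run"
    with_comodulogram: bool = False
    with_timecourse: bool = True
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw.pop("schema_version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Record of a pipeline run: config echo, hashes, warnings."""

    config: dict
    version: str
    outputs: dict[str, str] = field(default_factory=dict)  # name -> sha256
    warnings: list[str] = field(default_factory=list)
    results: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Simulate -> preprocess -> behaviour -> PAC -> stats, with a manifest.

    Produces, under ``cfg.out_dir``: ``mi_table.csv`` (per-trial zone MI),
    ``behavior.csv``, ``stats.json`` (group t-test on subject-mean MI plus a
    group x zone ANOVA with the three headline Bonferroni contrasts),
    optional per-group MI time courses and comodulograms, and
    ``manifest.json`` referencing every output with a content hash.
    """
    from . import __version__

    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    arena = ArenaSpec(cfg.arena_side, cfg.arena_centre_side)
    manifest = RunManifest(config=cfg.to_dict(), version=__version__)

    log.info("simulate: %d subjects/group, %d trials/subject, chi %.2f vs %.2f",
             cfg.n_subjects, cfg.trials_per_subject, cfg.chi_control, cfg.chi_cums)
    sessions = gen_group_dataset(
        cfg.n_subjects, cfg.trials_per_subject, cfg.chi_control, cfg.chi_cums,
        cfg.seed, arena=arena, noise_sd=cfg.noise_sd, fs=cfg.fs,
    )

    mi_rows = []
    beh_rows = []
    group_trials: dict[str, list] = {"control": [], "cums": []}
    import warnings as _warnings

    for ses in sessions:
        log.info("preprocess + PAC: subject %s", ses.subject_id)
        mpfc = preprocess_chain(ses.lfp_phase_region)
        bla = preprocess_chain(ses.lfp_amp_region)
        trials = extract_trials(ses.trajectory, arena)
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            segments = align_lfp_to_trials(mpfc, bla, trials, pad_s=1.0)
            for w in caught:
                manifest.warnings.append(f"{ses.subject_id}: {w.message}")
        pairs = [(seg.phase_seg, seg.amp_seg) for seg in segments]
        if pairs:
            zm = zone_mi(pairs, cfg.phase_band, cfg.amp_band, cfg.n_bins)
            for k, seg in enumerate(segments):
                mi_rows.append({
                    "group": ses.group_label,
                    "subject": ses.subject_id,
                    "rp_time": seg.trial.rp_time,
                    "dwell": seg.trial.dwell,
                    "peripheral_mi": zm[k, 0],
                    "central_mi": zm[k, 1],
                })
            group_trials[ses.group_label].extend(pairs)
        summary = behavior_summary(ses.trajectory, arena)
        beh_rows.append({"group": ses.group_label, "subject": ses.subject_id,
                         **summary.to_dict()})

    mi_table = pd.DataFrame(mi_rows)
    beh_table = pd.DataFrame(beh_rows)
    mi_path = outdir / "mi_table.csv"
    beh_path = outdir / "behavior.csv"
    mi_table.to_csv(mi_path, index=False)
    beh_table.to_csv(beh_path, index=False)
    manifest.outputs["mi_table.csv"] = _sha256(mi_path)
    manifest.outputs["behavior.csv"] = _sha256(beh_path)

    stats_out: dict = {}
    if not mi_table.empty:
        mi_table["trial_mean_mi"] = mi_table[["peripheral_mi", "central_mi"]].mean(axis=1)
        subj = mi_table.groupby(["group", "subject"])["trial_mean_mi"].mean()
        tt = ttest_independent(
            subj.loc["control"].to_numpy(), subj.loc["cums"].to_numpy()
        )
        stats_out["group_ttest"] = tt.to_dict()
        long = mi_table.melt(
            id_vars=["group"], value_vars=["peripheral_mi", "central_mi"],
            var_name="zone", value_name="mi",
        )
        long["zone"] = long["zone"].str.replace("_mi", "", regex=False)
        counts = long.groupby(["group", "zone"]).size()
        if counts.min() == counts.max() and counts.min() >= 2:
            pairs = [
                (("control", "peripheral"), ("control", "central")),
                (("control", "peripheral"), ("cums", "peripheral")),
                (("control", "central"), ("cums", "central")),
            ]
            an = anova_two_way(long["mi"], long["group"], long["zone"], pairs)
            stats_out["anova_group_zone"] = {
                "table": an.table.to_dict(orient="records"),
                "post_hoc": an.post_hoc.to_dict(orient="records"),
            }
        else:
            manifest.warnings.append("unbalanced trial counts: group x zone ANOVA skipped")
    stats_path = outdir / "stats.json"
    stats_path.write_text(json.dumps(stats_out, indent=2))
    manifest.outputs["stats.json"] = _sha256(stats_path)
    manifest.results = stats_out

    if cfg.with_timecourse:
        for group, pairs in group_trials.items():
            if not pairs:
                continue
            tc = mi_timecourse(pairs, cfg.phase_band, cfg.amp_band,
                               cfg.window_len, cfg.step)
            p = outdir / f"timecourse_{group}.csv"
            pd.DataFrame({
                "rel_time_s": tc.rel_times,
                "mi_mean": tc.mi_mean,
                "mi_sem": tc.mi_sem,
            }).to_csv(p, index=False)
            manifest.outputs[p.name] = _sha256(p)

    if cfg.with_comodulogram:
        for group in ("control", "cums"):
            ses = next(s for s in sessions if s.group_label == group)
            mpfc = preprocess_chain(ses.lfp_phase_region)
            bla = preprocess_chain(ses.lfp_amp_region)
            como = comodulogram(mpfc, bla)
            p = outdir / f"comodulogram_{group}.csv"
            _write_comodulogram(p, como)
            manifest.outputs[p.name] = _sha256(p)

    manifest_path = outdir / "manifest.json"
    manifest.to_json(manifest_path)
    log.info("pipeline complete: %d outputs, %d warnings",
             len(manifest.outputs), len(manifest.warnings))
    return manifest


def _write_comodulogram(path: Path, como) -> Path:
    """Matrix file: first row amplitude centres, first column phase centres."""
    grid = pd.DataFrame(
        como.mi_grid, index=como.phase_centres, columns=como.amp_centres
    )
    grid.index.name = "phase_hz"
    grid.to_csv(path)
    return path
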