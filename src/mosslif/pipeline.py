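"""End-to-end batch analysis: ingest -> ROI -> histograms -> distances ->
summaries -> Welch tests -> control bands -> ratios -> stressor calls -> CSVs.

Given a folder (or manifest) of trial images including a control trial, the
pipeline compares every trial session against the full control image pool,
summarizes the per-pair distance values per session, builds control bands
from the control pool's own session summaries (self-pairs excluded), and
classifies each session's deviation pattern.

Everything is deterministic given the configuration and inputs; re-running
writes byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distance import (
    ChannelCombo,
    DifferenceSample,
    PAIR_COMBO_NAMES,
    SINGLE_COMBO_NAMES,
    samples_to_frame,
)
from .errors import ConfigError, MossLifError
from .histogram import HistogramSet, compute_histograms
from .imaging import RoiRect, discover_layout, iter_images, load_manifest
from .ratios import DeviationPattern, classify_stressor, color_ratios
from .stats import (
    ControlBand,
    SessionSummary,
    all_pairs_differences,
    control_band,
    exceeds_band,
    summarize_session,
    welch_t,
)

logger = logging.getLogger(__name__)

ALL_COMBO_NAMES = SINGLE_COMBO_NAMES + PAIR_COMBO_NAMES


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one analysis run."""

    input_path: str
    out_dir: str
    control_trial_id: str = "control"
    roi: RoiRect | None = None
    metrics: tuple[str, ...] = ("density_difference", "dtw")
    combos: tuple[str, ...] = ALL_COMBO_NAMES
    level: float = 0.99
    replication_unit: str = "per_pair"  # or "per_image_mean"
    write_samples: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ConfigError(f"confidence level must be in (0, 1), got {self.level}")
        bad = [m for m in self.metrics if m not in ("density_difference", "dtw")]
        if bad:
            raise ConfigError(f"unknown metrics {bad}")
        bad = [c for c in self.combos if c not in ALL_COMBO_NAMES]
        if bad:
            raise ConfigError(f"unknown combos {bad}")
        if self.replication_unit not in ("per_pair", "per_image_mean"):
            raise ConfigError(f"unknown replication unit {self.replication_unit!r}")

    def lanes(self) -> list[tuple[str, ChannelCombo]]:
        """(metric, combo) pairs to compute: density_difference on single
        channels, DTW on both single channels and two-color combinations."""
        out = []
        for combo_name in self.combos:
            combo = ChannelCombo.parse(combo_name)
            for metric in self.metrics:
                if metric == "density_difference" and combo.kind != "single":
                    continue
                out.append((metric, combo))
        return out

    def flag_metric(self, combo: ChannelCombo) -> str | None:
        """Which metric's control band drives the deviation flag for a combo.

        Single channels use the density difference (the study's single-color
        method) when available, else DTW; two-color combinations always use
        DTW, the only metric defined for them.
        """
        if combo.kind == "single":
            if "density_difference" in self.metrics:
                return "density_difference"
            return "dtw" if "dtw" in self.metrics else None
        return "dtw" if "dtw" in self.metrics else None


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file; the `roi` key is [x0, y0, x1, y1]."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "roi" in raw and raw["roi"] is not None:
        raw["roi"] = RoiRect(*(int(v) for v in raw["roi"]))
    for key in ("metrics", "combos"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"invalid run configuration in {path}: {exc}") from exc


@dataclass
class RunResult:
    """In-memory bundle of every table the run produced."""

    session_summaries: pd.DataFrame
    control_bands: pd.DataFrame
    welch_tests: pd.DataFrame
    color_ratios: pd.DataFrame
    stressor_calls: pd.DataFrame
    stressor_calls_daily: pd.DataFrame
    metadata: dict
    samples: pd.DataFrame | None = None
    bands: dict = field(default_factory=dict)  # (metric, combo) -> ControlBand


def _group_by_session(samples: list[DifferenceSample]) -> dict[tuple, list[DifferenceSample]]:
    groups: dict[tuple, list[DifferenceSample]] = {}
    for s in samples:
        groups.setdefault(s.trial_meta.session_key, []).append(s)
    return groups


def _per_image_means(samples: list[DifferenceSample], side: str) -> np.ndarray:
    key = (lambda s: s.trial_meta) if side == "trial" else (lambda s: s.control_meta)
    acc: dict[tuple, list[float]] = {}
    for s in samples:
        m = key(s)
        acc.setdefault((m.trial_id, m.day, m.session, m.position, m.side), []).append(s.value)
    return np.array([float(np.mean(v)) for _, v in sorted(acc.items())])


def _session_sort(df: pd.DataFrame, extra: list[str] | None = None) -> pd.DataFrame:
    cols = ["trial_id", "day", "session"] + (extra or [])
    return df.sort_values(cols, kind="mergesort").reset_index(drop=True)


def run_analysis(config: RunConfig) -> RunResult:
    """Execute the full analysis and write the report bundle to ``out_dir``."""
    in_path = Path(config.input_path)
    if in_path.is_file():
        entries = load_manifest(in_path)
    elif in_path.is_dir():
        manifest = in_path / "manifest.csv"
        entries = load_manifest(manifest) if manifest.exists() else discover_layout(in_path)
    else:
        raise ConfigError(f"input path {in_path} does not exist")
    if not entries:
        raise ConfigError(f"no images found under {in_path}")

    logger.info("reading %d images", len(entries))
    by_trial: dict[str, list[HistogramSet]] = {}
    for img in iter_images(entries, roi=config.roi):
        by_trial.setdefault(img.meta.trial_id, []).append(compute_histograms(img))

    if config.control_trial_id not in by_trial:
        raise ConfigError(
            f"control trial {config.control_trial_id!r} not found; "
            f"trials present: {sorted(by_trial)}"
        )
    control_sets = by_trial[config.control_trial_id]
    if len(control_sets) < 2:
        raise ConfigError("need at least 2 control images")
    trial_ids = sorted(by_trial)
    logger.info(
        "trials: %s; control pool: %d images", ", ".join(trial_ids), len(control_sets)
    )

    summary_rows, band_rows, welch_rows, sample_frames = [], [], [], []
    bands: dict[tuple[str, str], ControlBand] = {}
    # (trial, day, session) -> combo name -> (flag, metric)
    flags: dict[tuple, dict[str, tuple[bool, str]]] = {}
    # (trial, day, session) -> channel -> session mean density difference
    single_dd_means: dict[tuple, dict[str, float]] = {}
    n_self_excluded = 0

    for metric, combo in config.lanes():
        lane = (metric, combo.name)
        logger.info("lane metric=%s combo=%s", metric, combo.name)
        # Leave-session-out: a control session is scored only against images
        # outside its own session, so its mean is exchangeable with an
        # independent trial session's (within-session pairs share the
        # session's acquisition state and would deflate the null).
        control_samples = all_pairs_differences(
            control_sets, control_sets, metric, combo, exclude="session"
        )
        n_self_excluded += len(control_sets) ** 2 - len(control_samples)
        control_sessions = _group_by_session(control_samples)
        control_summaries = {
            key: summarize_session(group) for key, group in sorted(control_sessions.items())
        }
        band = control_band(list(control_summaries.values()), level=config.level)
        bands[lane] = band
        band_rows.append(
            {
                "metric": metric,
                "combo": combo.name,
                "center": band.center,
                "ci_lo": band.ci99_lo,
                "ci_hi": band.ci99_hi,
                "sigma3_lo": band.sigma3_lo,
                "sigma3_hi": band.sigma3_hi,
                "n_sessions": band.n_sessions,
                "level": band.level,
            }
        )
        control_pool_values = np.array([s.value for s in control_samples])
        control_pool_image_means = _per_image_means(control_samples, side="control")

        for trial_id in trial_ids:
            if trial_id == config.control_trial_id:
                trial_sessions = control_sessions
                summaries = control_summaries
            else:
                samples = all_pairs_differences(by_trial[trial_id], control_sets, metric, combo)
                trial_sessions = _group_by_session(samples)
                summaries = {
                    key: summarize_session(group) for key, group in sorted(trial_sessions.items())
                }
            if config.write_samples:
                for group in trial_sessions.values():
                    sample_frames.append(samples_to_frame(group))
            for key, summ in summaries.items():
                flag = exceeds_band(summ, band)
                summary_rows.append(
                    {
                        "trial_id": summ.trial_id,
                        "day": summ.day,
                        "session": summ.session,
                        "metric": metric,
                        "combo": combo.name,
                        "mean": summ.mean,
                        "sd": summ.sd,
                        "se": summ.se,
                        "n": summ.n,
                        "exceeds_band": flag,
                    }
                )
                if config.flag_metric(combo) == metric:
                    flags.setdefault(key, {})[combo.name] = (flag, metric)
                if metric == "density_difference":
                    single_dd_means.setdefault(key, {})[combo.name] = summ.mean
                group = trial_sessions[key]
                if config.replication_unit == "per_pair":
                    a = np.array([s.value for s in group])
                    b = control_pool_values
                else:
                    a = _per_image_means(group, side="trial")
                    b = control_pool_image_means
                try:
                    w = welch_t(a, b)
                    welch_rows.append(
                        {
                            "trial_id": summ.trial_id,
                            "day": summ.day,
                            "session": summ.session,
                            "metric": metric,
                            "combo": combo.name,
                            "t": w.t,
                            "dof": w.dof,
                            "p": w.p,
                            "significant": bool(w.p < 1.0 - config.level),
                        }
                    )
                except MossLifError as exc:  # degenerate lanes
                    logger.warning("welch_t skipped for %s %s: %s", key, lane, exc)

    # Color ratios from the single-channel density differences (the
    # single-color method), one triple per trial session.
    ratio_rows = []
    for key in sorted(single_dd_means):
        means = single_dd_means[key]
        if set(means) != set(SINGLE_COMBO_NAMES):
            continue
        triple = color_ratios(means["R"], means["G"], means["B"])
        trial_id, day, session = key
        ratio_rows.append(
            {
                "trial_id": trial_id,
                "day": day,
                "session": session,
                "r_frac": triple.r_frac,
                "g_frac": triple.g_frac,
                "b_frac": triple.b_frac,
            }
        )

    # Stressor calls from the per-session deviation pattern, plus day-level
    # calls where a combo deviates only if every session of the day exceeds
    # the band (the am/pm sessions are replicate observations of one
    # treatment state, so requiring agreement damps session noise).
    call_rows = []
    day_flags: dict[tuple, dict[str, list]] = {}
    for key in sorted(flags):
        combo_flags = flags[key]
        if set(combo_flags) != set(ALL_COMBO_NAMES):
            continue  # pattern incomplete (e.g. DTW disabled): no call
        pattern = DeviationPattern(
            flags={c: combo_flags[c][0] for c in ALL_COMBO_NAMES},
            metric_by_combo={c: combo_flags[c][1] for c in ALL_COMBO_NAMES},
        )
        call = classify_stressor(pattern)
        trial_id, day, session = key
        for c in ALL_COMBO_NAMES:
            day_flags.setdefault((trial_id, day), {}).setdefault(c, []).append(
                (pattern.flags[c], pattern.metric_by_combo[c])
            )
        row = {"trial_id": trial_id, "day": day, "session": session}
        row.update({f"flag_{c}": pattern.flags[c] for c in ALL_COMBO_NAMES})
        row["label"] = call.label
        row["rationale"] = "; ".join(call.rationale)
        call_rows.append(row)

    daily_rows = []
    for (trial_id, day), combos in sorted(day_flags.items()):
        pattern = DeviationPattern(
            flags={c: all(f for f, _ in combos[c]) for c in ALL_COMBO_NAMES},
            metric_by_combo={c: combos[c][0][1] for c in ALL_COMBO_NAMES},
        )
        call = classify_stressor(pattern)
        row = {"trial_id": trial_id, "day": day}
        row.update({f"flag_{c}": pattern.flags[c] for c in ALL_COMBO_NAMES})
        row["label"] = call.label
        row["rationale"] = "; ".join(call.rationale)
        daily_rows.append(row)

    result = RunResult(
        session_summaries=_session_sort(pd.DataFrame(summary_rows), ["metric", "combo"]),
        control_bands=pd.DataFrame(band_rows).sort_values(["metric", "combo"]).reset_index(drop=True),
        welch_tests=_session_sort(pd.DataFrame(welch_rows), ["metric", "combo"]),
        color_ratios=pd.DataFrame(ratio_rows),
        stressor_calls=pd.DataFrame(call_rows),
        stressor_calls_daily=pd.DataFrame(daily_rows),
        metadata={
            "package": "mosslif",
            "version": __version__,
            "config": {
                "input_path": str(config.input_path),
                "out_dir": str(config.out_dir),
                "control_trial_id": config.control_trial_id,
                "roi": None
                if config.roi is None
                else [config.roi.x0, config.roi.y0, config.roi.x1, config.roi.y1],
                "metrics": list(config.metrics),
                "combos": list(config.combos),
                "level": config.level,
                "replication_unit": config.replication_unit,
                "seed": config.seed,
            },
            "n_images": len(entries),
            "n_control_images": len(control_sets),
            "n_control_self_pairs_excluded": n_self_excluded,
            "n_simultaneous_combo_tests": len(config.lanes()),
            "decisions": {
                "two_color_dtw_cost": "euclidean distance in 2-channel density space",
                "dtw_normalization": "cumulative cost, not path-length normalized",
                "control_self_pairs": "within-session pairs excluded (leave-session-out null)",
                "band": "t-based prediction interval on control session means",
                "flag_rule": "strict exceedance of the band",
                "multiple_testing_correction": "none",
            },
        },
        samples=pd.concat(sample_frames, ignore_index=True) if sample_frames else None,
        bands=bands,
    )
    _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.session_summaries.to_csv(out_dir / "session_summaries.csv", index=False)
    result.control_bands.to_csv(out_dir / "control_band.csv", index=False)
    result.welch_tests.to_csv(out_dir / "welch_tests.csv", index=False)
    result.color_ratios.to_csv(out_dir / "color_ratios.csv", index=False)
    result.stressor_calls.to_csv(out_dir / "stressor_calls.csv", index=False)
    result.stressor_calls_daily.to_csv(out_dir / "stressor_calls_daily.csv", index=False)
    if result.samples is not None:
        result.samples.to_csv(out_dir / "difference_samples.csv", index=False)
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(result.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote report bundle to %s", out_dir)
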