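"""On-disk dataset and result formats.

A dataset on disk is a directory with a JSON config plus, per subject, a
time-series CSV (``time_s,<ch1>,<ch2>,...``, one row per sample) and an
events CSV (``onset_s,condition``).  The dialect is deliberately minimal so
any preprocessing stack (including HomER exports) can produce it.

Config schema::

    {
      "conditions": [2 strings],
      "included_channels": [strings],
      "sample_rate_hz": number,
      "window": {"start_s": number, "end_s": number},
      "subjects": [{"id": str, "timeseries": str, "events": str}, ...]
    }

Results are written as a tidy long-format CSV (one row per outcome) plus a
JSON summary carrying accuracies, parameters, seed and software version, so
re-reading yields the in-memory values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Dataset, Event, Recording, TimeWindow, drop_invalid_subjects
from .decoding import DecodingResult
from .errors import (
    ChannelMismatchError,
    DatasetValidationError,
    MissingSubjectFileError,
    ResultWriteError,
)
from .inference import PermutationResult
from .subsets import SubsetReport

CONFIG_NAME = "config.json"


def _load_config(root: Path, config) -> dict:
    if config is None:
        config = root / CONFIG_NAME
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise MissingSubjectFileError(f"dataset config not found: {path}")
        with open(path) as fh:
            return json.load(fh)
    return dict(config)


def read_dataset(
    root_path, config=None, drop_invalid: bool = False
) -> Dataset:
    """Load and validate a dataset directory.

    Parameters
    ----------
    root_path : directory holding the CSV files (paths in the config are
        resolved against it).
    config : path or mapping; defaults to ``root_path/config.json``.
    drop_invalid : if True, subjects with zero trials in some condition are
        excluded with a logged warning instead of raising.
    """
    root = Path(root_path)
    cfg = _load_config(root, config)
    conditions = list(cfg["conditions"])
    channels = list(cfg["included_channels"])
    fs = float(cfg["sample_rate_hz"])
    window = None
    if cfg.get("window"):
        window = TimeWindow(cfg["window"]["start_s"], cfg["window"]["end_s"])

    recordings = []
    for sub in cfg["subjects"]:
        sid = sub["id"]
        ts_path = root / sub["timeseries"]
        ev_path = root / sub["events"]
        for p in (ts_path, ev_path):
            if not p.exists():
                raise MissingSubjectFileError(
                    f"subject {sid}: missing file {p}"
                )
        ts = pd.read_csv(ts_path, float_precision="round_trip")
        missing = [ch for ch in channels if ch not in ts.columns]
        if missing:
            raise ChannelMismatchError(
                f"subject {sid}: time-series file lacks channel(s) "
                f"{missing} required by the config"
            )
        hbo = ts[channels].to_numpy(dtype=float).T
        ev = pd.read_csv(ev_path, float_precision="round_trip")
        events = [
            Event(onset_s=float(row.onset_s), condition=str(row.condition))
            for row in ev.itertuples()
        ]
        recordings.append(
            Recording(
                subject_id=sid,
                hbo=hbo,
                channel_ids=channels,
                sample_rate_hz=fs,
                events=events,
            )
        )
    if drop_invalid:
        recordings = drop_invalid_subjects(recordings, conditions)
    return Dataset(
        recordings=recordings,
        conditions=conditions,
        included_channels=channels,
        analysis_window=window,
    )


def write_dataset(dataset: Dataset, root_path) -> Path:
    """Write a dataset to a directory in the CSV + JSON dialect above."""
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    subjects = []
    for rec in dataset.recordings:
        sid = rec.subject_id
        ts_name, ev_name = f"{sid}_timeseries.csv", f"{sid}_events.csv"
        t = np.arange(rec.n_samples) / rec.sample_rate_hz
        df = pd.DataFrame({"time_s": t})
        for ch in dataset.included_channels:
            df[ch] = rec.hbo[rec.channel_index(ch)]
        df.to_csv(root / ts_name, index=False, float_format="%.17g")
        pd.DataFrame(
            {
                "onset_s": [ev.onset_s for ev in rec.events],
                "condition": [ev.condition for ev in rec.events],
            }
        ).to_csv(root / ev_name, index=False, float_format="%.17g")
        subjects.append({"id": sid, "timeseries": ts_name, "events": ev_name})
    cfg = {
        "conditions": list(dataset.conditions),
        "included_channels": list(dataset.included_channels),
        "sample_rate_hz": dataset.recordings[0].sample_rate_hz,
        "window": (
            {
                "start_s": dataset.analysis_window.start_s,
                "end_s": dataset.analysis_window.end_s,
            }
            if dataset.analysis_window
            else None
        ),
        "subjects": subjects,
    }
    with open(root / CONFIG_NAME, "w") as fh:
        json.dump(cfg, fh, indent=2)
    return root / CONFIG_NAME


def _package_version() -> str:
    from . import __version__

    return __version__


def write_results(result, out_path) -> dict[str, Path]:
    """Serialise a decoding / subset / permutation result to CSV + JSON.

    Returns the paths written, keyed by role ("csv", "json", ...).
    """
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if isinstance(result, DecodingResult):
        if not result.outcomes:
            raise ResultWriteError("decoding result has no outcomes to write")
        rows = []
        for o in result.outcomes:
            row = {
                "unit_id": o.unit_id,
                "subject_id": o.subject_id,
                "condition": o.condition,
                "correct": o.correct,
            }
            row.update(o.correlations)
            rows.append(row)
        paths["csv"] = out / f"decoding_{result.level}_outcomes.csv"
        pd.DataFrame(rows).to_csv(paths["csv"], index=False, float_format="%.17g")
        summary = {
            "level": result.level,
            "overall_accuracy": result.overall_accuracy,
            "per_condition_accuracy": result.per_condition_accuracy,
            "per_subject_accuracy": result.per_subject_accuracy,
            "metadata": result.metadata,
            "software_version": _package_version(),
        }
        paths["json"] = out / f"decoding_{result.level}_summary.json"
    elif isinstance(result, SubsetReport):
        if result.table.empty:
            raise ResultWriteError("subset report is empty")
        paths["csv"] = out / "subset_accuracies.csv"
        result.table.to_csv(paths["csv"], index=False, float_format="%.17g")
        paths["outcomes_csv"] = out / "subset_outcomes.csv"
        result.outcomes.to_csv(
            paths["outcomes_csv"], index=False, float_format="%.17g"
        )
        from .subsets import informativeness_table

        paths["informativeness_csv"] = out / "channel_informativeness.csv"
        informativeness_table(result).to_csv(
            paths["informativeness_csv"], index=False, float_format="%.17g"
        )
        summary = {
            "metadata": result.metadata,
            "n_subsets": int(len(result.table)),
            "software_version": _package_version(),
        }
        paths["json"] = out / "subset_summary.json"
    elif isinstance(result, PermutationResult):
        if result.null_accuracies.size == 0:
            raise ResultWriteError("permutation result has an empty null")
        paths["csv"] = out / "null_accuracies.csv"
        pd.DataFrame({"null_accuracy": result.null_accuracies}).to_csv(
            paths["csv"], index=False, float_format="%.17g"
        )
        null = result.null_accuracies
        summary = {
            "level": result.level,
            "observed": result.observed_accuracy,
            "p_value": result.p_value,
            "M": result.n_permutations,
            "seed": result.seed,
            "per_condition": result.per_condition,
            "null_summary": {
                "mean": float(null.mean()),
                "sd": float(null.std(ddof=1)) if null.size > 1 else 0.0,
                "quantiles": {
                    str(q): float(np.quantile(null, q))
                    for q in (0.025, 0.25, 0.5, 0.75, 0.975)
                },
            },
            "metadata": result.metadata,
            "software_version": _package_version(),
        }
        paths["json"] = out / "permutation_summary.json"
    else:
        raise ResultWriteError(
            f"cannot serialise result of type {type(result).__name__}"
        )
    with open(paths["json"], "w") as fh:
        json.dump(summary, fh, indent=2)
    return paths
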