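"""Tap-record files and dataset (re)construction.

Tap records are UTF-8 TSV, one row per iteration, with columns
group_id, participant_id, trial_id, iteration_index, period_ms,
stimulus_onsets_ms and response_onsets_ms (the onset lists comma-joined).
Reading re-derives matching, averaging and validity from the raw onsets,
so a written dataset round-trips through the exact same preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .reproduction import TrialIteration, TrialRecord
from .rhythm_space import IntervalPattern
from .tap_preprocess import OnsetStream, preprocess_stream

__all__ = ["write_tap_records", "read_tap_records", "ReadReport", "records_to_trials"]

COLUMNS = [
    "group_id",
    "participant_id",
    "trial_id",
    "iteration_index",
    "period_ms",
    "stimulus_onsets_ms",
    "response_onsets_ms",
]


@dataclass
class ReadReport:
    n_rows: int = 0
    n_used: int = 0
    errors: list[str] = field(default_factory=list)


def _join(values: np.ndarray) -> str:
    return ",".join(repr(float(v)) for v in values)


def write_tap_records(trials: list[TrialRecord], path) -> None:
    rows = []
    for trial in trials:
        for it in trial.iterations:
            rows.append(
                {
                    "group_id": trial.group_id,
                    "participant_id": trial.participant_id,
                    "trial_id": trial.trial_id,
                    "iteration_index": it.index,
                    "period_ms": repr(float(it.stimulus.period)),
                    "stimulus_onsets_ms": _join(it.stream.stimulus_onsets),
                    "response_onsets_ms": _join(it.stream.response_onsets),
                }
            )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep="\t", index=False)


def read_tap_records(
    path, config: PipelineConfig | None = None
) -> tuple[list[TrialRecord], ReadReport]:
    """Read a tap-record TSV and rebuild preprocessed trials.

    Malformed rows are skipped and collected in the report; missing
    columns are a hard error.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tap-record file missing columns: {missing}")
    report = ReadReport(n_rows=len(df))
    rows = []
    expected = 3 * config.repetitions + 1
    for i, row in df.iterrows():
        try:
            period = float(row["period_ms"])
            stim = np.array([float(v) for v in str(row["stimulus_onsets_ms"]).split(",")])
            raw_resp = str(row["response_onsets_ms"])
            resp = (
                np.array([float(v) for v in raw_resp.split(",")])
                if raw_resp not in ("", "nan")
                else np.array([])
            )
            if len(stim) != expected:
                raise ValueError(
                    f"expected {expected} stimulus onsets, got {len(stim)}"
                )
            stream = OnsetStream(stimulus_onsets=stim, response_onsets=resp)
            rows.append(
                (
                    str(row["group_id"]),
                    str(row["participant_id"]),
                    int(row["trial_id"]),
                    int(row["iteration_index"]),
                    period,
                    stream,
                )
            )
            report.n_used += 1
        except (ValueError, TypeError) as exc:
            report.errors.append(f"row {i}: {exc}")
    trials = records_to_trials(rows, config)
    return trials, report


def records_to_trials(rows, config: PipelineConfig) -> list[TrialRecord]:
    """Group raw rows into trials and re-run preprocessing on each."""
    by_trial: dict[tuple, list] = {}
    for group, pid, tid, it_idx, period, stream in rows:
        by_trial.setdefault((group, pid, tid), []).append((it_idx, period, stream))
    trials = []
    for (group, pid, tid), items in sorted(by_trial.items()):
        items.sort(key=lambda x: x[0])
        iterations = []
        n_invalid = 0
        for it_idx, period, stream in items:
            # rows may carry another tempo; ms thresholds scale with period
            k = period / config.period_ms
            record = preprocess_stream(
                stream,
                repetitions=config.repetitions,
                match_window=config.match_window_ms * k,
                response_floor=config.response_floor_ms * k,
            )
            s = np.diff(stream.stimulus_onsets[:4])
            stimulus = IntervalPattern(
                float(s[0]), float(s[1]), float(s[2]), period=float(s.sum())
            )
            iterations.append(TrialIteration(it_idx, stimulus, stream, record))
            if not record.valid:
                n_invalid += 1
        seed = iterations[0].stimulus if iterations else None
        trials.append(
            TrialRecord(
                seed=seed,
                iterations=iterations,
                n_invalid=n_invalid,
                stopped_early=n_invalid >= config.max_invalid,
                group_id=group,
                participant_id=pid,
                trial_id=tid,
            )
        )
    return trials
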