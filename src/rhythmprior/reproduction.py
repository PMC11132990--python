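"""The iterated-reproduction protocol: seed -> reproduce -> feed back.

Each trial starts from a random seed rhythm.  On a valid iteration the
averaged response becomes the next stimulus; on an invalid iteration the
stimulus is repeated unchanged.  A trial stops once it accumulates three
invalid iterations.  Iterations keep their attempted index, so the nth
iteration is analysed as the nth iteration even when preceded by an
invalid one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .rhythm_space import IntervalPattern, sample_seed
from .tap_preprocess import (
    REPETITIONS,
    IterationRecord,
    OnsetStream,
    preprocess_stream,
)

__all__ = ["TrialIteration", "TrialRecord", "run_trial", "run_group"]

Responder = Callable[[IntervalPattern], OnsetStream]


@dataclass
class TrialIteration:
    index: int  # 1-based attempted-iteration index
    stimulus: IntervalPattern
    stream: OnsetStream
    record: IterationRecord


@dataclass
class TrialRecord:
    seed: IntervalPattern
    iterations: list[TrialIteration] = field(default_factory=list)
    n_invalid: int = 0
    stopped_early: bool = False
    group_id: str = "group"
    participant_id: str = "p0"
    trial_id: int = 0

    def iteration(self, index: int) -> TrialIteration | None:
        for it in self.iterations:
            if it.index == index:
                return it
        return None

    def fifth_iteration(self) -> TrialIteration | None:
        """The final-iteration record, if attempted and valid."""
        it = self.iteration(5)
        return it if it is not None and it.record.valid else None


def run_trial(
    seed: IntervalPattern,
    responder: Responder,
    n_iter: int = 5,
    max_invalid: int = 3,
    repetitions: int = REPETITIONS,
    match_window: float = 150.0,
    response_floor: float = 285.0,
) -> TrialRecord:
    """Run one iterated-reproduction trial.

    ``responder`` maps a stimulus pattern to an :class:`OnsetStream` (a
    simulated tapper, or replay of recorded data).  The invalid count is
    cumulative within the trial; the stop check runs after each iteration.
    """
    trial = TrialRecord(seed=seed)
    stimulus = seed
    for index in range(1, n_iter + 1):
        stream = responder(stimulus)
        record = preprocess_stream(
            stream,
            repetitions=repetitions,
            match_window=match_window,
            response_floor=response_floor,
        )
        trial.iterations.append(TrialIteration(index, stimulus, stream, record))
        if record.valid:
            r = record.response
            stimulus = IntervalPattern(
                float(r[0]), float(r[1]), float(r[2]), period=stimulus.period
            )
        else:
            trial.n_invalid += 1
            if trial.n_invalid >= max_invalid:
                trial.stopped_early = True
                break
    return trial


def run_group(
    n_trials: int,
    responder_factory: Callable[[str, np.random.Generator], Responder],
    rng: np.random.Generator,
    group_id: str = "group",
    n_participants: int = 20,
    period: float = 2000.0,
    min_seed_interval: float = 300.0,
    seeds: Sequence[IntervalPattern] | None = None,
    **trial_kwargs,
) -> list[TrialRecord]:
    """Run ``n_trials`` trials, assigned to participants round-robin.

    Deterministic for a given ``rng``: seeds and per-trial responder noise
    are drawn from spawned child streams in a fixed order.
    """
    trials: list[TrialRecord] = []
    scale = period / 2000.0
    trial_kwargs.setdefault("match_window", 150.0 * scale)
    trial_kwargs.setdefault("response_floor", 285.0 * scale)
    for t in range(n_trials):
        pid = f"p{t % max(1, n_participants)}"
        trial_rng = np.random.default_rng(rng.integers(2**31))
        if seeds is not None:
            seed = seeds[t]
        else:
            seed = sample_seed(trial_rng, period=period, min_interval=min_seed_interval)
        responder = responder_factory(pid, trial_rng)
        trial = run_trial(seed, responder, **trial_kwargs)
        trial.group_id = group_id
        trial.participant_id = pid
        trial.trial_id = t
        trials.append(trial)
    return trials
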