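"""Experimental design: block timing, scan annotation, and HRF-convolved targets.

The paradigm is a blocked two-task episodic memory experiment: at study,
alternating semantic ("Living?") and phonological ("Syllables?") mini-blocks;
at test, two retrieval sessions of alternating cued-recognition mini-blocks.
Each semantic/phonological block pair is followed by a fixation period.

Numeric task coding is fixed package-wide: semantic = +1, phonological = -1.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "TaskLabel",
    "MiniBlockSpec",
    "ExperimentDesign",
    "ScanAnnotation",
    "TASK_CODE",
    "default_design",
    "make_design",
    "block_duration_volumes",
    "annotate_scans",
    "hrf_kernel",
    "convolved_target",
]


class TaskLabel(str, Enum):
    SEMANTIC = "semantic"
    PHONOLOGICAL = "phonological"

    @property
    def code(self) -> int:
        """Fixed numeric coding: semantic=+1, phonological=-1."""
        return TASK_CODE[self]

    @property
    def other(self) -> "TaskLabel":
        return (
            TaskLabel.PHONOLOGICAL
            if self is TaskLabel.SEMANTIC
            else TaskLabel.SEMANTIC
        )


TASK_CODE = {TaskLabel.SEMANTIC: 1, TaskLabel.PHONOLOGICAL: -1}

PHASES = ("study", "test1", "test2")


@dataclass(frozen=True)
class MiniBlockSpec:
    """One mini-block of same-task trials within a phase."""

    phase: str
    task: TaskLabel
    n_trials: int
    soa_ms: float
    onset_s: float

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.soa_ms <= 0:
            raise ValueError("soa_ms must be positive")

    @property
    def duration_s(self) -> float:
        return self.n_trials * self.soa_ms / 1000.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Timing and labeling for one scanning session (study + two test phases)."""

    tr_s: float
    study: tuple[MiniBlockSpec, ...]
    test_sessions: tuple[tuple[MiniBlockSpec, ...], tuple[MiniBlockSpec, ...]]
    fixation_s: float

    def blocks(self, phase: str) -> tuple[MiniBlockSpec, ...]:
        if phase == "study":
            return self.study
        if phase == "test1":
            return self.test_sessions[0]
        if phase == "test2":
            return self.test_sessions[1]
        raise ValueError(f"unknown phase {phase!r}")

    def run_duration_s(self, phase: str) -> float:
        """Run length: end of the last block plus the trailing fixation period."""
        blocks = self.blocks(phase)
        last = blocks[-1]
        return last.onset_s + last.duration_s + self.fixation_s

    def n_scans(self, phase: str) -> int:
        """Number of volumes whose onset falls inside [0, run duration)."""
        return int(math.ceil(self.run_duration_s(phase) / self.tr_s - 1e-9))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "tr_s": self.tr_s,
            "fixation_s": self.fixation_s,
            "phases": {
                phase: [
                    {
                        "onset_s": b.onset_s,
                        "task": b.task.value,
                        "n_trials": b.n_trials,
                        "soa_ms": b.soa_ms,
                    }
                    for b in self.blocks(phase)
                ]
                for phase in PHASES
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentDesign":
        doc = json.loads(text)

        def _blocks(phase: str) -> tuple[MiniBlockSpec, ...]:
            return tuple(
                MiniBlockSpec(
                    phase=phase,
                    task=TaskLabel(b["task"]),
                    n_trials=int(b["n_trials"]),
                    soa_ms=float(b["soa_ms"]),
                    onset_s=float(b["onset_s"]),
                )
                for b in doc["phases"][phase]
            )

        return cls(
            tr_s=float(doc["tr_s"]),
            study=_blocks("study"),
            test_sessions=(_blocks("test1"), _blocks("test2")),
            fixation_s=float(doc["fixation_s"]),
        )

    def to_events(self, phase: str) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type) for one phase."""
        blocks = self.blocks(phase)
        return pd.DataFrame(
            {
                "onset": [b.onset_s for b in blocks],
                "duration": [b.duration_s for b in blocks],
                "trial_type": [b.task.value for b in blocks],
            }
        )


@dataclass(frozen=True)
class ScanAnnotation:
    """Per-volume bookkeeping: which block (if any) a scan belongs to."""

    scan_index: int
    onset_s: float
    block_index: int | None
    task: TaskLabel | None
    within_block_rank: int | None
    is_fixation: bool


def _alternating_blocks(
    phase: str,
    n_pairs: int,
    n_trials: int,
    soa_ms: float,
    fixation_s: float,
    start_task: TaskLabel,
) -> tuple[MiniBlockSpec, ...]:
    block_s = n_trials * soa_ms / 1000.0
    pair_period = 2 * block_s + fixation_s
    blocks = []
    for pair in range(n_pairs):
        t0 = pair * pair_period
        blocks.append(
            MiniBlockSpec(phase, start_task, n_trials, soa_ms, t0)
        )
        blocks.append(
            MiniBlockSpec(phase, start_task.other, n_trials, soa_ms, t0 + block_s)
        )
    return tuple(blocks)


def make_design(
    n_study_pairs: int = 8,
    study_trials: int = 15,
    study_soa_ms: float = 3000.0,
    n_test_pairs: int = 9,
    test_trials: int = 10,
    test_soa_ms: float = 4400.0,
    tr_s: float = 1.2,
    fixation_s: float = 21.0,
    start_task: TaskLabel = TaskLabel.SEMANTIC,
) -> ExperimentDesign:
    """Alternating-block session with arbitrary sizes (scaled variants)."""
    study = _alternating_blocks(
        "study", n_study_pairs, study_trials, study_soa_ms, fixation_s, start_task
    )
    test1 = _alternating_blocks(
        "test1", n_test_pairs, test_trials, test_soa_ms, fixation_s, start_task
    )
    test2 = _alternating_blocks(
        "test2", n_test_pairs, test_trials, test_soa_ms, fixation_s, start_task
    )
    return ExperimentDesign(
        tr_s=tr_s, study=study, test_sessions=(test1, test2), fixation_s=fixation_s
    )


def default_design(start_task: TaskLabel = TaskLabel.SEMANTIC) -> ExperimentDesign:
    """The default session timing.

    Study: 16 mini-blocks of 15 trials, SOA 3000 ms. Test: two sessions of
    18 mini-blocks of 10 trials, SOA 4400 ms. Tasks alternate; each block
    pair is followed by 21 s fixation. TR = 1.2 s. The starting task is
    counterbalanceable across subjects via ``start_task``.
    """
    return make_design(start_task=start_task)


def block_duration_volumes(block: MiniBlockSpec, tr_s: float) -> float:
    """Exact (unrounded) number of volumes spanned by a mini-block.

    15-trial blocks at SOA 3000 ms with TR 1.2 s span 37.5 volumes;
    10-trial blocks at SOA 4400 ms span 36.67 volumes.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    return block.n_trials * block.soa_ms / (1000.0 * tr_s)


def annotate_scans(design: ExperimentDesign, phase: str) -> list[ScanAnnotation]:
    """Label every acquired volume of a phase by block membership.

    A scan belongs to the block whose half-open interval
    [onset, onset + n_trials * SOA) contains the scan's acquisition onset;
    otherwise it is a fixation scan. Scan indexing is 0-based.
    """
    return list(_annotate_scans_cached(design, phase))


@functools.lru_cache(maxsize=64)
def _annotate_scans_cached(
    design: ExperimentDesign, phase: str
) -> tuple[ScanAnnotation, ...]:
    blocks = design.blocks(phase)
    n = design.n_scans(phase)
    annotations: list[ScanAnnotation] = []
    block_iter = 0
    rank = 0
    for i in range(n):
        t = i * design.tr_s
        # blocks are ordered by onset; advance past finished blocks
        while block_iter < len(blocks) and t >= (
            blocks[block_iter].onset_s + blocks[block_iter].duration_s
        ):
            block_iter += 1
            rank = 0
        if block_iter < len(blocks) and t >= blocks[block_iter].onset_s:
            annotations.append(
                ScanAnnotation(i, t, block_iter, blocks[block_iter].task, rank, False)
            )
            rank += 1
        else:
            annotations.append(ScanAnnotation(i, t, None, None, None, True))
    return tuple(annotations)


def hrf_kernel(dt_s: float) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function sampled at ``dt_s``.

    Response gamma: delay 6 s, dispersion 1; undershoot gamma: delay 16 s,
    dispersion 1; response:undershoot ratio 6; kernel length 32 s. The kernel
    is peak-normalized to 1. These are the standard canonical-HRF defaults.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0, 32 + dt_s / 2, dt_s)
    peak = _gamma_dist.pdf(t, a=6.0, scale=1.0)
    undershoot = _gamma_dist.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def task_boxcar(design: ExperimentDesign, phase: str) -> np.ndarray:
    """Per-scan +1/-1/0 task indicator (semantic/phonological/fixation)."""
    ann = annotate_scans(design, phase)
    return np.array(
        [0 if a.is_fixation else a.task.code for a in ann], dtype=float
    )


def convolved_target(design: ExperimentDesign, phase: str) -> np.ndarray:
    """HRF-convolved +/-1 block regressor, one value per acquired volume.

    The +/-1/0 boxcar sampled at TR is convolved with the canonical HRF and
    truncated to the run length. Fixation scans receive the (lagged) tail of
    preceding blocks; they shape the regressor even where they are excluded
    from decoding. The returned array is cached and read-only.
    """
    return _convolved_target_cached(design, phase)


@functools.lru_cache(maxsize=64)
def _convolved_target_cached(design: ExperimentDesign, phase: str) -> np.ndarray:
    box = task_boxcar(design, phase)
    kernel = hrf_kernel(design.tr_s)
    out = np.convolve(box, kernel)[: box.size]
    out.flags.writeable = False
    return out
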