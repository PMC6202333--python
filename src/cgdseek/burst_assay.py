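"""Neutrophil oxidative-burst (dihydrorhodamine) assay analysis.

A burst test compares per-cell fluorescence of unstimulated neutrophils with
PMA-stimulated neutrophils.  The stimulation index (SI) is computed here as
the ratio of geometric-mean fluorescence of the stimulated over the
unstimulated condition — the standard DHR-assay convention; published SI
values are often printed without their formula, so this choice is documented
rather than assumed universal.  A positivity gate is set at a quantile
(default 0.99) of the unstimulated distribution, and an SI strictly below 3
classifies the burst as impaired, the regime seen in severe (X-linked-like)
chronic granulomatous disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("cgdseek")

MIN_EVENTS = 100
DEFAULT_GATE_QUANTILE = 0.99
SI_IMPAIRED_THRESHOLD = 3.0


class AssayError(ValueError):
    """Unusable flow data (too few events, non-finite intensities...)."""


@dataclass(frozen=True)
class FlowEventSet:
    """Per-cell fluorescence intensities of one sample in one condition."""

    sample_id: str
    condition: str  # "unstimulated" | "PMA"
    fluorescences: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.fluorescences, dtype=float)
        object.__setattr__(self, "fluorescences", arr)
        if self.condition not in ("unstimulated", "PMA"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not np.all(np.isfinite(arr)):
            raise AssayError(f"{self.sample_id}: non-finite intensities")
        if np.any(arr < 0):
            raise AssayError(f"{self.sample_id}: negative intensities")

    def __len__(self) -> int:
        return len(self.fluorescences)


@dataclass(frozen=True)
class BurstResult:
    """Stimulation index with its gate and classification."""

    sample_id: str
    si: float
    pct_positive: float
    gate: float
    classification: str  # "impaired" | "normal"

    def __post_init__(self) -> None:
        if self.si <= 0:
            raise ValueError("stimulation index must be positive")
        if not (0.0 <= self.pct_positive <= 1.0):
            raise ValueError("pct_positive must lie in [0, 1]")


def gate_from_unstimulated(
    unstim: FlowEventSet, quantile: float = DEFAULT_GATE_QUANTILE
) -> float:
    """Positivity gate: empirical quantile of the unstimulated intensities."""
    if len(unstim) < MIN_EVENTS:
        raise AssayError(
            f"{unstim.sample_id}: {len(unstim)} unstimulated events, need >= {MIN_EVENTS}"
        )
    if not (0.0 <= quantile <= 1.0):
        raise ValueError("quantile must lie in [0, 1]")
    return float(np.quantile(unstim.fluorescences, quantile))


def _geometric_mean(x: np.ndarray, sample_id: str) -> float:
    if np.any(x <= 0):
        logger.info("%s: zero intensities present, applying +1 offset", sample_id)
        x = x + 1.0
    return float(np.exp(np.mean(np.log(x))))


def stimulation_index(
    stim: FlowEventSet,
    unstim: FlowEventSet,
    gate_quantile: float = DEFAULT_GATE_QUANTILE,
    si_threshold: float = SI_IMPAIRED_THRESHOLD,
) -> BurstResult:
    """Stimulation index of a paired burst test.

    SI = geometric-mean fluorescence (stimulated) / geometric-mean
    (unstimulated); samples containing zero intensities are offset by +1 in
    both conditions before taking logs.  ``pct_positive`` is the fraction of
    stimulated events above the unstimulated gate.
    """
    if stim.condition != "PMA" or unstim.condition != "unstimulated":
        raise ValueError("expected a PMA-stimulated and an unstimulated event set")
    if len(stim) < MIN_EVENTS or len(unstim) < MIN_EVENTS:
        raise AssayError(f"{stim.sample_id}: need >= {MIN_EVENTS} events per condition")
    offset_needed = np.any(stim.fluorescences <= 0) or np.any(unstim.fluorescences <= 0)
    s = stim.fluorescences + 1.0 if offset_needed else stim.fluorescences
    u = unstim.fluorescences + 1.0 if offset_needed else unstim.fluorescences
    if offset_needed:
        logger.info("%s: zero intensities present, applying +1 offset", stim.sample_id)
    si = float(np.exp(np.mean(np.log(s)) - np.mean(np.log(u))))
    gate = gate_from_unstimulated(unstim, gate_quantile)
    pct = float(np.mean(stim.fluorescences > gate))
    return BurstResult(
        sample_id=stim.sample_id,
        si=si,
        pct_positive=pct,
        gate=gate,
        classification=classify_burst_value(si, si_threshold),
    )


def classify_burst_value(si: float, threshold: float = SI_IMPAIRED_THRESHOLD) -> str:
    """``impaired`` iff the stimulation index is strictly below the threshold."""
    return "impaired" if si < threshold else "normal"


def classify_burst(result: BurstResult, threshold: float = SI_IMPAIRED_THRESHOLD) -> str:
    """Classification of an existing :class:`BurstResult` at a given threshold."""
    return classify_burst_value(result.si, threshold)


def burst_results_from_events(df, gate_quantile: float = DEFAULT_GATE_QUANTILE,
                              si_threshold: float = SI_IMPAIRED_THRESHOLD) -> list[BurstResult]:
    """Per-sample burst results from a long event table
    (columns: sample_id, condition, intensity)."""
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        sets = {}
        for cond, sub in grp.groupby("condition"):
            sets[cond] = FlowEventSet(sid, cond, sub["intensity"].to_numpy(dtype=float))
        if set(sets) != {"unstimulated", "PMA"}:
            raise AssayError(f"{sid}: need both unstimulated and PMA conditions")
        out.append(
            stimulation_index(sets["PMA"], sets["unstimulated"], gate_quantile, si_threshold)
        )
    return out
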