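"""Shared inflection/elbow detection for ranked signal curves.

Used both to separate super-enhancers from regular enhancers on the
signal-versus-rank curve and to pick high-variability motifs on the
variability-versus-rank curve, so the two analyses share one definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class RankCurve:
    """A descending-sorted signal curve with its inflection threshold.

    ``threshold_index`` is the number of leading (highest-signal) entries
    strictly above the threshold signal; ``signals[:threshold_index]`` are
    the calls above the elbow.
    """

    signals: np.ndarray  # descending
    normalized_rank: np.ndarray  # ascending in [0, 1]
    normalized_signal: np.ndarray  # ascending in [0, 1]
    threshold_index: int
    threshold_signal: float


def find_inflection(signals: np.ndarray, min_points: int = 10) -> RankCurve:
    """Inflection threshold of a ranked-signal curve.

    Rank and signal are rescaled to [0, 1] (ascending); the threshold sits
    where the tangent slope of the scaled curve equals 1, computed
    discretely as the point of maximal vertical distance below the
    diagonal.  Entries with signal strictly above the threshold signal are
    the above-elbow calls.  Scale-invariant: multiplying all signals by a
    positive constant leaves the threshold index unchanged.
    """
    desc = np.sort(np.asarray(signals, dtype=float))[::-1]
    n = desc.size
    if n < min_points:
        raise ValueError(f"need >= {min_points} values, got {n}")
    asc = desc[::-1]
    span = asc[-1] - asc[0]
    x = np.arange(n) / (n - 1)
    if span == 0:
        warnings.warn("flat signal curve; no calls above the elbow")
        return RankCurve(desc, x, np.zeros(n), 0, float(asc[-1]))
    y = (asc - asc[0]) / span
    elbow = int(np.argmax(x - y))
    threshold_signal = float(asc[elbow])
    threshold_index = int(np.sum(desc > threshold_signal))
    if threshold_index == 0 or threshold_index >= n - 1:
        warnings.warn("degenerate elbow at curve extreme")
    return RankCurve(desc, x, y, threshold_index, threshold_signal)
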