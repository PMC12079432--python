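"""Per-motif accessibility deviation z-scores with matched backgrounds.

For each motif (set of member peaks) and sample, the raw deviation is
Y = (X - E)/E where X is the observed count in member peaks and E is the
expectation under the all-sample average accessibility profile.  The raw
deviation is bias-corrected against deviations of GC- and
mean-accessibility-matched background peak sets, and standardized by the
background spread to give a z-score.  Background matching uses
equal-occupancy 2-D bins (GC fraction x log mean CPM) rather than
nearest-neighbour sampling; each member peak is replaced by a random peak
from its own bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import CountMatrix
from .elbow import find_inflection


@dataclass
class MotifPeakMembership:
    motif_ids: list[str]
    peak_ids: list[str]
    member: np.ndarray  # boolean, motifs x peaks

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != (len(self.motif_ids), len(self.peak_ids)):
            raise ValueError("membership matrix shape mismatch")

    @classmethod
    def from_dict(
        cls, membership: dict[str, list[str]], peak_ids: list[str]
    ) -> "MotifPeakMembership":
        peak_index = {p: i for i, p in enumerate(peak_ids)}
        motif_ids = list(membership)
        member = np.zeros((len(motif_ids), len(peak_ids)), dtype=bool)
        for j, m in enumerate(motif_ids):
            for p in membership[m]:
                if p in peak_index:
                    member[j, peak_index[p]] = True
        return cls(motif_ids, peak_ids, member)

    def usable(self) -> np.ndarray:
        """Motifs with at least one member peak."""
        return self.member.any(axis=1)


@dataclass
class DeviationScores:
    motif_ids: list[str]
    sample_ids: list[str]
    observed: np.ndarray  # X, motifs x samples
    expected: np.ndarray  # E
    raw_dev: np.ndarray  # Y
    corrected_dev: np.ndarray
    z: np.ndarray
    n_background: int


@dataclass
class MotifVariability:
    motif_id: str
    variability: float
    rank: int
    high_variability: bool


def expected_counts(
    counts: CountMatrix, member: MotifPeakMembership
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and expected motif counts per sample.

    X[j, i] is the observed count of sample i in motif-j peaks.  The
    expectation reflects the average accessibility profile of all
    samples: E[j, i] = (sample i total) x mean over samples of the
    fraction of each sample's reads falling in motif-j peaks.  This
    mean-of-fractions construction makes the raw deviation exactly
    invariant to rescaling any single sample's depth.  Motifs with zero
    counts everywhere are flagged by a warning and carry E = 0 rows
    (excluded downstream).
    """
    if counts.feature_ids != member.peak_ids:
        raise ValueError("counts and membership peak universes differ")
    mat = np.asarray(counts.counts, dtype=float)
    sample_totals = mat.sum(axis=0)
    x = member.member.astype(float) @ mat  # motifs x samples
    if (x.sum(axis=1) == 0).any():
        dead = [
            member.motif_ids[j]
            for j in np.flatnonzero(x.sum(axis=1) == 0)
        ]
        warnings.warn(f"motifs with zero counts excluded: {dead}")
    mean_fraction = (x / sample_totals[None, :]).mean(axis=1)
    e = np.outer(mean_fraction, sample_totals)
    return x, e


def raw_deviation(x: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Elementwise Y = (X - E)/E; undefined (NaN) where E = 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        y = (x - e) / e
    return np.where(e > 0, y, np.nan)


def accessibility_bins(
    gc: np.ndarray, mean_access: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Equal-occupancy 2-D bin index per peak (GC x log-mean-accessibility)."""
    gc = np.asarray(gc, dtype=float)
    acc = np.asarray(mean_access, dtype=float)

    def quantile_bin(v):
        edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(edges, v, side="right")

    return quantile_bin(gc) * n_bins + quantile_bin(acc)


def sample_background_sets(
    gc: np.ndarray,
    mean_access: np.ndarray,
    member: MotifPeakMembership,
    n_iter: int = 50,
    seed: int = 0,
    n_bins: int = 10,
) -> list[np.ndarray]:
    """Matched background peak-index sets, ``n_iter`` per motif.

    Each member peak is replaced by a peak drawn uniformly from its own
    (GC, accessibility) bin; a bin with a single occupant maps the peak to
    itself.  Returns one (n_iter, n_members) integer array per motif.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    bins = accessibility_bins(gc, mean_access, n_bins=n_bins)
    occupants = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    out = []
    for j in range(len(member.motif_ids)):
        members = np.flatnonzero(member.member[j])
        draws = np.empty((n_iter, members.size), dtype=np.int64)
        for k, p in enumerate(members):
            pool = occupants[bins[p]]
            draws[:, k] = pool[rng.integers(0, pool.size, size=n_iter)]
        out.append(draws)
    return out


def corrected_z(
    y: np.ndarray, background_y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Bias-corrected deviations and z-scores.

    corrected = Y - mean(background Y over iterations);
    z = corrected / sd(background Y, ddof=1).  Cells with zero background
    spread propagate as NaN.
    """
    if background_y.shape[0] < 2:
        raise ValueError("need >= 2 background iterations")
    bg_mean = background_y.mean(axis=0)
    bg_sd = background_y.std(axis=0, ddof=1)
    corrected = y - bg_mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = corrected / bg_sd
    # zero background spread: z is 0 when the correction is also exactly 0
    # (deviation indistinguishable from background), otherwise missing
    z = np.where(bg_sd > 0, z, np.where(corrected == 0, 0.0, np.nan))
    return corrected, z


def compute_deviations(
    counts: CountMatrix,
    member: MotifPeakMembership,
    gc: np.ndarray,
    n_iter: int = 50,
    seed: int = 0,
    n_bins: int = 10,
) -> DeviationScores:
    """Full deviation workflow: X/E, backgrounds, correction, z-scores."""
    mat = np.asarray(counts.counts, dtype=float)
    x, e = expected_counts(counts, member)
    y = raw_deviation(x, e)

    lib = mat.sum(axis=0)
    mean_access = np.log1p((mat / lib * 1e6).mean(axis=1))
    bg_sets = sample_background_sets(
        gc, mean_access, member, n_iter=n_iter, seed=seed, n_bins=n_bins
    )

    sample_totals = lib
    n_motifs, n_samples = x.shape
    bg_y = np.full((n_iter, n_motifs, n_samples), np.nan)
    for j, draws in enumerate(bg_sets):
        if draws.size == 0:
            continue
        # counts over background sets: sum member-replacement rows
        x_bg = mat[draws].sum(axis=1)  # n_iter x samples
        frac = (x_bg / sample_totals[None, :]).mean(axis=1, keepdims=True)
        e_bg = frac * sample_totals[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            bg_y[:, j, :] = np.where(e_bg > 0, (x_bg - e_bg) / e_bg, np.nan)

    corrected, z = corrected_z(y, bg_y)
    return DeviationScores(
        motif_ids=list(member.motif_ids),
        sample_ids=list(counts.sample_ids),
        observed=x,
        expected=e,
        raw_dev=y,
        corrected_dev=corrected,
        z=z,
        n_background=n_iter,
    )


def variability_rank(scores: DeviationScores) -> list[MotifVariability]:
    """Motifs ranked by cross-sample SD of the z-score (variability).

    High-variability motifs are those above the inflection of the
    variability-versus-rank curve (shared elbow definition).
    """
    if len(scores.sample_ids) < 2:
        raise ValueError("variability needs >= 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanstd(scores.z, axis=1, ddof=1)
    var = np.where(np.isfinite(var), var, 0.0)
    order = np.argsort(-var, kind="stable")
    if np.all(var == var[0]):
        warnings.warn("all variabilities equal; no high-variability motifs")
        cutoff = np.inf
    elif var.size >= 10:
        curve = find_inflection(var)
        cutoff = curve.threshold_signal
    else:
        cutoff = np.inf
    out = []
    for rank, j in enumerate(order, start=1):
        out.append(
            MotifVariability(
                motif_id=scores.motif_ids[j],
                variability=float(var[j]),
                rank=rank,
                high_variability=bool(var[j] > cutoff),
            )
        )
    return out
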