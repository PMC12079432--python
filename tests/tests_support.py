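"""Shared helpers for building planted-truth datasets in tests."""

import numpy as np

from peakscape.deviation import MotifPeakMembership, compute_deviations
from peakscape.simulate import SyntheticConfig, simulate_dataset


def overlap_unit_count(intervals) -> int:
    """Number of >=1 bp-overlap merged units (book-ended stay separate)."""
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    n = 0
    cur_chrom, cur_end = None, -1
    for iv in ordered:
        if iv.chrom == cur_chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            n += 1
            cur_chrom, cur_end = iv.chrom, iv.end
    return n


def deviation_config(seed=0, **overrides) -> SyntheticConfig:
    """Deviation-focused config: no SE clusters, no DE coupling."""
    base = dict(
        seed=seed,
        n_se_clusters=(0, 0, 0),
        de_fraction=0.0,
        motif_shift_effects={},
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def deviation_scores(config, n_iter=50, seed=0):
    dataset, truth = simulate_dataset(config)
    member = MotifPeakMembership.from_dict(
        dataset.membership, dataset.atac_counts.feature_ids
    )
    gc = np.array([p.gc for p in dataset.peaks])
    scores = compute_deviations(
        dataset.atac_counts, member, gc, n_iter=n_iter, seed=seed
    )
    return scores, truth


def null_deviation_scores(seed=0):
    """Motif z-scores with nothing planted (null calibration)."""
    return deviation_scores(deviation_config(seed=seed), seed=seed + 7)[0]


def planted_shift_scores(seed=0, shift=1.0):
    """One motif shifted by ``shift`` log2 units in condition B."""
    cfg = deviation_config(
        seed=seed, motif_shift_effects={"motif_000": shift}
    )
    scores, _ = deviation_scores(cfg, seed=seed + 7)
    return scores, "motif_000"
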