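"""Aggregate TF footprint profiles and the footprint-depth statistic.

A bound factor protects its motif core from Tn5 insertion, so the
cut-site density dips at the motif and rises in the flanks.  Profiles
average depth-normalized (per-million) cut counts across motif
occurrences; depth is the flank mean minus the core mean, with a 5 bp
guard band at the motif edge excluded from both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval
from .io import read_intervals


@dataclass
class CutSiteTrack:
    """Per-chromosome per-base cut (or coverage) arrays for one condition.

    The track total is cached on first access; treat the arrays as frozen
    once the track is queried.
    """

    arrays: dict[str, np.ndarray]
    _total: float | None = None

    @property
    def total(self) -> float:
        if self._total is None:
            self._total = float(sum(a.sum() for a in self.arrays.values()))
        return self._total

    @classmethod
    def from_bedgraph(
        cls, path, chrom_sizes: dict[str, int]
    ) -> "CutSiteTrack":
        arrays = {
            c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()
        }
        for rec in read_intervals(path, dialect="bedgraph"):
            iv = rec.interval
            if iv.chrom not in arrays:
                continue
            arrays[iv.chrom][iv.start : iv.end] += rec.value
        return cls(arrays)


@dataclass
class MotifOccurrence:
    motif_id: str
    position: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.position) < 4:
            raise ValueError("motif occurrences must be >= 4 bp wide")


@dataclass
class FootprintProfile:
    motif_id: str
    condition: str
    offsets: np.ndarray  # centered integer offsets, length 2*flank + width
    signal: np.ndarray  # per-million normalized mean cut counts
    n_occurrences: int
    motif_width: int
    flank: int


@dataclass
class FootprintDepth:
    motif_id: str
    condition: str
    depth: float


def aggregate_footprint(
    track: CutSiteTrack,
    occurrences: list[MotifOccurrence],
    flank: int = 100,
    condition: str = "",
) -> FootprintProfile:
    """Mean per-offset cut signal across motif occurrences.

    Windows span the motif plus ``flank`` bp on each side; minus-strand
    occurrences are reversed before averaging so offsets are
    strand-relative.  The mean is scaled by 1e6 / total cuts; occurrences
    extending beyond chromosome bounds are skipped.
    """
    if not occurrences:
        raise ValueError("no occurrences supplied")
    widths = {len(o.position) for o in occurrences}
    width = max(widths)
    usable = []
    for occ in occurrences:
        iv = occ.position
        if len(iv) != width or iv.chrom not in track.arrays:
            continue
        lo, hi = iv.start - flank, iv.end + flank
        if lo < 0 or hi > track.arrays[iv.chrom].size:
            continue
        window = track.arrays[iv.chrom][lo:hi]
        if iv.strand == "-":
            window = window[::-1]
        usable.append(window)
    if not usable:
        raise ValueError("no occurrence lies fully inside the track bounds")
    total = track.total
    signal = np.mean(usable, axis=0) * 1e6 / total
    length = width + 2 * flank
    offsets = np.arange(length) - length // 2
    return FootprintProfile(
        motif_id=occurrences[0].motif_id,
        condition=condition,
        offsets=offsets,
        signal=signal,
        n_occurrences=len(usable),
        motif_width=width,
        flank=flank,
    )


def footprint_depth(
    profile: FootprintProfile,
    motif_width: int | None = None,
    guard: int = 5,
) -> FootprintDepth:
    """Depth = flank mean - core mean, in per-million units.

    Core: offsets with |offset| <= width/2.  Flank: offsets with
    width/2 + guard < |offset| <= flank, so ``guard`` bp adjoining the
    motif edge contribute to neither term.
    """
    w = profile.motif_width if motif_width is None else motif_width
    if profile.flank < w:
        raise ValueError("flank must be at least the motif width")
    half = w / 2
    a = np.abs(profile.offsets)
    core = a <= half
    flank = (a > half + guard) & (a <= profile.flank)
    depth = float(profile.signal[flank].mean() - profile.signal[core].mean())
    return FootprintDepth(profile.motif_id, profile.condition, depth)


def compare_conditions(
    profile_a: FootprintProfile, profile_b: FootprintProfile
) -> tuple[float, FootprintProfile, FootprintProfile]:
    """Depth difference between conditions (b minus a).

    Positive delta means the footprint is deeper in condition b.
    """
    if profile_a.motif_id != profile_b.motif_id:
        raise ValueError("profiles are for different motifs")
    if profile_a.flank != profile_b.flank:
        raise ValueError("profiles use different flank sizes")
    delta = (
        footprint_depth(profile_b).depth - footprint_depth(profile_a).depth
    )
    return delta, profile_a, profile_b


def load_occurrences(path) -> dict[str, list[MotifOccurrence]]:
    """Read motif occurrences from BED6 (motif_id in the name column)."""
    out: dict[str, list[MotifOccurrence]] = {}
    for peak in read_intervals(path, dialect="bed"):
        out.setdefault(peak.id, []).append(
            MotifOccurrence(peak.id, peak.interval)
        )
    return out
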