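"""High-level amplicon calling from paired tumor/normal probe tracks.

The stages are: germline masking against the paired normal, running-median
smoothing, recursive binary segmentation, and thresholding of segment means
at the amplification cutoff (4.8 arbitrary copy-number units, the value-scale
equivalent of >7 DNA copies), so that broad polyploid gains are not called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .genome import (
    CytobandMap,
    GeneCatalog,
    GenomicInterval,
    chrom_sort_key,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

#: fixed critical values for accepting a segmentation split (z scale).
#: Not permutation-based: constants keep segmentation deterministic. They sit
#: above the empirical null maxima on smoothed noise tracks (~6.8 for single
#: splits, ~9.4 for the windowed carve-out scan, which searches many more
#: candidates), while real amplification events score z >~ 25.
SPLIT_Z_CRITICAL = 8.0
BUMP_Z_CRITICAL = 12.0


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class CallerConfig:
    """Amplicon caller policy.

    Only ``theta`` (the >4.8 arbitrary-unit amplification cutoff) is dictated
    by the measurement scale; the remaining knobs are caller policy:

    - ``smoothing_window``: running-median width in probes (odd).
    - ``min_probes``: minimum probes per segment and per reported amplicon.
    - ``merge_gap``: adjacent above-threshold segments closer than this many
      bp are merged (never across the p/q boundary).
    - ``germline_delta``: probes whose normal value deviates from diploid by
      more than this are treated as germline CNV and masked.
    - ``whole_chrom_fraction``: an amplicon spanning more than this fraction
      of its chromosome is flagged as a whole-chromosome suspect.
    """

    theta: float = 4.8
    smoothing_window: int = 5
    min_probes: int = 5
    merge_gap: int = 1_000_000
    germline_delta: float = 0.6
    whole_chrom_fraction: float = 0.9
    split_z: float = SPLIT_Z_CRITICAL
    bump_z: float = BUMP_Z_CRITICAL
    max_focal_probes: int = 120

    def __post_init__(self) -> None:
        if not self.theta > 2:
            raise CallingError("theta must exceed the diploid level 2")
        if self.smoothing_window % 2 != 1:
            raise CallingError("smoothing window must be odd")
        if self.min_probes < 1:
            raise CallingError("min_probes must be >= 1")


class ProbeTrack:
    """Per-sample probe positions and copy-number values in arbitrary units.

    Positions are strictly increasing within each chromosome; values are
    finite and non-negative (diploid = 2).
    """

    def __init__(self, sample: str, chrom, pos, value):
        self.sample = sample
        chrom = np.asarray(chrom, dtype=str)
        pos = np.asarray(pos, dtype=np.int64)
        value = np.asarray(value, dtype=np.float64)
        if not (len(chrom) == len(pos) == len(value)):
            raise CallingError("chrom/pos/value arrays differ in length")
        # normalize and rank per unique label only, then broadcast
        uniq, inverse = np.unique(chrom, return_inverse=True)
        norm = np.array([normalize_chrom(u) for u in uniq], dtype=object)
        keys = sorted(range(len(uniq)), key=lambda i: chrom_sort_key(norm[i]))
        rank_of = np.empty(len(uniq), dtype=np.int64)
        rank_of[keys] = np.arange(len(uniq))
        order = np.lexsort((pos, rank_of[inverse]))
        self.chrom = norm[inverse][order]
        self.pos = pos[order]
        self.value = value[order]
        self._index: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                self._index[str(self.chrom[start])] = slice(start, i)
                start = i
        for c, sl in self._index.items():
            p = self.pos[sl]
            if np.any(np.diff(p) <= 0):
                raise CallingError(f"{sample}: duplicate probe position on chrom {c}")
        if not np.all(np.isfinite(self.value)) or np.any(self.value < 0):
            raise CallingError(f"{sample}: values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._index)

    def per_chrom(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for c, sl in self._index.items():
            yield c, self.pos[sl], self.value[sl]

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sl = self._index[normalize_chrom(chrom)]
        return self.pos[sl], self.value[sl]

    def with_values(self, value: np.ndarray) -> "ProbeTrack":
        return ProbeTrack(self.sample, self.chrom, self.pos, value)


@dataclass(frozen=True)
class Segment:
    interval: GenomicInterval
    mean: float
    n_probes: int


@dataclass(frozen=True)
class Amplicon:
    """An amplified segment with genome annotation."""

    interval: GenomicInterval
    mean: float
    n_probes: int
    bands: tuple[str, ...] = ()
    genes: tuple[str, ...] = ()
    arms: tuple[str, ...] = ()
    whole_chrom_suspect: bool = False


def germline_mask(
    tumor: ProbeTrack, normal: ProbeTrack, delta: float = 0.6
) -> ProbeTrack:
    """Drop tumor probes at which the paired normal deviates from diploid.

    The two tracks must share an identical probe grid. Probes with
    ``|normal - 2| > delta`` (germline CNV, inherited in both samples) are
    removed from the tumor track; removal counts are logged.
    """
    if len(tumor) != len(normal):
        raise CallingError(
            f"probe grids differ in size ({len(tumor)} vs {len(normal)})"
        )
    same = (tumor.chrom == normal.chrom) & (tumor.pos == normal.pos)
    if not np.all(same):
        i = int(np.argmin(same))
        raise CallingError(
            "probe grids disagree at index "
            f"{i}: {tumor.chrom[i]}:{tumor.pos[i]} vs {normal.chrom[i]}:{normal.pos[i]}"
        )
    keep = np.abs(normal.value - 2.0) <= delta
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "%s: masked %d/%d probes as germline CNV (delta=%g)",
            tumor.sample, n_drop, len(tumor), delta,
        )
    return ProbeTrack(
        tumor.sample, tumor.chrom[keep], tumor.pos[keep], tumor.value[keep]
    )


def _running_median(x: np.ndarray, w: int) -> np.ndarray:
    n = len(x)
    if w == 1 or n == 0:
        return x.copy()
    h = w // 2
    out = np.empty_like(x)
    if n >= w:
        windows = np.lib.stride_tricks.sliding_window_view(x, w)
        out[h:n - h] = np.median(windows, axis=1)
    # edge windows are truncated, not padded
    for i in range(min(h, n)):
        out[i] = np.median(x[: i + h + 1])
        out[n - 1 - i] = np.median(x[max(0, n - 1 - i - h):])
    return out


def smooth(track: ProbeTrack, window: int = 5) -> ProbeTrack:
    """Per-chromosome running median with edge-truncated windows."""
    if window % 2 != 1:
        raise CallingError("smoothing window must be odd")
    values = track.value.copy()
    for c, sl in track._index.items():
        values[sl] = _running_median(track.value[sl], window)
    return track.with_values(values)


def _t_from_bss(x: np.ndarray, bss: float, n_groups: int = 2) -> float:
    """Mean-difference t-statistic from a between-group sum of squares.

    ``sqrt(bss)`` equals ``|mean difference| / sqrt(1/n1 + 1/n2)``; dividing
    by the pooled within-group standard deviation yields the two-sample
    t-statistic. Infinite when the split explains all variance (e.g. a
    noiseless step).
    """
    n = len(x)
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    within = max(ss_tot - bss, 0.0)
    if n <= n_groups:
        return np.inf
    s2 = within / (n - n_groups)
    if s2 <= 0:
        return np.inf if bss > 0 else 0.0
    return float(np.sqrt(bss / s2))


def _best_split(x: np.ndarray, min_probes: int) -> tuple[int, float] | None:
    """Best change-point of ``x`` by between-segment sum of squares.

    The leftmost split index ``k`` (left part ``x[:k]``) maximizing the
    between-segment sum of squares — equivalently minimizing the
    within-segment sum of squares — is returned together with the
    between-segment mean-difference t-statistic at that split (pooled
    within-segment variance).
    """
    n = len(x)
    if n < 2 * min_probes:
        return None
    csum = np.cumsum(x)
    total = csum[-1]
    k = np.arange(min_probes, n - min_probes + 1)
    mean_l = csum[k - 1] / k
    mean_r = (total - csum[k - 1]) / (n - k)
    bss = k * (n - k) / n * (mean_l - mean_r) ** 2
    i = int(np.argmax(bss))  # argmax takes the leftmost maximizer
    # guard against cumsum round-off on (near-)constant segments
    tol = 1e-9 * (1.0 + abs(float(x.mean())))
    if bss[i] <= 0 or abs(mean_l[i] - mean_r[i]) < tol:
        return None
    return int(k[i]), _t_from_bss(x, float(bss[i]))


def _best_bump(
    x: np.ndarray, min_probes: int, max_width: int
) -> tuple[int, int, float] | None:
    """Best interior window [i, i+w) by carve-out between-sum-of-squares.

    A short event in the middle of a long segment produces only a weak
    single-split statistic (either side of the split has nearly equal
    means), so when no single split fires we scan every window of width
    ``min_probes..max_width`` that leaves ``min_probes`` probes on both
    flanks and score mean(inside) vs mean(outside). Returns
    ``(i, w, z)`` for the best window; ties prefer the smaller width,
    then the leftmost start.
    """
    n = len(x)
    lo_w = min_probes
    hi_w = min(max_width, n - 2 * min_probes)
    if hi_w < lo_w:
        return None
    csum = np.concatenate(([0.0], np.cumsum(x)))
    total = csum[-1]
    best: tuple[float, int, int] | None = None
    for w in range(lo_w, hi_w + 1):
        starts_sum = csum[w:] - csum[:-w]
        mean_in = starts_sum / w
        mean_out = (total - starts_sum) / (n - w)
        b2 = w * (n - w) / n * (mean_in - mean_out) ** 2
        b2 = b2[min_probes: n - w - min_probes + 1]  # interior windows only
        if len(b2) == 0:
            continue
        j = int(np.argmax(b2))
        if best is None or b2[j] > best[0]:
            best = (float(b2[j]), min_probes + j, w)
    if best is None or best[0] <= 0:
        return None
    b2max, i, w = best
    mean_in = (csum[i + w] - csum[i]) / w
    mean_out = (total - (csum[i + w] - csum[i])) / (n - w)
    tol = 1e-9 * (1.0 + abs(float(x.mean())))
    if abs(mean_in - mean_out) < tol:
        return None
    return i, w, _t_from_bss(x, b2max)


def _segment_values(
    x: np.ndarray, min_probes: int, z_crit: float, bump_z: float,
    max_focal_probes: int,
) -> list[int]:
    """Recursive binary segmentation; returns sorted split indices."""
    splits: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        best = _best_split(x[lo:hi], min_probes)
        if best is not None and best[1] > z_crit:
            k = best[0]
            splits.append(lo + k)
            recurse(lo, lo + k)
            recurse(lo + k, hi)
            return
        bump = _best_bump(x[lo:hi], min_probes, max_focal_probes)
        if bump is not None and bump[2] > bump_z:
            i, w, _ = bump
            splits.extend([lo + i, lo + i + w])
            recurse(lo, lo + i)
            recurse(lo + i, lo + i + w)
            recurse(lo + i + w, hi)

    recurse(0, len(x))
    return sorted(splits)


def segment_track(
    track: ProbeTrack,
    min_probes: int = 5,
    z_crit: float = SPLIT_Z_CRITICAL,
    bump_z: float = BUMP_Z_CRITICAL,
    max_focal_probes: int = 120,
) -> list[Segment]:
    """Segment a (smoothed) track into mean-homogeneous runs per chromosome.

    Each accepted change-point maximizes the between-segment mean-difference
    statistic (scaled by the parent segment's standard deviation, so the
    chosen single split equally minimizes within-segment sum of squares);
    splits require ``min_probes`` probes on both sides and a statistic above
    ``z_crit``, ties going to the leftmost candidate. Interior focal events
    too short to move the single-split statistic are caught by the windowed
    carve-out scan (see :func:`_best_bump`). The returned segments cover
    every probe exactly once.
    """
    segments: list[Segment] = []
    for chrom, pos, val in track.per_chrom():
        cuts = [0] + _segment_values(val, min_probes, z_crit, bump_z,
                                     max_focal_probes) + [len(val)]
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            segments.append(Segment(
                GenomicInterval(chrom, int(pos[lo]), int(pos[hi - 1]) + 1),
                float(np.mean(val[lo:hi])),
                hi - lo,
            ))
    return segments


def _merge(a: Amplicon, b: Amplicon) -> Amplicon:
    n = a.n_probes + b.n_probes
    return Amplicon(
        GenomicInterval(a.interval.chrom, a.interval.start, b.interval.end),
        (a.mean * a.n_probes + b.mean * b.n_probes) / n,
        n,
    )


def call_amplicons(
    segments: Sequence[Segment],
    config: CallerConfig,
    cytobands: CytobandMap,
    catalog: GeneCatalog | None = None,
) -> list[Amplicon]:
    """Threshold, merge and annotate amplified segments for one sample.

    Segments with mean > ``theta`` and at least ``min_probes`` probes are
    kept; retained neighbours closer than ``merge_gap`` bp on the same arm
    are merged with probe-weighted means. Each amplicon is annotated with
    overlapping bands and genes plus its arm(s); one spanning more than
    ``whole_chrom_fraction`` of the chromosome is flagged but still reported.
    """
    kept = [
        Amplicon(s.interval, s.mean, s.n_probes)
        for s in sorted(segments, key=lambda s: (chrom_sort_key(s.interval.chrom),
                                                 s.interval.start))
        if s.mean > config.theta and s.n_probes >= config.min_probes
    ]
    merged: list[Amplicon] = []
    for amp in kept:
        if merged:
            prev = merged[-1]
            same_chrom = prev.interval.chrom == amp.interval.chrom
            if (
                same_chrom
                and amp.interval.start - prev.interval.end < config.merge_gap
                and cytobands.arms_of(prev.interval)
                == cytobands.arms_of(amp.interval)
                and len(cytobands.arms_of(amp.interval)) == 1
            ):
                merged[-1] = _merge(prev, amp)
                continue
        merged.append(amp)

    out = []
    for amp in merged:
        iv = amp.interval
        out.append(replace(
            amp,
            bands=tuple(cytobands.bands_overlapping(iv)),
            genes=tuple(catalog.genes_overlapping(iv)) if catalog else (),
            arms=cytobands.arms_of(iv),
            whole_chrom_suspect=(
                iv.length > config.whole_chrom_fraction
                * cytobands.chrom_length(iv.chrom)
            ),
        ))
    return out


def call_pair(
    tumor: ProbeTrack,
    normal: ProbeTrack,
    config: CallerConfig,
    cytobands: CytobandMap,
    catalog: GeneCatalog | None = None,
) -> tuple[list[Segment], list[Amplicon]]:
    """Full caller pipeline for one tumor/normal pair."""
    masked = germline_mask(tumor, normal, config.germline_delta)
    smoothed = smooth(masked, config.smoothing_window)
    segments = segment_track(smoothed, config.min_probes, config.split_z,
                             config.bump_z, config.max_focal_probes)
    return segments, call_amplicons(segments, config, cytobands, catalog)
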