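"""Gain/loss calling, candidate-run merging, and candidate-CNV extraction.

A segment is a gain (loss) when its mean log-ratio lies at least one unscaled
median absolute deviation above (below) the array's median probe log-ratio.
Consecutive same-sign calls are merged while the combined span stays under the
2.3 Mb cap; a gain/loss of span up to 2.3 Mb with at least one normal flank,
off the sex chromosomes and outside the physiological exclusion regions, is a
candidate germline variant — the unit the classifiers operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome_io import (
    GenomeAnnotation,
    ProbeProfile,
    RawSegment,
    ValidationError,
    chromosome_sort_key,
)

log = logging.getLogger(__name__)

GAIN = "gain"
LOSS = "loss"
NORMAL = "normal"
CHROM_EDGE = "chromosome_edge"

#: Maximum genomic span of a candidate CNV, in bases.
MAX_CANDIDATE_SPAN = 2_300_000
SEX_CHROMOSOMES = frozenset({"X", "Y"})


def unscaled_mad(values: np.ndarray, center: Optional[float] = None) -> float:
    """Median absolute deviation with no normal-consistency scaling."""
    values = np.asarray(values, dtype=float)
    if center is None:
        center = float(np.median(values))
    return float(np.median(np.abs(values - center)))


@dataclass(frozen=True)
class ArrayStats:
    """Robust noise statistics of one array.

    ``array_median``/``array_mad`` summarise raw probe log-ratios and set the
    gain/loss calling threshold; ``residual_mad`` summarises probe-minus-
    segment-mean residuals and normalises the height and break predictors.
    """

    sample_id: str
    array_median: float
    array_mad: float
    residual_mad: float

    def __post_init__(self):
        if self.array_mad < 0 or self.residual_mad < 0:
            raise ValidationError("MAD statistics must be non-negative")


@dataclass(frozen=True)
class CalledSegment(RawSegment):
    status: str = NORMAL
    merged_from: int = 1


@dataclass(frozen=True)
class CandidateCNV:
    """A gain/loss segment passing the candidacy rules; the unit of classification."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    n_markers: int
    mean: float
    status: str
    left_flank_status: str
    right_flank_status: str
    merged_from: int = 1

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def sign(self) -> int:
        return 1 if self.status == GAIN else -1

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.chromosome, self.start, self.end)


def compute_array_stats(
    profile: ProbeProfile, segments: Sequence[RawSegment], strict: bool = False
) -> ArrayStats:
    """Median/MAD of probe log-ratios plus the MAD of probe-minus-segment residuals."""
    if profile.n_probes == 0:
        raise ValidationError(f"{profile.sample_id}: empty profile")
    lr = profile.log_ratios
    med = float(np.median(lr))
    mad = unscaled_mad(lr, med)

    residuals = []
    unassigned = 0
    by_chrom: dict[str, list[RawSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        pos, vals = profile.chrom_data(chrom)
        if len(pos) == 0:
            continue
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        means = np.array([s.mean for s in segs])
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        unassigned += int((~ok).sum())
        residuals.append(vals[ok] - means[idx[ok]])
    covered = {c for c in by_chrom}
    for chrom in profile.chromosome_names:
        if chrom not in covered:
            unassigned += len(profile.chrom_data(chrom)[0])
    if unassigned:
        msg = f"{profile.sample_id}: {unassigned} probes fall on no segment"
        if strict:
            raise ValidationError(msg)
        log.warning(msg)
    res = np.concatenate(residuals) if residuals else np.empty(0)
    if len(res) == 0:
        raise ValidationError(f"{profile.sample_id}: no probe is assignable to a segment")
    return ArrayStats(
        sample_id=profile.sample_id,
        array_median=med,
        array_mad=mad,
        residual_mad=unscaled_mad(res),
    )


def call_status(mean: float, stats: ArrayStats) -> str:
    diff = mean - stats.array_median
    if stats.array_mad == 0:
        # Degenerate noise: any departure from the median is a call.
        return GAIN if diff > 0 else LOSS if diff < 0 else NORMAL
    if diff >= stats.array_mad:
        return GAIN
    if diff <= -stats.array_mad:
        return LOSS
    return NORMAL


def call_segments(
    segments: Sequence[RawSegment], stats: ArrayStats
) -> list[CalledSegment]:
    """Assign gain/loss/normal status to each segment; boundary means are calls."""
    if stats.array_mad == 0 and any(s.mean != stats.array_median for s in segments):
        log.warning("%s: array MAD is 0; calling degenerates to sign of mean", stats.sample_id)
    return [
        CalledSegment(
            sample_id=s.sample_id,
            chromosome=s.chromosome,
            start=s.start,
            end=s.end,
            n_markers=s.n_markers,
            mean=s.mean,
            status=call_status(s.mean, stats),
            merged_from=getattr(s, "merged_from", 1),
        )
        for s in segments
    ]


def merge_candidate_runs(
    called: Sequence[CalledSegment], max_span: int = MAX_CANDIDATE_SPAN
) -> list[CalledSegment]:
    """Merge maximal runs of consecutive same-status gains (losses) under the span cap.

    The merged segment spans the run, carries the marker-count-weighted mean,
    and records the member count in ``merged_from``.  Runs whose combined span
    is at or over the cap are left unmerged.  Idempotent.
    """
    out: list[CalledSegment] = []
    by_chrom: dict[str, list[CalledSegment]] = {}
    for seg in called:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        segs = sorted(by_chrom[chrom], key=lambda s: s.start)
        i = 0
        while i < len(segs):
            seg = segs[i]
            if seg.status == NORMAL:
                out.append(seg)
                i += 1
                continue
            j = i
            while j + 1 < len(segs) and segs[j + 1].status == seg.status:
                j += 1
            run = segs[i : j + 1]
            span = run[-1].end - run[0].start
            if len(run) > 1 and span < max_span:
                markers = np.array([s.n_markers for s in run])
                means = np.array([s.mean for s in run])
                out.append(
                    CalledSegment(
                        sample_id=seg.sample_id,
                        chromosome=chrom,
                        start=run[0].start,
                        end=run[-1].end,
                        n_markers=int(markers.sum()),
                        mean=float(np.average(means, weights=markers)),
                        status=seg.status,
                        merged_from=int(sum(s.merged_from for s in run)),
                    )
                )
            else:
                out.extend(run)
            i = j + 1
    return out


def extract_candidates(
    called: Sequence[CalledSegment],
    annotation: GenomeAnnotation,
    max_span: int = MAX_CANDIDATE_SPAN,
) -> list[CandidateCNV]:
    """Emit every gain/loss of span <= cap with a normal flank, subject to exclusions.

    Chromosome ends do not count as normal flanks; X/Y and anything intersecting
    a physiological exclusion region (>= 1 bp) are dropped.  Merging is assumed
    to have been applied already.
    """
    candidates: list[CandidateCNV] = []
    by_chrom: dict[str, list[CalledSegment]] = {}
    for seg in called:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        if chrom in SEX_CHROMOSOMES:
            continue
        segs = sorted(by_chrom[chrom], key=lambda s: s.start)
        for i, seg in enumerate(segs):
            if seg.status == NORMAL:
                continue
            if seg.span > max_span:
                continue
            left = segs[i - 1].status if i > 0 else CHROM_EDGE
            right = segs[i + 1].status if i + 1 < len(segs) else CHROM_EDGE
            if left != NORMAL and right != NORMAL:
                continue
            if annotation.overlaps_physiological(chrom, seg.start, seg.end):
                continue
            candidates.append(
                CandidateCNV(
                    sample_id=seg.sample_id,
                    chromosome=chrom,
                    start=seg.start,
                    end=seg.end,
                    n_markers=seg.n_markers,
                    mean=seg.mean,
                    status=seg.status,
                    left_flank_status=left,
                    right_flank_status=right,
                    merged_from=seg.merged_from,
                )
            )
    return candidates


@dataclass
class SampleCalls:
    """Everything the downstream stages need about one called sample."""

    sample_id: str
    profile: ProbeProfile
    stats: ArrayStats
    called: list[CalledSegment]  # after merging
    candidates: list[CandidateCNV]


def call_sample(
    profile: ProbeProfile,
    segments: Sequence[RawSegment],
    annotation: GenomeAnnotation,
    max_span: int = MAX_CANDIDATE_SPAN,
) -> SampleCalls:
    """Run stats -> call -> merge -> extract for one sample."""
    stats = compute_array_stats(profile, segments)
    called = merge_candidate_runs(call_segments(segments, stats), max_span)
    candidates = extract_candidates(called, annotation, max_span)
    return SampleCalls(
        sample_id=profile.sample_id,
        profile=profile,
        stats=stats,
        called=called,
        candidates=candidates,
    )


def noncandidate_aberrant(
    called: Sequence[CalledSegment], candidates: Sequence[CandidateCNV]
) -> list[CalledSegment]:
    """Gain/loss segments that failed candidacy (used by the CNA-overlap predictor)."""
    taken = {(c.chromosome, c.start, c.end) for c in candidates}
    return [
        s
        for s in called
        if s.status in (GAIN, LOSS) and (s.chromosome, s.start, s.end) not in taken
    ]
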