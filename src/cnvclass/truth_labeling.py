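"""Paired-normal truth labeling: segment overlap or the conditional segmentation test.

A tumor candidate is a true germline CNV when the matched normal shows the same
event: either the normal's own segmentation called a same-sign gain/loss that
overlaps the candidate, or the normal probe log-ratios under the candidate are
significantly extreme by a conditional permutation test.  Everything else is a
somatic CNA.

The permutation test conditions on the tumor's segmentation: the null pool is
the normal-sample log-ratios lying within the candidate and its two flanking
tumor segments.  ``k`` values are drawn without replacement ``R`` times; the
candidate's normal mean must both clear the normal array's gain/loss threshold
and be more extreme than the simulated means in at least a fraction ``1-alpha``
of draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .calling import GAIN, LOSS, ArrayStats, CalledSegment, CandidateCNV
from .genome_io import ProbeProfile, ValidationError

CNV = "CNV"
CNA = "CNA"

EVIDENCE_SEGMENT = "segment_overlap"
EVIDENCE_PERMUTATION = "permutation"
EVIDENCE_NONE = "none"


@dataclass(frozen=True)
class PermutationTestResult:
    k: int
    mu: float
    n_draws: int
    p_extreme: float
    threshold_pass: bool
    declared: bool


@dataclass(frozen=True)
class TruthLabel:
    label: str  # CNV or CNA
    evidence: str

    def __post_init__(self):
        if (self.label == CNV) != (self.evidence != EVIDENCE_NONE):
            raise ValidationError("CNV labels require evidence; CNA labels forbid it")


def match_to_normal(
    candidate: CandidateCNV, normal_called: Sequence[CalledSegment]
) -> bool:
    """True iff the candidate overlaps a same-sign called gain/loss in the normal."""
    want = GAIN if candidate.status == GAIN else LOSS
    for seg in normal_called:
        if seg.chromosome != candidate.chromosome or seg.status != want:
            continue
        if seg.start < candidate.end and candidate.start < seg.end:
            return True
    return False


def _flanking_interval(
    candidate: CandidateCNV, tumor_called: Sequence[CalledSegment]
) -> tuple[int, int]:
    """Genomic interval of the candidate plus its immediate tumor neighbors."""
    segs = sorted(
        (s for s in tumor_called if s.chromosome == candidate.chromosome),
        key=lambda s: s.start,
    )
    lo, hi = candidate.start, candidate.end
    left = [s for s in segs if s.end <= candidate.start]
    right = [s for s in segs if s.start >= candidate.end]
    if left:
        lo = left[-1].start
    if right:
        hi = right[0].end
    return lo, hi


def _draw_means(pool: np.ndarray, k: int, R: int, rng: np.random.Generator) -> np.ndarray:
    """Means of R size-k draws without replacement from the pool (vectorised)."""
    keys = rng.random((R, len(pool)))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return pool[idx].mean(axis=1)


def conditional_segmentation_test(
    candidate: CandidateCNV,
    tumor_called: Sequence[CalledSegment],
    normal_profile: ProbeProfile,
    normal_stats: ArrayStats,
    R: int = 1000,
    alpha: float = 0.01,
    rng_seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PermutationTestResult:
    """Permutation test of the normal signal under a tumor candidate.

    Declares a CNV iff the mean ``mu`` of the k in-candidate normal log-ratios
    clears the normal array's gain/loss threshold in the candidate's direction
    and fewer than ``alpha`` of the R simulated means are at least as extreme
    (ties count as extreme).
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    cand_values = normal_profile.values_in(
        candidate.chromosome, candidate.start, candidate.end
    )
    k = len(cand_values)
    if k == 0:
        raise ValidationError(
            f"candidate {candidate.chromosome}:{candidate.start}-{candidate.end} "
            "covers no probe in the normal profile"
        )
    lo, hi = _flanking_interval(candidate, tumor_called)
    pool = normal_profile.values_in(candidate.chromosome, lo, hi)
    if len(pool) < k:
        raise ValidationError(
            f"permutation pool ({len(pool)} probes) smaller than candidate ({k} probes)"
        )
    mu = float(cand_values.mean())
    s = 1.0 if candidate.status == GAIN else -1.0
    mu_star = _draw_means(np.asarray(pool, dtype=float), k, R, rng)
    p_extreme = float(np.mean(s * mu_star >= s * mu))
    threshold_pass = s * (mu - normal_stats.array_median) >= normal_stats.array_mad
    declared = bool(threshold_pass and p_extreme < alpha)
    return PermutationTestResult(
        k=k,
        mu=mu,
        n_draws=R,
        p_extreme=p_extreme,
        threshold_pass=bool(threshold_pass),
        declared=declared,
    )


def candidate_rng(rng_seed: int, candidate: CandidateCNV) -> np.random.Generator:
    """Per-candidate stream so relabeling is order-independent."""
    entropy = [
        int(rng_seed) & 0x7FFFFFFF,
        zlib.crc32(candidate.sample_id.encode()),
        zlib.crc32(candidate.chromosome.encode()),
        int(candidate.start),
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def label_candidates(
    candidates: Sequence[CandidateCNV],
    tumor_called: Sequence[CalledSegment],
    normal_profile: ProbeProfile,
    normal_called: Sequence[CalledSegment],
    normal_stats: ArrayStats,
    R: int = 1000,
    alpha: float = 0.01,
    rng_seed: int = 0,
) -> list[TruthLabel]:
    """Label each candidate CNV/CNA from the paired normal.

    Segment overlap short-circuits the permutation test; per-candidate RNG
    streams are derived from ``rng_seed`` and the candidate's identity.
    """
    labels = []
    for cand in candidates:
        if match_to_normal(cand, normal_called):
            labels.append(TruthLabel(CNV, EVIDENCE_SEGMENT))
            continue
        result = conditional_segmentation_test(
            cand,
            tumor_called,
            normal_profile,
            normal_stats,
            R=R,
            alpha=alpha,
            rng=candidate_rng(rng_seed, cand),
        )
        if result.declared:
            labels.append(TruthLabel(CNV, EVIDENCE_PERMUTATION))
        else:
            labels.append(TruthLabel(CNA, EVIDENCE_NONE))
    return labels
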