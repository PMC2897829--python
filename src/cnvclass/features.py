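"""The 16 candidate predictors plus the two Database scores.

Demographic features describe the candidate itself (length, height relative to
array noise, flank structure, proximity to centromere/telomere/segmental
duplications).  Cohort features compare the candidate against the other
patients' candidates and non-candidate aberrations.  Spatial features look at
the rest of the candidate's own chromosome.  The Database score is, averaged
over the candidate's probes, the number of distinct catalogued germline
variants covering each probe; Database score II averages the total number of
individuals reported to carry such variants.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import (
    NORMAL,
    ArrayStats,
    CalledSegment,
    CandidateCNV,
    SampleCalls,
    noncandidate_aberrant,
)
from .genome_io import DGVRecord, GenomeAnnotation, ProbeProfile, ValidationError

log = logging.getLogger(__name__)

CENTROMERE_WINDOW = 2_000_000
TELOMERE_WINDOW = 2_000_000
PROXIMITY_WINDOW = 500_000

PATTERN_GG = "GG"
PATTERN_LL = "LL"
PATTERN_GL = "GL"
PATTERN_NONE = "None"

#: Fixed column order of the assembled feature matrix.
FEATURE_COLUMNS = [
    "length_bp",
    "segmental_duplication",
    "near_centromere",
    "near_telomere",
    "sign",
    "height",
    "relative_height",
    "break_score",
    "surrounded_by_normals",
    "overlap_pattern",
    "overlap_pct",
    "matching_bkpt_pct",
    "close_to_other_candidates",
    "pct_normal",
    "ds_other_candidates",
    "overlap_with_cnas",
    "database_score",
    "database_score_ii",
]


class ProbeVariantCounts:
    """Per-probe counts of covering variant records and reported individuals."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (positions, n_variants, n_individuals)
        self._data = data

    def at(self, chrom: str, position: int) -> tuple[int, int]:
        entry = self._data.get(chrom)
        if entry is None:
            return (0, 0)
        pos, nv, ni = entry
        i = np.searchsorted(pos, position)
        if i >= len(pos) or pos[i] != position:
            return (0, 0)
        return (int(nv[i]), int(ni[i]))

    def slice(self, chrom: str, start: int, end: int):
        """(n_variants, n_individuals) arrays for probes with start <= pos < end."""
        entry = self._data.get(chrom)
        if entry is None:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        pos, nv, ni = entry
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return nv[i:j], ni[i:j]


def probe_variant_counts(
    dgv: Sequence[DGVRecord], probes: ProbeProfile
) -> ProbeVariantCounts:
    """Count, per probe, the distinct variants containing it and their carriers.

    Containment is half-open in internal coordinates: a probe exactly at a
    record's converted end lies outside.  Records lacking an individual count
    contribute 0 to the carrier sum.
    """
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[DGVRecord]] = {}
    for rec in dgv:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    for chrom in probes.chromosome_names:
        pos, _ = probes.chrom_data(chrom)
        n = len(pos)
        dv = np.zeros(n + 1, dtype=np.int64)
        di = np.zeros(n + 1, dtype=np.int64)
        for rec in by_chrom.get(chrom, ()):
            i = np.searchsorted(pos, rec.start, side="left")
            j = np.searchsorted(pos, rec.end, side="left")
            if j > i:
                dv[i] += 1
                dv[j] -= 1
                ind = rec.n_individuals or 0
                di[i] += ind
                di[j] -= ind
        data[chrom] = (pos, np.cumsum(dv[:-1]), np.cumsum(di[:-1]))
    return ProbeVariantCounts(data)


def database_score(candidate: CandidateCNV, counts: ProbeVariantCounts) -> float:
    """Mean number of covering variants over the candidate's probes."""
    nv, _ = counts.slice(candidate.chromosome, candidate.start, candidate.end)
    if len(nv) == 0:
        raise ValidationError(
            f"candidate {candidate.chromosome}:{candidate.start}-{candidate.end} has no probes"
        )
    return float(nv.mean())


def database_score_ii(candidate: CandidateCNV, counts: ProbeVariantCounts) -> float:
    """Mean number of reported carrier individuals over the candidate's probes."""
    nv, ni = counts.slice(candidate.chromosome, candidate.start, candidate.end)
    if len(nv) == 0:
        raise ValidationError(
            f"candidate {candidate.chromosome}:{candidate.start}-{candidate.end} has no probes"
        )
    return float(ni.mean())


def _ratio(numerator: float, denom: float) -> float:
    if denom > 0:
        return numerator / denom
    return 0.0 if numerator == 0 else math.inf


def demographic_features(
    candidate: CandidateCNV,
    called: Sequence[CalledSegment],
    stats: ArrayStats,
    annotation: GenomeAnnotation,
    centromere_window: int = CENTROMERE_WINDOW,
    telomere_window: int = TELOMERE_WINDOW,
) -> dict:
    """Length, annotation proximity, sign, noise-normalised height and break."""
    chrom = candidate.chromosome
    length = annotation.chromosome_lengths.get(chrom)

    near_cent = 0
    cent = annotation.centromere(chrom)
    if cent is not None:
        cs, ce = cent
        for endpoint in (candidate.start, candidate.end):
            if cs - centromere_window <= endpoint <= ce + centromere_window:
                near_cent = 1
                break

    near_tel = 0
    if candidate.start <= telomere_window:
        near_tel = 1
    elif length is not None and candidate.end >= length - telomere_window:
        near_tel = 1

    segs = sorted(
        (s for s in called if s.chromosome == chrom), key=lambda s: s.start
    )
    left = next((s for s in reversed(segs) if s.end <= candidate.start), None)
    right = next((s for s in segs if s.start >= candidate.end), None)
    if left is None or right is None:
        log.debug(
            "%s %s:%d-%d: missing neighbor at chromosome edge; break set to 0",
            candidate.sample_id, chrom, candidate.start, candidate.end,
        )
        break_score = 0.0
    else:
        break_score = _ratio(abs(left.mean - right.mean), stats.residual_mad)

    height = abs(candidate.mean)
    return {
        "length_bp": candidate.span,
        "segmental_duplication": int(
            annotation.overlaps_segdup(chrom, candidate.start, candidate.end)
        ),
        "near_centromere": near_cent,
        "near_telomere": near_tel,
        "sign": candidate.sign,
        "height": height,
        "relative_height": _ratio(height, stats.residual_mad),
        "break_score": break_score,
        "surrounded_by_normals": int(
            candidate.left_flank_status == NORMAL
            and candidate.right_flank_status == NORMAL
        ),
    }


def _intersects(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def cohort_features(
    candidate: CandidateCNV,
    cohort_candidates: Mapping[str, Sequence[CandidateCNV]],
    cohort_noncandidates: Mapping[str, Sequence[CalledSegment]],
) -> dict:
    """Overlap pattern/percentages against the other patients in the cohort.

    With a cohort of one patient the denominators vanish; all values are zero
    / ``None`` and a warning is logged.
    """
    others = [s for s in cohort_candidates if s != candidate.sample_id]
    if not others:
        log.warning("cohort of one patient: cohort features are degenerate zeros")
        return {
            "overlap_pattern": PATTERN_NONE,
            "overlap_pct": 0.0,
            "matching_bkpt_pct": 0.0,
            "overlap_with_cnas": 0,
        }

    n_other = len(others)
    overlapping_patients = 0
    matching_patients = 0
    cna_patients = 0
    signs: set[int] = set()
    patients_with_overlap: set[str] = set()
    own_bkpts = {candidate.start, candidate.end}
    for other in others:
        has_overlap = False
        has_match = False
        for cand in cohort_candidates.get(other, ()):
            if cand.chromosome != candidate.chromosome:
                continue
            if _intersects(cand.start, cand.end, candidate.start, candidate.end):
                has_overlap = True
                signs.add(cand.sign)
                patients_with_overlap.add(other)
            if own_bkpts & {cand.start, cand.end}:
                has_match = True
        overlapping_patients += has_overlap
        matching_patients += has_match
        for seg in cohort_noncandidates.get(other, ()):
            if (
                seg.chromosome == candidate.chromosome
                and seg.status == candidate.status
                and _intersects(seg.start, seg.end, candidate.start, candidate.end)
            ):
                cna_patients += 1
                break

    if not signs:
        pattern = PATTERN_NONE
    elif signs == {1}:
        pattern = PATTERN_GG
    elif signs == {-1}:
        pattern = PATTERN_LL
    else:
        pattern = PATTERN_GL

    return {
        "overlap_pattern": pattern,
        "overlap_pct": overlapping_patients / n_other,
        "matching_bkpt_pct": matching_patients / n_other,
        "overlap_with_cnas": cna_patients,
    }


def spatial_features(
    candidate: CandidateCNV,
    same_patient_candidates: Sequence[CandidateCNV],
    called_chromosome_segments: Sequence[CalledSegment],
    per_candidate_database_scores: Mapping[tuple, float],
    proximity_window: int = PROXIMITY_WINDOW,
) -> dict:
    """Same-chromosome context: nearby candidates, normal fraction, peer DGV scores."""
    chrom = candidate.chromosome
    peers = [
        c
        for c in same_patient_candidates
        if c.chromosome == chrom and c.key != candidate.key
    ]

    close = 0
    for peer in peers:
        gap = max(peer.start - candidate.end, candidate.start - peer.end, 0)
        if gap <= proximity_window:
            close = 1
            break

    chrom_segs = [s for s in called_chromosome_segments if s.chromosome == chrom]
    total = sum(s.n_markers for s in chrom_segs)
    normal = sum(s.n_markers for s in chrom_segs if s.status == NORMAL)
    pct_normal = normal / total if total else 0.0

    peer_scores = [per_candidate_database_scores[c.key] for c in peers]
    ds_other = float(np.mean(peer_scores)) if peer_scores else 0.0

    return {
        "close_to_other_candidates": close,
        "pct_normal": pct_normal,
        "ds_other_candidates": ds_other,
    }


def build_feature_matrix(
    samples: Mapping[str, SampleCalls],
    dgv: Sequence[DGVRecord],
    annotation: GenomeAnnotation,
    centromere_window: int = CENTROMERE_WINDOW,
    telomere_window: int = TELOMERE_WINDOW,
    proximity_window: int = PROXIMITY_WINDOW,
) -> pd.DataFrame:
    """One complete feature row per candidate across the cohort.

    Returns a DataFrame with identity columns (sample, chromosome, start, end,
    status) followed by :data:`FEATURE_COLUMNS`, sorted by candidate identity so
    the result is independent of the mapping's iteration order.
    """
    cohort_candidates = {s: calls.candidates for s, calls in samples.items()}
    cohort_noncandidates = {
        s: noncandidate_aberrant(calls.called, calls.candidates)
        for s, calls in samples.items()
    }

    scores: dict[tuple, tuple[float, float]] = {}
    for s, calls in samples.items():
        counts = probe_variant_counts(dgv, calls.profile)
        for cand in calls.candidates:
            scores[cand.key] = (
                database_score(cand, counts),
                database_score_ii(cand, counts),
            )
    ds_map = {k: v[0] for k, v in scores.items()}

    rows = []
    for s in sorted(samples):
        calls = samples[s]
        for cand in calls.candidates:
            row = {
                "sample": cand.sample_id,
                "chromosome": cand.chromosome,
                "start": cand.start,
                "end": cand.end,
                "status": cand.status,
            }
            row.update(
                demographic_features(
                    cand, calls.called, calls.stats, annotation,
                    centromere_window, telomere_window,
                )
            )
            row.update(
                cohort_features(cand, cohort_candidates, cohort_noncandidates)
            )
            row.update(
                spatial_features(
                    cand, calls.candidates, calls.called, ds_map, proximity_window
                )
            )
            row["database_score"], row["database_score_ii"] = scores[cand.key]
            rows.append(row)

    df = pd.DataFrame(
        rows, columns=["sample", "chromosome", "start", "end", "status"] + FEATURE_COLUMNS
    )
    if len(df):
        numeric = df[[c for c in FEATURE_COLUMNS if c != "overlap_pattern"]]
        bad = numeric.isna()
        if bad.any().any():
            r = int(np.flatnonzero(bad.any(axis=1).to_numpy())[0])
            feats = list(numeric.columns[bad.iloc[r]])
            raise ValidationError(
                f"undefined feature(s) {feats} for candidate "
                f"{df.iloc[r]['sample']} {df.iloc[r]['chromosome']}:"
                f"{df.iloc[r]['start']}-{df.iloc[r]['end']}"
            )
        df = df.sort_values(["sample", "chromosome", "start", "end"]).reset_index(drop=True)
    return df


def encode_features(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix: one-hot the overlap pattern (baseline ``None``)."""
    X = df[[c for c in FEATURE_COLUMNS if c != "overlap_pattern"]].copy()
    for level in (PATTERN_GG, PATTERN_LL, PATTERN_GL):
        X[f"overlap_pattern_{level}"] = (df["overlap_pattern"] == level).astype(int)
    return X.astype(float)
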