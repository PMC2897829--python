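"""Synthetic paired tumor/normal cohorts with oracle segmentations and a toy DGV.

The generator plants three kinds of events on a shared probe grid: germline
CNV loci (present in both tumor and normal of carrier patients, each with a
population frequency), recurrent somatic CNA loci and private CNAs (tumor
only), plus optional reference-sample CNVs that appear in every array because
the common reference carries them.  Probe log-ratios are the sum of active
event shifts and Gaussian noise, with a small rate of isolated outlier spikes.
Instead of running a real segmenter, the oracle segmentation places breakpoints
at the true event boundaries, optionally jittered by a few probes per sample to
emulate segmentation breakpoint error; real CBS/GLAD output can be substituted
through the SEG reader at any time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .calling import MAX_CANDIDATE_SPAN
from .genome_io import (
    DGVRecord,
    GenomeAnnotation,
    ProbeProfile,
    RawSegment,
    ValidationError,
    write_bed,
    write_chromosome_lengths,
    write_dgv,
    write_probe_profiles,
    write_seg,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Locus:
    """A plantable event: interval, carrier frequency, sign, and log-ratio shift."""

    chromosome: str
    start: int
    end: int
    frequency: float
    sign: int
    mean_shift: float


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_patients: int
    chromosomes: dict[str, int]
    probe_spacing: int = 9_000  # AG244-like density
    cnv_loci: list[Locus] = field(default_factory=list)
    cna_recurrent_loci: list[Locus] = field(default_factory=list)
    private_cna_rate: float = 3.0  # expected events per patient
    private_cna_length: tuple[int, int] = (50_000, 3_000_000)
    noise_sd: float = 0.12
    outlier_rate: float = 0.002
    breakpoint_jitter_probes: int = 0
    reference_cnv_loci: list[Locus] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for locus in self.cnv_loci + self.cna_recurrent_loci + self.reference_cnv_loci:
            if not 0.0 <= locus.frequency <= 1.0:
                raise ValidationError(f"locus frequency {locus.frequency} outside [0, 1]")
            length = self.chromosomes.get(locus.chromosome)
            if length is None or locus.start < 0 or locus.end > length:
                raise ValidationError(
                    f"locus {locus.chromosome}:{locus.start}-{locus.end} outside chromosome bounds"
                )
        for locus in self.cnv_loci + self.reference_cnv_loci:
            if locus.end - locus.start > MAX_CANDIDATE_SPAN:
                raise ValidationError("germline CNV loci must not exceed the 2.3 Mb regime")


@dataclass(frozen=True)
class GroundTruthEvent:
    patient: str
    chromosome: str
    start: int
    end: int
    kind: str  # CNV or CNA
    sign: int
    present_in_normal: bool


@dataclass
class Patient:
    patient_id: str
    tumor: ProbeProfile
    normal: ProbeProfile
    tumor_segments: list[RawSegment]
    normal_segments: list[RawSegment]


@dataclass
class Cohort:
    spec: CohortSpec
    patients: list[Patient]
    ground_truth: list[GroundTruthEvent]


def _probe_grid(spec: CohortSpec) -> dict[str, np.ndarray]:
    return {
        chrom: np.arange(spec.probe_spacing // 2, length, spec.probe_spacing, dtype=np.int64)
        for chrom, length in spec.chromosomes.items()
    }


def _resolve_overlaps(events: list[tuple[Locus, str]]) -> list[tuple[Locus, str]]:
    """Drop later-listed events that intersect an earlier kept one on the same chromosome."""
    kept: list[tuple[Locus, str]] = []
    trees: dict[str, IntervalTree] = {}
    for locus, kind in events:
        tree = trees.setdefault(locus.chromosome, IntervalTree())
        if tree.overlap(locus.start, locus.end):
            log.debug("dropping overlapping planted event %s:%d-%d", locus.chromosome,
                      locus.start, locus.end)
            continue
        tree.addi(locus.start, locus.end)
        kept.append((locus, kind))
    return kept


def _jitter_boundary(
    index: int, n_probes: int, jitter: int, rng: np.random.Generator
) -> int:
    if jitter <= 0:
        return index
    return int(np.clip(index + rng.integers(-jitter, jitter + 1), 0, n_probes))


def _segment_sample(
    profile: ProbeProfile,
    events: Sequence[Locus],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> list[RawSegment]:
    """Oracle segmentation: event-boundary probe indices (jittered), means from data."""
    segments: list[RawSegment] = []
    by_chrom: dict[str, list[Locus]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chromosome, []).append(ev)
    for chrom, length in spec.chromosomes.items():
        pos, vals = profile.chrom_data(chrom)
        n = len(pos)
        if n == 0:
            continue
        cut_indices = {0, n}
        for ev in sorted(by_chrom.get(chrom, ()), key=lambda e: e.start):
            i = int(np.searchsorted(pos, ev.start, side="left"))
            j = int(np.searchsorted(pos, ev.end, side="left"))
            cut_indices.add(_jitter_boundary(i, n, spec.breakpoint_jitter_probes, rng))
            cut_indices.add(_jitter_boundary(j, n, spec.breakpoint_jitter_probes, rng))
        cuts = sorted(cut_indices)
        for a, b in zip(cuts, cuts[1:]):
            if b <= a:
                continue
            start = 0 if a == 0 else int((pos[a - 1] + pos[a]) // 2)
            end = length if b == n else int((pos[b - 1] + pos[b]) // 2)
            segments.append(
                RawSegment(
                    sample_id=profile.sample_id,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    n_markers=b - a,
                    mean=float(vals[a:b].mean()),
                )
            )
    return segments


def _build_profile(
    sample_id: str,
    grid: dict[str, np.ndarray],
    events: Sequence[Locus],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> ProbeProfile:
    chroms, positions, values = [], [], []
    for chrom in spec.chromosomes:
        pos = grid[chrom]
        lr = rng.normal(0.0, spec.noise_sd, size=len(pos)) if spec.noise_sd > 0 else np.zeros(len(pos))
        for ev in events:
            if ev.chromosome != chrom:
                continue
            mask = (pos >= ev.start) & (pos < ev.end)
            lr[mask] += ev.mean_shift
        if spec.outlier_rate > 0 and spec.noise_sd > 0:
            spikes = rng.random(len(pos)) < spec.outlier_rate
            lr[spikes] += rng.choice([-1.0, 1.0], size=int(spikes.sum())) * 5 * spec.noise_sd
        chroms.extend([chrom] * len(pos))
        positions.append(pos)
        values.append(lr)
    return ProbeProfile(
        sample_id=sample_id,
        chromosomes=np.array(chroms, dtype=object),
        positions=np.concatenate(positions),
        log_ratios=np.concatenate(values),
    )


def _private_cnas(spec: CohortSpec, rng: np.random.Generator) -> list[Locus]:
    chrom_names = list(spec.chromosomes)
    lengths = np.array([spec.chromosomes[c] for c in chrom_names], dtype=float)
    weights = lengths / lengths.sum()
    out = []
    for _ in range(rng.poisson(spec.private_cna_rate)):
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        lo, hi = spec.private_cna_length
        span = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        span = min(span, spec.chromosomes[chrom] - 1)
        start = int(rng.integers(0, spec.chromosomes[chrom] - span))
        sign = int(rng.choice([-1, 1]))
        out.append(
            Locus(chrom, start, start + span, 1.0, sign, sign * float(rng.uniform(0.35, 0.6)))
        )
    return out


def generate_cohort(spec: CohortSpec, rng: Optional[np.random.Generator] = None) -> Cohort:
    """Simulate paired tumor/normal profiles, oracle segments and ground truth."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    grid = _probe_grid(spec)
    patients: list[Patient] = []
    truth: list[GroundTruthEvent] = []
    for p in range(spec.n_patients):
        pid = f"patient{p:03d}"
        germline: list[tuple[Locus, str]] = [
            (locus, "CNV") for locus in spec.reference_cnv_loci
        ]
        for locus in spec.cnv_loci:
            if rng.random() < locus.frequency:
                germline.append((locus, "CNV"))
        somatic: list[tuple[Locus, str]] = []
        for locus in spec.cna_recurrent_loci:
            if rng.random() < locus.frequency:
                somatic.append((locus, "CNA"))
        somatic.extend((locus, "CNA") for locus in _private_cnas(spec, rng))

        kept = _resolve_overlaps(germline + somatic)
        germline_kept = [ev for ev, kind in kept if kind == "CNV"]
        tumor_events = [ev for ev, _ in kept]

        tumor = _build_profile(f"{pid}_T", grid, tumor_events, spec, rng)
        normal = _build_profile(f"{pid}_N", grid, germline_kept, spec, rng)
        tumor_segments = _segment_sample(tumor, tumor_events, spec, rng)
        normal_segments = _segment_sample(normal, germline_kept, spec, rng)
        patients.append(
            Patient(
                patient_id=pid,
                tumor=tumor,
                normal=normal,
                tumor_segments=tumor_segments,
                normal_segments=normal_segments,
            )
        )
        for ev, kind in kept:
            truth.append(
                GroundTruthEvent(
                    patient=pid,
                    chromosome=ev.chromosome,
                    start=ev.start,
                    end=ev.end,
                    kind=kind,
                    sign=ev.sign,
                    present_in_normal=(kind == "CNV"),
                )
            )
    return Cohort(spec=spec, patients=patients, ground_truth=truth)


def generate_dgv(
    spec: CohortSpec,
    extra_noise_records: int = 0,
    rng: Optional[np.random.Generator] = None,
    records_per_locus: tuple[int, int] = (1, 6),
    endpoint_wiggle_frac: float = 0.1,
) -> list[DGVRecord]:
    """Emulate a germline-variant catalogue covering the spec's CNV loci.

    Each CNV locus yields ``records_per_locus`` (inclusive bounds, default 1-6)
    redundant records with perturbed endpoints, distinct variation ids, 1-3
    source studies, and carrier counts scaled by the locus frequency; extra
    uniform records model catalogue noise.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    records: list[DGVRecord] = []
    counter = 0
    for li, locus in enumerate(spec.cnv_loci + spec.reference_cnv_loci):
        n_rec = int(rng.integers(records_per_locus[0], records_per_locus[1] + 1))
        studies = [f"study_{li}_{s}" for s in range(int(rng.integers(1, 4)))]
        span = locus.end - locus.start
        for _ in range(n_rec):
            wiggle = max(1, int(span * endpoint_wiggle_frac)) if endpoint_wiggle_frac > 0 else 0
            s = max(0, locus.start + int(rng.integers(-wiggle, wiggle + 1)))
            e = min(
                spec.chromosomes[locus.chromosome],
                locus.end + int(rng.integers(-wiggle, wiggle + 1)),
            )
            if e <= s:
                e = s + 1
            records.append(
                DGVRecord(
                    variation_id=f"V{counter}",
                    chromosome=locus.chromosome,
                    start=s,
                    end=e,
                    study_id=studies[int(rng.integers(0, len(studies)))],
                    n_individuals=int(1 + rng.binomial(100, locus.frequency)),
                )
            )
            counter += 1
    chrom_names = list(spec.chromosomes)
    for _ in range(extra_noise_records):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        span = int(np.exp(rng.uniform(np.log(10_000), np.log(500_000))))
        start = int(rng.integers(0, max(1, spec.chromosomes[chrom] - span)))
        records.append(
            DGVRecord(
                variation_id=f"V{counter}",
                chromosome=chrom,
                start=start,
                end=start + span,
                study_id=f"noise_study_{int(rng.integers(0, 5))}",
                n_individuals=int(rng.integers(1, 10)),
            )
        )
        counter += 1
    return records


def default_annotation(spec: CohortSpec, rng: Optional[np.random.Generator] = None) -> GenomeAnnotation:
    """Centromere mid-chromosome, one segdup and one physiological region per chromosome."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    centromeres = {}
    segdup: dict[str, IntervalTree] = {}
    physio: dict[str, IntervalTree] = {}
    for chrom, length in spec.chromosomes.items():
        mid = length // 2
        centromeres[chrom] = (mid - 500_000, mid + 500_000)
        s = int(rng.integers(0, max(1, length - 400_000)))
        segdup.setdefault(chrom, IntervalTree()).addi(s, s + 400_000)
        p = int(rng.integers(0, max(1, length - 200_000)))
        physio.setdefault(chrom, IntervalTree()).addi(p, p + 200_000)
    return GenomeAnnotation(
        chromosome_lengths=dict(spec.chromosomes),
        centromeres=centromeres,
        segmental_duplications=segdup,
        physiological_regions=physio,
    )


# ---------------------------------------------------------------------------
# presets


def _default_loci(chromosomes: dict[str, int], rng: np.random.Generator,
                  n_cnv: int, n_cna: int) -> tuple[list[Locus], list[Locus]]:
    """Fixed loci drawn once from the preset's own rng; CNVs in the <=2.3 Mb regime."""
    chrom_names = list(chromosomes)
    cnv, cna = [], []
    taken: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_names}

    def place(span: int) -> Optional[tuple[str, int, int]]:
        for _ in range(50):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            limit = chromosomes[chrom] - span
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            if not taken[chrom].overlap(start, start + span):
                taken[chrom].addi(start, start + span)
                return chrom, start, start + span
        return None

    for _ in range(n_cnv):
        span = int(np.exp(rng.uniform(np.log(30_000), np.log(1_500_000))))
        spot = place(span)
        if spot is None:
            continue
        chrom, s, e = spot
        sign = int(rng.choice([-1, 1]))
        cnv.append(
            Locus(chrom, s, e, float(rng.uniform(0.15, 0.6)), sign,
                  sign * float(rng.uniform(0.4, 0.6)))
        )
    for _ in range(n_cna):
        span = int(np.exp(rng.uniform(np.log(200_000), np.log(2_000_000))))
        spot = place(span)
        if spot is None:
            continue
        chrom, s, e = spot
        sign = int(rng.choice([-1, 1]))
        cna.append(
            Locus(chrom, s, e, float(rng.uniform(0.2, 0.4)), sign,
                  sign * float(rng.uniform(0.4, 0.6)))
        )
    return cnv, cna


def small_spec(seed: int = 0) -> CohortSpec:
    """6 patients, 2 chromosomes of 30 Mb; full pipeline in well under a minute."""
    chromosomes = {"1": 30_000_000, "2": 30_000_000}
    rng = np.random.default_rng(seed)
    cnv, cna = _default_loci(chromosomes, rng, n_cnv=6, n_cna=3)
    return CohortSpec(
        n_patients=6,
        chromosomes=chromosomes,
        cnv_loci=cnv,
        cna_recurrent_loci=cna,
        private_cna_rate=2.0,
        noise_sd=0.12,
        breakpoint_jitter_probes=1,
        seed=seed,
    )


def default_spec(seed: int = 0) -> CohortSpec:
    """40 patients, 4 chromosomes of 60 Mb, jitter 2 probes, noise sd 0.12."""
    chromosomes = {str(c): 60_000_000 for c in (1, 2, 3, 4)}
    rng = np.random.default_rng(seed)
    cnv, cna = _default_loci(chromosomes, rng, n_cnv=14, n_cna=5)
    return CohortSpec(
        n_patients=40,
        chromosomes=chromosomes,
        cnv_loci=cnv,
        cna_recurrent_loci=cna,
        private_cna_rate=3.0,
        noise_sd=0.12,
        breakpoint_jitter_probes=2,
        seed=seed,
    )


def random_cohort_spec(seed: int, n_patients: int = 4) -> CohortSpec:
    """Small randomised cohort with planted events on both sides of the 2.3 Mb cap."""
    chromosomes = {"1": 20_000_000, "2": 20_000_000}
    rng = np.random.default_rng(seed)
    cnv, _ = _default_loci(chromosomes, rng, n_cnv=4, n_cna=0)
    cna = []
    for chrom in chromosomes:
        span = int(rng.integers(2_500_000, 8_000_000))  # deliberately over the cap
        start = int(rng.integers(0, chromosomes[chrom] - span))
        sign = int(rng.choice([-1, 1]))
        cna.append(Locus(chrom, start, start + span, 0.7, sign, sign * 0.5))
    return CohortSpec(
        n_patients=n_patients,
        chromosomes=chromosomes,
        probe_spacing=9_000,
        cnv_loci=cnv,
        cna_recurrent_loci=cna,
        private_cna_rate=2.0,
        noise_sd=0.1,
        breakpoint_jitter_probes=1,
        seed=seed,
    )


@dataclass
class Fixture:
    directory: Optional[Path]
    spec: CohortSpec
    cohort: Cohort
    dgv: list[DGVRecord]
    annotation: GenomeAnnotation
    paths: dict[str, Path] = field(default_factory=dict)


def end_to_end_fixture(
    preset: str = "small", out_dir=None, seed: int = 0
) -> Fixture:
    """Bundle a cohort, DGV and annotation; optionally write all external formats.

    Presets: ``small`` (6 patients, 2 x 30 Mb) and ``default`` (40 patients,
    4 x 60 Mb, breakpoint jitter 2, noise sd 0.12).
    """
    if preset == "small":
        spec = small_spec(seed)
    elif preset == "default":
        spec = default_spec(seed)
    else:
        raise ValidationError(f"unknown preset {preset!r}")
    cohort = generate_cohort(spec)
    dgv = generate_dgv(spec, extra_noise_records=20)
    annotation = default_annotation(spec)

    fixture = Fixture(
        directory=None, spec=spec, cohort=cohort, dgv=dgv, annotation=annotation
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tumor_profiles = {p.tumor.sample_id: p.tumor for p in cohort.patients}
        normal_profiles = {p.normal.sample_id: p.normal for p in cohort.patients}
        paths = {
            "tumor_probes": out / "tumor_probes.tsv",
            "normal_probes": out / "normal_probes.tsv",
            "tumor_seg": out / "tumor.seg",
            "normal_seg": out / "normal.seg",
            "dgv": out / "dgv.tsv",
            "chrom_lengths": out / "chrom_lengths.tsv",
            "centromeres": out / "centromeres.bed",
            "segdup": out / "segdup.bed",
            "physiological": out / "physiological.bed",
        }
        write_probe_profiles(tumor_profiles, paths["tumor_probes"])
        write_probe_profiles(normal_profiles, paths["normal_probes"])
        write_seg({p.tumor.sample_id: p.tumor_segments for p in cohort.patients},
                  paths["tumor_seg"])
        write_seg({p.normal.sample_id: p.normal_segments for p in cohort.patients},
                  paths["normal_seg"])
        write_dgv(dgv, paths["dgv"])
        write_chromosome_lengths(annotation.chromosome_lengths, paths["chrom_lengths"])
        write_bed(
            [(c, s, e) for c, (s, e) in annotation.centromeres.items()],
            paths["centromeres"],
        )
        write_bed(
            [(c, iv.begin, iv.end) for c, t in annotation.segmental_duplications.items()
             for iv in sorted(t)],
            paths["segdup"],
        )
        write_bed(
            [(c, iv.begin, iv.end) for c, t in annotation.physiological_regions.items()
             for iv in sorted(t)],
            paths["physiological"],
        )
        fixture.directory = out
        fixture.paths = paths
    return fixture
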