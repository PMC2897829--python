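"""End-to-end orchestration: classify, train, simulate.

These functions are the library face of the command line: each takes a
:class:`RunConfig` (paths plus the handful of tunable thresholds) and runs the
stage pipeline — load, call, merge, extract, featurize, then either apply a
classifier or label against paired normals and train new ones.  All randomness
flows from the single config seed through named substreams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import calling, features, genome_io, models, simulate, truth_labeling
from .calling import MAX_CANDIDATE_SPAN, SampleCalls
from .genome_io import ConfigurationError, GenomeAnnotation, ValidationError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    tumor_probes: Optional[str] = None
    tumor_seg: Optional[str] = None
    normal_probes: Optional[str] = None
    normal_seg: Optional[str] = None
    dgv: Optional[str] = None
    chrom_lengths: Optional[str] = None
    centromere_bed: Optional[str] = None
    segdup_bed: Optional[str] = None
    physiological_bed: Optional[str] = None
    out: Optional[str] = None
    out_dir: Optional[str] = None
    model: str = "cbs_smoothed_full"  # published tree id or model file path
    overlap_feature: str = "overlap_pct"
    alpha: float = 0.01
    permutation_draws: int = 1000
    max_candidate_span: int = MAX_CANDIDATE_SPAN
    centromere_window: int = features.CENTROMERE_WINDOW
    telomere_window: int = features.TELOMERE_WINDOW
    proximity_window: int = features.PROXIMITY_WINDOW
    train_fraction: float = 0.6
    preset: str = "small"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        for name in ("max_candidate_span", "centromere_window", "telomere_window",
                     "proximity_window"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def load_annotation(config: RunConfig) -> GenomeAnnotation:
    if config.chrom_lengths is None:
        raise ConfigurationError("chromosome lengths path is required")
    bed_paths = {}
    for role, path in (
        ("centromere", config.centromere_bed),
        ("segmental_duplication", config.segdup_bed),
        ("physiological", config.physiological_bed),
    ):
        if path is not None:
            bed_paths[role] = path
    return genome_io.read_annotations(bed_paths, config.chrom_lengths)


def call_cohort(
    profiles: Mapping[str, genome_io.ProbeProfile],
    segments: Mapping[str, Sequence[genome_io.RawSegment]],
    annotation: GenomeAnnotation,
    max_span: int = MAX_CANDIDATE_SPAN,
) -> dict[str, SampleCalls]:
    """Run stats/call/merge/extract per sample; log counts at each filter stage."""
    out: dict[str, SampleCalls] = {}
    for sample, profile in profiles.items():
        if sample not in segments:
            raise ValidationError(f"no segmentation provided for sample {sample}")
        calls = calling.call_sample(profile, segments[sample], annotation, max_span)
        n_aberrant = sum(1 for s in calls.called if s.status != calling.NORMAL)
        log.info(
            "%s: %d segments loaded, %d gain/loss after merging, %d candidates",
            sample, len(segments[sample]), n_aberrant, len(calls.candidates),
        )
        out[sample] = calls
    return out


def featurize(
    samples: Mapping[str, SampleCalls],
    dgv,
    annotation: GenomeAnnotation,
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    config = config or RunConfig()
    return features.build_feature_matrix(
        samples, dgv, annotation,
        centromere_window=config.centromere_window,
        telomere_window=config.telomere_window,
        proximity_window=config.proximity_window,
    )


def _candidates_in_matrix_order(samples: Mapping[str, SampleCalls], matrix: pd.DataFrame):
    lookup = {
        cand.key: cand for calls in samples.values() for cand in calls.candidates
    }
    return [
        lookup[(row["sample"], row["chromosome"], row["start"], row["end"])]
        for _, row in matrix.iterrows()
    ]


def classify_run(config: RunConfig):
    """Extract candidates, featurize, classify, and write the report TSV.

    Returns (feature matrix, predictions).
    """
    if config.tumor_probes is None or config.tumor_seg is None:
        raise ConfigurationError("tumor probe and segmentation paths are required")
    annotation = load_annotation(config)
    profiles = genome_io.read_probe_profiles(config.tumor_probes)
    segments = genome_io.read_seg(config.tumor_seg)
    samples = call_cohort(profiles, segments, annotation, config.max_candidate_span)

    # Every shipped model consumes the Database score, so the table is mandatory.
    if config.dgv is None:
        raise ConfigurationError(
            f"model {config.model!r} requires Database scores; provide a DGV table"
        )
    dgv = genome_io.read_dgv(config.dgv, known_chromosomes=annotation.chromosome_lengths)

    matrix = featurize(samples, dgv, annotation, config)
    if len(profiles) == 1:
        log.warning("cohort of one patient: cohort features are degenerate zeros")

    feature_part = matrix[features.FEATURE_COLUMNS]
    if config.model in models.PUBLISHED_TREES:
        predictions = models.predict_published_tree_frame(
            feature_part, config.model, config.overlap_feature
        )
    else:
        frozen = models.load_model(config.model)
        predictions = frozen.predict(features.encode_features(matrix))

    if config.out is not None:
        cands = _candidates_in_matrix_order(samples, matrix)
        genome_io.write_report(cands, feature_part, predictions, config.out)
    summary = pd.Series(predictions).value_counts().to_dict()
    log.info("classified %d candidates: %s", len(predictions), summary)
    return matrix, predictions


def label_cohort(
    cohort: simulate.Cohort,
    annotation: GenomeAnnotation,
    R: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    max_span: int = MAX_CANDIDATE_SPAN,
):
    """Call every tumor sample and truth-label its candidates from the paired normal.

    Returns (samples keyed by tumor sample id, label map keyed by candidate key).
    """
    samples: dict[str, SampleCalls] = {}
    label_map: dict[tuple, truth_labeling.TruthLabel] = {}
    for patient in cohort.patients:
        tcalls = calling.call_sample(
            patient.tumor, patient.tumor_segments, annotation, max_span
        )
        nstats = calling.compute_array_stats(patient.normal, patient.normal_segments)
        ncalled = calling.merge_candidate_runs(
            calling.call_segments(patient.normal_segments, nstats), max_span
        )
        labels = truth_labeling.label_candidates(
            tcalls.candidates, tcalls.called, patient.normal, ncalled, nstats,
            R=R, alpha=alpha, rng_seed=seed,
        )
        samples[patient.tumor.sample_id] = tcalls
        for cand, lab in zip(tcalls.candidates, labels):
            label_map[cand.key] = lab
    return samples, label_map


def split_patients(
    patient_ids: Sequence[str], train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Patient-level train/test split; no patient's candidates straddle the split."""
    ids = sorted(set(patient_ids))
    if len(ids) < 2:
        raise ValidationError("training requires at least two patients")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    perm = rng.permutation(len(ids))
    n_train = max(1, min(len(ids) - 1, int(round(train_fraction * len(ids)))))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


@dataclass
class TrainResult:
    cart: models.CartModel
    forest: models.ForestModel
    cart_report: models.EvaluationReport
    forest_report: models.EvaluationReport
    matrix: pd.DataFrame
    labels: list[str]
    train_samples: list[str]
    test_samples: list[str]
    paths: dict[str, Path] = field(default_factory=dict)


def train_on_fixture(
    fixture: simulate.Fixture, config: Optional[RunConfig] = None
) -> TrainResult:
    """Truth-label a synthetic (or loaded) cohort, train CART + forest, evaluate held out."""
    config = config or RunConfig()
    samples, label_map = label_cohort(
        fixture.cohort, fixture.annotation,
        R=config.permutation_draws, alpha=config.alpha, seed=config.seed,
        max_span=config.max_candidate_span,
    )
    matrix = featurize(samples, fixture.dgv, fixture.annotation, config)
    labels = [
        label_map[(row["sample"], row["chromosome"], row["start"], row["end"])].label
        for _, row in matrix.iterrows()
    ]
    train_ids, test_ids = split_patients(
        matrix["sample"].tolist(), config.train_fraction, config.seed
    )
    X = features.encode_features(matrix)
    y = np.asarray(labels, dtype=object)
    in_train = matrix["sample"].isin(train_ids).to_numpy()

    cart = models.train_cart(X[in_train], y[in_train], seed=config.seed)
    forest = models.train_rf(X[in_train], y[in_train], seed=config.seed)
    test_samples = matrix.loc[~in_train, "sample"].tolist()
    cart_report = models.evaluate(cart.predict(X[~in_train]), y[~in_train], test_samples)
    forest_report = models.evaluate(forest.predict(X[~in_train]), y[~in_train], test_samples)

    result = TrainResult(
        cart=cart, forest=forest,
        cart_report=cart_report, forest_report=forest_report,
        matrix=matrix, labels=list(labels),
        train_samples=train_ids, test_samples=test_ids,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.paths = {
            "cart": out / "cart_model.json",
            "forest": out / "forest_model.json",
        }
        models.save_model(cart, result.paths["cart"])
        models.save_model(forest, result.paths["forest"])
    return result


def train_run(config: RunConfig) -> TrainResult:
    """Train from files: paired tumor/normal probes + segmentations + DGV + annotation."""
    for name in ("tumor_probes", "tumor_seg", "normal_probes", "normal_seg", "dgv"):
        if getattr(config, name) is None:
            raise ConfigurationError(f"training requires {name}")
    annotation = load_annotation(config)
    tumors = genome_io.read_probe_profiles(config.tumor_probes)
    normals = genome_io.read_probe_profiles(config.normal_probes)
    tumor_segs = genome_io.read_seg(config.tumor_seg)
    normal_segs = genome_io.read_seg(config.normal_seg)
    dgv = genome_io.read_dgv(config.dgv, known_chromosomes=annotation.chromosome_lengths)

    # Pair tumor/normal by shared patient prefix (<patient>_T / <patient>_N).
    patients = []
    for tid, tumor in tumors.items():
        pid = tid[:-2] if tid.endswith("_T") else tid
        nid = f"{pid}_N"
        if nid not in normals:
            raise ValidationError(f"no paired normal found for tumor sample {tid}")
        patients.append(
            simulate.Patient(
                patient_id=pid,
                tumor=tumor,
                normal=normals[nid],
                tumor_segments=list(tumor_segs[tid]),
                normal_segments=list(normal_segs[nid]),
            )
        )
    spec = simulate.CohortSpec(n_patients=len(patients),
                               chromosomes=dict(annotation.chromosome_lengths))
    fixture = simulate.Fixture(
        directory=None, spec=spec,
        cohort=simulate.Cohort(spec=spec, patients=patients, ground_truth=[]),
        dgv=dgv, annotation=annotation,
    )
    return train_on_fixture(fixture, config)


def simulate_run(config: RunConfig) -> simulate.Fixture:
    if config.out_dir is None:
        raise ConfigurationError("simulate requires an output directory")
    return simulate.end_to_end_fixture(config.preset, out_dir=config.out_dir,
                                       seed=config.seed)
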