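import numpy as np
import pytest
from intervaltree import IntervalTree

from cnvclass.calling import GAIN, LOSS, NORMAL, ArrayStats, CalledSegment, CandidateCNV
from cnvclass.genome_io import GenomeAnnotation, ProbeProfile
from cnvclass import simulate


def make_profile(sample_id, chrom_positions, values=None, rng=None):
    """Profile from {chrom: positions}; values default to N(0, 0.1) noise."""
    chroms, positions, lrs = [], [], []
    rng = rng or np.random.default_rng(0)
    for chrom, pos in chrom_positions.items():
        pos = np.asarray(pos, dtype=np.int64)
        chroms.extend([chrom] * len(pos))
        positions.append(pos)
        if values is not None and chrom in values:
            lrs.append(np.asarray(values[chrom], dtype=float))
        else:
            lrs.append(rng.normal(0, 0.1, len(pos)))
    return ProbeProfile(
        sample_id=sample_id,
        chromosomes=np.array(chroms, dtype=object),
        positions=np.concatenate(positions),
        log_ratios=np.concatenate(lrs),
    )


def make_called(sample, chrom, triples, merged_from=None):
    """CalledSegments from (start, end, n_markers, mean, status) tuples."""
    out = []
    for i, (start, end, n, mean, status) in enumerate(triples):
        out.append(
            CalledSegment(
                sample_id=sample, chromosome=chrom, start=start, end=end,
                n_markers=n, mean=mean, status=status,
                merged_from=1 if merged_from is None else merged_from[i],
            )
        )
    return out


def make_candidate(
    sample="S1", chrom="1", start=1_000_000, end=1_100_000, n_markers=10,
    mean=0.5, status=GAIN, left=NORMAL, right=NORMAL, merged_from=1,
):
    return CandidateCNV(
        sample_id=sample, chromosome=chrom, start=start, end=end,
        n_markers=n_markers, mean=mean, status=status,
        left_flank_status=left, right_flank_status=right, merged_from=merged_from,
    )


@pytest.fixture
def bare_annotation():
    """Two 30 Mb autosomes plus X, centromeres mid-chromosome, no exclusions."""
    lengths = {"1": 30_000_000, "2": 30_000_000, "X": 30_000_000}
    return GenomeAnnotation(
        chromosome_lengths=lengths,
        centromeres={c: (14_500_000, 15_500_000) for c in lengths},
    )


@pytest.fixture
def physio_annotation(bare_annotation):
    ann = bare_annotation
    tree = IntervalTree()
    tree.addi(5_000_000, 5_200_000)
    return GenomeAnnotation(
        chromosome_lengths=ann.chromosome_lengths,
        centromeres=ann.centromeres,
        physiological_regions={"1": tree},
    )


@pytest.fixture(scope="session")
def small_fixture():
    return simulate.end_to_end_fixture("small", seed=11)


@pytest.fixture
def flat_stats():
    return ArrayStats(sample_id="S1", array_median=0.0, array_mad=0.1, residual_mad=0.1)
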