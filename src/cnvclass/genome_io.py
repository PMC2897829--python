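"""Readers and writers for the tab-delimited formats the toolkit touches.

All genomic intervals are 0-based half-open **internally**.  SEG and DGV
files carry 1-based inclusive coordinates and are converted on ingest; the
report writer converts back on output.  BED input is already half-open and
passes through unchanged.  Chromosome names are normalised by stripping any
``chr`` prefix; the sex chromosomes are recognised under either spelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not parse under the documented dialect."""


class ValidationError(ValueError):
    """Parsed content violates an internal invariant."""


class ConfigurationError(ValueError):
    """A column map or path configuration is incomplete."""


# ---------------------------------------------------------------------------
# coordinate and chromosome conventions


def to_internal(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    s, e = int(start) - 1, int(end)
    if e <= s:
        raise ValidationError(f"empty or inverted interval ({start}, {end})")
    return s, e


def to_external(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval back to 1-based inclusive."""
    return int(start) + 1, int(end)


def normalize_chromosome(name: str) -> str:
    c = str(name).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.lower() in ("x", "y"):
        return c.upper()
    return c


def chromosome_sort_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except ValueError:
        pass
    if chrom == "X":
        return (1, 23, "")
    if chrom == "Y":
        return (1, 24, "")
    return (2, 0, chrom)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ProbeProfile:
    """One sample's probe-level log-ratio profile, sorted by (chromosome, position)."""

    sample_id: str
    chromosomes: np.ndarray  # str per probe
    positions: np.ndarray  # int64, bp
    log_ratios: np.ndarray  # float64
    _index: dict = field(default_factory=dict, init=False, repr=False, compare=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.log_ratios = np.asarray(self.log_ratios, dtype=np.float64)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        if np.isnan(self.log_ratios).any():
            raise ValidationError(f"{self.sample_id}: missing log-ratios after load")
        self._build_index()

    def _build_index(self):
        self._index = {}
        n = len(self.positions)
        i = 0
        while i < n:
            c = self.chromosomes[i]
            j = i
            while j < n and self.chromosomes[j] == c:
                j += 1
            if c in self._index:
                raise ValidationError(
                    f"{self.sample_id}: chromosome {c} appears in non-contiguous blocks"
                )
            pos = self.positions[i:j]
            if n and np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"{self.sample_id}: positions not strictly increasing on chromosome {c}"
                )
            self._index[c] = (i, j)
            i = j

    @classmethod
    def from_dataframe(cls, sample_id: str, df: pd.DataFrame) -> "ProbeProfile":
        """Build from columns chromosome/position/log_ratio, sorting canonically."""
        d = df.copy()
        d["chromosome"] = [normalize_chromosome(c) for c in d["chromosome"]]
        d["_key"] = [chromosome_sort_key(c) for c in d["chromosome"]]
        d = d.sort_values(["_key", "position"], kind="mergesort")
        return cls(
            sample_id=sample_id,
            chromosomes=d["chromosome"].to_numpy(dtype=object),
            positions=d["position"].to_numpy(dtype=np.int64),
            log_ratios=d["log_ratio"].to_numpy(dtype=np.float64),
        )

    @property
    def chromosome_names(self) -> list[str]:
        return list(self._index)

    @property
    def n_probes(self) -> int:
        return len(self.positions)

    def chrom_data(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions, log_ratios) views for one chromosome; empty arrays if absent."""
        span = self._index.get(chrom)
        if span is None:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64)
        i, j = span
        return self.positions[i:j], self.log_ratios[i:j]

    def values_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Log-ratios of probes with start <= position < end."""
        pos, lr = self.chrom_data(chrom)
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return lr[i:j]

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos, _ = self.chrom_data(chrom)
        return int(
            np.searchsorted(pos, end, side="left") - np.searchsorted(pos, start, side="left")
        )


@dataclass(frozen=True)
class RawSegment:
    """A constant-copy-number segment as emitted by an external segmenter."""

    sample_id: str
    chromosome: str
    start: int  # 0-based half-open
    end: int
    n_markers: int
    mean: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"{self.sample_id} {self.chromosome}: segment end {self.end} <= start {self.start}"
            )
        if self.n_markers <= 0:
            raise ValidationError(f"{self.sample_id}: segment with n_markers <= 0")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DGVRecord:
    """One germline-variant record from a DGV-style table."""

    variation_id: str
    chromosome: str
    start: int  # 0-based half-open
    end: int
    study_id: str
    n_individuals: Optional[int] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(f"DGV {self.variation_id}: end <= start")


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus centromere, segmental-duplication and exclusion intervals."""

    chromosome_lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    segmental_duplications: dict[str, IntervalTree] = field(default_factory=dict)
    physiological_regions: dict[str, IntervalTree] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, (s, e) in self.centromeres.items():
            self._check_interval(chrom, s, e, "centromere")
        for role, trees in (
            ("segmental duplication", self.segmental_duplications),
            ("physiological region", self.physiological_regions),
        ):
            for chrom, tree in trees.items():
                for iv in tree:
                    self._check_interval(chrom, iv.begin, iv.end, role)

    def _check_interval(self, chrom, s, e, role):
        length = self.chromosome_lengths.get(chrom)
        if length is not None and (s < 0 or e > length):
            raise ValidationError(
                f"{role} interval ({s}, {e}) exceeds chromosome {chrom} length {length}"
            )

    def _overlaps(self, trees: dict, chrom: str, start: int, end: int) -> bool:
        tree = trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def overlaps_segdup(self, chrom: str, start: int, end: int) -> bool:
        return self._overlaps(self.segmental_duplications, chrom, start, end)

    def overlaps_physiological(self, chrom: str, start: int, end: int) -> bool:
        return self._overlaps(self.physiological_regions, chrom, start, end)

    def centromere(self, chrom: str) -> Optional[tuple[int, int]]:
        return self.centromeres.get(chrom)


# ---------------------------------------------------------------------------
# readers


def read_probe_profiles(path) -> dict[str, ProbeProfile]:
    """Load a probe matrix TSV: probe_id, chromosome, position, then one column per sample.

    Rows with a missing log-ratio are dropped from the affected sample only;
    drop counts are logged per sample.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = ["probe_id", "chromosome", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    pos = pd.to_numeric(df["position"], errors="coerce")
    bad = pos.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise FormatError(f"{path}: unparseable position at line {line}")
    df["position"] = pos.astype(np.int64)
    df["chromosome"] = [normalize_chromosome(c) for c in df["chromosome"]]
    dup = df.duplicated(subset=["chromosome", "position"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise FormatError(f"{path}: duplicated (chromosome, position) at line {line}")

    sample_cols = [c for c in df.columns if c not in required]
    profiles: dict[str, ProbeProfile] = {}
    for sample in sample_cols:
        vals = pd.to_numeric(df[sample], errors="coerce")
        keep = ~vals.isna()
        dropped = int((~keep).sum())
        if dropped:
            log.info("%s: dropped %d probes with missing log-ratios", sample, dropped)
        sub = pd.DataFrame(
            {
                "chromosome": df.loc[keep, "chromosome"],
                "position": df.loc[keep, "position"],
                "log_ratio": vals[keep],
            }
        )
        profiles[sample] = ProbeProfile.from_dataframe(sample, sub)
    return profiles


SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def read_seg(path) -> dict[str, list[RawSegment]]:
    """Load a SEG table (1-based inclusive coordinates) into internal segments."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 6:
        raise FormatError(f"{path}: SEG requires 6 columns, found {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = SEG_COLUMNS
    out: dict[str, list[RawSegment]] = {}
    for sample, grp in df.groupby("ID", sort=False):
        segs = []
        for row in grp.itertuples(index=False):
            chrom = normalize_chromosome(row[1])
            start, end = to_internal(int(row[2]), int(row[3]))
            segs.append(
                RawSegment(
                    sample_id=str(sample),
                    chromosome=chrom,
                    start=start,
                    end=end,
                    n_markers=int(row[4]),
                    mean=float(row[5]),
                )
            )
        out[str(sample)] = sort_segments(segs)
    return out


def sort_segments(segments: Sequence[RawSegment]) -> list[RawSegment]:
    """Sort one sample's segments canonically and verify per-chromosome non-overlap."""
    segs = sorted(segments, key=lambda s: (chromosome_sort_key(s.chromosome), s.start))
    for a, b in zip(segs, segs[1:]):
        if a.chromosome == b.chromosome and b.start < a.end:
            raise ValidationError(
                f"{a.sample_id} {a.chromosome}: overlapping segments "
                f"({a.start}, {a.end}) and ({b.start}, {b.end})"
            )
    return segs


#: Physical column names of the DGV v7 hg18 text dump for each logical field.
DEFAULT_DGV_COLUMN_MAP = {
    "variation_id": "VariationID",
    "chromosome": "Chr",
    "start": "Start",
    "end": "End",
    "study_id": "Reference",
    "n_individuals": "SampleSize",
}


def read_dgv(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    known_chromosomes: Optional[Iterable[str]] = None,
) -> list[DGVRecord]:
    """Load a DGV-style variant table (1-based inclusive coordinates).

    ``column_map`` names the physical column for each logical field
    (``n_individuals`` may be omitted); the default targets the v7 text dump.
    Records on chromosomes outside ``known_chromosomes`` are kept but counted
    in a warning.
    """
    cmap = dict(DEFAULT_DGV_COLUMN_MAP if column_map is None else column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["variation_id", "chromosome", "start", "end", "study_id"]
    for logical in required:
        col = cmap.get(logical)
        if col is None or col not in df.columns:
            raise ConfigurationError(
                f"{path}: column map entry for '{logical}' "
                f"({col!r}) not found in file columns {list(df.columns)}"
            )
    ind_col = cmap.get("n_individuals")
    has_ind = ind_col is not None and ind_col in df.columns

    records: list[DGVRecord] = []
    seen: set[str] = set()
    unknown = 0
    known = set(known_chromosomes) if known_chromosomes is not None else None
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        vid = str(d[cmap["variation_id"]])
        if vid in seen:
            raise ValidationError(f"{path}: duplicate variation_id {vid}")
        seen.add(vid)
        chrom = normalize_chromosome(d[cmap["chromosome"]])
        start, end = to_internal(int(d[cmap["start"]]), int(d[cmap["end"]]))
        n_ind = None
        if has_ind:
            raw = d[ind_col]
            if raw is not None and str(raw) not in ("", "nan", "NA"):
                n_ind = int(float(raw))
        if known is not None and chrom not in known:
            unknown += 1
        records.append(
            DGVRecord(
                variation_id=vid,
                chromosome=chrom,
                start=start,
                end=end,
                study_id=str(d[cmap["study_id"]]),
                n_individuals=n_ind,
            )
        )
    if unknown:
        log.warning("%s: %d records on chromosomes absent from the annotation", path, unknown)
    return records


def _read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((normalize_chromosome(parts[0]), int(parts[1]), int(parts[2])))
    return out


def read_chromosome_lengths(path) -> dict[str, int]:
    lengths = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            lengths[normalize_chromosome(chrom)] = int(length)
    return lengths


def read_annotations(
    bed_paths: Mapping[str, str | Path], chrom_lengths_path
) -> GenomeAnnotation:
    """Assemble a GenomeAnnotation from role-keyed BED files plus a lengths table.

    Recognised roles: ``centromere`` (one interval per chromosome),
    ``segmental_duplication``, ``physiological``.
    """
    lengths = read_chromosome_lengths(chrom_lengths_path)
    centromeres: dict[str, tuple[int, int]] = {}
    trees = {"segmental_duplication": {}, "physiological": {}}
    for role, path in bed_paths.items():
        intervals = _read_bed(path)
        if role == "centromere":
            for chrom, s, e in intervals:
                centromeres[chrom] = (s, e)
        elif role in trees:
            for chrom, s, e in intervals:
                trees[role].setdefault(chrom, IntervalTree()).addi(s, e)
        else:
            raise ConfigurationError(f"unknown annotation role {role!r}")
    return GenomeAnnotation(
        chromosome_lengths=lengths,
        centromeres=centromeres,
        segmental_duplications=trees["segmental_duplication"],
        physiological_regions=trees["physiological"],
    )


# ---------------------------------------------------------------------------
# writers


def write_probe_profiles(profiles: Mapping[str, ProbeProfile], path) -> None:
    """Write profiles back to the probe-matrix TSV dialect (shared probe grid required)."""
    samples = list(profiles)
    first = profiles[samples[0]]
    frame = pd.DataFrame(
        {
            "probe_id": [f"P{i}" for i in range(first.n_probes)],
            "chromosome": first.chromosomes,
            "position": first.positions,
        }
    )
    for s in samples:
        p = profiles[s]
        if not (
            np.array_equal(p.positions, first.positions)
            and np.array_equal(p.chromosomes, first.chromosomes)
        ):
            raise ValidationError("write_probe_profiles requires a shared probe grid")
        frame[s] = p.log_ratios
    frame.to_csv(path, sep="\t", index=False)


def write_seg(segments: Mapping[str, Sequence[RawSegment]], path) -> None:
    rows = []
    for sample, segs in segments.items():
        for seg in segs:
            s1, e1 = to_external(seg.start, seg.end)
            rows.append((sample, seg.chromosome, s1, e1, seg.n_markers, seg.mean))
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def write_dgv(records: Sequence[DGVRecord], path) -> None:
    rows = []
    for r in records:
        s1, e1 = to_external(r.start, r.end)
        rows.append(
            (r.variation_id, r.chromosome, s1, e1, r.study_id,
             "" if r.n_individuals is None else r.n_individuals)
        )
    pd.DataFrame(
        rows, columns=[DEFAULT_DGV_COLUMN_MAP[k] for k in
                       ("variation_id", "chromosome", "start", "end", "study_id", "n_individuals")]
    ).to_csv(path, sep="\t", index=False)


def write_bed(intervals: Iterable[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def write_chromosome_lengths(lengths: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def write_report(candidates, features: pd.DataFrame, predictions, path, truths=None) -> None:
    """One TSV row per candidate: identity, features, predicted (and true) class.

    Output coordinates are 1-based inclusive.  Column order: sample, chromosome,
    start, end, status, mean, the feature columns in their fixed order, predicted,
    true (if given).
    """
    n = len(candidates)
    if len(features) != n or len(predictions) != n or (truths is not None and len(truths) != n):
        raise ValidationError(
            f"aligned collections required: {n} candidates, {len(features)} feature rows, "
            f"{len(predictions)} predictions"
        )
    rows = []
    for cand in candidates:
        s1, e1 = to_external(cand.start, cand.end)
        rows.append((cand.sample_id, cand.chromosome, s1, e1, cand.status, cand.mean))
    head = pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end", "status", "mean"])
    body = features.reset_index(drop=True)
    out = pd.concat([head, body], axis=1)
    out["predicted"] = list(predictions)
    if truths is not None:
        out["true"] = list(truths)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
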