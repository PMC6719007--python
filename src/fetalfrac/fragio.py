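"""Fragment-level I/O and length-profile construction.

Reads paired-end alignments (SAM/BAM) of shallow-WGS maternal-plasma
libraries, applies the retained-read filters (properly paired, primary,
non-duplicate, MAPQ threshold), and tallies fragment lengths and
per-chromosome fragment counts.  From those tallies it builds the
171-dimensional fragment-length profile (proportion of fragments at each
length 50-220 bp) that every downstream length-based fetal-fraction
estimator consumes, and provides TSV round-tripping of per-sample profile
tables plus the train-set feature standardizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from sklearn.preprocessing import StandardScaler

DEFAULT_LENGTH_RANGE: tuple[int, int] = (50, 220)
N_LENGTHS = DEFAULT_LENGTH_RANGE[1] - DEFAULT_LENGTH_RANGE[0] + 1  # 171
DEFAULT_MIN_MAPQ = 40

#: attribute columns recognised in profile tables, all optional
OPTIONAL_COLUMNS = ("chry_fraction", "ga", "bmi", "lc", "seqff_value", "reference_ff", "true_ff")


class SchemaError(ValueError):
    """Profile table does not match the expected column schema."""


class ValidationError(ValueError):
    """Profile table content fails a value-level check."""


@dataclass
class FragmentSet:
    """Filtered fragment tallies for one sample.

    ``length_histogram`` maps fragment length (bp) to count; it keeps all
    observed lengths — restriction to 50-220 bp happens when the profile is
    built.  ``per_chrom_fragments`` counts retained fragments per reference
    sequence name.
    """

    sample_id: str
    length_histogram: dict[int, int] = field(default_factory=dict)
    per_chrom_fragments: dict[str, int] = field(default_factory=dict)

    @property
    def total_fragments(self) -> int:
        return sum(self.per_chrom_fragments.values())

    def chrom_count(self, name: str) -> int:
        """Count for a chromosome, accepting both 'chrY' and 'Y' spellings."""
        if name in self.per_chrom_fragments:
            return self.per_chrom_fragments[name]
        alt = name[3:] if name.startswith("chr") else "chr" + name
        return self.per_chrom_fragments.get(alt, 0)

    def chry_fraction(self, denominator: str = "all") -> float:
        """Fraction of retained fragments mapping to chrY.

        denominator: 'all' (default) uses every retained fragment,
        'autosomal' uses autosomes plus chrY only.
        """
        y = self.chrom_count("chrY")
        if denominator == "all":
            total = self.total_fragments
        elif denominator == "autosomal":
            total = y
            for chrom, n in self.per_chrom_fragments.items():
                base = chrom[3:] if chrom.startswith("chr") else chrom
                if base.isdigit():
                    total += n
        else:
            raise ValueError(f"unknown denominator rule: {denominator!r}")
        if total == 0:
            raise ValidationError(f"sample {self.sample_id}: no fragments for chrY fraction")
        return y / total


@dataclass
class LengthProfile:
    """Proportions of fragment lengths 50..220 bp for one sample."""

    sample_id: str
    proportions: np.ndarray
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        lo, hi = self.length_range
        expected = hi - lo + 1
        if self.proportions.shape != (expected,):
            raise ValidationError(
                f"sample {self.sample_id}: expected {expected} proportions, "
                f"got shape {self.proportions.shape}"
            )
        if np.any(self.proportions < 0):
            raise ValidationError(f"sample {self.sample_id}: negative proportions")
        total = self.proportions.sum()
        if total > 0 and abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"sample {self.sample_id}: proportions sum to {total:.6g}, expected 1"
            )

    @property
    def lengths(self) -> np.ndarray:
        lo, hi = self.length_range
        return np.arange(lo, hi + 1)

    def proportion_at(self, length: int) -> float:
        lo, hi = self.length_range
        if not lo <= length <= hi:
            raise ValueError(f"length {length} outside profile range {self.length_range}")
        return float(self.proportions[length - lo])

    def mean_length(self) -> float:
        return float(self.lengths @ self.proportions)


@dataclass
class SampleRecord:
    """One sample: its length profile plus optional per-sample attributes.

    All fraction-valued attributes live in [0, 1]; ``true_ff`` is only ever
    set by the simulator, ``reference_ff`` is the Y-based reference value.
    """

    sample_id: str
    profile: LengthProfile
    chry_fraction: float | None = None
    ga: float | None = None
    bmi: float | None = None
    lc: float | None = None
    seqff_value: float | None = None
    reference_ff: float | None = None
    true_ff: float | None = None

    def __post_init__(self) -> None:
        for name in ("chry_fraction", "seqff_value", "true_ff"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"sample {self.sample_id}: {name}={v} outside [0,1]")
        if self.bmi is not None and self.bmi <= 0:
            raise ValidationError(f"sample {self.sample_id}: bmi must be positive")


@dataclass
class Dataset:
    """Ordered collection of SampleRecords with aligned profiles."""

    records: list[SampleRecord]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_ids in dataset")
        if self.records:
            rng = self.records[0].profile.length_range
            for r in self.records:
                if r.profile.length_range != rng:
                    raise ValidationError("records carry profiles of different length ranges")

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            return Dataset([self.records[i] for i in np.asarray(idx)])
        return self.records[idx]

    def profile_matrix(self) -> np.ndarray:
        """N x 171 matrix of length proportions."""
        return np.vstack([r.profile.proportions for r in self.records])

    def attribute(self, name: str) -> np.ndarray:
        """Vector of a per-sample attribute; absent values become NaN."""
        out = np.full(len(self.records), np.nan)
        for i, r in enumerate(self.records):
            v = getattr(r, name)
            if v is not None:
                out[i] = v
        return out

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset([self.records[i] for i in indices])


# ---------------------------------------------------------------------------
# alignment reading
# ---------------------------------------------------------------------------

def read_fragments(
    alignment_path: str | Path,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    sample_id: str | None = None,
) -> FragmentSet:
    """Tally fragment lengths and per-chromosome counts from a SAM/BAM file.

    A fragment is counted once, from its first-in-pair record, when the pair
    is properly paired, both mates mapped, the record is a primary,
    non-duplicate alignment and its MAPQ is at least ``min_mapq``.  Fragment
    length is the span from the leftmost to the rightmost mapped base of the
    pair, i.e. the absolute template length.
    """
    path = Path(alignment_path)
    if sample_id is None:
        sample_id = path.stem
    fs = FragmentSet(sample_id=sample_id)
    try:
        af = pysam.AlignmentFile(str(path), require_index=False)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read alignment file {path}: {exc}") from exc
    with af:
        any_proper = False
        for rec in af.fetch(until_eof=True):
            if not rec.is_paired or not rec.is_proper_pair:
                continue
            if rec.is_unmapped or rec.mate_is_unmapped:
                continue
            any_proper = True
            if not rec.is_read1:
                continue
            if rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            tlen = abs(rec.template_length)
            if tlen == 0:
                continue
            fs.length_histogram[tlen] = fs.length_histogram.get(tlen, 0) + 1
            chrom = rec.reference_name
            fs.per_chrom_fragments[chrom] = fs.per_chrom_fragments.get(chrom, 0) + 1
    if not any_proper:
        raise IOError(f"no properly paired reads in {path}")
    return fs


def build_length_profile(
    fragments: FragmentSet,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> LengthProfile:
    """Proportion of fragments at each length in ``length_range``.

    Only in-range fragments enter the denominator; lengths outside the
    range neither contribute mass nor dilute the in-range proportions.
    """
    lo, hi = length_range
    counts = np.zeros(hi - lo + 1, dtype=float)
    for length, n in fragments.length_histogram.items():
        if lo <= length <= hi:
            counts[length - lo] += n
    total = counts.sum()
    if total <= 0:
        raise ValidationError(
            f"sample {fragments.sample_id}: no fragments in length range {length_range}"
        )
    return LengthProfile(fragments.sample_id, counts / total, length_range)


# ---------------------------------------------------------------------------
# profile tables
# ---------------------------------------------------------------------------

def _length_columns(length_range: tuple[int, int]) -> list[str]:
    lo, hi = length_range
    return [f"L{i}" for i in range(lo, hi + 1)]


def load_profile_table(
    path: str | Path,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> Dataset:
    """Load a per-sample profile table (TSV).

    Schema: ``sample_id``, one column per length (``L50`` .. ``L220``,
    counts or proportions), plus any of the optional attribute columns.
    Count rows are normalised to proportions; proportion rows must sum to 1.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing 'sample_id' column")
    cols = _length_columns(length_range)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing length columns: {missing[:5]}"
                          + ("..." if len(missing) > 5 else ""))
    records = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        vals = row[cols].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValidationError(f"sample {sid}: negative length values")
        total = vals.sum()
        if total <= 0:
            raise ValidationError(f"sample {sid}: empty length profile")
        if total > 1.5:  # counts: normalise
            vals = vals / total
        elif abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"sample {sid}: proportions sum to {total:.6g}, expected 1"
            )
        else:
            vals = vals / total  # remove rounding drift
        kwargs = {}
        for name in OPTIONAL_COLUMNS:
            if name in df.columns and pd.notna(row[name]):
                kwargs[name] = float(row[name])
        records.append(SampleRecord(sid, LengthProfile(sid, vals, length_range), **kwargs))
    return Dataset(records)


def write_profile_table(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset to the TSV schema read by :func:`load_profile_table`."""
    if not dataset.records:
        raise ValidationError("cannot write an empty dataset")
    rng = dataset.records[0].profile.length_range
    cols = _length_columns(rng)
    rows = []
    for r in dataset.records:
        row: dict[str, object] = {"sample_id": r.sample_id}
        row.update(zip(cols, (repr(float(v)) for v in r.profile.proportions)))
        for name in OPTIONAL_COLUMNS:
            v = getattr(r, name)
            if v is not None:
                row[name] = repr(float(v))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature zero-mean/unit-variance transform fitted on training data.

    Population (divide-by-N) variance; zero-variance features get scale 1 so
    they map to exactly 0.
    """

    mean_: np.ndarray
    scale_: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Standardizer":
        return cls(np.asarray(d["mean"], float), np.asarray(d["scale"], float))


def fit_standardizer(profiles: Iterable[LengthProfile] | np.ndarray) -> Standardizer:
    """Fit the zero-mean/unit-variance transform on training profiles only."""
    if isinstance(profiles, np.ndarray):
        X = profiles
    else:
        X = np.vstack([p.proportions for p in profiles])
    if X.shape[0] < 2:
        raise ValidationError("standardizer needs at least 2 training profiles")
    scaler = StandardScaler().fit(X)  # population variance, scale 1 on constants
    return Standardizer(mean_=scaler.mean_.copy(), scale_=scaler.scale_.copy())


def apply_standardizer(
    standardizer: Standardizer, profiles: Iterable[LengthProfile] | np.ndarray
) -> np.ndarray:
    if isinstance(profiles, np.ndarray):
        X = profiles
    else:
        X = np.vstack([p.proportions for p in profiles])
    return standardizer.transform(X)
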