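"""LOESS-based GC-bias correction of binned fragment counts.

Coverage in shallow WGS depends on local GC content.  The correction fits a
locally weighted regression of per-bin fragment count on per-bin GC
fraction over usable autosomal bins and reweights each bin by
``global_mean / fitted(GC)`` so that corrected counts are flat in GC.
Per-chromosome corrected totals are the sums of corrected bin counts —
except chromosome Y, whose mappable portion is too small for a stable fit
and whose totals always pass through uncorrected.

Bin tables are plain DataFrames with columns ``chrom, start, end, gc,
raw_count`` (BED-like, 0-based half-open); ``gc`` is NaN where the
reference sequence is mostly N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_BIN_SIZE = 20_000
DEFAULT_SPAN = 0.3
MAX_N_FRACTION = 0.5
MIN_USABLE_BINS = 50

BIN_COLUMNS = ["chrom", "start", "end", "gc", "raw_count"]


class GCModelError(ValueError):
    pass


def _is_autosome(chrom: str) -> bool:
    base = chrom[3:] if chrom.startswith("chr") else chrom
    return base.isdigit()


def _is_chry(chrom: str) -> bool:
    base = chrom[3:] if chrom.startswith("chr") else chrom
    return base.upper() == "Y"


def make_bins(chrom_lengths: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Tile chromosomes into fixed-size bins (last bin truncated)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, bin_size):
            rows.append((chrom, start, min(start + bin_size, length)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["gc"] = np.nan
    df["raw_count"] = 0.0
    return df


def compute_bin_gc(reference_fasta: str | Path, bins: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``gc`` column from a reference FASTA.

    GC = (G+C)/(A+C+G+T) per bin; bins with more than 50% N are flagged
    invalid (gc = NaN).
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference_fasta), "fasta")}
    out = bins.copy()
    gcs = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        if row.chrom not in seqs:
            raise GCModelError(f"chromosome {row.chrom!r} absent from reference")
        seq = seqs[row.chrom][row.start:row.end]
        if not seq:
            continue
        n_frac = seq.count("N") / len(seq)
        acgt = sum(seq.count(b) for b in "ACGT")
        if n_frac > MAX_N_FRACTION or acgt == 0:
            continue
        gcs[i] = (seq.count("G") + seq.count("C")) / acgt
    out["gc"] = gcs
    return out


@dataclass
class GCModel:
    """Fitted count-vs-GC curve plus the global mean used for reweighting."""

    gc_grid: np.ndarray       # sorted GC values of the fit
    fitted_grid: np.ndarray   # lowess-fitted expected count at gc_grid
    global_mean: float
    span: float

    def expected_count(self, gc) -> np.ndarray:
        """Expected raw count at the given GC fraction(s) (linear interp,
        constant extrapolation beyond the fitted range)."""
        return np.interp(np.asarray(gc, float), self.gc_grid, self.fitted_grid)


def usable_mask(bins: pd.DataFrame) -> np.ndarray:
    return np.asarray(bins["gc"].notna() & (bins["raw_count"] > 0))


def fit_gc_model(bins: pd.DataFrame, span: float = DEFAULT_SPAN) -> GCModel:
    """Locally weighted regression of raw count on GC over usable autosomal bins."""
    auto = np.asarray([_is_autosome(c) for c in bins["chrom"]])
    mask = usable_mask(bins) & auto
    if mask.sum() < MIN_USABLE_BINS:
        raise GCModelError(
            f"need >= {MIN_USABLE_BINS} usable autosomal bins with positive counts, "
            f"got {int(mask.sum())}"
        )
    gc = bins.loc[mask, "gc"].to_numpy(float)
    counts = bins.loc[mask, "raw_count"].to_numpy(float)
    sm = lowess(counts, gc, frac=span, return_sorted=True)
    # lowess returns one row per input point; collapse ties on gc
    grid, idx = np.unique(sm[:, 0], return_index=True)
    fitted = sm[idx, 1]
    model = GCModel(gc_grid=grid, fitted_grid=fitted, global_mean=float(counts.mean()), span=span)
    if np.any(model.fitted_grid <= 0):
        raise GCModelError("fitted GC curve is non-positive; model misfit")
    return model


def apply_gc_weights(bins: pd.DataFrame, model: GCModel) -> tuple[pd.DataFrame, pd.Series]:
    """Reweight bin counts and sum per-chromosome corrected totals.

    Corrected count = raw * global_mean / fitted(GC) for usable bins;
    invalid bins keep their raw count but are excluded from totals.
    Chromosome Y totals are always the raw sums.
    """
    out = bins.copy()
    mask = usable_mask(out)
    fitted = model.expected_count(out.loc[mask, "gc"])
    if np.any(fitted <= 0):
        raise GCModelError("fitted expected count <= 0 at a usable bin")
    corrected = out["raw_count"].to_numpy(float).copy()
    corrected[np.asarray(mask)] = (
        out.loc[mask, "raw_count"].to_numpy(float) * model.global_mean / fitted
    )
    out["corrected_count"] = corrected

    totals = {}
    for chrom, grp in out.groupby("chrom", sort=False):
        if _is_chry(chrom):
            totals[chrom] = float(grp["raw_count"].sum())
        else:
            gmask = usable_mask(grp)
            totals[chrom] = float(grp.loc[gmask, "corrected_count"].sum())
    return out, pd.Series(totals, name="corrected_total")


def read_bin_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BIN_COLUMNS if c not in df.columns]
    if missing:
        raise GCModelError(f"{path}: missing bin-table columns {missing}")
    return df


def write_bin_table(bins: pd.DataFrame, path: str | Path) -> None:
    bins.to_csv(path, sep="\t", index=False)
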