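"""From read counts and qPCR totals to filtered absolute abundances.

Amplicon sequencing of pooled droplets yields per-sample sequence-variant
(SV) read counts — compositional data.  A parallel qPCR measurement of
total 16S rRNA gene concentration restores scale: multiplying each
sample's relative SV abundances by its qPCR total gives absolute SV
abundances in qPCR units, which is the quantity all growth statistics are
computed on.

The preprocessing order is fixed: sequencing-depth filter (samples must
exceed 5,000 reads), pseudocount of 1, normalisation to relative
abundances, then qPCR scaling.  Detection of an SV (for the >5-samples
inclusion rule) is always judged on raw counts, before the pseudocount —
otherwise the pseudocount would make every SV "detected" everywhere.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "MIN_READS",
    "MIN_DETECTION_SAMPLES",
    "filter_low_depth",
    "to_relative_with_pseudocount",
    "absolute_abundance",
    "detection_filter",
]

#: Samples must have strictly more reads than this to be analysed.
MIN_READS = 5000

#: SVs must appear (raw count > 0) in strictly more samples than this.
MIN_DETECTION_SAMPLES = 5


def filter_low_depth(counts: pd.DataFrame, min_reads: int = MIN_READS) -> pd.DataFrame:
    """Drop samples (rows) whose total read count is not > ``min_reads``.

    Shallow samples are prone to library-preparation artifacts; the strict
    inequality means a sample with exactly ``min_reads`` reads is removed.
    """
    depth = counts.sum(axis=1)
    keep = depth > min_reads
    dropped = list(counts.index[~keep])
    if dropped:
        warnings.warn(
            f"removed {len(dropped)} low-depth sample(s): {dropped}", stacklevel=2
        )
    out = counts.loc[keep]
    if out.empty:
        warnings.warn("depth filter removed every sample", stacklevel=2)
    return out


def to_relative_with_pseudocount(
    counts: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Pseudocounted relative abundances; each row sums to 1.

    A pseudocount (default 1) avoids zeros ahead of the log transform used
    in growth fitting.  An all-zero row becomes uniform.
    """
    if counts.shape[1] == 0:
        raise ValueError("count table has no SV columns")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    shifted = counts.astype(float) + pseudocount
    row_sums = shifted.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("a row sums to zero; use a positive pseudocount")
    return shifted.div(row_sums, axis=0)


def absolute_abundance(relative: pd.DataFrame, qpcr: pd.Series) -> pd.DataFrame:
    """Scale relative abundances by per-sample total 16S concentration.

    ``value(s, v) = relative(s, v) × qpcr(s)``; row sums equal the qPCR
    totals.  Negative qPCR readings (instrument artifacts) are clamped to
    0 with a warning.  A sample missing from ``qpcr`` raises a KeyError
    naming it.
    """
    missing = [s for s in relative.index if s not in qpcr.index]
    if missing:
        raise KeyError(f"samples missing from qPCR table: {missing}")
    q = qpcr.loc[relative.index].astype(float)
    if (q < 0).any():
        bad = list(q.index[q < 0])
        warnings.warn(f"clamped negative qPCR value(s) to 0: {bad}", stacklevel=2)
        q = q.clip(lower=0.0)
    return relative.mul(q, axis=0)


def detection_filter(
    counts: pd.DataFrame, min_samples: int = MIN_DETECTION_SAMPLES
) -> pd.Index:
    """SVs detected (raw count > 0) in strictly more than ``min_samples`` samples.

    Returns the retained SV identifiers, in table order.
    """
    presence = (counts > 0).sum(axis=0)
    return counts.columns[presence > min_samples]
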