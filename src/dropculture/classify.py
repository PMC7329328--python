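"""Endpoint preprocessing and growth/no-growth threshold calibration.

Endpoint carbon-source assays compare each carbon condition with a
matched no-carbon control: sample qPCR totals indicating overall growth
below the mean no-carbon level are zeroed, absolute SV abundances are
computed, per-SV medians are taken across replicates and the matched
no-carbon median is subtracted (floored at zero).  The result is a
continuous SV × carbon growth matrix.

To turn continuous growth values into growth calls, a threshold is
calibrated against reference data — well-plate OD screens of isolates,
where an isolate is considered to grow on a carbon when its OD exceeds
20% of its per-isolate maximum.  Calibration scans all achievable
thresholds on the growth scores and picks the one maximizing Youden's
J = TPR − FPR.  In kinetics mode the threshold is the growth limit of
detection (Δln ≥ 1.48, about 2.14 doublings); in endpoint mode it is
assay-specific and must be calibrated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import absolute_abundance, to_relative_with_pseudocount

__all__ = [
    "GrowthThreshold",
    "ConfusionMetrics",
    "PLATE_GROWTH_FRACTION",
    "plate_growth_reference",
    "preprocess_endpoint",
    "roc_youden",
    "classify_growth",
    "confusion_metrics",
]

#: Well-plate growth call: OD above this fraction of the isolate's maximum.
PLATE_GROWTH_FRACTION = 0.20


@dataclass(frozen=True)
class GrowthThreshold:
    """A calibrated growth threshold with its ROC context.

    ``roc_points`` holds one row per candidate threshold (sorted by
    threshold) with the TPR and FPR of the rule ``score ≥ threshold``.
    """

    threshold: float
    j_statistic: float
    tpr: float
    fpr: float
    roc_points: pd.DataFrame


@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary-classification summary; undefined ratios are NaN."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    false_discovery_rate: float


def plate_growth_reference(od: pd.DataFrame,
                           fraction: float = PLATE_GROWTH_FRACTION) -> pd.DataFrame:
    """Boolean growth calls from a well-plate OD endpoint matrix.

    Each isolate row is normalised to its own maximum OD; entries strictly
    above ``fraction`` (default 20%) of that maximum are growth.  An
    all-zero isolate yields an all-false row with a warning.
    """
    calls = pd.DataFrame(False, index=od.index, columns=od.columns, dtype=bool)
    for isolate, row in od.iterrows():
        m = row.max()
        if m <= 0:
            warnings.warn(
                f"isolate {isolate!r} has no positive OD; calling all-false",
                stacklevel=2,
            )
            continue
        calls.loc[isolate] = row > fraction * m
    return calls


def preprocess_endpoint(
    counts: pd.DataFrame,
    qpcr: pd.Series,
    metadata: pd.DataFrame,
    no_carbon: str = "none",
    pseudocount: float = 1.0,
    condition_col: str = "condition",
    donor_col: str = "donor",
) -> pd.DataFrame:
    """Endpoint assay preprocessing against matched no-carbon controls.

    Steps, per donor when a donor column is present: (1) zero any
    sample's qPCR total that falls below the mean no-carbon qPCR (such
    samples show no overall growth); (2) compute absolute abundances
    (pseudocount → relative → qPCR scaling); (3) take the per-SV median
    across replicates within each condition; (4) subtract the matched
    no-carbon median per SV; (5) floor negatives at zero.

    Returns a continuous SV × carbon growth matrix (no-carbon column
    removed); with several donors the rows are a (donor, SV) MultiIndex.
    """
    if condition_col not in metadata.columns:
        raise ValueError(f"metadata lacks a {condition_col!r} column")
    if no_carbon not in set(metadata[condition_col]):
        raise ValueError(f"no-carbon condition {no_carbon!r} absent from metadata")

    if donor_col in metadata.columns and metadata[donor_col].nunique() > 1:
        pieces = {}
        for donor, sub in metadata.groupby(donor_col):
            pieces[donor] = _preprocess_one(
                counts.loc[sub.index], qpcr.loc[sub.index], sub,
                no_carbon, pseudocount, condition_col,
            )
        return pd.concat(pieces, names=["donor", "sv"])
    return _preprocess_one(
        counts.loc[metadata.index], qpcr.loc[metadata.index], metadata,
        no_carbon, pseudocount, condition_col,
    )


def _preprocess_one(counts, qpcr, metadata, no_carbon, pseudocount,
                    condition_col) -> pd.DataFrame:
    nc_samples = metadata.index[metadata[condition_col] == no_carbon]
    if len(nc_samples) == 0:
        raise ValueError(f"no samples for no-carbon condition {no_carbon!r}")
    nc_mean = float(qpcr.loc[nc_samples].mean())
    adjusted = qpcr.astype(float).where(qpcr >= nc_mean, 0.0)

    rel = to_relative_with_pseudocount(counts, pseudocount=pseudocount)
    absolute = absolute_abundance(rel, adjusted)

    medians = absolute.groupby(metadata[condition_col]).median()
    control = medians.loc[no_carbon]
    net = medians.sub(control, axis=1).clip(lower=0.0)
    net = net.drop(index=no_carbon)
    return net.T  # SV × carbon


def roc_youden(scores, labels) -> GrowthThreshold:
    """Calibrate a growth threshold by maximizing Youden's J = TPR − FPR.

    Candidate thresholds are the midpoints between consecutive sorted
    unique scores plus sentinels below and above all scores; a score is
    classified as growth when it is ≥ the threshold.  Ties on J are
    broken toward the smallest threshold (maximal sensitivity).
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=bool).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes for a ROC")

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])

    rows = []
    best = None
    for thr in cands:
        pred = s >= thr
        tpr = float((pred & y).sum() / n_pos)
        fpr = float((pred & ~y).sum() / n_neg)
        j = tpr - fpr
        rows.append((float(thr), tpr, fpr))
        if best is None or j > best[0] + 1e-15:
            best = (j, float(thr), tpr, fpr)
    j, thr, tpr, fpr = best
    roc = pd.DataFrame(rows, columns=["threshold", "tpr", "fpr"])
    return GrowthThreshold(threshold=thr, j_statistic=j, tpr=tpr, fpr=fpr,
                           roc_points=roc)


def classify_growth(matrix: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Boolean growth calls: entry true iff value ≥ threshold (closed rule)."""
    return matrix >= threshold


def confusion_metrics(predicted: pd.DataFrame | np.ndarray,
                      reference: pd.DataFrame | np.ndarray) -> ConfusionMetrics:
    """Accuracy, sensitivity, specificity and FDR of boolean growth calls.

    Ratios with a zero denominator are reported as NaN rather than 0.
    """
    p = np.asarray(predicted, dtype=bool)
    r = np.asarray(reference, dtype=bool)
    if p.shape != r.shape:
        raise ValueError("predicted and reference must have the same shape")
    tp = int((p & r).sum())
    fp = int((p & ~r).sum())
    tn = int((~p & ~r).sum())
    fn = int((~p & r).sum())

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=ratio(tp + tn, tp + fp + tn + fn),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        false_discovery_rate=ratio(fp, tp + fp),
    )
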