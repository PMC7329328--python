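"""Ecology statistics on SV × carbon growth matrices.

Once growth calls are made, the biological questions are about structure:
which taxa are primary degraders (grow with at least one polysaccharide
as sole carbon source), whether degraders are specialists (exactly one
polysaccharide) or generalists (two or more), whether those lifestyles
are unevenly distributed across phyla, which prebiotic combinations would
stimulate the most taxa, and whether utilization profiles track
phylogeny.

Glucose is a viability control throughout: glucose consumers normalise
degrader statistics per donor (PD/GC) to control for differences in
sample handling, but glucose never counts toward a lifestyle.

All hypothesis tests are permutation tests with an add-one correction,
``p = (exceed + 1)/(n_perm + 1)``, so p-values are never zero and are
exactly reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "PermutationResult",
    "MantelResult",
    "primary_degraders",
    "classify_lifestyle",
    "normalize_by_glucose",
    "phylum_lifestyle_permutation",
    "permutation_frame",
    "combo_coverage",
    "combo_enrichment",
    "cluster_profiles",
    "mantel_test",
]


@dataclass(frozen=True)
class PermutationResult:
    """One permutation test: observed statistic, exceedances, p-value."""

    observed: float
    n_permutations: int
    exceed_count: int
    p_value: float


@dataclass(frozen=True)
class MantelResult:
    """Mantel matrix correlation and its permutation p-value."""

    r: float
    p_value: float
    n_permutations: int


def _check_polys(matrix: pd.DataFrame, polysaccharides: Sequence[str]) -> list[str]:
    polys = list(polysaccharides)
    if not polys:
        raise ValueError("no polysaccharide columns flagged")
    missing = [c for c in polys if c not in matrix.columns]
    if missing:
        raise ValueError(f"polysaccharide columns absent from matrix: {missing}")
    return polys


def primary_degraders(matrix: pd.DataFrame,
                      polysaccharides: Sequence[str]) -> pd.Index:
    """SVs growing on at least one polysaccharide (glucose/no-carbon excluded)."""
    polys = _check_polys(matrix, polysaccharides)
    mask = matrix[polys].any(axis=1)
    return matrix.index[mask]


def classify_lifestyle(matrix: pd.DataFrame,
                       polysaccharides: Sequence[str]) -> pd.Series:
    """Label each SV specialist / generalist / nondegrader.

    Exactly one utilized polysaccharide makes a specialist, two or more a
    generalist; specialists and generalists together are exactly the
    primary degraders.
    """
    polys = _check_polys(matrix, polysaccharides)
    n = matrix[polys].sum(axis=1)
    labels = pd.Series("nondegrader", index=matrix.index, name="lifestyle")
    labels[n == 1] = "specialist"
    labels[n >= 2] = "generalist"
    return labels


def normalize_by_glucose(degrader_stat: pd.Series,
                         glucose_stat: pd.Series) -> pd.Series:
    """Per-donor PD/GC ratio, controlling degrader levels for viability.

    Elementwise ratio of a primary-degrader statistic (richness count or
    summed abundance) to the matching glucose-consumer statistic.  Donors
    with a zero glucose statistic get NaN (undefined ratio) with a
    warning.
    """
    gc = glucose_stat.astype(float)
    ratio = degrader_stat.astype(float) / gc.where(gc > 0)
    undefined = list(ratio.index[gc <= 0])
    if undefined:
        warnings.warn(
            f"glucose-consumer statistic is 0 for donor(s) {undefined}; "
            "ratio undefined", stacklevel=2,
        )
    return ratio.rename("pd_gc_ratio")


def phylum_lifestyle_permutation(
    matrix: pd.DataFrame,
    taxonomy: pd.Series,
    polysaccharides: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[tuple[str, str], PermutationResult]:
    """Test phylum × lifestyle association by permuting taxonomy labels.

    The statistic for each (phylum, lifestyle) cell is the number of SVs
    in it.  The null keeps every SV's utilization profile (hence its
    lifestyle) intact and randomly reassigns phylum labels across SVs;
    the one-sided p-value is the add-one-corrected fraction of
    permutations in which the cell count is at or above the observed one.
    Results are returned for every phylum × {specialist, generalist}
    combination.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value",
                      stacklevel=2)
    lifestyles = classify_lifestyle(matrix, polysaccharides)
    tax = taxonomy.loc[matrix.index]
    phyla = sorted(tax.unique())
    kinds = ["specialist", "generalist"]

    ph_codes = pd.Categorical(tax, categories=phyla).codes.astype(np.intp)
    ls_codes = pd.Categorical(lifestyles, categories=kinds).codes.astype(np.intp)
    in_kind = ls_codes >= 0  # nondegraders carry labels but count in no cell

    def cell_counts(ph: np.ndarray) -> np.ndarray:
        counts = np.zeros((len(phyla), len(kinds)), dtype=np.intp)
        np.add.at(counts, (ph[in_kind], ls_codes[in_kind]), 1)
        return counts

    observed = cell_counts(ph_codes)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        exceed += cell_counts(rng.permutation(ph_codes)) >= observed

    results: dict[tuple[str, str], PermutationResult] = {}
    for i, ph in enumerate(phyla):
        for j, kind in enumerate(kinds):
            results[(ph, kind)] = PermutationResult(
                observed=float(observed[i, j]),
                n_permutations=n_perm,
                exceed_count=int(exceed[i, j]),
                p_value=(int(exceed[i, j]) + 1) / (n_perm + 1),
            )
    return results


def permutation_frame(
    results: Mapping[tuple[str, str], PermutationResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tabulate permutation results, flagging cells with p below alpha."""
    rows = [
        {
            "phylum": ph, "lifestyle": kind, "observed": r.observed,
            "exceed_count": r.exceed_count, "n_permutations": r.n_permutations,
            "p_value": r.p_value, "significant": r.p_value < alpha,
        }
        for (ph, kind), r in results.items()
    ]
    return pd.DataFrame(rows).set_index(["phylum", "lifestyle"])


def combo_coverage(matrix: pd.DataFrame, polysaccharides: Sequence[str],
                   k: int) -> pd.Series:
    """Fraction of primary degraders stimulated by each size-k prebiotic combo.

    For every size-``k`` subset of polysaccharides, the fraction of
    primary degraders growing on at least one member.  Sorted descending,
    so the first entry is the best cocktail of that size.
    """
    polys = _check_polys(matrix, polysaccharides)
    if not 1 <= k <= len(polys):
        raise ValueError(f"k must lie in [1, {len(polys)}]")
    degraders = primary_degraders(matrix, polys)
    if len(degraders) == 0:
        raise ValueError("no primary degraders in matrix")
    sub = matrix.loc[degraders, polys]
    cov = {
        combo: float(sub[list(combo)].any(axis=1).mean())
        for combo in combinations(polys, k)
    }
    out = pd.Series(cov, name="coverage")
    return out.sort_values(ascending=False, kind="stable")


def combo_enrichment(
    matrix: pd.DataFrame,
    polysaccharides: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Over/under-representation of exact utilization patterns.

    The null preserves each carbon's marginal prevalence by independently
    shuffling every polysaccharide column across SVs, breaking
    between-carbon correlation.  For each utilization pattern observed in
    the data, two one-sided add-one-corrected p-values are reported:
    ``p_over`` (permuted count ≥ observed) and ``p_under`` (≤ observed).
    With fewer than two polysaccharides there are no combinations and the
    result is empty.
    """
    polys = _check_polys(matrix, polysaccharides)
    if len(polys) < 2:
        return pd.DataFrame(
            columns=["observed", "exceed_over", "exceed_under",
                     "p_over", "p_under"]
        )
    X = matrix[polys].to_numpy(dtype=bool)
    n, m = X.shape
    weights = 1 << np.arange(m)

    def pattern_counts(mat: np.ndarray) -> np.ndarray:
        codes = mat @ weights
        return np.bincount(codes, minlength=1 << m)

    observed = pattern_counts(X)
    seen = np.flatnonzero(observed)
    rng = np.random.default_rng(seed)
    over = np.zeros(1 << m, dtype=np.intp)
    under = np.zeros(1 << m, dtype=np.intp)
    perm = X.copy()
    for _ in range(n_perm):
        for j in range(m):
            perm[:, j] = X[rng.permutation(n), j]
        counts = pattern_counts(perm)
        over += counts >= observed
        under += counts <= observed

    rows = []
    for code in seen:
        pattern = tuple(bool(code >> j & 1) for j in range(m))
        rows.append({
            "pattern": pattern,
            "carbons": tuple(p for j, p in enumerate(polys) if code >> j & 1),
            "observed": int(observed[code]),
            "exceed_over": int(over[code]),
            "exceed_under": int(under[code]),
            "p_over": (int(over[code]) + 1) / (n_perm + 1),
            "p_under": (int(under[code]) + 1) / (n_perm + 1),
        })
    return pd.DataFrame(rows).set_index("pattern")


def cluster_profiles(
    matrix: pd.DataFrame,
    k: int = 2,
    method: str = "average",
    cut_height: float | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Hierarchically cluster SV growth profiles (Euclidean distance).

    Agglomerative clustering of the continuous growth matrix rows,
    returning the linkage matrix and a flat assignment — by default a
    two-group cut (single- vs multi-carbon profiles), overridable with an
    explicit ``cut_height``.  Rows are processed in SV-id order so
    zero-distance ties resolve deterministically.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 SVs to cluster")
    ordered = matrix.sort_index()
    Z = linkage(ordered.to_numpy(dtype=float), method=method,
                metric="euclidean")
    if cut_height is not None:
        flat = fcluster(Z, t=cut_height, criterion="distance")
    else:
        flat = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=ordered.index, name="cluster")
    return Z, labels.loc[matrix.index]


def mantel_test(
    dist_profiles: np.ndarray | pd.DataFrame,
    dist_taxonomy: np.ndarray | pd.DataFrame,
    n_perm: int = 9_999,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson correlation of the off-diagonal entries.  The
    p-value comes from jointly permuting rows and columns of the second
    matrix, one-sided for positive association, add-one corrected.
    Supplying 0/1 same-taxon distance matrices per rank tests whether
    utilization profiles track phylogeny at that rank.
    """
    X = np.asarray(dist_profiles, dtype=float)
    Y = np.asarray(dist_taxonomy, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("distance matrices must be square and equally sized")
    if X.shape[0] < 3:
        raise ValueError("Mantel test needs matrices of size >= 3")
    for M, name in ((X, "first"), (Y, "second")):
        if not np.allclose(M, M.T):
            raise ValueError(f"{name} matrix is not symmetric")

    iu = np.triu_indices_from(X, k=1)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) == 0 or np.std(b) == 0:
            raise ValueError("constant distance matrix; correlation undefined")
        return float(np.corrcoef(a, b)[0, 1])

    x = X[iu]
    r_obs = corr(x, Y[iu])
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr(x, Y[np.ix_(p, p)][iu]) >= r_obs:
            exceed += 1
    return MantelResult(r=r_obs, p_value=(exceed + 1) / (n_perm + 1),
                        n_permutations=n_perm)
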