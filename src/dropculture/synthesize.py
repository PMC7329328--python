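"""Synthetic droplet-culture experiments with known ground truth.

Real droplet experiments observe a community only through sequencing
counts and bulk qPCR.  This module generates such observations from a
fully known latent community so that every downstream stage — abundance
preprocessing, Gompertz fitting, threshold calibration, ecology
statistics — can be tested end to end against truth.

The latent model: each sequence variant (SV) carries modified-Gompertz
parameters on the natural-log abundance scale, so the curve fitted
downstream is exactly the simulated latent trajectory.  Nongrowing or
nonviable SVs sit flat at their inoculum offset.  At each sampled time
point the total 16S concentration is the sum of latent abundances
perturbed by multiplicative lognormal qPCR noise, and reads are drawn
multinomially from the latent relative abundances at a fixed depth.

Carbon-source experiments add a known SV × carbon utilization truth
matrix with specialist/generalist structure: an SV grows at the 48-h
endpoint only on carbons it can utilize, glucose acts as the viability
control (every growing SV utilizes it) and the no-carbon condition stays
at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinetics import DEFAULT_BOUNDS, FitBounds, GompertzParams, gompertz

__all__ = [
    "SyntheticCommunitySpec",
    "random_community",
    "simulate_timeseries",
    "simulate_prebiotic_experiment",
    "simulate_reference_plates",
    "DEFAULT_POLYSACCHARIDES",
    "ENDPOINT_TIME_H",
]

DEFAULT_POLYSACCHARIDES = ("inulin", "gos", "dextrin", "xylan")

#: Default endpoint sampling time: carbon-source assays are read out
#: roughly two days after inoculation, once most taxa have saturated.
ENDPOINT_TIME_H = 48.0

_PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")
_PHYLUM_PROBS = (0.5, 0.25, 0.15, 0.10)


@dataclass
class SyntheticCommunitySpec:
    """A latent community: growth parameters, viability, taxonomy, truth.

    ``growth_params`` is an (n_svs, 4) array of (A, μ, λ, A₀) per SV on
    the ln-abundance scale; nongrowers (``growing_flags`` False) have
    μ = 0 and A = 0 so their latent trajectory is flat at A₀.
    ``initial_fractions`` are inoculum relative abundances (a simplex).
    ``utilization_truth`` is a boolean SV × carbon matrix whose columns
    include every assayable carbon (glucose equals the growing flags;
    polysaccharide columns define degrader lifestyles).
    """

    growth_params: np.ndarray
    growing_flags: np.ndarray
    initial_fractions: np.ndarray
    taxonomy: pd.Series
    utilization_truth: pd.DataFrame
    seed: int
    sv_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.growth_params = np.asarray(self.growth_params, dtype=float)
        self.growing_flags = np.asarray(self.growing_flags, dtype=bool)
        self.initial_fractions = np.asarray(self.initial_fractions, dtype=float)
        n = self.growth_params.shape[0]
        if self.growth_params.shape != (n, 4):
            raise ValueError("growth_params must be (n_svs, 4)")
        if not self.sv_ids:
            self.sv_ids = [f"sv{i:03d}" for i in range(n)]
        if len(self.sv_ids) != n or self.growing_flags.shape != (n,):
            raise ValueError("per-SV field lengths disagree")
        if not np.isclose(self.initial_fractions.sum(), 1.0):
            raise ValueError("initial_fractions must sum to 1")
        lb, ub = DEFAULT_BOUNDS.arrays()
        growers = self.growth_params[self.growing_flags]
        if growers.size and not (
            np.all(growers > lb) and np.all(growers < ub)
        ):
            raise ValueError("grower parameters must lie strictly inside bounds")

    @property
    def n_svs(self) -> int:
        return self.growth_params.shape[0]

    def params(self, i: int) -> GompertzParams:
        return GompertzParams(*self.growth_params[i])


def random_community(
    n_svs: int = 50,
    polysaccharides: Sequence[str] = DEFAULT_POLYSACCHARIDES,
    seed: int = 0,
    p_growing: float = 0.25,
    p_degrader: float = 0.5,
    p_specialist: float = 0.3,
    dirichlet_concentration: float = 0.5,
    bounds: FitBounds = DEFAULT_BOUNDS,
) -> SyntheticCommunitySpec:
    """Draw a random community emulating a human gut droplet inoculum.

    Defaults mirror the assayed communities: about a quarter of SVs
    actively grow in rich medium, half of the growers degrade at least
    one polysaccharide, and specialists (exactly one polysaccharide) are
    outnumbered by generalists roughly 2:1.  Inoculum fractions come from
    a symmetric Dirichlet (concentration 0.5) so most taxa are rare.
    Growth parameters are drawn from ranges typical of gut anaerobes
    (doubling times of tens of minutes to hours, lags up to ~10 h),
    strictly inside the fitting bounds.
    """
    rng = np.random.default_rng(seed)
    growing = rng.random(n_svs) < p_growing
    # A ~ amplitude of ln-abundance increase; mu per hour; lam hours; A0 offset
    A = rng.uniform(2.0, 10.0, n_svs)
    mu = rng.uniform(0.1, 1.5, n_svs)
    lam = rng.uniform(0.5, 10.0, n_svs)
    A0 = rng.uniform(0.5, 5.0, n_svs)
    A[~growing] = 0.0
    mu[~growing] = 0.0
    params = np.column_stack([A, mu, lam, A0])

    fractions = rng.dirichlet(np.full(n_svs, dirichlet_concentration))
    taxonomy = pd.Series(
        rng.choice(_PHYLA, size=n_svs, p=_PHYLUM_PROBS),
        index=[f"sv{i:03d}" for i in range(n_svs)],
        name="phylum",
    )

    carbons = list(polysaccharides) + ["glucose"]
    truth = pd.DataFrame(
        False, index=taxonomy.index, columns=carbons, dtype=bool
    )
    truth["glucose"] = growing
    n_poly = len(polysaccharides)
    for i in np.flatnonzero(growing):
        if rng.random() >= p_degrader:
            continue
        if rng.random() < p_specialist or n_poly == 1:
            chosen = rng.choice(n_poly, size=1, replace=False)
        else:
            k = int(rng.integers(2, n_poly + 1))
            chosen = rng.choice(n_poly, size=k, replace=False)
        truth.iloc[i, sorted(chosen)] = True

    return SyntheticCommunitySpec(
        growth_params=params,
        growing_flags=growing,
        initial_fractions=fractions,
        taxonomy=taxonomy,
        utilization_truth=truth,
        seed=seed,
        sv_ids=list(taxonomy.index),
    )


def _latent_ln(spec: SyntheticCommunitySpec, t: float,
               active: np.ndarray | None = None) -> np.ndarray:
    """Latent ln-abundance of every SV at time ``t``.

    ``active`` optionally masks which SVs grow (condition-dependent);
    inactive or nongrowing SVs stay flat at A₀.
    """
    if active is None:
        active = spec.growing_flags
    y = np.empty(spec.n_svs)
    for i in range(spec.n_svs):
        A, mu, lam, A0 = spec.growth_params[i]
        if active[i] and spec.growing_flags[i]:
            y[i] = gompertz(t, GompertzParams(A, mu, lam, A0))
        else:
            y[i] = A0
    return y


def _qpcr_noise(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_timeseries(
    spec: SyntheticCommunitySpec,
    times: Iterable[float],
    read_depth: int = 30_000,
    qpcr_cv: float = 0.1,
    n_replicates: int = 1,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict]:
    """Simulate a destructive longitudinal sampling experiment.

    Returns ``(counts, qpcr, metadata, truth)`` where counts is a
    samples × SVs integer table (each row sums to ``read_depth``), qpcr
    the per-sample total 16S concentration, metadata carries time and
    replicate per sample, and truth records the latent ln-abundance
    matrix and the generating parameters.
    """
    times = list(times)
    if not times:
        raise ValueError("times must be nonempty")
    if any(t < 0 or t > 200 for t in times):
        raise ValueError("times must lie within [0, 200] hours")
    if read_depth <= 0:
        raise ValueError("read_depth must be positive")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    rows, qpcr_vals, meta_rows, latent_rows, names = [], [], [], [], []
    for t in times:
        y = _latent_ln(spec, t)
        abund = np.exp(y)
        frac = abund / abund.sum()
        for rep in range(1, n_replicates + 1):
            name = f"t{t:g}_r{rep}"
            names.append(name)
            rows.append(rng.multinomial(read_depth, frac))
            qpcr_vals.append(abund.sum() * float(_qpcr_noise(rng, qpcr_cv)))
            meta_rows.append({"time": float(t), "replicate": rep})
            latent_rows.append(y)

    counts = pd.DataFrame(rows, index=names, columns=spec.sv_ids, dtype=int)
    qpcr = pd.Series(qpcr_vals, index=names, name="qpcr")
    meta = pd.DataFrame(meta_rows, index=names)
    truth = {
        "latent_ln_abundance": pd.DataFrame(
            latent_rows, index=names, columns=spec.sv_ids
        ),
        "growth_params": spec.growth_params.copy(),
        "growing_flags": spec.growing_flags.copy(),
    }
    return counts, qpcr, meta, truth


def simulate_prebiotic_experiment(
    spec: SyntheticCommunitySpec,
    carbons: Sequence[str],
    n_replicates: int = 3,
    read_depth: int = 30_000,
    endpoint_time: float = ENDPOINT_TIME_H,
    qpcr_cv: float = 0.1,
    replicate_cv: float = 0.1,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict]:
    """Simulate an endpoint carbon-utilization screen.

    Each carbon condition (which must include the no-carbon control
    ``"none"``) is sampled at the endpoint in ``n_replicates`` replicates.
    An SV reaches its Gompertz endpoint only on carbons marked true in
    the utilization truth; otherwise (and always under no-carbon) it stays
    at its inoculum baseline.  Replicate-level biological noise is
    multiplicative lognormal on latent abundances, applied independently
    per replicate, on top of qPCR noise and multinomial counting.
    """
    carbons = list(carbons)
    if len(set(carbons)) != len(carbons):
        raise ValueError("duplicate carbon names")
    if "none" not in carbons:
        raise ValueError('the no-carbon control "none" must be included')
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)

    rows, qpcr_vals, meta_rows, names, latent = [], [], [], [], {}
    for carbon in carbons:
        if carbon == "none":
            active = np.zeros(spec.n_svs, dtype=bool)
        elif carbon in spec.utilization_truth.columns:
            active = spec.utilization_truth[carbon].to_numpy()
        else:
            raise KeyError(f"carbon {carbon!r} absent from utilization truth")
        y = _latent_ln(spec, endpoint_time, active=active)
        latent[carbon] = y
        base = np.exp(y)
        for rep in range(1, n_replicates + 1):
            abund = base * _qpcr_noise(rng, replicate_cv, size=spec.n_svs)
            frac = abund / abund.sum()
            name = f"{carbon}_r{rep}"
            names.append(name)
            rows.append(rng.multinomial(read_depth, frac))
            qpcr_vals.append(abund.sum() * float(_qpcr_noise(rng, qpcr_cv)))
            meta_rows.append({"condition": carbon, "replicate": rep})

    counts = pd.DataFrame(rows, index=names, columns=spec.sv_ids, dtype=int)
    qpcr = pd.Series(qpcr_vals, index=names, name="qpcr")
    meta = pd.DataFrame(meta_rows, index=names)
    truth = {
        "utilization": spec.utilization_truth.copy(),
        "latent_ln_endpoint": pd.DataFrame(latent, index=spec.sv_ids),
        "growing_flags": spec.growing_flags.copy(),
    }
    return counts, qpcr, meta, truth


def simulate_reference_plates(
    spec: SyntheticCommunitySpec,
    carbons: Sequence[str] | None = None,
    od_range: tuple[float, float] = (0.4, 1.0),
    noise_sd: float = 0.02,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a well-plate OD600 endpoint screen of isolates.

    OD endpoints are proportional to the utilization truth — a utilized
    carbon draws an OD in ``od_range``, an unutilized one is zero — plus
    additive Gaussian noise clipped at zero.  Returns ``(od, truth)``.
    Well-plate screens handle isolates, not communities, so the spec may
    hold at most 96 SVs.
    """
    if spec.n_svs > 96:
        raise ValueError("well-plate simulation limited to 96 isolates")
    cols = (
        list(carbons) if carbons is not None
        else list(spec.utilization_truth.columns)
    )
    truth = spec.utilization_truth[cols]
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    amplitude = rng.uniform(*od_range, size=truth.shape)
    od = amplitude * truth.to_numpy(dtype=float)
    if noise_sd > 0:
        od = np.clip(od + rng.normal(0.0, noise_sd, size=od.shape), 0.0, None)
    od_df = pd.DataFrame(od, index=truth.index, columns=cols)
    return od_df, truth.copy()
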