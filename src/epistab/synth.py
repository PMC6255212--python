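"""Synthetic-data generators for every input the pipeline consumes.

Each generator draws from the same model family its downstream fit assumes
(second-order decay, two-state melt, flat-then-linear SLS rise, additive
hypercube plus pairwise couplings, multivariate-Gaussian CA fluctuations),
so at zero noise every fit is an exact right-inverse of its generator.
Noise is Gaussian on the measured channel; all randomness comes from an
explicit seed, so an identical spec yields identical output.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    ActivityDecaySeries,
    MeltSeries,
    StabilityRecord,
    TemperatureActivitySeries,
    TrajectoryEnsemble,
    celsius_to_kelvin,
)
from .errors import ValidationError
from .unfolding import two_state_signal

DEFAULT_T_GRID = np.arange(30.0, 91.0, 1.0)  # thermal-ramp readout, every 1 degC


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_decay(
    kd: float,
    a0: float = 100.0,
    times: np.ndarray | None = None,
    sigma: float = 0.0,
    seed=0,
    variant: str = "synthetic",
    temperature: float = 60.0,
) -> ActivityDecaySeries:
    """Second-order decay series A(t) = 1/(1/A0 + kd t) with Gaussian noise on A."""
    if kd < 0 or a0 <= 0:
        raise ValidationError("need kd >= 0 and A0 > 0")
    if times is None:
        times = np.arange(0.0, 70.0, 10.0)
    times = np.asarray(times, dtype=float)
    a = 1.0 / (1.0 / a0 + kd * times)
    if sigma > 0:
        a = a + _rng(seed).normal(0.0, sigma, size=a.shape)
        if np.any(a <= 0):
            warnings.warn("noise produced non-positive activities; clipping", stacklevel=2)
            a = np.clip(a, 1e-6, None)
    return ActivityDecaySeries(variant=variant, temperature=temperature, times=times, activities=a)


def gen_melt(
    tm_c: float,
    dhvh: float,
    i_n: float = 0.85,
    a: float = 1e-4,
    i_d: float = 1.05,
    b: float = 5e-5,
    t_grid: np.ndarray | None = None,
    sigma: float = 0.0,
    seed=0,
    variant: str = "synthetic",
    sls: np.ndarray | None = None,
) -> MeltSeries:
    """Two-state melt curve on a thermal ramp; baselines linear in Kelvin.

    Defaults mimic an intrinsic-fluorescence 350/330 ratio rising from ~0.9
    to ~1.07 across the transition on a 30-90 degC per-1-degC grid.
    """
    t_c = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    if not (t_c.min() < tm_c < t_c.max()):
        raise ValidationError(f"Tm={tm_c} outside the temperature grid")
    t_k = celsius_to_kelvin(t_c)
    y = two_state_signal(t_k, i_n, a, i_d, b, dhvh, celsius_to_kelvin(tm_c))
    if sigma > 0:
        y = y + _rng(seed).normal(0.0, sigma, size=y.shape)
    return MeltSeries(variant=variant, temperatures=t_c, ratio=y, sls=sls)


def gen_sls(
    tagg_c: float,
    rise_slope: float = 1000.0,
    baseline: float = 100.0,
    t_grid: np.ndarray | None = None,
    sigma: float = 0.0,
    seed=0,
    variant: str = "synthetic",
) -> MeltSeries:
    """SLS channel: flat baseline, then a linear rise starting at Tagg."""
    t_c = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    y = baseline + rise_slope * np.clip(t_c - tagg_c, 0.0, None)
    if sigma > 0:
        y = y + _rng(seed).normal(0.0, sigma, size=y.shape)
    return MeltSeries(variant=variant, temperatures=t_c, sls=y)


def gen_t50_series(
    t50_c: float,
    width: float = 1.5,
    upper: float = 100.0,
    lower: float = 0.0,
    t_grid: np.ndarray | None = None,
    sigma: float = 0.0,
    seed=0,
    variant: str = "synthetic",
) -> TemperatureActivitySeries:
    """Boltzmann residual-activity-vs-temperature curve for T50 fitting."""
    t_c = np.arange(22.0, 66.0, 1.0) if t_grid is None else np.asarray(t_grid, dtype=float)
    ra = lower + (upper - lower) / (1.0 + np.exp((t_c - t50_c) / width))
    if sigma > 0:
        ra = ra + _rng(seed).normal(0.0, sigma, size=ra.shape)
    return TemperatureActivitySeries(variant=variant, temperatures=t_c, activities=ra)


@dataclass
class TrajectoryTruth:
    """Ground truth of a generated ensemble: target DCCM and RMSF."""

    dccm: np.ndarray
    rmsf: np.ndarray


def build_correlation(n_atoms: int, blocks: list[tuple[np.ndarray, np.ndarray, float]] | None) -> np.ndarray:
    """Residue-residue correlation matrix: identity plus planted blocks.

    Each block is (index_array_i, index_array_j, rho).  Correlation rho is
    planted between every atom pair across the two groups; pairs within
    each group are set to rho as well (compound symmetry over the union),
    since a cross-group correlation without the matching within-group
    correlation would not be a valid (positive semi-definite) correlation
    structure.
    """
    corr = np.eye(n_atoms)
    for idx_i, idx_j, rho in blocks or []:
        union = np.union1d(np.atleast_1d(idx_i), np.atleast_1d(idx_j))
        for i, j in itertools.combinations(union, 2):
            corr[i, j] = corr[j, i] = rho
    return corr


def gen_trajectory(
    reference: np.ndarray,
    sigmas: np.ndarray | float = 1.0,
    blocks: list[tuple[np.ndarray, np.ndarray, float]] | None = None,
    n_frames: int = 1000,
    n_replicates: int = 1,
    seed=0,
    resids: np.ndarray | None = None,
    chains: np.ndarray | None = None,
    ar1_phi: float = 0.0,
) -> tuple[TrajectoryEnsemble, TrajectoryTruth]:
    """Gaussian CA fluctuations about a reference with a planted DCCM.

    Each axis fluctuates independently with the same residue-residue
    correlation matrix, so the ground-truth isotropic DCCM equals that
    matrix and the ground-truth RMSF is sqrt(3)*sigma_i.  Frames are i.i.d.
    by default; ``ar1_phi`` adds AR(1) frame-to-frame memory with the same
    stationary covariance, for effective-sample-size studies.
    """
    reference = np.asarray(reference, dtype=float)
    n = reference.shape[0]
    sig = np.broadcast_to(np.asarray(sigmas, dtype=float), (n,)).copy()
    if np.any(sig < 0):
        raise ValidationError("sigmas must be non-negative")
    corr = build_correlation(n, blocks)
    cov = corr * np.outer(sig, sig)
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ValidationError("covariance assembly is not positive semi-definite") from exc
    rng = _rng(seed)
    reps = []
    for _ in range(n_replicates):
        z = rng.standard_normal((n_frames, n, 3))
        if ar1_phi:
            innov_scale = math.sqrt(1.0 - ar1_phi**2)
            for f in range(1, n_frames):
                z[f] = ar1_phi * z[f - 1] + innov_scale * z[f]
        dev = np.einsum("ij,fjk->fik", chol, z)
        reps.append(reference[None, :, :] + dev)
    ens = TrajectoryEnsemble(
        replicates=reps,
        resids=np.arange(1, n + 1) if resids is None else np.asarray(resids),
        chains=np.array(["A"] * n) if chains is None else np.asarray(chains),
    )
    return ens, TrajectoryTruth(dccm=corr, rmsf=math.sqrt(3.0) * sig)


def gen_landscape(
    unit_effects: dict[str, float],
    couplings: dict[frozenset, float] | None = None,
    sigma: float = 0.0,
    seed=0,
    metric: str = "tm",
    wt_value: float = 0.0,
    alphabet: str = "ABCD",
) -> dict[str, StabilityRecord]:
    """Stability records over the full hypercube of the given units.

    Vertex value = WT base + sum of present unit effects + sum of injected
    couplings whose two units are co-present + Gaussian measurement error.
    """
    units = list(unit_effects)
    if len(set("".join(units))) != len("".join(units)):
        raise ValidationError("units must be disjoint mutation sets")
    couplings = couplings or {}
    rng = _rng(seed)
    records: dict[str, StabilityRecord] = {}
    for r in range(len(units) + 1):
        for combo in itertools.combinations(units, r):
            letters = set(itertools.chain.from_iterable(combo))
            label = "".join(a for a in alphabet if a in letters) or "WT"
            value = wt_value + sum(unit_effects[u] for u in combo)
            for pair, c in couplings.items():
                if pair <= set(combo):
                    value += c
            if sigma > 0:
                value += rng.normal(0.0, sigma)
            rec = StabilityRecord(variant=label)
            setattr(rec, metric, value)
            rec.se[metric] = sigma
            records[label] = rec
    return records
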