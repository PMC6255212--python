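"""Per-residue flexibility and dynamics cross-correlation analysis.

All quantities are computed on CA atoms after rigid-body least-squares
superposition of every frame onto a reference, so that overall translation
and rotation do not inflate the internal fluctuations:

* RMSF_i = sqrt( < |r_i - <r_i>|^2 > ) over frames, in Angstrom; replicate
  profiles are averaged arithmetically.
* The normalized RMSF change of a variant vs WT divides each profile by its
  own all-residue mean before differencing, which removes overall
  simulation-scale differences (temperature, length, replicate) while
  preserving the spatial pattern.
* The dynamics cross-correlation matrix (DCCM) uses the standard isotropic
  dot-product normalization C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>)
  with dr the instantaneous deviation from the time mean; values in [-1, 1],
  computed per replicate and then averaged.  For a homodimer the two chains'
  intra-chain blocks are averaged into one monomer-sized map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .datatypes import TrajectoryEnsemble
from .errors import ValidationError


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Angstrom), replicate-averaged when flagged."""

    resids: np.ndarray
    rmsf: np.ndarray
    variant: str = ""
    replicate_averaged: bool = False

    def __post_init__(self):
        self.resids = np.asarray(self.resids, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.resids.shape != self.rmsf.shape:
            raise ValidationError("resids and rmsf must have equal length")
        if np.any(self.rmsf < 0):
            raise ValidationError("RMSF values must be non-negative")


@dataclass
class DCCMatrix:
    """Symmetric unit-diagonal matrix of CA displacement correlations."""

    matrix: np.ndarray
    resids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or self.resids.shape != (n,):
            raise ValidationError("DCCM must be square with one residue id per row")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValidationError("DCCM must be symmetric")
        if np.any(np.abs(self.matrix) > 1 + 1e-9):
            raise ValidationError("DCCM entries must lie in [-1, 1]")


def _kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of one frame onto the reference coords."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return rot.apply(mob_c) + reference.mean(axis=0)


def superpose(
    ensemble: TrajectoryEnsemble,
    reference_frame: int = 0,
    iterative_mean: bool = False,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> TrajectoryEnsemble:
    """Superpose every frame of every replicate onto a common reference.

    The default reference is one frame of the first replicate (its first
    frame); superposition is an ordinary-least-squares rigid-body (Kabsch)
    fit over all CA atoms.  With ``iterative_mean=True`` the reference is
    refined to the mean structure of all frames until it moves by less
    than ``tol`` Angstrom RMS.
    """
    if ensemble.n_atoms < 3:
        raise ValidationError("superposition needs at least 3 atoms")
    ref = ensemble.replicates[0][reference_frame]
    if np.linalg.matrix_rank(ref - ref.mean(axis=0)) < 2:
        raise ValidationError("reference geometry is degenerate (collinear atoms)")

    def fit_all(reference):
        return [
            np.stack([_kabsch_superpose(frame, reference) for frame in rep])
            for rep in ensemble.replicates
        ]

    fitted = fit_all(ref)
    if iterative_mean:
        for _ in range(max_iter):
            mean_struct = np.mean(np.concatenate(fitted, axis=0), axis=0)
            shift = float(np.sqrt(((mean_struct - ref) ** 2).sum(axis=1).mean()))
            ref = mean_struct
            fitted = fit_all(ref)
            if shift < tol:
                break
    return TrajectoryEnsemble(
        replicates=fitted,
        resids=ensemble.resids.copy(),
        chains=ensemble.chains.copy(),
        chain_pairing=ensemble.chain_pairing,
        frame_interval_ps=ensemble.frame_interval_ps,
    )


def compute_rmsf(ensemble: TrajectoryEnsemble, variant: str = "") -> RMSFProfile:
    """Per-residue RMSF about the time-mean position, replicate-averaged."""
    profiles = []
    for rep in ensemble.replicates:
        if rep.shape[0] < 2:
            raise ValidationError("RMSF needs at least 2 frames")
        dev = rep - rep.mean(axis=0, keepdims=True)
        profiles.append(np.sqrt((dev**2).sum(axis=2).mean(axis=0)))
    return RMSFProfile(
        resids=ensemble.resids,
        rmsf=np.mean(profiles, axis=0),
        variant=variant,
        replicate_averaged=len(profiles) > 1,
    )


def delta_rmsf_norm(variant: RMSFProfile, wt: RMSFProfile, method: str = "mean") -> np.ndarray:
    """Normalized RMSF change per residue: normalize each profile, then subtract.

    ``method="mean"`` (default) divides each profile by its own all-residue
    mean, making the result invariant to multiplying either profile by a
    positive constant; ``method="zscore"`` centers and scales by each
    profile's SD instead, additionally equalizing spread.
    """
    if variant.resids.shape != wt.resids.shape or np.any(variant.resids != wt.resids):
        raise ValidationError("variant and WT profiles cover different residues")
    if method == "mean":
        for prof in (variant, wt):
            if prof.rmsf.mean() <= 0:
                raise ValidationError("cannot normalize an all-zero RMSF profile")
        return variant.rmsf / variant.rmsf.mean() - wt.rmsf / wt.rmsf.mean()
    if method == "zscore":
        for prof in (variant, wt):
            if prof.rmsf.std() <= 0:
                raise ValidationError("cannot z-score a constant RMSF profile")
        zv = (variant.rmsf - variant.rmsf.mean()) / variant.rmsf.std()
        zw = (wt.rmsf - wt.rmsf.mean()) / wt.rmsf.std()
        return zv - zw
    raise ValidationError(f"unknown normalization method {method!r}")


def site_window_mean(
    resids: np.ndarray, values: np.ndarray, site: int, width: int = 11
) -> float:
    """Mean of a per-residue profile over a window centered on a mutation site.

    ``width`` must be odd; the window is clipped at chain termini.  Residue
    ids are 1-based sequence numbers.
    """
    if width < 1 or width % 2 == 0:
        raise ValidationError("window width must be an odd positive integer")
    resids = np.asarray(resids)
    values = np.asarray(values, dtype=float)
    if site not in resids:
        raise ValidationError(f"site {site} not among residues {resids.min()}..{resids.max()}")
    half = width // 2
    mask = (resids >= site - half) & (resids <= site + half)
    return float(values[mask].mean())


def compute_dccm(ensemble: TrajectoryEnsemble, min_frames: int = 10) -> DCCMatrix:
    """Dynamics cross-correlation matrix, per replicate then averaged.

    Atoms with zero positional variance get off-diagonal 0 and diagonal 1,
    recorded in the provenance.
    """
    mats = []
    frozen: set[int] = set()
    for rep in ensemble.replicates:
        if rep.shape[0] < min_frames:
            raise ValidationError(f"DCCM needs at least {min_frames} frames per replicate")
        dev = rep - rep.mean(axis=0, keepdims=True)  # (F, N, 3)
        flat = np.ascontiguousarray(dev.transpose(1, 0, 2)).reshape(rep.shape[1], -1)
        cov = flat @ flat.T / rep.shape[0]
        var = np.diag(cov).copy()
        zero = var <= 0
        frozen |= set(np.where(zero)[0].tolist())
        var[zero] = 1.0
        c = cov / np.sqrt(np.outer(var, var))
        c[zero, :] = 0.0
        c[:, zero] = 0.0
        np.fill_diagonal(c, 1.0)
        mats.append(np.clip(c, -1.0, 1.0))
    avg = np.mean(mats, axis=0)
    avg = (avg + avg.T) / 2.0
    np.fill_diagonal(avg, 1.0)
    return DCCMatrix(
        matrix=avg,
        resids=ensemble.resids,
        provenance={
            "replicates": ensemble.n_replicates,
            "frames_per_replicate": [int(r.shape[0]) for r in ensemble.replicates],
            "zero_variance_atoms": sorted(frozen),
        },
    )


def average_chains(dccm: DCCMatrix, chains: np.ndarray, pairing: dict[int, int] | None = None) -> DCCMatrix:
    """Average the two chains' intra-chain blocks of a homodimer DCCM.

    ``pairing`` maps second-chain residue ids onto equivalent first-chain
    residue ids (default: identical numbering).  Inter-chain entries are
    discarded.  Single-chain input is returned unchanged.
    """
    chains = np.asarray(chains)
    uniq = list(dict.fromkeys(chains.tolist()))
    if len(uniq) == 1:
        return dccm
    if len(uniq) != 2:
        raise ValidationError(f"chain averaging expects 1 or 2 chains, got {uniq}")
    ca, cb = uniq
    idx_a = np.where(chains == ca)[0]
    idx_b = np.where(chains == cb)[0]
    res_a = dccm.resids[idx_a]
    res_b = dccm.resids[idx_b]
    if pairing is None:
        pairing = {int(r): int(r) for r in res_b}
    mapped = [pairing.get(int(r)) for r in res_b]
    if any(m is None for m in mapped) or sorted(mapped) != sorted(res_a.tolist()):
        raise ValidationError("chain pairing is not a bijection between the chains' residues")
    # reorder chain-B rows so residue k of B aligns with its partner in A
    pos_a = {int(r): i for i, r in enumerate(res_a)}
    order_b = np.argsort([pos_a[m] for m in mapped])
    block_a = dccm.matrix[np.ix_(idx_a, idx_a)]
    bb = dccm.matrix[np.ix_(idx_b, idx_b)]
    block_b = bb[np.ix_(order_b, order_b)]
    avg = (block_a + block_b) / 2.0
    np.fill_diagonal(avg, 1.0)
    prov = dict(dccm.provenance)
    prov["chains_averaged"] = [str(ca), str(cb)]
    return DCCMatrix(matrix=avg, resids=res_a, provenance=prov)


@dataclass(frozen=True)
class CorrelatedRegion:
    """A pair of sequence regions with coherent (anti)correlated dynamics."""

    resid_range_i: tuple[int, int]
    resid_range_j: tuple[int, int]
    mean_c: float
    kind: str  # "correlated" | "anticorrelated"


def correlated_regions(
    dccm: DCCMatrix,
    threshold: float = 0.2,
    min_separation: int = 20,
    min_block: int = 3,
) -> list[CorrelatedRegion]:
    """Off-diagonal blocks whose coupling magnitude exceeds a cutoff.

    Entries with |C_ij| >= threshold and sequence separation > min_separation
    are grouped into connected components (4-neighbour connectivity in the
    matrix plane); each component at least ``min_block`` residues wide in
    both directions is reported once (upper triangle) with the mean C over
    its entries and a correlated/anticorrelated label.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    from scipy import ndimage

    m = dccm.matrix
    resids = dccm.resids
    n = m.shape[0]
    sep = np.abs(resids[:, None] - resids[None, :])
    mask = (np.abs(m) >= threshold) & (sep > min_separation) & (np.triu(np.ones((n, n), bool), 1))
    out: list[CorrelatedRegion] = []
    for signed_mask, kind in ((mask & (m > 0), "correlated"), (mask & (m < 0), "anticorrelated")):
        labels, n_comp = ndimage.label(signed_mask)
        for comp in range(1, n_comp + 1):
            rows, cols = np.where(labels == comp)
            if len(set(rows)) < min_block or len(set(cols)) < min_block:
                continue
            out.append(
                CorrelatedRegion(
                    resid_range_i=(int(resids[rows.min()]), int(resids[rows.max()])),
                    resid_range_j=(int(resids[cols.min()]), int(resids[cols.max()])),
                    mean_c=float(m[rows, cols].mean()),
                    kind=kind,
                )
            )
    out.sort(key=lambda r: (r.resid_range_i, r.resid_range_j))
    return out
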