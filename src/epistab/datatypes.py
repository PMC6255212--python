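"""Core domain types shared by every stage of the stability pipeline.

Conventions, applied uniformly:

* Residual enzyme activity is stored in **percent** of the untreated
  control (A0 ~ 100).  The second-order deactivation rate constant kd
  therefore has units %^-1 min^-1 and the half-life is 1/(100*kd) min.
* Temperatures cross module boundaries in **degrees Celsius** and are
  converted to Kelvin (T_K = T_C + 273.15) inside thermodynamic math.
* Residue numbering is 1-based, matching the usual sequence numbering of
  mutation names such as H192P or G506A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

CELSIUS_OFFSET = 273.15

#: Gas constant in cal mol^-1 K^-1, used by the two-state unfolding model.
R_CAL = 1.987
#: Gas constant in J mol^-1 K^-1, used by deactivation free energies.
R_J = 8.314


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET


@dataclass(frozen=True)
class MutationSet:
    """A variant identified by which mutations out of an ordered alphabet it carries.

    The alphabet assigns one letter per mutation (e.g. A=H192P, B=A282P,
    C=I365L, D=G506A); a variant is a bit vector over that alphabet and its
    canonical label is the concatenation of the present letters in alphabet
    order, or ``"WT"`` when no mutation is present.
    """

    alphabet: tuple[str, ...]
    genotype: tuple[bool, ...]

    def __post_init__(self):
        if len(self.alphabet) != len(self.genotype):
            raise ValidationError(
                f"genotype length {len(self.genotype)} != alphabet length {len(self.alphabet)}"
            )
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValidationError("alphabet letters must be unique")

    @property
    def label(self) -> str:
        letters = "".join(a for a, g in zip(self.alphabet, self.genotype) if g)
        return letters or "WT"

    @property
    def letters(self) -> frozenset[str]:
        return frozenset(a for a, g in zip(self.alphabet, self.genotype) if g)

    @classmethod
    def from_label(cls, label: str, alphabet: tuple[str, ...] | str) -> "MutationSet":
        alphabet = tuple(alphabet)
        if label == "WT":
            present: set[str] = set()
        else:
            present = set(label)
            unknown = present - set(alphabet)
            if unknown:
                raise ValidationError(f"unknown mutation letters {sorted(unknown)} for alphabet {alphabet}")
        return cls(alphabet, tuple(a in present for a in alphabet))

    def is_wt(self) -> bool:
        return not any(self.genotype)


def _as_sorted_xy(x, y, name_x: str):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"{name_x} and values must be 1-D arrays of equal length")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.any(np.diff(x) <= 0):
        dup = x[np.where(np.diff(x) <= 0)[0]]
        raise ValidationError(f"{name_x} must be strictly increasing; duplicates at {dup.tolist()}")
    return x, y


@dataclass
class ActivityDecaySeries:
    """Residual activity (%) versus incubation time (min) for one variant at one temperature."""

    variant: str
    temperature: float  # deg C of the incubation
    times: np.ndarray  # min, strictly increasing
    activities: np.ndarray  # percent of untreated control

    def __post_init__(self):
        self.times, self.activities = _as_sorted_xy(self.times, self.activities, "times")
        if len(self.times) < 3:
            raise ValidationError("decay series needs at least 3 time points")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class MeltSeries:
    """Thermal-ramp readout for one variant.

    ``ratio`` is the intrinsic-fluorescence 350 nm / 330 nm intensity ratio;
    ``sls`` the optional static-light-scattering counts at 266 nm (arbitrary
    units) recorded simultaneously.
    """

    variant: str
    temperatures: np.ndarray  # deg C, strictly increasing
    ratio: np.ndarray | None = None
    sls: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        order = np.argsort(t, kind="stable")
        if np.any(np.diff(t[order]) <= 0):
            raise ValidationError("melt temperatures must be strictly increasing (no duplicates)")
        self.temperatures = t[order]
        for name in ("ratio", "sls"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != t.shape:
                    raise ValidationError(f"{name} length {arr.shape} != temperature length {t.shape}")
                setattr(self, name, arr[order])
        if len(self.temperatures) < 10:
            raise ValidationError("melt series needs at least 10 temperature points")

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass
class TemperatureActivitySeries:
    """Residual activity (%) after a fixed incubation versus incubation temperature (deg C)."""

    variant: str
    temperatures: np.ndarray
    activities: np.ndarray
    incubation_min: float = 15.0

    def __post_init__(self):
        self.temperatures, self.activities = _as_sorted_xy(
            self.temperatures, self.activities, "temperatures"
        )

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass
class StabilityRecord:
    """Fitted per-variant stability metrics, with standard errors and fit diagnostics.

    All temperatures in deg C; kd in %^-1 min^-1; t_half in min; dHvh in
    kcal mol^-1 and dSvh in kcal mol^-1 K^-1; fT a mole fraction at the
    stated reference temperature (default 60 deg C); ddg the deactivation
    free-energy change versus WT in kJ mol^-1.
    """

    variant: str
    kd: float = math.nan
    t_half: float = math.nan
    t50: float = math.nan
    tm: float = math.nan
    dhvh: float = math.nan
    dsvh: float = math.nan
    f_t: float = math.nan
    f_t_ref_c: float = 60.0
    tagg: float = math.nan
    ddg: float = math.nan
    se: dict[str, float] = field(default_factory=dict)
    r2: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not math.isnan(self.f_t) and not (0.0 <= self.f_t <= 1.0):
            raise ValidationError(f"fT={self.f_t} outside [0, 1]")
        if not math.isnan(self.kd) and not math.isnan(self.t_half):
            if (self.kd > 0) != (self.t_half > 0):
                raise ValidationError("t_half > 0 must hold exactly when kd > 0")
        if not (math.isnan(self.dhvh) or math.isnan(self.dsvh) or math.isnan(self.tm)):
            expect = self.dhvh / celsius_to_kelvin(self.tm)
            if abs(expect - self.dsvh) > 1e-9 * max(1.0, abs(expect)):
                raise ValidationError("dSvh inconsistent with dHvh / Tm(K)")


@dataclass
class TrajectoryEnsemble:
    """Replicate CA-atom coordinate trajectories with residue/chain maps.

    ``replicates`` holds one (frames, atoms, 3) array per independent run, in
    Angstrom.  ``resids`` and ``chains`` map each atom (one CA per residue) to
    its 1-based residue id and chain id.  ``chain_pairing`` maps residue ids of
    the second chain onto equivalent residues of the first for homodimer
    averaging; identity for monomers.
    """

    replicates: list[np.ndarray]
    resids: np.ndarray  # (atoms,) int
    chains: np.ndarray  # (atoms,) str
    chain_pairing: dict[int, int] | None = None
    frame_interval_ps: float = 10.0

    def __post_init__(self):
        if not self.replicates:
            raise ValidationError("ensemble needs at least one replicate")
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
        self.resids = np.asarray(self.resids, dtype=int)
        self.chains = np.asarray(self.chains)
        n_atoms = self.replicates[0].shape[1]
        for i, rep in enumerate(self.replicates):
            if rep.ndim != 3 or rep.shape[2] != 3:
                raise ValidationError(f"replicate {i} is not a (frames, atoms, 3) array")
            if rep.shape[1] != n_atoms:
                raise ValidationError(f"replicate {i} atom count {rep.shape[1]} != {n_atoms}")
            if rep.shape[0] < 2:
                raise ValidationError(f"replicate {i} has fewer than 2 frames")
        if self.resids.shape != (n_atoms,) or self.chains.shape != (n_atoms,):
            raise ValidationError("resids/chains maps must have one entry per atom")

    @property
    def n_atoms(self) -> int:
        return self.replicates[0].shape[1]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)
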