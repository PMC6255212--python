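"""Epistasis quantification and mutational-pathway analysis.

For any stability metric expressed as a change relative to WT (ddG in
kJ mol^-1, dTm or dTagg in deg C), the interaction between two disjoint
mutation sets X and Y is the coupling

    coupling = delta_XY - (delta_X + delta_Y),

zero for perfectly additive effects.  The classification follows the usual
intragenic-epistasis taxonomy: positive (double exceeds the sum), negative
i.e. partially additive (between the better single and the sum), sign (the
double is worse than at least one single), and reciprocal sign (the double
is worse than WT).  Classification is evaluated against a tolerance band —
by default the propagated standard error — since the categories touch at
their boundaries.

Variants live on a 2^n hypercube over n mutational "units"; a unit may be a
single mutation or a co-inherited group (e.g. an already-characterized
double mutant treated as one step).  A forward pathway is one of the n!
orderings of the units; the landscape has no local minima when every step
of every pathway is favorable within tolerance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .datatypes import StabilityRecord
from .errors import ValidationError

CATEGORIES = ("additive", "positive", "negative", "sign", "reciprocal-sign")


def classify_epistasis(
    delta_x: float, delta_y: float, delta_xy: float, tolerance: float = 0.0
) -> str:
    """Classify the interaction between two mutation sets for one metric.

    Precedence: reciprocal-sign, then sign, then additive / positive /
    negative, because the categories overlap at their boundaries.  ``sign``
    uses the weaker reading "the double is below at least one single"
    (delta_xy < max(delta_x, delta_y)).
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be non-negative")
    coupling = delta_xy - (delta_x + delta_y)
    if delta_xy < -tolerance:
        return "reciprocal-sign"
    if delta_xy < max(delta_x, delta_y) - tolerance:
        return "sign"
    if abs(coupling) <= tolerance:
        return "additive"
    return "positive" if coupling > tolerance else "negative"


@dataclass(frozen=True)
class CouplingResult:
    """Observed-vs-expected decomposition for one bipartition X + Y -> XY."""

    x: str
    y: str
    delta_x: float
    delta_y: float
    delta_xy: float
    coupling: float
    se_coupling: float
    category: str
    weak_sign: bool = False  # sign epistasis vs max() only, not vs min()

    @property
    def expected(self) -> float:
        return self.delta_x + self.delta_y


def coupling(
    delta_x: float,
    delta_y: float,
    delta_xy: float,
    se_x: float | None = None,
    se_y: float | None = None,
    se_xy: float | None = None,
    x: str = "X",
    y: str = "Y",
    tolerance: float | None = None,
) -> CouplingResult:
    """Coupling term of one double-mutant cycle, with SE propagation.

    ``tolerance`` for classification defaults to the propagated SE when SEs
    are supplied, else 0.  The partners' labels must be disjoint mutation
    sets.
    """
    if x != "X" and y != "Y" and set(x) & set(y):
        raise ValidationError(f"partners {x!r} and {y!r} share mutations")
    ses = [se_x, se_y, se_xy]
    if any(s is not None for s in ses):
        se_c = math.sqrt(sum((s or 0.0) ** 2 for s in ses))
    else:
        se_c = 0.0
    tol = se_c if tolerance is None else tolerance
    c = delta_xy - (delta_x + delta_y)
    category = classify_epistasis(delta_x, delta_y, delta_xy, tol)
    weak = category == "sign" and not (delta_xy < min(delta_x, delta_y) - tol)
    return CouplingResult(
        x=x, y=y, delta_x=delta_x, delta_y=delta_y, delta_xy=delta_xy,
        coupling=c, se_coupling=se_c, category=category, weak_sign=weak,
    )


def _canonical(letters: frozenset[str], alphabet: str) -> str:
    return "".join(a for a in alphabet if a in letters) or "WT"


@dataclass
class FitnessLandscape:
    """Per-genotype metric deltas (vs WT) over a hypercube of mutational units."""

    alphabet: str
    units: tuple[str, ...]
    metric: str
    values: dict[str, float] = field(default_factory=dict)
    ses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for u in self.units:
            if set(u) & seen:
                raise ValidationError(f"unit {u!r} overlaps another unit")
            if not set(u) <= set(self.alphabet):
                raise ValidationError(f"unit {u!r} outside alphabet {self.alphabet!r}")
            seen |= set(u)
        if "WT" not in self.values:
            raise ValidationError("landscape must contain WT")
        if abs(self.values["WT"]) > 1e-12:
            raise ValidationError("WT delta must be 0 (all values are relative to WT)")

    def vertex_label(self, unit_subset) -> str:
        letters = frozenset(itertools.chain.from_iterable(unit_subset))
        return _canonical(letters, self.alphabet)

    def all_vertices(self) -> list[str]:
        out = []
        for r in range(len(self.units) + 1):
            for combo in itertools.combinations(self.units, r):
                out.append(self.vertex_label(combo))
        return out

    def missing_vertices(self) -> list[str]:
        return [v for v in self.all_vertices() if v not in self.values]

    def se(self, label: str) -> float:
        return self.ses.get(label, 0.0)


def build_landscape(
    records: dict[str, StabilityRecord],
    metric: str,
    units: tuple[str, ...],
    alphabet: str = "ABCD",
) -> FitnessLandscape:
    """Assemble a landscape of metric deltas (vs WT) from fitted records.

    ``metric`` names a StabilityRecord attribute ("tm", "tagg", "t50",
    "t_half", "ddg"); deltas are value(variant) - value(WT).  Missing
    vertices are tolerated and listed by ``missing_vertices()``; a missing
    WT is an error.
    """
    if "WT" not in records:
        raise ValidationError("records must include WT")
    wt_val = getattr(records["WT"], metric)
    if math.isnan(wt_val):
        raise ValidationError(f"WT record lacks metric {metric!r}")
    values, ses = {}, {}
    for label, rec in records.items():
        val = getattr(rec, metric)
        if math.isnan(val):
            continue
        values[label] = val - wt_val
        se = rec.se.get(metric, math.nan)
        wt_se = records["WT"].se.get(metric, math.nan)
        if not (math.isnan(se) or math.isnan(wt_se)):
            ses[label] = math.hypot(se, wt_se) if label != "WT" else 0.0
    values["WT"] = 0.0
    ses["WT"] = 0.0
    return FitnessLandscape(alphabet=alphabet, units=tuple(units), metric=metric,
                            values=values, ses=ses)


@dataclass(frozen=True)
class Pathway:
    """One ordering of mutational steps from WT to the full combination."""

    order: tuple[str, ...]  # units in the order acquired
    vertices: tuple[str, ...]  # WT ... full target
    step_deltas: tuple[float, ...]
    monotone: bool


def enumerate_pathways(landscape: FitnessLandscape, tolerance: float = 0.0) -> list[Pathway]:
    """All n! forward pathways over the landscape's units, with step verdicts.

    Each pathway is annotated monotone-increasing if every step delta is
    > -tolerance.  Raises if any hypercube vertex lacks a value.
    """
    missing = landscape.missing_vertices()
    if missing:
        raise ValidationError(f"incomplete hypercube; missing vertices: {missing}")
    pathways = []
    for order in itertools.permutations(landscape.units):
        vertices = ["WT"]
        acquired: list[str] = []
        for unit in order:
            acquired.append(unit)
            vertices.append(landscape.vertex_label(acquired))
        deltas = tuple(
            landscape.values[vertices[i + 1]] - landscape.values[vertices[i]]
            for i in range(len(order))
        )
        pathways.append(
            Pathway(
                order=tuple(order),
                vertices=tuple(vertices),
                step_deltas=deltas,
                monotone=all(d > -tolerance for d in deltas),
            )
        )
    return pathways


def no_local_minima(pathways: list[Pathway]) -> bool:
    """True when every step of every pathway is favorable (within tolerance)."""
    return all(p.monotone for p in pathways)


def final_step_couplings(landscape: FitnessLandscape, target: str) -> list[CouplingResult]:
    """Couplings for every bipartition X + Y of the target's units.

    For a target built from units U, each split of U into two non-empty
    groups whose vertex labels both exist in the landscape yields one
    CouplingResult (2^(n-1) - 1 splits when all vertices are present).
    """
    if target not in landscape.values:
        raise ValidationError(f"target {target!r} not in landscape")
    target_letters = set(target) if target != "WT" else set()
    units = [u for u in landscape.units if set(u) <= target_letters]
    if set().union(*[set(u) for u in units] or [set()]) != target_letters:
        raise ValidationError(f"target {target!r} is not a union of landscape units")
    results = []
    n = len(units)
    for r in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), r):
            if r * 2 == n and 0 not in combo:
                continue  # avoid double-counting complementary splits
            x_units = [units[i] for i in combo]
            y_units = [units[i] for i in range(n) if i not in combo]
            x_lab = landscape.vertex_label(x_units)
            y_lab = landscape.vertex_label(y_units)
            if x_lab not in landscape.values or y_lab not in landscape.values:
                continue
            results.append(
                coupling(
                    landscape.values[x_lab],
                    landscape.values[y_lab],
                    landscape.values[target],
                    se_x=landscape.se(x_lab),
                    se_y=landscape.se(y_lab),
                    se_xy=landscape.se(target),
                    x=x_lab,
                    y=y_lab,
                )
            )
    return results
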