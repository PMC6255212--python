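"""Reference panel: published stability measurements for the E. coli
transketolase variant set used throughout the examples.

Four individually stabilizing mutations — A = H192P, B = A282P (surface of
the PP-binding domain), C = I365L, D = G506A (Pyr-domain hydrophobic core)
— combined along two phases: first A+B into AB, then {AB, C, D} into the
quadruple ABCD.  Values are the published per-variant measurements: Tagg
and Tm in degC, dSvh in kcal mol^-1 K^-1, f60 (unfolded fraction at 60
degC), kd in %^-1 min^-1, half-life in min, and T50 (15-min incubation) in
degC.  ``math.nan`` marks quantities not determined for that variant.
These constants parameterize the synthetic generators in demo/acceptance
runs; nothing in the fitting code depends on them.
"""

from __future__ import annotations

import math

ALPHABET = "ABCD"
MUTATION_NAMES = {"A": "H192P", "B": "A282P", "C": "I365L", "D": "G506A"}
MUTATION_SITES = {"A": 192, "B": 282, "C": 365, "D": 506}

#: Units of the two combination phases: phase 1 built AB from A and B;
#: phase 2 treats AB as a single inherited unit alongside C and D.
PHASE1_UNITS = ("A", "B")
PHASE2_UNITS = ("AB", "C", "D")

ND = math.nan

#: Per-variant measured panel: (tagg, tm, dsvh, f60, kd, t_half, t50).
REFERENCE_PANEL: dict[str, dict[str, float]] = {
    "WT":   dict(tagg=65.7, tm=65.7, dsvh=0.23,  f60=0.12,  kd=2.80e-3, t_half=4.0,  t50=58.5),
    "A":    dict(tagg=66.2, tm=66.5, dsvh=0.32,  f60=0.049, kd=0.66e-3, t_half=15.2, t50=ND),
    "B":    dict(tagg=65.9, tm=66.3, dsvh=0.25,  f60=0.088, kd=1.29e-3, t_half=7.7,  t50=ND),
    "C":    dict(tagg=66.9, tm=67.1, dsvh=0.25,  f60=0.082, kd=ND,      t_half=ND,   t50=ND),
    "D":    dict(tagg=66.6, tm=66.7, dsvh=0.22,  f60=0.08,  kd=ND,      t_half=ND,   t50=ND),
    "CD":   dict(tagg=66.8, tm=67.2, dsvh=0.078, f60=0.24,  kd=ND,      t_half=ND,   t50=ND),
    "AB":   dict(tagg=66.6, tm=67.4, dsvh=0.19,  f60=0.11,  kd=0.54e-3, t_half=19.3, t50=ND),
    "ABC":  dict(tagg=68.1, tm=68.6, dsvh=0.13,  f60=0.13,  kd=0.20e-3, t_half=50.6, t50=ND),
    "ABD":  dict(tagg=67.6, tm=68.1, dsvh=0.19,  f60=0.043, kd=0.19e-3, t_half=53.2, t50=ND),
    "ABCD": dict(tagg=69.3, tm=68.9, dsvh=0.17,  f60=0.11,  kd=0.12e-3, t_half=82.5, t50=61.0),
}

#: Printed 1/RA-vs-time regression lines (slope, intercept) at 60 degC.
SECOND_ORDER_LINES: dict[str, tuple[float, float]] = {
    "WT":   (0.00275, -0.0085),
    "AB":   (0.00052, -0.0016),
    "ABC":  (0.000197, 0.0076),
    "ABD":  (0.000187, 0.0075),
    "ABCD": (0.000121, 0.0099),
}

#: Retained activity after 1 h at 60 degC: the quadruple kept 66.2%,
#: a 10.2-fold improvement over WT.
RETAINED_1H_ABCD = 0.662
RETAINED_1H_FOLD_OVER_WT = 10.2

#: Width (degC) used when synthesizing Boltzmann residual-activity curves.
T50_CURVE_WIDTH = 1.5


def dhvh_from_panel(label: str) -> float:
    """van't Hoff enthalpy (kcal/mol) implied by a panel row's Tm and dSvh."""
    row = REFERENCE_PANEL[label]
    return row["dsvh"] * (row["tm"] + 273.15)
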