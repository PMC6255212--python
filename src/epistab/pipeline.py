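"""End-to-end orchestration: curve files -> stability records -> epistasis
reports, and trajectories -> RMSF / DCCM reports.

A run is described by a :class:`RunConfig` (usually loaded from YAML): a
per-variant manifest of input files, the mutation alphabet and unit
partition, reference temperatures, and an output directory.  Per-variant
fit failures are recorded and skipped, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .datatypes import StabilityRecord, celsius_to_kelvin
from .dynamics import (
    average_chains,
    compute_dccm,
    compute_rmsf,
    correlated_regions,
    delta_rmsf_norm,
    site_window_mean,
    superpose,
)
from .epistasis import build_landscape, enumerate_pathways, final_step_couplings, no_local_minima
from .errors import EpistabError, ValidationError
from .kinetics import ddg_inactivation, fit_second_order, fit_t50, half_life, retained_activity
from .unfolding import detect_tagg, fit_two_state, fraction_unfolded, svh

log = logging.getLogger("epistab")


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    manifest: dict[str, dict[str, str]]  # variant label -> {"decay": path, "melt": path, ...}
    alphabet: str = "ABCD"
    units: tuple[str, ...] = ("AB", "C", "D")
    incubation_c: float = 60.0
    ft_reference_c: float = 60.0
    ddg_time_min: float = 60.0
    window_width: int = 11
    dccm_threshold: float = 0.2
    mutation_sites: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    outdir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "units" in raw:
            raw["units"] = tuple(raw["units"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for temp in (self.incubation_c, self.ft_reference_c):
            if not 0.0 <= temp <= 120.0:
                raise ValidationError(f"temperature {temp} degC outside the physical range 0-120")
        for variant, files in self.manifest.items():
            for kind, path in files.items():
                if not Path(path).exists():
                    raise ValidationError(f"{variant}/{kind}: file not found: {path}")


def fit_variant(
    label: str,
    decay=None,
    melt=None,
    sls=None,
    t50_series=None,
    ft_reference_c: float = 60.0,
) -> StabilityRecord:
    """Fit every supplied series for one variant into a StabilityRecord."""
    rec = StabilityRecord(variant=label, f_t_ref_c=ft_reference_c)
    if decay is not None:
        fit = fit_second_order(decay)
        rec.kd = fit.kd
        rec.t_half = half_life(fit.kd) if fit.kd > 0 else math.inf
        rec.se["kd"] = fit.se_kd
        if fit.kd > 0:
            rec.se["t_half"] = fit.se_kd / (100.0 * fit.kd**2)
        rec.r2["decay"] = fit.r2
    if melt is not None:
        ts = fit_two_state(melt)
        rec.tm = ts.tm
        rec.dhvh = ts.dhvh
        rec.dsvh = ts.dsvh
        rec.f_t = fraction_unfolded(
            ts.dhvh, celsius_to_kelvin(ts.tm), celsius_to_kelvin(ft_reference_c)
        )
        rec.se["tm"] = ts.se["tm"]
        rec.r2["melt"] = ts.r2
    if sls is not None:
        onset = detect_tagg(sls)
        rec.tagg = onset if onset is not None else math.nan
    if t50_series is not None:
        bf = fit_t50(t50_series)
        rec.t50 = bf.t50
        rec.se["t50"] = bf.se_t50
        rec.r2["t50"] = bf.r2
    return rec


def run_stability(config: RunConfig) -> dict:
    """Full stability pass: fits, records, landscapes, epistasis report.

    Returns a report dict (also written to ``outdir``) with one record per
    variant, observed-vs-expected couplings for every final-step
    bipartition of the full combination, pathway verdicts, and a failure
    list; raises only on configuration errors.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records: dict[str, StabilityRecord] = {}
    failures: dict[str, str] = {}
    for label, files in config.manifest.items():
        try:
            decay = (
                eio.read_curve_table(files["decay"], "decay", variant=label,
                                     temperature=config.incubation_c)
                if "decay" in files else None
            )
            melt = eio.read_curve_table(files["melt"], "melt", variant=label) if "melt" in files else None
            sls = eio.read_curve_table(files["sls"], "melt", variant=label) if "sls" in files else None
            t50s = (
                eio.read_curve_table(files["t50"], "t50-series", variant=label)
                if "t50" in files else None
            )
            records[label] = fit_variant(
                label, decay=decay, melt=melt, sls=sls, t50_series=t50s,
                ft_reference_c=config.ft_reference_c,
            )
            log.info("fitted %s: %s", label, records[label])
        except EpistabError as exc:
            failures[label] = str(exc)
            log.warning("variant %s failed: %s", label, exc)

    # deactivation free energies vs WT from the fitted decay models
    if "WT" in records and records["WT"].kd > 0:
        wt_fit_ra = _ra_fraction(records["WT"], config.ddg_time_min)
        for label, rec in records.items():
            if rec.kd > 0 and wt_fit_ra is not None:
                ra = _ra_fraction(rec, config.ddg_time_min)
                if ra is not None:
                    rec.ddg = (
                        0.0
                        if label == "WT"
                        else ddg_inactivation(wt_fit_ra, ra, celsius_to_kelvin(config.incubation_c))
                    )

    report: dict = {"records": {k: dataclasses.asdict(v) for k, v in records.items()},
                    "failures": failures, "epistasis": {}}
    full = "".join(a for a in config.alphabet if any(a in u for u in config.units))
    if len(records) > 1 and "WT" in records:
        for metric in ("tm", "tagg", "ddg", "t50"):
            have = [l for l, r in records.items() if not math.isnan(getattr(r, metric))]
            if len(have) < 3 or "WT" not in have:
                continue
            scape = build_landscape(records, metric, config.units, config.alphabet)
            entry: dict = {"deltas": scape.values, "missing": scape.missing_vertices()}
            if full in scape.values:
                entry["final_step_couplings"] = [
                    dataclasses.asdict(c) for c in final_step_couplings(scape, full)
                ]
            if not scape.missing_vertices():
                paths = enumerate_pathways(scape)
                entry["n_pathways"] = len(paths)
                entry["no_local_minima"] = no_local_minima(paths)
            report["epistasis"][metric] = entry
    elif len(records) <= 1:
        log.warning("fewer than two variants fitted; epistasis analysis skipped")

    eio.write_records(records.values(), outdir / "stability_records.json")
    (outdir / "stability_report.json").write_text(
        json.dumps(report, indent=2, default=_json_default) + "\n"
    )
    return report


def _ra_fraction(rec: StabilityRecord, t_min: float) -> float | None:
    if rec.kd <= 0 or math.isnan(rec.kd):
        return None
    from .kinetics import SecondOrderFit

    fit = SecondOrderFit(kd=rec.kd, inv_a0=0.01, r2=math.nan, se_kd=math.nan)
    return retained_activity(fit, t_min) / 100.0


def run_dynamics(
    trajectories: dict[str, list],
    wt_label: str = "WT",
    fmt: str = "pdb",
    mutation_sites: dict[str, int] | None = None,
    window_width: int = 11,
    dccm_threshold: float = 0.2,
    outdir: str | Path = ".",
    chain_pairing: dict[int, int] | None = None,
) -> dict:
    """Trajectory pass: RMSF, normalized dRMSF vs WT, DCCM, region report.

    ``trajectories`` maps variant label -> list of replicate files.  Raises
    when dRMSF is requested without a WT entry.
    """
    if wt_label not in trajectories:
        raise ValidationError(f"dRMSF analysis needs a {wt_label!r} trajectory")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles, dccms = {}, {}
    for label, paths in trajectories.items():
        ens = superpose(eio.read_trajectory(paths, fmt=fmt, chain_pairing=chain_pairing))
        profiles[label] = compute_rmsf(ens, variant=label)
        dccm = compute_dccm(ens)
        dccms[label] = average_chains(dccm, ens.chains, ens.chain_pairing)
        eio.write_profile_tsv(profiles[label].resids, profiles[label].rmsf,
                              outdir / f"rmsf_{label}.tsv")
        eio.write_matrix_tsv(dccms[label].matrix, dccms[label].resids,
                             outdir / f"dccm_{label}.tsv")

    report: dict = {"variants": list(trajectories), "delta_rmsf_site_means": {}, "regions": {}}
    wt_prof = profiles[wt_label]
    for label, prof in profiles.items():
        if label == wt_label:
            continue
        d = delta_rmsf_norm(prof, wt_prof)
        eio.write_profile_tsv(prof.resids, d, outdir / f"delta_rmsf_{label}.tsv", column="delta_rmsf_norm")
        site_means = {
            name: site_window_mean(prof.resids, d, site, window_width)
            for name, site in (mutation_sites or {}).items()
            if site in prof.resids
        }
        report["delta_rmsf_site_means"][label] = site_means
    for label, dccm in dccms.items():
        report["regions"][label] = [
            dataclasses.asdict(r) for r in correlated_regions(dccm, threshold=dccm_threshold)
        ]
    (outdir / "dynamics_report.json").write_text(
        json.dumps(report, indent=2, default=_json_default) + "\n"
    )
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
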