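"""Self-demonstrating run: synthesize the reference variant panel and push
it through the whole stability pipeline.

The generators are parameterized with the published panel constants
(:mod:`epistab.presets`), written out as ordinary CSV inputs, and then
re-fitted by the same code paths a real dataset would take.  Noise
defaults are sized to the panel's reported triplicate SEMs; sigma=0 gives
exact round trips.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets
from .pipeline import RunConfig, run_stability
from .synth import gen_decay, gen_melt, gen_sls, gen_t50_series

#: Default measurement noise, sized to the panel's reported SEM magnitudes.
DEFAULT_NOISE = {"decay": 1.0, "melt": 0.002, "sls": 50.0, "t50": 1.0}


def generate_reference_inputs(
    outdir, seed: int = 0, noise: dict | None = None
) -> dict[str, dict[str, str]]:
    """Write synthetic CSV inputs for every panel variant; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    noise = {**DEFAULT_NOISE, **(noise or {})}
    rng = np.random.default_rng(seed)
    manifest: dict[str, dict[str, str]] = {}
    for label, row in presets.REFERENCE_PANEL.items():
        files: dict[str, str] = {}
        if not math.isnan(row["kd"]):
            series = gen_decay(
                kd=row["kd"], times=np.arange(0.0, 121.0, 10.0),
                sigma=noise["decay"], seed=rng, variant=label,
            )
            files["decay"] = _write(outdir / f"decay_{label}.csv",
                                    time=series.times, activity=series.activities)
        melt = gen_melt(
            tm_c=row["tm"], dhvh=presets.dhvh_from_panel(label),
            sigma=noise["melt"], seed=rng, variant=label,
        )
        files["melt"] = _write(outdir / f"melt_{label}.csv",
                               temperature=melt.temperatures, ratio=melt.ratio)
        sls = gen_sls(tagg_c=row["tagg"], sigma=noise["sls"], seed=rng, variant=label)
        files["sls"] = _write(outdir / f"sls_{label}.csv",
                              temperature=sls.temperatures, sls=sls.sls)
        if not math.isnan(row["t50"]):
            t50s = gen_t50_series(
                t50_c=row["t50"], width=presets.T50_CURVE_WIDTH,
                sigma=noise["t50"], seed=rng, variant=label,
            )
            files["t50"] = _write(outdir / f"t50_{label}.csv",
                                  temperature=t50s.temperatures, activity=t50s.activities)
        manifest[label] = files
    return manifest


def _write(path: Path, **columns) -> str:
    pd.DataFrame(columns).to_csv(path, index=False)
    return str(path)


def run_reference_demo(outdir, seed: int = 0, noise: dict | None = None) -> dict:
    """Generate the synthetic panel and run the full stability pipeline on it."""
    outdir = Path(outdir)
    manifest = generate_reference_inputs(outdir / "inputs", seed=seed, noise=noise)
    config = RunConfig(
        manifest=manifest,
        alphabet=presets.ALPHABET,
        units=presets.PHASE2_UNITS,
        mutation_sites={presets.MUTATION_NAMES[k]: v for k, v in presets.MUTATION_SITES.items()},
        seed=seed,
        outdir=str(outdir),
    )
    return run_stability(config)
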