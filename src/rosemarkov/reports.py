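"""Report bundle generation: one call regenerates every headline output of
a scenario — equilibrium JSON, convergence trajectory CSV, the sensitivity
scenario table CSV, the derivative report JSON, and a run log."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy
import pandas

from . import __version__
from .config import ScenarioConfig
from .model import IllnessDeathModel
from .sensitivity import build_table1, round_half_up

#: Display precision for derived rates, matching how such figures are
#: conventionally reported: percents and per-100k rates to one decimal,
#: per-1k rates to two decimals.
ROUNDING_RULES = {
    "suicide_rate_per_100k": 1,
    "other_cause_death_rate_per_1k": 2,
    "mentally_ill_percent": 1,
}


def equilibrium_payload(config: ScenarioConfig) -> dict:
    """Equilibrium fractions, counts, normalizer and derived rates."""
    eq = IllnessDeathModel(config.params, config.Q0).equilibrium()
    return {
        "Q0": config.Q0,
        "R": eq.R,
        "fractions": {
            "w": eq.w_frac,
            "x": eq.x_frac,
            "y": eq.y_frac,
            "z": eq.z_frac,
        },
        "counts": {
            "w": eq.w_frac * eq.Q0,
            "x": eq.x_frac * eq.Q0,
            "y": eq.y_frac * eq.Q0,
            "z": eq.z_frac * eq.Q0,
        },
        "rates": {
            "suicide_rate_per_100k": round_half_up(
                eq.suicide_rate_per_100k, ROUNDING_RULES["suicide_rate_per_100k"]
            ),
            "other_cause_death_rate_per_1k": round_half_up(
                eq.other_cause_death_rate_per_1k,
                ROUNDING_RULES["other_cause_death_rate_per_1k"],
            ),
            "mentally_ill_percent": round_half_up(
                eq.mentally_ill_percent, ROUNDING_RULES["mentally_ill_percent"]
            ),
        },
    }


def sensitivity_payload(config: ScenarioConfig) -> dict:
    report = IllnessDeathModel(config.params, config.Q0).sensitivity(
        which="p41", dp=config.reference_dp41
    )
    return {
        "Q0": config.Q0,
        "z_count": report.z_count,
        "dz_dp": report.dz_dp,
        "reference": {
            "which": report.which,
            "dp": report.dp,
            "delta_z": report.delta_z,
            "delta_z_over_z": report.delta_z_over_z,
            "equivalent_dp42": report.equivalent_dp42,
        },
    }


def run_report(config: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full report bundle for one scenario into ``outdir``.

    Outputs are byte-stable for a fixed config and seed except for the
    timestamp line of the log.  Returns the paths written, keyed by kind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = IllnessDeathModel(config.params, config.Q0)

    paths = {
        "equilibrium": outdir / "equilibrium.json",
        "trajectory": outdir / "trajectory.csv",
        "table1": outdir / "table1.csv",
        "sensitivity": outdir / "sensitivity.json",
        "log": outdir / "report.log",
    }

    paths["equilibrium"].write_text(
        json.dumps(equilibrium_payload(config), indent=2, sort_keys=True) + "\n"
    )

    initial = model.initial_state(config.initial_ill)
    result = model.iterate(initial, tol=config.tol, max_years=config.max_years)
    result.trajectory_frame().to_csv(paths["trajectory"], index=False)

    table = build_table1(config.params, config.Q0, config.reference_dp41)
    table.to_csv(paths["table1"])

    paths["sensitivity"].write_text(
        json.dumps(sensitivity_payload(config), indent=2, sort_keys=True) + "\n"
    )

    log_lines = [
        f"timestamp: {datetime.now(timezone.utc).isoformat()}",
        f"rosemarkov version: {__version__}",
        f"python: {platform.python_version()}  numpy: {numpy.__version__}  "
        f"pandas: {pandas.__version__}",
        f"config hash: {config.digest()}",
        "config: " + json.dumps(config.as_dict(), sort_keys=True),
        f"trajectory: converged in {result.years_to_converge} years "
        f"(residual {result.residual:.3e} of Q0, tol {config.tol:g})",
        "rounding: z and delta_z to integer; delta_z/z to 0.1 percentage "
        "point; equivalent dp42 to integer x 1e-5; rates per "
        + json.dumps(ROUNDING_RULES, sort_keys=True)
        + "; all half away from zero",
    ]
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths
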