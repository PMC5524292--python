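"""Result serialization: CSV time series, JSON summaries, run metadata."""

from __future__ import annotations

import json
from pathlib import Path

from .config import ScenarioConfig
from .engine import DT_DEFAULT, HemodynamicSummary, SimulationResult
from .errors import InvalidInputError

_UNITS = {
    "t": "s", "v_": "cm3", "q_": "cm3/s", "p_": "mmHg", "pw_f": "mmHg",
    "ve": "l/min", "theta": "beats", "phi": "breaths",
    "ca_": "mlgas/ml", "cv_": "mlgas/ml", "cmv_o2": "mlgas/ml",
    "pa_o2": "mmHg", "pa_co2": "mmHg", "hr": "bpm", "vc": "1",
    "pintr": "mmHg", "a_drive": "1", "pset_eff": "mmHg",
    "vo2_uptake": "ml/min", "vco2_lung": "ml/min", "vo2_demand": "ml/min",
    "paco2_art": "mmHg", "pao2_art": "mmHg", "f_resp": "1/min",
    "vt": "l", "va": "l/min", "pm_l": "mmHg", "cap_eff": "cm3/mmHg",
}


def _unit_for(col: str) -> str:
    if col in _UNITS:
        return _UNITS[col]
    for prefix, unit in _UNITS.items():
        if prefix.endswith("_") and col.startswith(prefix):
            return unit
    return "1"


def write_outputs(result: SimulationResult, summary: HemodynamicSummary,
                  outdir: str | Path, config: ScenarioConfig | None = None,
                  prefix: str = "run", dt: float = DT_DEFAULT) -> dict[str, Path]:
    """Write the CSV time series, JSON summary and run metadata.

    Returns the paths written, keyed ``timeseries`` / ``summary`` /
    ``metadata``.  The CSV header declares the unit of every column.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InvalidInputError(f"cannot create output dir {outdir}: {exc}")

    df = result.as_dataframe()
    df.columns = [f"{c} [{_unit_for(c)}]" for c in df.columns]
    ts_path = outdir / f"{prefix}_timeseries.csv"
    sm_path = outdir / f"{prefix}_summary.json"
    md_path = outdir / f"{prefix}_metadata.json"
    try:
        df.to_csv(ts_path, index=False, float_format="%.6g")
        sm_path.write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
        meta = {
            "config_hash": config.config_hash() if config else None,
            "condition": config.condition if config else None,
            "dt_internal_s": dt,
            "n_samples": int(result.t.size),
            "t_end_s": float(result.t[-1]),
            "events": [[t, msg] for t, msg in result.events],
        }
        md_path.write_text(json.dumps(meta, indent=2) + "\n")
    except OSError as exc:
        raise InvalidInputError(f"failed writing outputs under {outdir}: {exc}")
    return {"timeseries": ts_path, "summary": sm_path, "metadata": md_path}


def read_summary(path: str | Path) -> dict[str, float]:
    """Re-parse a written summary JSON file."""
    with open(path) as fh:
        return json.load(fh)
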