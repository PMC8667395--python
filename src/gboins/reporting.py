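"""Table writers for boundary tables and operating characteristics."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .boundaries import BoundaryParams, boundary_table, preset_constants
from .endpoint_models import BINOMIAL, normal_family
from .simulator import OCResult, Scenario

#: Per-dose sample-size grid used for the published boundary tables.
TABLE1_GRID = tuple(range(3, 31, 3))


def report_table1(out_path: str | Path | None = None) -> pd.DataFrame:
    """The four standard pre-tabulated boundary blocks.

    (Quasi-)Bernoulli and continuous endpoints at targets 0.2 and 0.3, with
    the tabulation constants, eps = 0.5, N0 = 6, phi1 = 0.6 phi0,
    phi2 = 1.4 phi0 and plug-in SD 1.1 phi0.  Display values are 2-dp
    half-up; full-precision twins are kept alongside.
    """
    blocks = []
    for endpoint, family_key, make_family in (
        ("bernoulli", "binomial", lambda phi0: BINOMIAL),
        ("continuous", "normal", lambda phi0: normal_family(plugin_value=1.1 * phi0)),
    ):
        for phi0 in (0.2, 0.3):
            c1, c2 = preset_constants("table1", family_key, phi0)
            params = BoundaryParams(phi0=phi0, c1=c1, c2=c2, sigma=1.1 * phi0)
            table = boundary_table(make_family(phi0), params, TABLE1_GRID)
            table.insert(0, "endpoint", endpoint)
            table.insert(1, "target", phi0)
            blocks.append(table)
    result = pd.concat(blocks, ignore_index=True)
    if out_path is not None:
        result.to_csv(out_path, index=False)
    return result


def oc_frame(
    results: list[tuple[Scenario, str, OCResult]]
) -> pd.DataFrame:
    """Long-format comparison table: per scenario and design, one selection
    row (proportions, 2 dp) and one allocation row (patients, 1 dp)."""
    if not results:
        raise ValueError("no results to report")
    rows = []
    for scenario, design, oc in results:
        base = {
            "scenario": scenario.name,
            "design": design,
            "true_mtd": scenario.true_mtd + 1,
            "pcs": round(oc.pcs, 1),
            "avg_n_at_mtd": round(oc.avg_n_at_mtd, 1),
            "overdose_risk_60": round(oc.overdose_risk_60, 1),
            "overdose_risk_80": round(oc.overdose_risk_80, 1),
            "underdose_risk_80": round(oc.underdose_risk_80, 1),
            "pct_no_selection": round(oc.pct_no_selection, 1),
            "n_reps": oc.n_reps,
        }
        sel = {
            f"d{j + 1}": round(v / 100.0, 2)
            for j, v in enumerate(oc.selection_pct)
        }
        alloc = {f"d{j + 1}": round(v, 1) for j, v in enumerate(oc.allocation)}
        rows.append({**base, "row": "selection", **sel})
        rows.append({**base, "row": "allocation", **alloc})
    return pd.DataFrame(rows)


def report_oc(
    results: list[tuple[Scenario, str, OCResult]],
    out_path: str | Path,
) -> pd.DataFrame:
    """Write the comparison table as CSV plus a JSON mirror of the same numbers."""
    frame = oc_frame(results)
    out_path = Path(out_path)
    frame.to_csv(out_path, index=False)
    payload = frame.to_dict(orient="records")
    out_path.with_suffix(".json").write_text(json.dumps(payload, indent=2))
    return frame
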