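"""Report assembly and run manifests.

Builds the base-case strategy table (one row per strategy per country with
incremental columns), the subgroup table, and a JSON run manifest that
records everything needed to re-run a command to bit-identical outputs:
command, config path, seed, package version, engine conventions and the
list of files written.
"""
from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .analysis import BaseCaseResult, conventions_for, run_base_case
from .params import ParameterBundle

__all__ = ["RunManifest", "base_case_table", "base_case_report", "write_manifest"]


@dataclass
class RunManifest:
    """Provenance record for one command invocation."""

    command: str
    config: str
    seed: int | None
    outputs: list[str] = field(default_factory=list)
    conventions: dict = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))
    version: str = __version__

    def add(self, path: str | Path) -> Path:
        path = Path(path)
        self.outputs.append(str(path))
        return path

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def base_case_table(results: dict[str, BaseCaseResult]) -> pd.DataFrame:
    """Strategy-level table with incremental columns on the comparator row.

    Dollar cells are rounded to integers, (Q)ALYs to two decimals; the
    incremental columns are computed from full-precision totals before any
    rounding.
    """
    rows = []
    for country_label, res in results.items():
        inc = res.incremental
        for label, s in res.summaries.items():
            is_cmp = label == inc.comparator
            rows.append(
                {
                    "country": country_label,
                    "strategy": label,
                    "total_cost": round(s.total_cost),
                    "ly": round(s.total_ly, 2),
                    "qaly": round(s.total_qaly, 2),
                    "icer_per_ly": (
                        round(inc.icer_per_ly)
                        if is_cmp and isinstance(inc.icer_per_ly, float)
                        else (inc.icer_per_ly if is_cmp else None)
                    ),
                    "icer_per_qaly": (
                        round(inc.icer_per_qaly)
                        if is_cmp and isinstance(inc.icer_per_qaly, float)
                        else (inc.icer_per_qaly if is_cmp else None)
                    ),
                    "inhb": round(inc.inhb, 2) if is_cmp else None,
                }
            )
    return pd.DataFrame(rows)


def base_case_report(
    bundle: ParameterBundle, countries: tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, dict[str, BaseCaseResult]]:
    """Base case for the requested countries: display table + raw results."""
    countries = countries or tuple(bundle.countries)
    results = {cl: run_base_case(bundle, cl) for cl in countries}
    return base_case_table(results), results


def write_manifest(
    manifest: RunManifest, out_dir: str | Path, bundle: ParameterBundle | None = None
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if bundle is not None and not manifest.conventions:
        manifest.conventions = {
            cl: conventions_for(bundle, cl).as_dict() for cl in bundle.countries
        }
    path = out_dir / "manifest.json"
    path.write_text(manifest.to_json())
    return path
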