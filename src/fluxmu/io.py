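"""Readers, writers and run manifests (CSV/YAML/JSON throughout)."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .budget import BudgetResult
from .correction import DerivativeComposition, DerivativeGroup
from .errors import FluxmuError
from .fit import ConfidenceIntervals, FitResult, MeasurementSet
from .network import FluxNetwork, parse_network

_DATA = resources.files("fluxmu") / "data"

BUNDLED_NETWORK = "network_glycolysis_ppp.csv"
BUNDLED_COMPOSITIONS = "compositions_sugar_phosphates.yaml"


def load_network(path: str | Path | None = None) -> FluxNetwork:
    """Parse a network CSV; defaults to the bundled glycolysis/PPP model."""
    if path is None:
        with resources.as_file(_DATA / BUNDLED_NETWORK) as p:
            return parse_network(p)
    return parse_network(path)


def load_compositions(path: str | Path | None = None) -> dict[str, DerivativeComposition]:
    """Load derivative compositions from YAML (defaults to the bundled set)."""
    if path is None:
        text = (_DATA / BUNDLED_COMPOSITIONS).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    comps = {}
    for met, entry in raw.items():
        groups: list[DerivativeGroup] = []
        for g in entry.get("groups", []):
            group = DerivativeGroup(
                g["name"], int(g["carbons"]), int(g.get("silicons", 0))
            )
            groups.extend([group] * int(g.get("count", 1)))
        comps[met] = DerivativeComposition(
            metabolite=met,
            backbone_carbons=int(entry["backbone_carbons"]),
            groups=tuple(groups),
            neutral_loss_carbons=int(entry.get("neutral_loss_carbons", 0)),
        )
    return comps


def read_area_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a raw-area CSV (metabolite, iso, area) into per-metabolite vectors.

    Isotopologue indices must be contiguous from 0 per metabolite and areas
    non-negative; violations name the offending rows.
    """
    df = pd.read_csv(path)
    required = {"metabolite", "iso", "area"}
    if not required.issubset(df.columns):
        raise FluxmuError(f"{path}: need columns {sorted(required)}")
    neg = df.index[df["area"] < 0].tolist()
    if neg:
        raise FluxmuError(f"{path}: negative areas at rows {neg}")
    table = {}
    for met, grp in df.groupby("metabolite", sort=False):
        isos = sorted(grp["iso"].astype(int))
        expected = list(range(len(isos)))
        if isos != expected:
            missing = sorted(set(range(max(isos) + 1)) - set(isos))
            raise FluxmuError(
                f"{path}: {met} isotopologue indices not contiguous from 0 "
                f"(missing M+{missing})"
            )
        table[met] = (
            grp.sort_values("iso")["area"].to_numpy(dtype=float)
        )
    return table


def write_area_table(table: Mapping[str, np.ndarray], path: str | Path) -> None:
    rows = [
        (met, k, float(a))
        for met, areas in table.items()
        for k, a in enumerate(np.atleast_1d(areas))
    ]
    pd.DataFrame(rows, columns=["metabolite", "iso", "area"]).to_csv(path, index=False)


def read_measurements(path: str | Path) -> MeasurementSet:
    """Read a measurement CSV (metabolite, iso, value, sd[, include, inflation])."""
    return MeasurementSet(pd.read_csv(path))


def write_measurements(meas: MeasurementSet, path: str | Path) -> None:
    meas.data.to_csv(path, index=False)


def corrected_frame(results: Mapping[str, Any]) -> pd.DataFrame:
    """Tidy frame (metabolite, iso, raw, corrected, F, IF) from CorrectedAreas."""
    rows = []
    for met, corr in results.items():
        retained = corr.retained
        total = retained.sum()
        for k in range(corr.a_corr.size):
            rows.append(
                (
                    met,
                    k,
                    float(corr.a_raw[k]),
                    float(corr.a_corr[k]),
                    int(corr.flags[k]),
                    float(retained[k] / total) if total > 0 else np.nan,
                )
            )
    return pd.DataFrame(
        rows, columns=["metabolite", "iso", "raw", "corrected", "F", "IF"]
    )


def budget_frames(results: Mapping[str, BudgetResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(summary, shares) tidy frames across metabolites."""
    summaries, shares = [], []
    for met, res in results.items():
        s = res.summary.reset_index(names="isotopologue")
        s.insert(0, "metabolite", met)
        summaries.append(s)
        sh = res.shares.reset_index(names="component").melt(
            id_vars="component", var_name="isotopologue", value_name="share_pct"
        )
        sh.insert(0, "metabolite", met)
        shares.append(sh)
    return pd.concat(summaries, ignore_index=True), pd.concat(shares, ignore_index=True)


def fit_frame(fit: FitResult) -> pd.DataFrame:
    rows = [("net", r, v) for r, v in fit.nets.items()] + [
        ("exchange", r, v) for r, v in fit.exchanges.items()
    ]
    return pd.DataFrame(rows, columns=["kind", "reaction", "flux"])


def write_results(
    objects: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> Path:
    """Write result frames as CSVs plus a JSON run manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in objects.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p.name
    config = dict(config or {})
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "fluxmu",
        "version": _version(),
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "files": written,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    return mpath


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("fluxmu")
    except Exception:
        return "unknown"
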