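"""CSV/JSON input and output for the pipeline stages.

Time–activity tables come in two flavours:

* fraction variant — columns ``patient_id, organ, t_h, value[, sd]`` where
  ``value`` is the fraction of injected activity;
* raw-count variant — columns ``patient_id, organ, t_h, ant_main,
  post_main, ant_low, post_low, ant_up, post_up``: anterior/posterior
  counts in the main and two scatter windows.  TEW scatter correction is
  applied per view, and fractions are formed by the conjugate-view method
  against the earliest whole-body row of the same patient.

Lines starting with ``#`` are provenance headers and are ignored on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__ as _version
from .kinetics import (
    ExponentialFitResults,
    PlanarCounts,
    TimeActivityCurve,
    conjugate_view_fraction,
    tew_scatter_correct,
)

__all__ = ["read_tac_csv", "write_tac_csv", "write_fits_json", "read_fits_json"]

_FRACTION_COLS = ["patient_id", "organ", "t_h", "value"]
_RAW_COLS = [
    "patient_id", "organ", "t_h",
    "ant_main", "post_main", "ant_low", "post_low", "ant_up", "post_up",
]

#: default energy windows (keV widths): 20% of 208 keV main, 10% of 175/238 keV
TEW_WIDTHS_KEV = {"main": 41.6, "lower": 17.5, "upper": 23.8}


def provenance_header(**kwargs) -> str:
    items = ", ".join(f"{k}={v}" for k, v in kwargs.items())
    return f"# actichain v{_version}" + (f" | {items}" if items else "")


def _tew_row(row: pd.Series, view: str) -> float:
    return tew_scatter_correct(
        row[f"{view}_main"], row[f"{view}_low"], row[f"{view}_up"],
        TEW_WIDTHS_KEV["main"], TEW_WIDTHS_KEV["lower"], TEW_WIDTHS_KEV["upper"],
    )


def read_tac_csv(path: str | Path) -> dict[tuple[str, str], TimeActivityCurve]:
    """Read a TAC CSV (either variant) into per-(patient, organ) curves."""
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    if set(_RAW_COLS) <= cols:
        df = df.sort_values(["patient_id", "organ", "t_h"])
        frames = []
        for pid, grp in df.groupby("patient_id"):
            wb = grp[grp["organ"] == "whole_body"].sort_values("t_h")
            if wb.empty:
                raise ValueError(
                    f"raw-count variant needs a 'whole_body' organ for patient {pid!r}"
                )
            ref_row = wb.iloc[0]
            ref = PlanarCounts(_tew_row(ref_row, "ant"), _tew_row(ref_row, "post"))
            vals = grp.apply(
                lambda r: conjugate_view_fraction(
                    PlanarCounts(_tew_row(r, "ant"), _tew_row(r, "post")), ref
                ),
                axis=1,
            )
            out = grp[["patient_id", "organ", "t_h"]].copy()
            out["value"] = vals
            frames.append(out)
        df = pd.concat(frames, ignore_index=True)
    elif not set(_FRACTION_COLS) <= cols:
        missing = [c for c in _FRACTION_COLS if c not in cols]
        raise ValueError(f"TAC CSV missing required column(s): {missing}")

    curves: dict[tuple[str, str], TimeActivityCurve] = {}
    for (pid, organ), grp in df.groupby(["patient_id", "organ"]):
        grp = grp.sort_values("t_h")
        sd = tuple(grp["sd"]) if "sd" in grp.columns and grp["sd"].notna().all() else None
        curves[(str(pid), str(organ))] = TimeActivityCurve(
            organ=str(organ),
            times_h=tuple(grp["t_h"].astype(float)),
            values=tuple(grp["value"].astype(float)),
            sd=sd,
        )
    return curves


def write_tac_csv(
    curves: Mapping[tuple[str, str], TimeActivityCurve],
    path: str | Path,
    **provenance,
) -> None:
    rows = []
    for (pid, organ), tac in curves.items():
        for t, v in zip(tac.times_h, tac.values):
            rows.append({"patient_id": pid, "organ": organ, "t_h": t, "value": v})
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(provenance_header(**provenance) + "\n")
        df.to_csv(fh, index=False)


def write_fits_json(
    fits: Mapping[tuple[str, str], ExponentialFitResults],
    path: str | Path,
    **provenance,
) -> None:
    payload: dict = {"_meta": provenance_header(**provenance), "fits": {}}
    for (pid, organ), fit in fits.items():
        payload["fits"].setdefault(pid, {})[organ] = {
            "model": fit.model,
            "amplitudes": list(fit.amplitudes),
            "rates_per_h": list(fit.rates),
            "rss": fit.rss,
            "effective_half_life_h": fit.effective_half_life_h,
            "residence_time_h": fit.residence_time_h,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fits_json(path: str | Path) -> dict[tuple[str, str], dict]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for pid, organs in payload["fits"].items():
        for organ, rec in organs.items():
            out[(pid, organ)] = rec
    return out
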