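"""Packaged reference tables from the 13-patient ¹⁷⁷Lu-PSMA dosimetry cohort.

Three small CSVs ship with the package:

* ``table1_dose_coefficients.csv`` — per-patient RBE-5-weighted predictive
  dose coefficients (Bd_RBE5/MBq) for kidneys, liver, parotid and
  submandibular glands, red marrow (missing for four patients) and whole
  body.
* ``table2_radiobiology_parameters.csv`` — the radiobiology parameter set
  (α/β, μ, reference injection activity, RBE_exp, d, TD50, m).
* ``table3_bed.csv`` — per-patient BED_H (Gy) at 100 kBq/kg for parotid,
  submandibular and salivary glands (salivary = per-patient mean of the
  other two).

These are inputs for cohort statistics and NTCP curves, not recomputation
targets: the per-patient washout constants and body weights behind them are
not available, so the package treats them as measured data.
"""

from __future__ import annotations

import hashlib
import io
from importlib import resources

import pandas as pd

from .radiobiology import RadiobiologyParams

__all__ = [
    "load_dose_coefficients",
    "load_bed_table",
    "load_radiobiology_defaults",
    "load_reference_tables",
    "fixture_sha256",
]

ORGANS = ("kidneys", "liver", "parotid", "submandibular", "red_marrow", "whole_body")
REFERENCE_ACTIVITY_KBQ_PER_KG = 100.0
#: mean salivary-gland coefficient of the no-protector reference cohort, Sv_RBE5/MBq
REFERENCE_SALIVARY_MEAN = 2.33
#: cohort median body weight (kg) and per-organ median effective half-lives (h)
DEFAULT_WEIGHT_KG = 80.0
DEFAULT_EFFECTIVE_HALF_LIFE_H = {
    "kidneys": 17.6,
    "liver": 12.1,
    "parotid": 25.5,
    "submandibular": 10.0,
    "red_marrow": 2.1,
    "whole_body": 5.7,
    # salivary glands are evaluated as the PG/SG mean; same rule for the default
    "salivary": (25.5 + 10.0) / 2.0,
}


def _read(name: str) -> bytes:
    return resources.files("actichain.data").joinpath(name).read_bytes()


def fixture_sha256(name: str) -> str:
    """SHA-256 of a packaged data file (used to pin fixtures in tests)."""
    return hashlib.sha256(_read(name)).hexdigest()


def load_dose_coefficients() -> pd.DataFrame:
    """13×6 per-patient dose coefficients, Bd_RBE5/MBq, indexed by patient."""
    df = pd.read_csv(io.BytesIO(_read("table1_dose_coefficients.csv")), index_col="patient")
    return df[list(ORGANS)]


def load_bed_table() -> pd.DataFrame:
    """13×3 per-patient BED_H (Gy) at 100 kBq/kg, indexed by patient."""
    return pd.read_csv(io.BytesIO(_read("table3_bed.csv")), index_col="patient")


def load_radiobiology_defaults() -> RadiobiologyParams:
    """Radiobiology parameters from the packaged parameter table."""
    df = pd.read_csv(io.BytesIO(_read("table2_radiobiology_parameters.csv")))
    values = dict(zip(df["parameter"], df["value"]))
    return RadiobiologyParams(
        alpha_beta=float(values["alpha_beta"]),
        mu=float(values["mu"]),
        rbe_exp=float(values["rbe_exp"]),
        d_ref=float(values["d_ref"]),
        td50=float(values["td50"]),
        m=float(values["m"]),
    )


def load_parameter_table() -> pd.DataFrame:
    return pd.read_csv(io.BytesIO(_read("table2_radiobiology_parameters.csv")))


def load_reference_tables() -> dict:
    """All packaged reference tables in one call."""
    return {
        "dose_coefficients": load_dose_coefficients(),
        "parameters": load_parameter_table(),
        "radiobiology": load_radiobiology_defaults(),
        "bed": load_bed_table(),
    }
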