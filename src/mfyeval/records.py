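"""Domain record types: cows, herd diets, and their tabular (CSV) form.

Cow records carry one animal's identity, herd membership, physiology and
milk test-day results.  Diet records carry one herd's ration composition
on a dry matter (DM) basis.  Both are plain dataclasses with explicit
``validate`` methods; tabular I/O goes through pandas with the column
names below as the canonical header row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

import pandas as pd

from mfyeval.errors import EmptyInputError, MissingColumnError, ValidationError

#: Default body condition score assigned when BCS was not scored on farm.
DEFAULT_BCS = 2.5

#: Relative tolerance for the observed-MFY consistency check
#: (observed_mfy_g must equal milk_yield * fat_pct * 10 up to rounding).
MFY_CONSISTENCY_RTOL = 5e-3

COW_COLUMNS = [
    "cow_id",
    "herd_id",
    "parity_raw",
    "an_bw",
    "an_bcs",
    "an_daylact",
    "milk_yield",
    "fat_pct",
    "protein_pct",
    "lactose_pct",
    "observed_mfy_g",
]

#: Optional cow columns the pipeline understands.
COW_OPTIONAL_COLUMNS = ["mp_g", "dmi_obs"]

DIET_COLUMNS = [
    "herd_id",
    "dt_fndf",
    "dt_adf",
    "dt_ndf",
    "fa_pct_dm",
    "dig_c160_pct_dm",
    "dig_c183_pct_dm",
    "ile_pct_mp",
    "met_pct_mp",
    "forndf48_ndf",
]


def binarize_parity(lactation_number: int) -> int:
    """Map raw lactation number to the two-class parity code.

    1 = primiparous (first lactation), 2 = multiparous (any later
    lactation).  The intake and fat-yield equations only distinguish
    these two classes.
    """
    if lactation_number < 1:
        raise ValidationError(f"lactation number must be >= 1, got {lactation_number}")
    return 1 if lactation_number == 1 else 2


@dataclass
class CowRecord:
    """One cow's test-day record.

    ``an_parity`` is the binary parity class used by the equations and
    is derived from ``parity_raw`` (the lactation number) unless given.
    ``observed_mfy_g`` defaults to ``milk_yield * fat_pct * 10`` (kg/d
    times percent gives dag/d; the factor 10 converts to g/d).
    """

    cow_id: str
    herd_id: str
    parity_raw: int
    an_bw: float
    an_daylact: float
    milk_yield: float
    fat_pct: float
    an_bcs: float = DEFAULT_BCS
    protein_pct: Optional[float] = None
    lactose_pct: Optional[float] = None
    observed_mfy_g: Optional[float] = None
    mp_g: Optional[float] = None
    dmi_obs: Optional[float] = None
    an_parity: int = field(init=False)

    def __post_init__(self):
        self.an_parity = binarize_parity(int(self.parity_raw))
        if self.observed_mfy_g is None:
            self.observed_mfy_g = self.milk_yield * self.fat_pct * 10.0

    def validate(self) -> None:
        if self.an_parity not in (1, 2):
            raise ValidationError(f"an_parity must be 1 or 2, got {self.an_parity}")
        if not 1.0 <= self.an_bcs <= 5.0:
            raise ValidationError(f"BCS must lie in [1, 5], got {self.an_bcs}")
        if self.an_daylact < 1:
            raise ValidationError(f"DIM must be >= 1, got {self.an_daylact}")
        if self.an_bw <= 0 or self.milk_yield < 0:
            raise ValidationError("body weight must be positive and milk yield non-negative")
        expected = self.milk_yield * self.fat_pct * 10.0
        if expected > 0 and not math.isclose(
            self.observed_mfy_g, expected, rel_tol=MFY_CONSISTENCY_RTOL, abs_tol=1.0
        ):
            raise ValidationError(
                f"observed_mfy_g={self.observed_mfy_g:.1f} inconsistent with "
                f"milk_yield*fat_pct*10={expected:.1f} for cow {self.cow_id}"
            )


@dataclass
class DietComposition:
    """One herd diet's nutrient concentrations, % of DM unless noted.

    ``ile_pct_mp`` / ``met_pct_mp`` are amino acid concentrations as a
    percentage of metabolizable protein (MP); ``forndf48_ndf`` is 48-h
    in vitro forage NDF digestibility as % of NDF.
    """

    herd_id: str
    dt_fndf: float
    dt_adf: float
    dt_ndf: float
    fa_pct_dm: float
    dig_c160_pct_dm: float
    dig_c183_pct_dm: float
    ile_pct_mp: float
    met_pct_mp: float
    forndf48_ndf: float

    def validate(self) -> None:
        if not 0 < self.dt_adf < self.dt_ndf < 100:
            raise ValidationError(
                f"require 0 < ADF < NDF < 100 (%DM); got ADF={self.dt_adf}, NDF={self.dt_ndf}"
            )
        if not 0 <= self.dt_fndf <= self.dt_ndf:
            raise ValidationError(
                f"forage NDF ({self.dt_fndf}) must lie in [0, NDF={self.dt_ndf}]"
            )
        for name in (
            "fa_pct_dm",
            "dig_c160_pct_dm",
            "dig_c183_pct_dm",
            "ile_pct_mp",
            "met_pct_mp",
            "forndf48_ndf",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{name} must lie in [0, 100], got {v}")


def _read_table(path, table: str, required: list[str]) -> pd.DataFrame:
    """Read a delimited table (comma default, tab fallback) and check columns."""
    df = pd.read_csv(path)
    if df.shape[1] == 1 and required[0] not in df.columns:
        df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(table, missing)
    if df.empty:
        raise EmptyInputError(f"{table} table at {path} contains no records")
    return df


def read_cow_table(path) -> pd.DataFrame:
    """Read a cow-record CSV/TSV; fills defaults for optional columns.

    Missing ``an_bcs`` values default to 2.5 (BCS not scored); missing
    ``observed_mfy_g`` is computed from milk yield and fat percentage.
    """
    required = [c for c in COW_COLUMNS if c not in ("an_bcs", "observed_mfy_g",
                                                    "protein_pct", "lactose_pct")]
    df = _read_table(path, "cow", required)
    if "an_bcs" not in df.columns:
        df["an_bcs"] = DEFAULT_BCS
    df["an_bcs"] = df["an_bcs"].fillna(DEFAULT_BCS)
    if "observed_mfy_g" not in df.columns:
        df["observed_mfy_g"] = df["milk_yield"] * df["fat_pct"] * 10.0
    df["an_parity"] = df["parity_raw"].astype(int).map(binarize_parity)
    return df


def read_diet_table(path) -> pd.DataFrame:
    """Read a diet-composition CSV/TSV keyed on herd_id."""
    df = _read_table(path, "diet", DIET_COLUMNS)
    return df


def cows_to_frame(records: list[CowRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r) if f.name != "an_parity"}
        d["an_parity"] = r.an_parity
        rows.append(d)
    return pd.DataFrame(rows)


def diets_to_frame(diets: list[DietComposition]) -> pd.DataFrame:
    return pd.DataFrame([{f.name: getattr(d, f.name) for f in fields(d)} for d in diets])
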