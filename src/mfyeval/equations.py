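"""Closed-form prediction equations for lactating dairy cows.

Implements the NASEM (2021) multivariate milk fat yield (MFY) equation
and the two dry matter intake (DMI) models it is paired with for
on-farm use:

* MFY (g/d) as a linear function of days in milk, non-fat dry matter
  intake, digested palmitic (16:0) and alpha-linolenic (18:3) acid
  intakes, and absorbed isoleucine and methionine;
* DMI from animal factors alone (parity, milk net-energy output, body
  weight, body condition score, days in milk) — an asymptotic
  lactation-curve form;
* DMI from feed plus animal factors (forage NDF, ADF/NDF ratio, forage
  NDF digestibility and milk production target) with two centered
  interaction terms.

All functions accept scalars or numpy arrays and broadcast; identical
inputs give bit-identical outputs.  Negative predictions are physically
meaningless but are returned as-is with a :class:`PredictionWarning`
rather than clamped, so downstream evaluation sees every record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from mfyeval.config import MILK_NE_COEFFICIENTS, MilkNECoefficients
from mfyeval.errors import PredictionWarning, ValidationError

__all__ = [
    "MFYInputs",
    "predict_milk_fat_yield",
    "predict_dmi_animal",
    "predict_dmi_feed_animal",
    "milk_net_energy",
]

# ---------------------------------------------------------------------------
# Milk fat yield equation coefficients (g/d scale).
MFY_INTERCEPT = 453.0          # g/d
MFY_DIM = -1.42                # g/d per day in milk
MFY_NONFAT_DMI = 24.52         # g/d per kg/d of (DMI - FA intake)
MFY_DIG_C160 = 0.41            # g/d per g/d digested 16:0 (kg/d * 1000)
MFY_DIG_C183 = 1.80            # g/d per g/d digested 18:3 (kg/d * 1000)
MFY_ABS_ILE = 1.45             # g/d per g/d absorbed Ile
MFY_ABS_MET = 1.34             # g/d per g/d absorbed Met

# DMI from animal factors (kg/d scale): base-intake term coefficients ...
DMI1_INTERCEPT = 3.7
DMI1_PARITY = 5.7              # added for multiparous (An_Parity - 1)
DMI1_NE = 0.305                # per Mcal/d milk net energy
DMI1_BW = 0.022                # per kg body weight
DMI1_BCS = -0.689              # per BCS unit
DMI1_BCS_PARITY = -1.87        # extra BCS slope for multiparous
# ... and the days-in-milk adjustment (fraction of mature intake).
DMI1_ADJ_SCALE = 0.212
DMI1_ADJ_SCALE_PARITY = 0.136
DMI1_ADJ_RATE = 0.053          # per day

# DMI from feed and animal factors (kg/d scale).
DMI2_INTERCEPT = 12.0
DMI2_FNDF = -0.107             # per % forage NDF in diet DM
DMI2_ADF_NDF = 8.17            # per unit ADF/NDF ratio
DMI2_NDFD = 0.0253             # per % forage NDF digestibility
DMI2_INT1 = -0.328             # (ADF/NDF - 0.602) x (NDFD - 48.3)
DMI2_MILK = 0.225              # per kg/d milk production target
DMI2_INT2 = 0.00390            # (NDFD - 48.3) x (milk - 33.1)
DMI2_ADF_NDF_CENTER = 0.602
DMI2_NDFD_CENTER = 48.3
DMI2_MILK_CENTER = 33.1


@dataclass
class MFYInputs:
    """The seven resolved predictors of the milk fat yield equation.

    Units: days for ``an_lactday``; kg/d for the intakes; g/d for the
    absorbed amino acids.
    """

    an_lactday: float      # days in milk
    dt_dmin: float         # dry matter intake, kg/d
    dt_fain: float         # dietary fatty acid intake, kg/d
    dt_digc160in: float    # digested 16:0 intake, kg/d
    dt_digc183in: float    # digested 18:3 intake, kg/d
    abs_ile_g: float       # absorbed isoleucine, g/d
    abs_met_g: float       # absorbed methionine, g/d

    def validate(self) -> None:
        for name in (
            "an_lactday", "dt_dmin", "dt_fain", "dt_digc160in",
            "dt_digc183in", "abs_ile_g", "abs_met_g",
        ):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"{name} must be finite")
            if np.any(np.asarray(v) < 0):
                raise ValidationError(f"{name} must be >= 0")
        if np.any(np.asarray(self.dt_fain) > np.asarray(self.dt_dmin)):
            raise ValidationError("fatty acid intake cannot exceed dry matter intake")


def predict_milk_fat_yield(inputs: MFYInputs) -> float | np.ndarray:
    """Predicted milk fat yield (g/d).

    ``453 - 1.42*DIM + 24.52*(DMI - FAIn) + 0.41*1000*DigC160In
    + 1.80*1000*DigC183In + 1.45*AbsIle + 1.34*AbsMet`` with intakes in
    kg/d and absorbed amino acids in g/d.  A negative result (possible
    at extreme days in milk) is returned unmodified with a warning.
    """
    inputs.validate()
    mfy = (
        MFY_INTERCEPT
        + MFY_DIM * np.asarray(inputs.an_lactday, dtype=float)
        + MFY_NONFAT_DMI * (np.asarray(inputs.dt_dmin, dtype=float)
                            - np.asarray(inputs.dt_fain, dtype=float))
        + MFY_DIG_C160 * np.asarray(inputs.dt_digc160in, dtype=float) * 1000.0
        + MFY_DIG_C183 * np.asarray(inputs.dt_digc183in, dtype=float) * 1000.0
        + MFY_ABS_ILE * np.asarray(inputs.abs_ile_g, dtype=float)
        + MFY_ABS_MET * np.asarray(inputs.abs_met_g, dtype=float)
    )
    if np.any(mfy < 0):
        warnings.warn(
            "predicted milk fat yield is negative for at least one record",
            PredictionWarning,
            stacklevel=2,
        )
    return mfy if isinstance(mfy, np.ndarray) and mfy.ndim else float(mfy)


def dmi_animal_base(parity, milk_neuse_target, bw, bcs):
    """Base (mature) intake term of the animal-factors DMI model, kg/d."""
    p = np.asarray(parity, dtype=float) - 1.0
    return (
        DMI1_INTERCEPT
        + DMI1_PARITY * p
        + DMI1_NE * np.asarray(milk_neuse_target, dtype=float)
        + DMI1_BW * np.asarray(bw, dtype=float)
        + (DMI1_BCS + DMI1_BCS_PARITY * p) * np.asarray(bcs, dtype=float)
    )


def dmi_animal_adjustment(parity, dim):
    """Days-in-milk intake adjustment, a fraction in (0, 1) rising to 1."""
    p = np.asarray(parity, dtype=float) - 1.0
    return 1.0 - (DMI1_ADJ_SCALE + DMI1_ADJ_SCALE_PARITY * p) * np.exp(
        -DMI1_ADJ_RATE * np.asarray(dim, dtype=float)
    )


def predict_dmi_animal(parity, milk_neuse_target, bw, bcs, dim) -> float | np.ndarray:
    """DMI (kg/d) from animal factors alone.

    Product of a base intake term (linear in parity class, milk
    net-energy output in Mcal/d, body weight in kg and BCS) and an
    exponential days-in-milk adjustment approaching 1 as lactation
    advances.

    Parameters follow the equation's conventions: ``parity`` is 1
    (primiparous) or 2 (multiparous); ``dim`` must be >= 1.
    """
    parity_arr = np.asarray(parity)
    if not np.all(np.isin(parity_arr, (1, 2))):
        raise ValidationError("parity class must be 1 or 2")
    if np.any(np.asarray(dim) <= 0):
        raise ValidationError("days in milk must be >= 1")
    if np.any(np.asarray(bcs) < 1) or np.any(np.asarray(bcs) > 5):
        raise ValidationError("BCS must lie in [1, 5]")
    dmi = dmi_animal_base(parity, milk_neuse_target, bw, bcs) * dmi_animal_adjustment(
        parity, dim
    )
    if np.any(dmi < 0):
        warnings.warn(
            "predicted DMI (animal factors) is negative for at least one record",
            PredictionWarning,
            stacklevel=2,
        )
    return dmi if isinstance(dmi, np.ndarray) and dmi.ndim else float(dmi)


def predict_dmi_feed_animal(diet, milk_prod_target) -> float | np.ndarray:
    """DMI (kg/d) from feed composition plus the milk production target.

    Six-term sum: intercept, forage NDF penalty, ADF/NDF ratio, forage
    NDF digestibility (NDFD, 48-h in vitro), an (ADF/NDF)x(NDFD)
    interaction centered at 0.602 and 48.3, the milk production target,
    and an NDFDxmilk interaction centered at 48.3 and 33.1 kg/d.

    ``diet`` may be a :class:`~mfyeval.records.DietComposition` or any
    object with ``dt_fndf``, ``dt_adf``, ``dt_ndf``, ``forndf48_ndf``
    attributes (arrays allowed).
    """
    ndf = np.asarray(diet.dt_ndf, dtype=float)
    if np.any(ndf <= 0):
        raise ValidationError("diet NDF must be positive (ADF/NDF ratio undefined)")
    ratio = np.asarray(diet.dt_adf, dtype=float) / ndf
    ndfd = np.asarray(diet.forndf48_ndf, dtype=float)
    milk = np.asarray(milk_prod_target, dtype=float)
    dmi = (
        DMI2_INTERCEPT
        + DMI2_FNDF * np.asarray(diet.dt_fndf, dtype=float)
        + DMI2_ADF_NDF * ratio
        + DMI2_NDFD * ndfd
        + DMI2_INT1 * (ratio - DMI2_ADF_NDF_CENTER) * (ndfd - DMI2_NDFD_CENTER)
        + DMI2_MILK * milk
        + DMI2_INT2 * (ndfd - DMI2_NDFD_CENTER) * (milk - DMI2_MILK_CENTER)
    )
    if np.any(dmi < 0):
        warnings.warn(
            "predicted DMI (feed and animal factors) is negative for at least one record",
            PredictionWarning,
            stacklevel=2,
        )
    return dmi if isinstance(dmi, np.ndarray) and dmi.ndim else float(dmi)


def milk_net_energy(
    milk_yield,
    fat_pct,
    protein_pct,
    lactose_pct,
    coefficients: str | MilkNECoefficients = "nasem2021_true_protein",
) -> float | np.ndarray:
    """Net energy exported in milk (Mcal/d) from yield and composition.

    Per-kg milk energy is a linear function of fat, protein and lactose
    concentrations (% w/w); the coefficient set is looked up by name in
    :data:`mfyeval.config.MILK_NE_COEFFICIENTS` (or passed directly).
    The default set treats the protein input as true protein; the
    ``nasem2021_crude_protein`` set applies the crude-to-true protein
    conversion inside the protein coefficient.
    """
    if isinstance(coefficients, str):
        try:
            coefficients = MILK_NE_COEFFICIENTS[coefficients]
        except KeyError:
            raise ValidationError(
                f"unknown milk NE coefficient set '{coefficients}'; "
                f"available: {sorted(MILK_NE_COEFFICIENTS)}"
            ) from None
    for name, v in (("fat", fat_pct), ("protein", protein_pct), ("lactose", lactose_pct)):
        if v is None or not np.all(np.isfinite(np.asarray(v, dtype=float))):
            raise ValidationError(f"milk {name} concentration is required and must be finite")
    energy_per_kg = (
        coefficients.fat * np.asarray(fat_pct, dtype=float)
        + coefficients.protein * np.asarray(protein_pct, dtype=float)
        + coefficients.lactose * np.asarray(lactose_pct, dtype=float)
    ) / 100.0
    ne = np.asarray(milk_yield, dtype=float) * energy_per_kg
    return ne if isinstance(ne, np.ndarray) and ne.ndim else float(ne)
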