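"""Resolve diet-level nutrient concentrations into per-cow predictors.

The fat-yield equation consumes *daily amounts* (kg/d of fatty acids,
g/d of absorbed amino acids), while herd records carry *concentrations*
(% of diet DM, % of metabolizable protein).  This module converts one
into the other with plain concentration x intake products:

    intake (kg/d)      = DMI (kg/d) x concentration (% of DM) / 100
    absorbed AA (g/d)  = MP supply (g/d) x concentration (% of MP) / 100

This is deliberately simpler than a full digestion model: herd-level
feed analyses rarely support fatty-acid digestibility or post-ruminal
protein-flow sub-models, so evaluation at this resolution treats the
tabulated digestible-FA and %-of-MP values as the best available
characterisation of the diet.  All derivations are homogeneous of
degree one in intake: doubling DMI (or MP supply) doubles every output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from mfyeval.equations import MFYInputs
from mfyeval.errors import ValidationError

__all__ = [
    "ProteinSupply",
    "derive_fa_intake",
    "derive_digested_fa",
    "derive_absorbed_aa",
    "resolve_mfy_inputs",
]


@dataclass
class ProteinSupply:
    """Metabolizable protein supply, or directly measured absorbed AA.

    Exactly one mode must be used: either ``mp_g`` (g/d of MP, to be
    split by diet AA concentrations) or the direct pair
    ``abs_ile_g``/``abs_met_g`` (g/d, passed through unchanged).
    """

    mp_g: Optional[float] = None
    abs_ile_g: Optional[float] = None
    abs_met_g: Optional[float] = None

    def validate(self) -> None:
        direct = self.abs_ile_g is not None or self.abs_met_g is not None
        if self.mp_g is not None and direct:
            raise ValidationError("give either mp_g or the direct AA pair, not both")
        if self.mp_g is None and not direct:
            raise ValidationError("one of mp_g or the direct AA pair is required")
        if direct and (self.abs_ile_g is None or self.abs_met_g is None):
            raise ValidationError("direct mode requires both abs_ile_g and abs_met_g")
        for v in (self.mp_g, self.abs_ile_g, self.abs_met_g):
            if v is not None and np.any(np.asarray(v) < 0):
                raise ValidationError("protein supply values must be >= 0")


def _pct_product(amount, pct, amount_name: str, pct_name: str):
    amount_arr = np.asarray(amount, dtype=float)
    pct_arr = np.asarray(pct, dtype=float)
    if np.any(amount_arr < 0):
        raise ValidationError(f"{amount_name} must be >= 0")
    if np.any(pct_arr < 0) or np.any(pct_arr > 100):
        raise ValidationError(f"{pct_name} must lie in [0, 100]")
    out = amount_arr * pct_arr / 100.0
    return out if out.ndim else float(out)


def derive_fa_intake(dmi, fa_pct_dm):
    """Dietary fatty acid intake (kg/d) = DMI x FA concentration (% DM) / 100.

    Whether ``fa_pct_dm`` holds total fatty acids or crude fat is the
    caller's calibration choice; feed analyses commonly report crude
    fat, which slightly overstates FA.
    """
    return _pct_product(dmi, fa_pct_dm, "dmi", "fa_pct_dm")


def derive_digested_fa(dmi, dig_pct_dm):
    """Digested fatty acid intake (kg/d) for one FA given its digestible
    concentration (% of DM)."""
    return _pct_product(dmi, dig_pct_dm, "dmi", "dig_pct_dm")


def derive_absorbed_aa(supply: ProteinSupply, ile_pct_mp, met_pct_mp):
    """Absorbed (Ile, Met) in g/d.

    MP mode splits the MP supply by the diet's AA concentrations
    (% of MP); direct mode passes the measured pair through unchanged.
    """
    supply.validate()
    if supply.mp_g is None:
        return supply.abs_ile_g, supply.abs_met_g
    return (
        _pct_product(supply.mp_g, ile_pct_mp, "mp_g", "ile_pct_mp"),
        _pct_product(supply.mp_g, met_pct_mp, "mp_g", "met_pct_mp"),
    )


def resolve_mfy_inputs(dim, dmi, diet, supply: ProteinSupply) -> MFYInputs:
    """Assemble the seven fat-yield predictors for one cow (or vectors).

    ``diet`` is a :class:`~mfyeval.records.DietComposition` (or any
    object exposing its concentration fields, arrays allowed).
    """
    abs_ile, abs_met = derive_absorbed_aa(supply, diet.ile_pct_mp, diet.met_pct_mp)
    return MFYInputs(
        an_lactday=dim,
        dt_dmin=dmi,
        dt_fain=derive_fa_intake(dmi, diet.fa_pct_dm),
        dt_digc160in=derive_digested_fa(dmi, diet.dig_c160_pct_dm),
        dt_digc183in=derive_digested_fa(dmi, diet.dig_c183_pct_dm),
        abs_ile_g=abs_ile,
        abs_met_g=abs_met,
    )
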