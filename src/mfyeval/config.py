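"""Run configuration: milk-energy coefficient sets, moment conventions,
column mappings and noise settings, loadable from a YAML file.

Everything that is a *convention* rather than a printed equation
coefficient lives here, so a single config file pins down a run:

* which milk net-energy coefficient set converts milk composition to
  Mcal/d (the nutrient-requirements reference offers variants with and
  without the crude-to-true protein adjustment; neither is hard-coded
  into the equations module);
* the moment convention for the agreement statistics (population ``1/n``
  by default — it makes the MSE partition an exact identity — with the
  sample ``n-1`` convention available for cross-checks against other
  software);
* which DMI sources the pipeline evaluates;
* defaults that stand in for variables commercial records often lack
  (metabolizable protein supply scaled to milk yield, BCS = 2.5).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from mfyeval.errors import ValidationError


@dataclass(frozen=True)
class MilkNECoefficients:
    """Mcal per kg of milk component (applied to % w/w concentrations / 100)."""

    fat: float
    protein: float
    lactose: float
    protein_basis: str  # "true" or "crude"


#: Named milk net-energy coefficient sets (Mcal per kg of component).
#: The default treats the milk protein input as true protein; the crude
#: variant folds a 0.951 crude-to-true conversion into the protein term.
MILK_NE_COEFFICIENTS: dict[str, MilkNECoefficients] = {
    "nasem2021_true_protein": MilkNECoefficients(9.29, 5.85, 3.95, "true"),
    "nasem2021_crude_protein": MilkNECoefficients(9.29, 5.85 * 0.951, 3.95, "crude"),
}

#: DMI sources the pipeline can evaluate, in report column order
#: (animal factors first).
DMI_SOURCES = ("animal_factors", "feed_animal_factors", "observed")


@dataclass
class RunConfig:
    """Configuration for a prediction/evaluation run."""

    milk_ne_coefficients: str = "nasem2021_true_protein"
    moment_convention: str = "population"  # or "sample"
    dmi_sources: tuple[str, ...] = ("animal_factors", "feed_animal_factors")
    default_bcs: float = 2.5
    # Metabolizable protein supply fallback when no mp_g column exists:
    # mp_g = mp_intercept_g + mp_slope_g_per_kg_milk * milk_yield.
    # A plausibility default, not estimated from any dataset.
    mp_intercept_g: float = 1200.0
    mp_slope_g_per_kg_milk: float = 45.0

    def __post_init__(self):
        if self.milk_ne_coefficients not in MILK_NE_COEFFICIENTS:
            raise ValidationError(
                f"unknown milk NE coefficient set '{self.milk_ne_coefficients}'"
            )
        if self.moment_convention not in ("population", "sample"):
            raise ValidationError("moment_convention must be 'population' or 'sample'")
        self.dmi_sources = tuple(self.dmi_sources)
        unknown = [s for s in self.dmi_sources if s not in DMI_SOURCES]
        if unknown:
            raise ValidationError(f"unknown dmi_source(s): {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Short stable hash of the configuration, logged for reproducibility."""
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
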