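"""Compound parameter models: victims, metabolites and perpetrators.

A :class:`CompoundModel` bundles everything the simulation engine needs
for one analyte: physicochemistry, the segmented gut absorption terms
with optional saturable P-gp efflux, the lumped distribution terms, and
per-pathway intrinsic clearances plus renal filtration/secretion.
Perpetrators use the same schema with a simple systemic clearance and a
fixed first-pass availability instead of the pathway machinery.

Internal unit convention: hours, litres, milligrams, with plasma
concentrations reported in ng/mL and enzyme-site concentrations in uM
(converted through the molecular weight).

All parameter files bundled under ``pbpkddi/data/compounds`` are
reconstructions: literature-typical starting values calibrated so the
reduced model reproduces published clinical exposure and interaction
magnitudes.  Each file records per-value ``source`` annotations.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, model_validator

PATHWAYS = ("CES", "UGT2B15", "CYP3A4", "CYP2J2", "OTHER")
INHIBITION_TARGETS = ("CYP3A4", "CYP2J2", "PGP_GUT", "PGP_RENAL", "OAT3")


class ValidationFileError(ValueError):
    """A compound or interaction file failed validation."""


class AbsorptionParams(BaseModel):
    """Oral absorption through a segmented lumen chain.

    ``ka_h`` moves drug from each lumen segment into its enterocyte
    compartment; ``k_ent_h`` moves enterocyte drug onward into the portal
    inflow of the liver.  Perpetrators set ``k_ent_h`` to None and are
    absorbed straight into the central compartment with a fixed
    ``first_pass_availability``.
    """

    ka_h: float = Field(gt=0)
    lag_h: float = Field(default=0.0, ge=0)
    gut_segments: int = Field(default=7, ge=1)
    transit_time_h: float = Field(default=3.32, gt=0)
    k_ent_h: float | None = Field(default=None, gt=0)
    fraction_released: float = Field(default=1.0, gt=0, le=1)
    first_pass_availability: float = Field(default=1.0, gt=0, le=1)
    gut_free_fraction: float = Field(default=1.0, gt=0, le=1)
    v_lumen_total_L: float = Field(default=0.25, gt=0)
    v_ent_total_L: float = Field(default=0.07, gt=0)


class PgpGutParams(BaseModel):
    """Michaelis–Menten efflux from enterocyte back into the lumen."""

    km_uM: float = Field(gt=0)
    jmax_mg_h: float = Field(ge=0)
    #: declared basis of jmax: per reference whole gut (scaled by PGP_GUT
    #: abundance), never per unit length
    basis: Literal["whole_gut"] = "whole_gut"


class BioavailabilityRule(BaseModel):
    """Dose-threshold rule on fraction released (e.g. rivaroxaban >10 mg)."""

    f_low_dose: float = Field(gt=0, le=1)
    f_high_dose: float = Field(gt=0, le=1)
    dose_threshold_mg: float = Field(gt=0)

    def fraction_released(self, dose_mg: float) -> float:
        return self.f_low_dose if dose_mg <= self.dose_threshold_mg else self.f_high_dose


class DistributionParams(BaseModel):
    vc_L_per_kg: float = Field(gt=0)
    vp_L_per_kg: float = Field(default=0.0, ge=0)
    q_inter_L_h: float = Field(default=0.0, ge=0)
    kp_liver: float = Field(default=1.0, gt=0)


class ClearanceParams(BaseModel):
    """Per-pathway hepatic intrinsic clearances and renal terms.

    ``clint_L_h`` values are expressed for a reference adult liver
    (1.8 L) and are scaled by subject liver volume and the matching
    abundance scalar.  ``renal_secretion_L_h`` is expressed at a
    reference GFR of 100 mL/min and scales with subject renal function.
    ``systemic_cl_L_h`` is the simple linear clearance used for
    perpetrator models instead of the mechanistic terms.
    """

    clint_L_h: dict[str, float] = Field(default_factory=dict)
    fm: dict[str, float] = Field(default_factory=dict)
    renal_filtration: bool = True
    renal_secretion_L_h: float = Field(default=0.0, ge=0)
    secretion_split: dict[str, float] = Field(default_factory=dict)
    systemic_cl_L_h: float | None = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "ClearanceParams":
        for pw, v in self.clint_L_h.items():
            if pw not in PATHWAYS:
                raise ValidationFileError(f"unknown clearance pathway {pw!r}")
            if v < 0:
                raise ValidationFileError(f"clint_L_h[{pw}] is negative")
        if any(f < 0 for f in self.fm.values()):
            raise ValidationFileError("fm entries must be >= 0")
        if sum(self.fm.values()) > 1.0 + 1e-9:
            raise ValidationFileError(
                f"fm fractions sum to {sum(self.fm.values()):.3f} > 1"
            )
        split_sum = sum(self.secretion_split.values())
        if self.secretion_split and abs(split_sum - 1.0) > 1e-6:
            raise ValidationFileError("secretion_split fractions must sum to 1")
        for t in self.secretion_split:
            if t not in ("PGP_RENAL", "OAT3"):
                raise ValidationFileError(f"unknown secretion transporter {t!r}")
        return self


class MetaboliteLink(BaseModel):
    child: str
    formation_fraction: float = Field(gt=0, le=1)
    #: which elimination pathway's flux forms the child
    pathway: str

    @model_validator(mode="after")
    def _check(self) -> "MetaboliteLink":
        if self.pathway not in PATHWAYS:
            raise ValidationFileError(f"metabolite pathway {self.pathway!r} unknown")
        return self


class CompoundModel(BaseModel):
    name: str
    molecular_weight: float = Field(gt=0)
    fu_plasma: float = Field(gt=0, le=1)
    blood_to_plasma: float = Field(default=1.0, gt=0)
    absorption: AbsorptionParams | None = None
    pgp_gut: PgpGutParams | None = None
    bioavailability_rule: BioavailabilityRule | None = None
    distribution: DistributionParams
    clearance: ClearanceParams
    metabolite_links: list[MetaboliteLink] = Field(default_factory=list)

    def conc_mg_L_to_uM(self, conc_mg_L: float) -> float:
        return conc_mg_L * 1000.0 / self.molecular_weight

    def fraction_released(self, dose_mg: float) -> float:
        if self.bioavailability_rule is not None:
            return self.bioavailability_rule.fraction_released(dose_mg)
        if self.absorption is not None:
            return self.absorption.fraction_released
        return 1.0


class InteractionParameters(BaseModel):
    """Competitive-inhibition constants of one perpetrator, per target."""

    perpetrator: str
    ki_uM: dict[str, float]
    mechanism: Literal["competitive"] = "competitive"

    @model_validator(mode="after")
    def _check(self) -> "InteractionParameters":
        for target, ki in self.ki_uM.items():
            if target not in INHIBITION_TARGETS:
                raise ValidationFileError(f"unknown inhibition target {target!r}")
            if ki <= 0:
                raise ValidationFileError(f"Ki for {target} must be > 0")
        return self


# ---------------------------------------------------------------------------
# file IO

def _strip_annotations(obj):
    """Drop ``_comment``/``source`` annotation keys so files can self-document."""
    if isinstance(obj, dict):
        return {
            k: _strip_annotations(v)
            for k, v in obj.items()
            if not k.startswith("_") and k != "source"
        }
    if isinstance(obj, list):
        return [_strip_annotations(v) for v in obj]
    return obj


def load_compound(path: str | Path) -> CompoundModel:
    """Load and validate one compound parameter file (JSON)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        raw = json.load(fh)
    try:
        return CompoundModel.model_validate(_strip_annotations(raw))
    except ValidationFileError:
        raise
    except Exception as exc:  # pydantic ValidationError names the field
        raise ValidationFileError(f"{path.name}: {exc}") from exc


def save_compound(model: CompoundModel, path: str | Path) -> None:
    Path(path).write_text(model.model_dump_json(indent=2))


def load_bundled_compound(name: str) -> CompoundModel:
    """Load a compound shipped with the package by short name."""
    ref = resources.files("pbpkddi.data.compounds").joinpath(f"{name}.json")
    with resources.as_file(ref) as path:
        return load_compound(path)


def load_bundled_chain(name: str) -> list[CompoundModel]:
    """Load a victim with its metabolite chain, parent first.

    Children are resolved from bundled files by name; the dabigatran
    glucuronide is derived from the dabigatran model (its disposition is
    assumed equal to the parent's) rather than shipped as its own file.
    """
    models: list[CompoundModel] = [load_bundled_compound(name)]
    queue = list(models[0].metabolite_links)
    seen = {models[0].name}
    while queue:
        link = queue.pop(0)
        if link.child in seen:
            continue
        if link.child == "dabigatran_glucuronide":
            parent = next(m for m in models if any(
                ln.child == link.child for ln in m.metabolite_links
            ))
            child = derive_dabg_model(parent)
        else:
            child = load_bundled_compound(link.child)
        models.append(child)
        seen.add(child.name)
        queue.extend(child.metabolite_links)
    return models


def load_interactions(path: str | Path | None = None) -> dict[str, InteractionParameters]:
    """Load the Ki table keyed by perpetrator; defaults to the bundled file."""
    if path is None:
        ref = resources.files("pbpkddi.data").joinpath("interactions.json")
        with resources.as_file(ref) as p:
            raw = json.loads(Path(p).read_text())
    else:
        raw = json.loads(Path(path).read_text())
    raw = _strip_annotations(raw)
    out = {}
    for perp, ki in raw.items():
        out[perp] = InteractionParameters(perpetrator=perp, ki_uM=ki)
    return out


# ---------------------------------------------------------------------------
# derived quantities

def retrograde_clint(total_clint: float, fm: dict[str, float]) -> dict[str, float]:
    """Split a total intrinsic clearance into per-pathway values by fm.

    The remainder (1 - sum fm) is assigned to the ``OTHER`` pathway.
    """
    if total_clint < 0:
        raise ValueError("total_clint must be >= 0")
    s = sum(fm.values())
    if any(f < 0 for f in fm.values()):
        raise ValueError("fm fractions must be >= 0")
    if s > 1.0 + 1e-12:
        raise ValueError(f"fm fractions sum to {s} > 1")
    out = {pw: f * total_clint for pw, f in fm.items()}
    out["OTHER"] = (1.0 - s) * total_clint
    return out


def derive_dabg_model(
    dab: CompoundModel,
    name: str = "dabigatran_glucuronide",
    molecular_weight: float = 647.6,
) -> CompoundModel:
    """Derive the dabigatran-glucuronide model by cloning dabigatran.

    The glucuronide's disposition parameters are assumed equal to the
    parent's; name and molecular weight are overridden, hepatic pathways
    and further metabolite links are removed (the glucuronide is cleared
    renally).
    """
    child = dab.model_copy(deep=True)
    child.name = name
    child.molecular_weight = molecular_weight
    child.metabolite_links = []
    child.clearance = child.clearance.model_copy(
        update={"clint_L_h": {}, "fm": {}}
    )
    child.absorption = None
    child.pgp_gut = None
    child.bioavailability_rule = None
    return child
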