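"""Compound and study-design file formats.

Files are YAML with a fixed schema and fixed units (no in-file unit
expressions): permeabilities in 1e-6 cm/s (Caco-2) and 1e-4 cm/s (Peff),
rate constants in 1/h, volumes in L/kg, clearances in L/h, per-enzyme
intrinsic clearances in uL/min/pmol, Vmax in pmol/min/pmol, Km and Ki in uM.
Unknown keys are schema errors.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .vocab import ALL_TARGETS, DEFAULT_TISSUE_SCALARS, ENZYMES, TISSUES


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CompoundClass(str, enum.Enum):
    MONOPROTIC_BASE = "monoprotic base"
    MONOPROTIC_ACID = "monoprotic acid"
    DIPROTIC_BASE = "diprotic base"
    DIPROTIC_ACID = "diprotic acid"
    AMPHOLYTE = "ampholyte"
    NEUTRAL = "neutral"


class BindingProtein(str, enum.Enum):
    ALBUMIN = "albumin"
    AAG = "AAG"


class Calibrator(_Strict):
    """Permeability calibrator: measured Caco-2 Papp (1e-6 cm/s) and, when
    known, its reference human jejunal Peff (1e-4 cm/s)."""

    name: str
    papp: float = Field(gt=0)
    peff_ref: Optional[float] = Field(default=None, gt=0)


class EffluxParams(_Strict):
    """Apical efflux of a transporter substrate out of the enterocyte,
    competing with basolateral (villous-blood) uptake."""

    target: str = "P-gp"
    cl_efflux: float = Field(gt=0, description="efflux clearance, L/h")

    @model_validator(mode="after")
    def _known_target(self):
        if self.target not in ALL_TARGETS:
            raise ValueError(f"unknown efflux target {self.target!r}")
        return self


class AbsorptionParams(_Strict):
    model: str = "first_order"
    papp_caco2: Optional[float] = Field(default=None, gt=0)
    calibrators: list[Calibrator] = Field(default_factory=list)
    peff_man: Optional[float] = Field(default=None, gt=0)
    ka: Optional[float] = Field(default=None, gt=0)
    fa: Optional[float] = Field(default=None, gt=0, le=1)
    fu_gut: float = Field(default=1.0, gt=0, le=1)
    qgut: float = Field(gt=0, description="Qgut hybrid flow, L/h")
    efflux: Optional[EffluxParams] = None

    @model_validator(mode="after")
    def _route_to_peff(self):
        if self.model != "first_order":
            raise ValueError("only the first_order absorption model is supported")
        has_papp = self.papp_caco2 is not None and len(self.calibrators) > 0
        has_peff = self.peff_man is not None
        has_kafa = self.ka is not None and self.fa is not None
        if not (has_papp or has_peff or has_kafa):
            raise ValueError(
                "absorption needs (papp_caco2 + calibrators), peff_man, or (ka, fa)"
            )
        return self


class MinimalPBPKParams(_Strict):
    """Minimal-PBPK distribution block: systemic compartment exchanging with
    a single adjusting compartment (SAC).  Influx into the SAC is
    k_in*V_sac*C_plasma and efflux is k_out*A_sac, which makes
    Vss = Vc + V_sac*k_in/k_out (+ liver term) the consistent reading of a
    parameter set carrying Vss, V_sac, k_in and k_out together."""

    vss: float = Field(gt=0, description="L/kg")
    kp_scalar: float = Field(default=1.0, gt=0)
    kp_liver: float = Field(
        default=1.0,
        gt=0,
        description="liver:blood partition (base value; kp_scalar multiplies it)",
    )
    k_in: float = Field(ge=0, description="1/h")
    k_out: float = Field(ge=0, description="1/h")
    v_sac: float = Field(ge=0, description="L/kg")

    @model_validator(mode="after")
    def _sac_consistent(self):
        if self.v_sac > 0 and (self.k_in <= 0 or self.k_out <= 0):
            raise ValueError("k_in and k_out must be > 0 when v_sac > 0")
        if self.v_sac >= self.vss:
            raise ValueError("vss must exceed v_sac")
        return self


class MMParams(_Strict):
    vmax: float = Field(ge=0, description="pmol/min/pmol")
    km: float = Field(gt=0, description="uM (unbound)")


class EliminationParams(_Strict):
    cl_iv: Optional[float] = Field(default=None, gt=0, description="L/h")
    cl_renal: float = Field(default=0.0, ge=0, description="L/h")
    fm_map: dict[str, float] = Field(default_factory=dict)
    linear_clint_map: dict[str, float] = Field(default_factory=dict)
    mm_map: dict[str, MMParams] = Field(default_factory=dict)
    tissue_scalars: dict[str, dict[str, float]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        for m in (self.fm_map, self.linear_clint_map, self.mm_map, self.tissue_scalars):
            for enz in m:
                if enz not in ENZYMES:
                    raise ValueError(f"unknown enzyme {enz!r}")
        bad = [e for e, f in self.fm_map.items() if f < 0]
        if bad:
            raise ValueError(f"negative fm for {bad}")
        total = sum(self.fm_map.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"fm_map sums to {total:.4g} > 1")
        both = set(self.linear_clint_map) & set(self.mm_map)
        if both:
            raise ValueError(f"enzymes in both linear and MM maps: {sorted(both)}")
        if any(v < 0 for v in self.linear_clint_map.values()):
            raise ValueError("linear CLint must be >= 0")
        for enz, scal in self.tissue_scalars.items():
            for tis, v in scal.items():
                if tis not in TISSUES:
                    raise ValueError(f"unknown tissue {tis!r}")
                if v < 0:
                    raise ValueError(f"negative tissue scalar for {enz}/{tis}")
        return self

    def tissue_scalar(self, enzyme: str, tissue: str) -> float:
        """Expression scalar for enzyme x tissue (compound override, else
        the vocabulary default)."""
        override = self.tissue_scalars.get(enzyme)
        if override is not None and tissue in override:
            return override[tissue]
        return DEFAULT_TISSUE_SCALARS[enzyme][tissue]


class InteractionParams(_Strict):
    ki_map: dict[str, float] = Field(default_factory=dict)
    fu_mic_map: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        for tgt, ki in self.ki_map.items():
            if tgt not in ALL_TARGETS:
                raise ValueError(f"unknown interaction target {tgt!r}")
            if ki <= 0:
                raise ValueError(f"Ki must be > 0 for {tgt}")
        for tgt, fu in self.fu_mic_map.items():
            if tgt not in self.ki_map:
                raise ValueError(f"fu_mic for {tgt!r} without a Ki")
            if not (0 < fu <= 1):
                raise ValueError(f"fu_mic must be in (0, 1] for {tgt}")
        return self

    def ki_u(self, target: str) -> float:
        """Unbound inhibition constant Ki*fu_mic (uM); derived, never stored."""
        return self.ki_map[target] * self.fu_mic_map.get(target, 1.0)


class InductionParams(_Strict):
    target: str
    ind_max: float = Field(ge=0, description="maximal fold-induction minus 1")
    ind_c50: float = Field(gt=0, description="uM unbound")
    hill: float = Field(default=1.0, gt=0)
    group: str = Field(
        default="default",
        description="induction block name; study designs may enable extra blocks",
    )

    @model_validator(mode="after")
    def _known_target(self):
        if self.target not in ENZYMES:
            raise ValueError(f"unknown induction target {self.target!r}")
        return self


class CompoundModel(_Strict):
    name: str
    mw: float = Field(gt=0, description="g/mol")
    logp: float
    compound_class: CompoundClass
    pka: Optional[float] = None
    bp_ratio: float = Field(gt=0)
    fu_plasma: float = Field(gt=0, le=1)
    binding_protein: BindingProtein = BindingProtein.ALBUMIN
    absorption: AbsorptionParams
    distribution: MinimalPBPKParams
    elimination: EliminationParams
    interaction: Optional[InteractionParams] = None
    induction: list[InductionParams] = Field(default_factory=list)
    provenance: Optional[str] = Field(
        default=None, description="free-text parameter sourcing notes"
    )

    @property
    def fu_blood(self) -> float:
        return self.fu_plasma / self.bp_ratio

    def has_interactions(self) -> bool:
        return bool(
            (self.interaction and self.interaction.ki_map) or self.induction
        )


class Regimen(_Strict):
    interval_h: float = Field(gt=0)
    n_doses: int = Field(ge=1)


class Route(str, enum.Enum):
    ORAL = "oral"
    IV = "iv"


class VictimArm(_Strict):
    compound: str
    dose_mg: float = Field(ge=0)  # 0 allowed at engine level; flagged by validate_study
    route: Route = Route.ORAL
    regimen: Regimen = Regimen(interval_h=24.0, n_doses=1)
    sampling_duration_h: float = Field(default=72.0, gt=0)


class PerpetratorArm(_Strict):
    compound: str
    dose_mg: float = Field(gt=0)
    route: Route = Route.ORAL
    regimen: Regimen
    lead_in_days: float = Field(ge=0)
    victim_dose_day: float = Field(ge=0, description="day of victim dose, day 0 = first perpetrator dose")
    induction_groups: list[str] = Field(default_factory=lambda: ["default"])


class PopulationSpec(_Strict):
    n: int = Field(ge=1)
    age_range: tuple[float, float] = (20.0, 50.0)
    prop_female: float = Field(default=0.5, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _ages(self):
        lo, hi = self.age_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid age range {self.age_range}")
        return self


class StudyDesign(_Strict):
    name: str = "study"
    victim: VictimArm
    perpetrator: Optional[PerpetratorArm] = None
    population: PopulationSpec
    outputs: list[str] = Field(default_factory=lambda: ["cmax", "auc_0_inf", "gmr"])


# --------------------------------------------------------------------------
# file I/O


class SchemaError(ValueError):
    """A compound/study file violated the published schema."""


def _load_yaml(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    with open(p) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{p}: top level must be a mapping")
    return data


def load_compound(path: str | Path) -> CompoundModel:
    """Read and validate a compound file; all invariants enforced."""
    try:
        return CompoundModel.model_validate(_load_yaml(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # pydantic errors carry the offending field path
        raise SchemaError(f"{path}: {exc}") from exc


def compound_from_dict(data: dict) -> CompoundModel:
    return CompoundModel.model_validate(data)


def save_compound(model: CompoundModel, path: str | Path) -> None:
    """Write a compound file that round-trips losslessly through YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            model.model_dump(mode="json", exclude_none=True, exclude_defaults=False),
            fh,
            sort_keys=False,
        )


def load_study(path: str | Path) -> StudyDesign:
    try:
        return StudyDesign.model_validate(_load_yaml(path))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def validate_study(
    design: StudyDesign, compounds: Mapping[str, CompoundModel]
) -> list[str]:
    """Report-based consistency check; the study is runnable iff the report
    is empty."""
    report: list[str] = []
    if design.victim.compound not in compounds:
        report.append(f"victim compound {design.victim.compound!r} not available")
    if design.victim.dose_mg <= 0:
        report.append("victim dose must be > 0")
    perp = design.perpetrator
    if perp is not None:
        if perp.compound not in compounds:
            report.append(f"perpetrator compound {perp.compound!r} not available")
        span_h = perp.regimen.interval_h * perp.regimen.n_doses
        if perp.victim_dose_day * 24.0 > span_h:
            report.append(
                "victim dose day falls after the perpetrator regimen ends "
                f"({perp.victim_dose_day} d vs {span_h / 24:.1f} d span)"
            )
        if perp.victim_dose_day < perp.lead_in_days:
            report.append(
                "victim dose day precedes the stated perpetrator lead-in"
            )
        pc = compounds.get(perp.compound)
        if pc is not None:
            for grp in perp.induction_groups:
                if grp != "default" and all(b.group != grp for b in pc.induction):
                    report.append(
                        f"induction group {grp!r} not defined by {perp.compound}"
                    )
    return report
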