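"""Virtual healthy-volunteer populations: physiology, enzymology and
reproducible between-subject variability.

The default system file describes a generic North-European-style healthy
adult population (organ flows, liver weight, microsomal scaling, enzyme
abundances, turnover).  Values are editable defaults with provenance notes
recorded in the file itself; liver abundances of the three soticlestat-
clearing isoforms are calibrated so that the forward well-stirred clearance
computed from the per-isoform intrinsic clearances reproduces the observed
systemic clearance (see docs/methods.md).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .compound_io import PopulationSpec, StudyDesign
from .vocab import ENZYMES


class TissueAbundance(BaseModel):
    model_config = ConfigDict(extra="forbid")
    liver: float = Field(ge=0, description="pmol/mg microsomal protein")
    gut: float = Field(ge=0, description="pmol total small intestine")
    kidney: float = Field(ge=0, description="pmol/mg kidney microsomal protein")


class SystemParameters(BaseModel):
    """One (virtual) subject's physiology and enzymology."""

    model_config = ConfigDict(extra="forbid")

    body_weight: float = Field(default=70.0, gt=0, description="kg")
    liver_weight: float = Field(gt=0, description="g")
    mppgl: float = Field(gt=0, description="mg microsomal protein / g liver")
    kidney_weight: float = Field(gt=0, description="g")
    mppgk: float = Field(gt=0, description="mg microsomal protein / g kidney")
    q_hepatic: float = Field(gt=0, description="total liver blood flow, L/h")
    q_villous: float = Field(gt=0, description="villous mucosal blood flow, L/h")
    q_kidney: float = Field(gt=0, description="renal blood flow, L/h")
    enterocyte_volume: float = Field(gt=0, description="L")
    small_intestine_radius: float = Field(gt=0, description="cm")
    small_intestine_transit: float = Field(gt=0, description="h")
    gfr: float = Field(gt=0, description="L/h")
    abundance: dict[str, TissueAbundance]
    kdeg: dict[str, float] = Field(
        default_factory=dict, description="enzyme turnover, 1/h"
    )
    peff_reference: dict[str, float] = Field(
        default_factory=dict,
        description="calibrator name -> human jejunal Peff, 1e-4 cm/s",
    )

    @model_validator(mode="after")
    def _complete(self):
        missing = [e for e in ENZYMES if e not in self.abundance]
        if missing:
            raise ValueError(f"abundance missing for enzymes: {missing}")
        unknown = [e for e in self.abundance if e not in ENZYMES]
        if unknown:
            raise ValueError(f"abundance given for unknown enzymes: {unknown}")
        for e, k in self.kdeg.items():
            if e not in ENZYMES:
                raise ValueError(f"kdeg for unknown enzyme {e!r}")
            if k <= 0:
                raise ValueError(f"kdeg must be > 0 ({e})")
        return self

    # convenience totals -------------------------------------------------
    def liver_microsomal_protein(self) -> float:
        """Total hepatic microsomal protein, mg."""
        return self.mppgl * self.liver_weight

    def kidney_microsomal_protein(self) -> float:
        return self.mppgk * self.kidney_weight

    def total_pmol(self, enzyme: str, tissue: str) -> float:
        ab = self.abundance[enzyme]
        if tissue == "liver":
            return ab.liver * self.liver_microsomal_protein()
        if tissue == "intestine":
            return ab.gut
        if tissue == "kidney":
            return ab.kidney * self.kidney_microsomal_protein()
        raise KeyError(tissue)


class Individual(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: int
    sex: str
    age: float
    body_weight: float
    system: SystemParameters


_DATA = importlib.resources.files("pbpkddi") / "data"


def default_system(path: Optional[str | Path] = None) -> SystemParameters:
    """The packaged default system parameter set (population means)."""
    if path is None:
        raw = (_DATA / "system_default.yaml").read_text()
    else:
        raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    data.pop("provenance", None)
    cv = data.pop("cv", None)
    sp = SystemParameters.model_validate(data)
    sp.__dict__["_cv_spec"] = cv or {}
    return sp


def default_cv_spec(path: Optional[str | Path] = None) -> dict[str, float]:
    """Between-subject coefficients of variation shipped in the system file."""
    if path is None:
        raw = (_DATA / "system_default.yaml").read_text()
    else:
        raw = Path(path).read_text()
    return yaml.safe_load(raw).get("cv", {})


# --------------------------------------------------------------------------
# sampling

#: allometric exponents: flows scale with BW^0.75, organ sizes with BW^1
_FLOW_KEYS = ("q_hepatic", "q_villous", "q_kidney", "gfr")
_SIZE_KEYS = ("liver_weight", "kidney_weight", "enterocyte_volume")

#: reference weight geometric means by sex (kg)
_WEIGHT_GM = {"F": 66.0, "M": 78.0}


def _lognormal(rng: np.random.Generator, gm: float, cv: float) -> float:
    """Draw with the nominal value preserved as the geometric mean."""
    if cv <= 0:
        return gm
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return float(gm * np.exp(sigma * rng.standard_normal()))


def sample_population(
    design: StudyDesign | PopulationSpec,
    defaults: SystemParameters,
    cv_spec: Optional[dict[str, float]] = None,
    seed: Optional[int] = None,
) -> list[Individual]:
    """Draw a reproducible virtual population.

    ``cv_spec`` maps parameter names (``liver_weight``, ``q_hepatic``,
    ``mppgl``, ``body_weight``, ``abundance`` for all isoform abundances, or
    per-enzyme keys like ``abundance:CYP3A4``) to lognormal coefficients of
    variation.  With every CV at zero each subject equals the defaults scaled
    only by its demographic weight draw (which is itself frozen when
    ``body_weight`` has CV 0).
    """
    pop = design.population if isinstance(design, StudyDesign) else design
    if cv_spec is None:
        cv_spec = getattr(defaults, "_cv_spec", None) or default_cv_spec()
    if any(v < 0 for v in cv_spec.values()):
        raise ValueError("CVs must be >= 0")
    if seed is None:
        seed = pop.seed
    rng = np.random.default_rng(seed)

    n = pop.n
    n_female = int(round(pop.prop_female * n))
    sexes = ["F"] * n_female + ["M"] * (n - n_female)

    lo, hi = pop.age_range
    individuals: list[Individual] = []
    bw_ref = defaults.body_weight
    for i in range(n):
        sex = sexes[i]
        age = float(rng.uniform(lo, hi))
        bw = _lognormal(rng, _WEIGHT_GM[sex], cv_spec.get("body_weight", 0.0))
        size_f = bw / bw_ref
        flow_f = (bw / bw_ref) ** 0.75

        sys_d = defaults.model_dump()
        sys_d["body_weight"] = bw
        for key in _SIZE_KEYS:
            sys_d[key] = _lognormal(rng, sys_d[key] * size_f, cv_spec.get(key, 0.0))
        for key in _FLOW_KEYS:
            sys_d[key] = _lognormal(rng, sys_d[key] * flow_f, cv_spec.get(key, 0.0))
        for key in ("mppgl", "mppgk"):
            sys_d[key] = _lognormal(rng, sys_d[key], cv_spec.get(key, 0.0))
        for enz, ab in sys_d["abundance"].items():
            cv = cv_spec.get(f"abundance:{enz}", cv_spec.get("abundance", 0.0))
            shared = rng.standard_normal()  # correlated across tissues
            if cv > 0:
                sigma = np.sqrt(np.log(1.0 + cv * cv))
                mult = float(np.exp(sigma * shared))
            else:
                mult = 1.0
            for tis in ("liver", "gut", "kidney"):
                ab[tis] = ab[tis] * mult
        individuals.append(
            Individual(
                id=i,
                sex=sex,
                age=age,
                body_weight=bw,
                system=SystemParameters.model_validate(sys_d),
            )
        )
    return individuals
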