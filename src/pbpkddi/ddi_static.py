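"""Closed-form DDI screens and the Ki,u sensitivity scan.

The mechanistic static model combines per-enzyme net interaction factors
(inhibition x induction) with the victim's fractional metabolism and gut
availability:

    AUCR = (FG'/FG)^-1_gut-applied * 1 / (sum_e fm_e*f_e + (1 - sum_e fm_e))

evaluated at fixed, documented perpetrator concentrations (unbound average
steady-state hepatic inlet for the liver; dose/250 mL for the gut — the
standard conservative regulatory convention).  It is a fast screen and an
upper bound on the dynamic engine's AUC GMR for sustained inhibitor
exposure at its maximum concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .absorption_clearance import (
    derive_absorption,
    fg_qgut,
    gut_clu_int,
    per_enzyme_linear_clint,
    retrograde_clint,
)
from .compound_io import CompoundModel, StudyDesign
from .pbpk_engine import EngineOptions
from .population import SystemParameters, default_system


@dataclass
class StaticDDIResult:
    target: str
    r_basic: float
    aucr_static: float
    inputs: dict = field(default_factory=dict)


def _victim_disposition(victim: CompoundModel, system: SystemParameters):
    elim = victim.elimination
    per_enzyme = per_enzyme_linear_clint(victim)
    if not per_enzyme:
        derived = retrograde_clint(
            elim.cl_iv, elim.cl_renal, victim.fu_blood, elim.fm_map, system,
            compound=victim, bp_ratio=victim.bp_ratio,
        )
        per_enzyme = derived.per_enzyme_clu_int
    clu_gut = gut_clu_int(victim, system, per_enzyme)
    fg = fg_qgut(victim.absorption.qgut, victim.absorption.fu_gut, clu_gut)
    return per_enzyme, fg


def r_basic(i_u: float, ki_u: float) -> float:
    """Basic regulatory R-value 1 + I_u/Ki_u."""
    if i_u < 0 or ki_u <= 0:
        raise ValueError("concentrations >= 0 and ki_u > 0 required")
    return 1.0 + i_u / ki_u


def static_perpetrator_concentrations(
    perp: CompoundModel,
    dose_mg: float,
    interval_h: float,
    system: Optional[SystemParameters] = None,
) -> tuple[float, float]:
    """(unbound hepatic-inlet average Css, gut concentration), both uM.

    Hepatic: fu_p * (Cavg_ss + fa*ka*Dose/Q_H) with Cavg_ss = F*D/(CL*tau);
    gut: Dose / 250 mL.
    """
    system = system if system is not None else default_system()
    elim = perp.elimination
    _, ka, fa = derive_absorption(perp, system)
    derived = retrograde_clint(
        elim.cl_iv, elim.cl_renal, perp.fu_blood,
        elim.fm_map, system, compound=perp, bp_ratio=perp.bp_ratio,
    )
    f_oral = fa * derived.fg * derived.fh
    cavg = f_oral * dose_mg / (elim.cl_iv * interval_h)  # mg/L plasma
    inlet = cavg + fa * ka * dose_mg / system.q_hepatic / perp.bp_ratio
    i_liver_u = perp.fu_plasma * inlet * 1000.0 / perp.mw
    i_gut = dose_mg / 0.25 / perp.mw * 1000.0
    return i_liver_u, i_gut


def mechanistic_static_aucr(
    victim: CompoundModel,
    liver_factors: Mapping[str, float],
    gut_factors: Optional[Mapping[str, float]] = None,
    system: Optional[SystemParameters] = None,
) -> StaticDDIResult:
    """Static AUC ratio for a victim given net per-enzyme interaction
    factors (1 = no interaction, <1 inhibition of activity is expressed as a
    factor on CLu_int, i.e. factor 0.5 halves that isoform's clearance).

    Reduces to 1 when every factor is 1.
    """
    system = system if system is not None else default_system()
    for f in list(liver_factors.values()) + list((gut_factors or {}).values()):
        if f < 0:
            raise ValueError("interaction factors must be >= 0")
    per_enzyme, fg = _victim_disposition(victim, system)
    clu_gut_ddi = gut_clu_int(victim, system, per_enzyme, gut_factors or {})
    fg_ddi = fg_qgut(victim.absorption.qgut, victim.absorption.fu_gut, clu_gut_ddi)
    fm = victim.elimination.fm_map
    fm_sum = sum(fm.values())
    hep = sum(f_e * liver_factors.get(e, 1.0) for e, f_e in fm.items()) + (
        1.0 - fm_sum
    )
    aucr = (fg_ddi / fg) / hep
    return StaticDDIResult(
        target=",".join(sorted(set(liver_factors) | set(gut_factors or {}))),
        r_basic=max(
            (1.0 / f for f in liver_factors.values() if f > 0), default=1.0
        ),
        aucr_static=aucr,
        inputs={
            "fg": fg,
            "fg_ddi": fg_ddi,
            "hepatic_term": hep,
            "liver_factors": dict(liver_factors),
            "gut_factors": dict(gut_factors or {}),
        },
    )


def ki_sensitivity_scan(
    design: StudyDesign,
    compounds: Mapping[str, CompoundModel],
    targets: Sequence[str],
    fold_reductions: Sequence[float],
    system: Optional[SystemParameters] = None,
    seed: Optional[int] = None,
    options: Optional[EngineOptions] = None,
) -> list[dict]:
    """Repeat a dynamic DDI study with the perpetrator's Ki,u for the named
    targets divided by each fold-reduction.  Fold 1 is the baseline row and
    is identical to the unscaled study."""
    from .trial_stats import run_ddi_study

    if any(f <= 0 for f in fold_reductions):
        raise ValueError("fold reductions must be > 0")
    if design.perpetrator is None:
        raise ValueError("sensitivity scan needs a perpetrator arm")
    rows: list[dict] = []
    for fold in fold_reductions:
        comps = dict(compounds)
        perp = comps[design.perpetrator.compound].model_copy(deep=True)
        if perp.interaction is not None and fold != 1.0:
            for tgt in targets:
                if tgt in perp.interaction.ki_map:
                    perp.interaction.ki_map[tgt] /= fold
        comps[design.perpetrator.compound] = perp
        res = run_ddi_study(design, comps, system, seed, options)
        rows.append(
            {
                "fold_reduction": fold,
                "auc_gmr": res.gmr_auc.point if res.gmr_auc else None,
                "cmax_gmr": res.gmr_cmax.point if res.gmr_cmax else None,
            }
        )
    return rows
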