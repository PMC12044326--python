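"""Closed-form parameter derivations.

Implements the permeability calibration (Caco-2 -> human jejunal Peff),
first-order absorption predictions (ka, fa), the well-stirred organ
clearance model, Michaelis-Menten intrinsic clearance, the Qgut intestinal
first-pass availability, and the iterative retrograde derivation of
per-isoform unbound intrinsic clearances from an observed in-vivo clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .compound_io import AbsorptionParams, Calibrator, CompoundModel
from .population import SystemParameters
from .vocab import OTHER_PATHWAY, scale_clint


# --------------------------------------------------------------------------
# permeability / absorption


def predict_peff(
    papp: float,
    calibrators: Sequence[Calibrator | tuple],
    reference_map: Optional[Mapping[str, float]] = None,
) -> float:
    """Human jejunal Peff (1e-4 cm/s) from a Caco-2 Papp (1e-6 cm/s).

    Log-log linear regression of reference-scale Peff on measured Papp over
    the calibrator set (low- and high-permeability anchors).  Calibrators may
    carry their reference Peff directly or have it resolved from
    ``reference_map`` (the system file's ``peff_reference`` block).
    """
    if papp <= 0:
        raise ValueError("papp must be > 0")
    pts: list[tuple[float, float]] = []
    for cal in calibrators:
        if isinstance(cal, tuple):
            cal = Calibrator(name=cal[0], papp=cal[1], peff_ref=cal[2])
        ref = cal.peff_ref
        if ref is None and reference_map is not None:
            ref = reference_map.get(cal.name)
        if ref is not None:
            pts.append((cal.papp, ref))
    if not pts:
        raise ValueError(
            "no calibrator carries a reference Peff; supply peff_man explicitly"
        )
    lx = np.log10([p for p, _ in pts])
    ly = np.log10([r for _, r in pts])
    if len(pts) == 1:
        # single anchor: unit log-log slope through the anchor
        slope, intercept = 1.0, ly[0] - lx[0]
    else:
        slope, intercept = np.polyfit(lx, ly, 1)
    return float(10.0 ** (slope * np.log10(papp) + intercept))


def predict_ka_fa(peff: float, geometry: SystemParameters) -> tuple[float, float]:
    """First-order absorption rate constant ka (1/h) and fraction absorbed fa
    from jejunal Peff (1e-4 cm/s) and small-intestine geometry.

    ka = 2*Peff/R (cylindrical surface-to-volume); fa from the 7-compartment
    small-intestine transit closed form fa = 1 - (1 + ka*Tsi/7)^-7.
    """
    if peff <= 0:
        raise ValueError("peff must be > 0")
    peff_cm_s = peff * 1.0e-4
    ka = 2.0 * peff_cm_s / geometry.small_intestine_radius * 3600.0  # 1/h
    tsi = geometry.small_intestine_transit
    fa = 1.0 - (1.0 + ka * tsi / 7.0) ** -7
    return float(ka), float(fa)


def derive_absorption(
    compound: CompoundModel, system: SystemParameters
) -> tuple[float, float, float]:
    """(peff, ka, fa) for a compound: predicted from Caco-2 data when
    available, with explicit file values taking precedence as overrides."""
    absn: AbsorptionParams = compound.absorption
    peff = absn.peff_man
    if peff is None and absn.papp_caco2 is not None and absn.calibrators:
        peff = predict_peff(
            absn.papp_caco2, absn.calibrators, system.peff_reference
        )
    if peff is not None:
        ka_pred, fa_pred = predict_ka_fa(peff, system)
    else:
        ka_pred = fa_pred = None  # type: ignore[assignment]
    ka = absn.ka if absn.ka is not None else ka_pred
    fa = absn.fa if absn.fa is not None else fa_pred
    if ka is None or fa is None:
        raise ValueError(
            f"{compound.name}: cannot derive ka/fa (no permeability route and "
            "no explicit override)"
        )
    return (peff if peff is not None else float("nan")), float(ka), float(fa)


# --------------------------------------------------------------------------
# clearance primitives


def well_stirred_cl(clu_int: float, fu_blood: float, q_organ: float) -> float:
    """Well-stirred organ blood clearance: Q*fu_b*CLu_int/(Q + fu_b*CLu_int)."""
    if clu_int < 0 or fu_blood < 0 or q_organ < 0:
        raise ValueError("well_stirred_cl inputs must be >= 0")
    x = fu_blood * clu_int
    if q_organ == 0:
        return 0.0
    return q_organ * x / (q_organ + x)


def mm_clint(vmax: float, km: float, cu: float) -> float:
    """Michaelis-Menten intrinsic clearance Vmax/(Km + Cu), uL/min/pmol for
    Vmax in pmol/min/pmol and Km, Cu in uM."""
    if km <= 0:
        raise ValueError("km must be > 0")
    if cu < 0:
        raise ValueError("cu must be >= 0")
    return vmax / (km + cu)


def fg_qgut(qgut: float, fu_gut: float, clu_int_gut: float) -> float:
    """Intestinal first-pass availability FG = Qgut/(Qgut + fu_gut*CLu_int,gut)."""
    if qgut <= 0:
        raise ValueError("qgut must be > 0")
    if fu_gut < 0 or clu_int_gut < 0:
        raise ValueError("fu_gut and clu_int_gut must be >= 0")
    return qgut / (qgut + fu_gut * clu_int_gut)


# --------------------------------------------------------------------------
# retrograde derivation


@dataclass
class DerivedClearances:
    """Outcome of the retrograde derivation for one compound."""

    fu_blood: float
    cl_hepatic: float  # blood clearance, L/h
    cl_renal_metabolic: float  # blood clearance, L/h
    clu_int_hepatic: float  # whole-liver unbound intrinsic clearance, L/h
    clu_int_renal: float  # whole-kidney unbound intrinsic clearance, L/h
    per_enzyme_clu_int: dict[str, float] = field(default_factory=dict)  # uL/min/pmol
    other_clu_int_hepatic: float = 0.0  # L/h, uninhibitable remainder
    fg: float = 1.0
    fh: float = 1.0


def _liver_pool_pmol(compound: CompoundModel, system: SystemParameters, enz: str) -> float:
    scal = compound.elimination.tissue_scalar(enz, "liver")
    return system.total_pmol(enz, "liver") * scal


def _kidney_pool_pmol(compound: CompoundModel, system: SystemParameters, enz: str) -> float:
    scal = compound.elimination.tissue_scalar(enz, "kidney")
    return system.total_pmol(enz, "kidney") * scal


def gut_clu_int(
    compound: CompoundModel,
    system: SystemParameters,
    per_enzyme: Mapping[str, float],
    factors: Optional[Mapping[str, float]] = None,
) -> float:
    """Whole-gut unbound intrinsic clearance (L/h) from per-pmol values and
    intestinal abundances; linear (Vmax/Km) for saturable isoforms.  An
    optional ``factors`` map multiplies each isoform's activity (net
    inhibition x induction)."""
    total = 0.0
    for enz, u in per_enzyme.items():
        scal = compound.elimination.tissue_scalar(enz, "intestine")
        if scal <= 0:
            continue
        f = 1.0 if factors is None else factors.get(enz, 1.0)
        total += scale_clint(u, system.total_pmol(enz, "intestine") * scal) * f
    return total


def per_enzyme_linear_clint(compound: CompoundModel) -> dict[str, float]:
    """Low-concentration per-pmol intrinsic clearances (uL/min/pmol) for every
    isoform parameterized directly in the compound file (CLint entries plus
    Vmax/Km for saturable ones)."""
    out = dict(compound.elimination.linear_clint_map)
    for enz, mm in compound.elimination.mm_map.items():
        out[enz] = mm_clint(mm.vmax, mm.km, 0.0)
    return out


def retrograde_clint(
    cl_iv: float,
    cl_renal: float,
    fu_blood: float,
    fm_map: Mapping[str, float],
    system: SystemParameters,
    compound: Optional[CompoundModel] = None,
    bp_ratio: float = 1.0,
) -> DerivedClearances:
    """Invert the well-stirred model: from the observed systemic plasma
    clearance (net of excretory renal clearance) recover the whole-organ and
    per-isoform unbound intrinsic clearances.

    The hepatic pool is split across isoforms in proportion to ``fm_map``;
    isoforms with kidney expression contribute a renal metabolic clearance
    alongside the hepatic one, coupled through the same per-pmol value.  The
    remainder ``1 - sum(fm)`` is carried as an uninhibitable hepatic pathway.
    """
    if cl_iv <= cl_renal:
        raise ValueError("cl_iv must exceed cl_renal")
    cl_met_blood = (cl_iv - cl_renal) / bp_ratio
    if cl_met_blood >= system.q_hepatic + system.q_kidney:
        raise ValueError(
            "metabolic blood clearance exceeds available organ blood flow; "
            "the well-stirred model cannot represent this compound"
        )
    fm_sum = sum(fm_map.values())
    other = max(0.0, 1.0 - fm_sum)

    # per-pmol values parameterized as u_e = theta*fm_e / (liver pool * k),
    # i.e. the hepatic CLu_int splits exactly as fm_map.
    pools_l: dict[str, float] = {}
    kidney_ratio = 0.0  # CLu_int,K per unit theta
    for enz, fm in fm_map.items():
        if fm == 0:
            continue
        pool_l = (
            _liver_pool_pmol(compound, system, enz)
            if compound is not None
            else system.total_pmol(enz, "liver")
        )
        if pool_l <= 0:
            raise ValueError(f"{enz}: fm > 0 but no hepatic expression")
        pools_l[enz] = pool_l
        pool_k = (
            _kidney_pool_pmol(compound, system, enz)
            if compound is not None
            else system.total_pmol(enz, "kidney")
        )
        kidney_ratio += fm * pool_k / pool_l

    def forward(theta: float) -> float:
        cl_h = well_stirred_cl(theta * (fm_sum + other), fu_blood, system.q_hepatic)
        cl_k = well_stirred_cl(theta * kidney_ratio, fu_blood, system.q_kidney)
        return cl_h + cl_k

    hi = 1.0
    while forward(hi) < cl_met_blood:
        hi *= 2.0
        if hi > 1e16:
            raise ValueError("retrograde model failed to bracket the target")
    theta = brentq(lambda t: forward(t) - cl_met_blood, 0.0, hi, xtol=1e-14, rtol=1e-15)

    per_enzyme = {
        enz: theta * fm / (pools_l[enz] * (60.0 / 1.0e6))
        for enz, fm in fm_map.items()
        if fm > 0
    }
    clu_h = theta * (fm_sum + other)
    clu_k = theta * kidney_ratio
    cl_h = well_stirred_cl(clu_h, fu_blood, system.q_hepatic)
    cl_k = well_stirred_cl(clu_k, fu_blood, system.q_kidney)
    fh = 1.0 - cl_h / system.q_hepatic

    fg = 1.0
    if compound is not None:
        clu_gut = gut_clu_int(compound, system, per_enzyme)
        fg = fg_qgut(compound.absorption.qgut, compound.absorption.fu_gut, clu_gut)

    return DerivedClearances(
        fu_blood=fu_blood,
        cl_hepatic=cl_h,
        cl_renal_metabolic=cl_k,
        clu_int_hepatic=clu_h,
        clu_int_renal=clu_k,
        per_enzyme_clu_int=per_enzyme,
        other_clu_int_hepatic=theta * other,
        fg=fg,
        fh=fh,
    )
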