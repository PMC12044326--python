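"""Non-compartmental analysis and DDI trial statistics.

NCA uses the linear-up/log-down trapezoid, automatic terminal-phase
selection (best adjusted R^2 over the last 3..8 points, excluding Cmax) and
log-linear extrapolation to infinity.  DDI contrasts are within-subject:
the same virtual individuals are simulated with and without the
perpetrator, and the geometric mean ratio of an exposure metric is reported
with a t-based 90% confidence interval on the paired log ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .compound_io import CompoundModel, StudyDesign
from .pbpk_engine import ConcProfile, EngineOptions, simulate
from .population import (
    Individual,
    SystemParameters,
    default_cv_spec,
    default_system,
    sample_population,
)


@dataclass
class PKMetrics:
    subject_id: int
    cmax: float  # ng/mL
    tmax: float  # h
    auc_0_t: float  # h*ng/mL
    auc_0_inf: Optional[float] = None  # h*ng/mL
    lambda_z: Optional[float] = None  # 1/h
    extrap_pct: Optional[float] = None  # % of AUC0-inf
    flags: list[str] = field(default_factory=list)


class NCAError(ValueError):
    pass


def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c1 > 0 and c0 > 0:
            auc += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            auc += dt * (c0 + c1) / 2.0
    return auc


def _lambda_z(t: np.ndarray, c: np.ndarray, i_cmax: int) -> tuple[Optional[float], float]:
    """Terminal slope by best adjusted-R^2 regression over the last 3..8
    positive points after Cmax.  Returns (lambda_z, adj_r2)."""
    pos = (c > 0) & (np.arange(len(c)) > i_cmax)
    ti, ci = t[pos], np.log(c[pos])
    best: tuple[Optional[float], float] = (None, -np.inf)
    for k in range(3, min(8, len(ti)) + 1):
        x, y = ti[-k:], ci[-k:]
        n = len(x)
        slope, intercept, r, _, _ = sps.linregress(x, y)
        if slope >= 0:
            continue
        adj = 1.0 - (1.0 - r * r) * (n - 1) / (n - 2)
        if adj > best[1]:
            best = (-slope, adj)
    return best


def nca(profile: ConcProfile, subject_id: int = 0) -> PKMetrics:
    """Non-compartmental metrics for one profile (time re-zeroed at dose)."""
    t = np.asarray(profile.time, dtype=float)
    c = np.asarray(profile.plasma, dtype=float)
    if len(t) < 4:
        raise NCAError("need at least 4 samples")
    if np.any(np.diff(t) <= 0):
        raise NCAError("time grid must be strictly increasing")
    if not np.any(c > 0):
        m = PKMetrics(subject_id, 0.0, 0.0, 0.0)
        m.flags.append("all-zero profile")
        return m
    # numerical quantification floor: trailing samples below 1e-6 x Cmax are
    # integrator noise, not signal; drop them as below-quantification
    lloq = float(np.max(c)) * 1e-6
    keep = len(c)
    while keep > 1 and c[keep - 1] < lloq:
        keep -= 1
    t, c = t[:keep], c[:keep]
    i_cmax = int(np.argmax(c))
    cmax = float(c[i_cmax])
    tmax = float(t[i_cmax])
    auc_t = _auc_lin_up_log_down(t, c)
    m = PKMetrics(subject_id, cmax, tmax, auc_t)
    n_term = int(np.sum((c > 0) & (np.arange(len(c)) > i_cmax)))
    if n_term < 3:
        m.flags.append("too few terminal points for lambda_z")
        return m
    lz, _ = _lambda_z(t, c, i_cmax)
    if lz is None:
        m.flags.append("non-monotone terminal phase; AUC0-inf not estimable")
        return m
    c_last = float(c[c > 0][-1])
    auc_inf = auc_t + c_last / lz
    m.lambda_z = lz
    m.auc_0_inf = auc_inf
    m.extrap_pct = 100.0 * (c_last / lz) / auc_inf
    return m


# --------------------------------------------------------------------------


@dataclass
class GMRResult:
    point: float
    ci_lower: float
    ci_upper: float
    n: int
    alpha: float = 0.10


def gmr(
    test: Sequence[float], ref: Sequence[float], alpha: float = 0.10
) -> GMRResult:
    """Geometric mean ratio of paired test/reference values with a
    t-distribution (1-alpha) CI on the per-subject log ratios."""
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape or test.ndim != 1:
        raise ValueError("test and reference must be paired 1-d sequences")
    if np.any(test <= 0) or np.any(ref <= 0):
        raise ValueError("metrics must be positive for a log-scale contrast")
    logr = np.log(test) - np.log(ref)
    n = len(logr)
    mean = float(np.mean(logr))
    sd = float(np.std(logr, ddof=1)) if n > 1 else 0.0
    half = (
        sps.t.ppf(1.0 - alpha / 2.0, n - 1) * sd / math.sqrt(n) if n > 1 else 0.0
    )
    return GMRResult(
        point=math.exp(mean),
        ci_lower=math.exp(mean - half),
        ci_upper=math.exp(mean + half),
        n=n,
        alpha=alpha,
    )


def geometric_mean(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.exp(np.mean(np.log(v))))


@dataclass
class DDIStudyResult:
    design_name: str
    reference: list[PKMetrics]
    test: list[PKMetrics] = field(default_factory=list)
    gmr_cmax: Optional[GMRResult] = None
    gmr_auc: Optional[GMRResult] = None
    summary: dict[str, float] = field(default_factory=dict)

    def table(self) -> dict:
        out = dict(self.summary)
        if self.gmr_cmax is not None:
            out["cmax_gmr"] = self.gmr_cmax.point
            out["cmax_gmr_ci"] = (self.gmr_cmax.ci_lower, self.gmr_cmax.ci_upper)
        if self.gmr_auc is not None:
            out["auc_gmr"] = self.gmr_auc.point
            out["auc_gmr_ci"] = (self.gmr_auc.ci_lower, self.gmr_auc.ci_upper)
        return out


def _victim_window(result_profile: ConcProfile) -> ConcProfile:
    """Post-final-dose window, re-zeroed at the profile's own last recorded
    dose time (exactly zero-shift for single doses at t=0)."""
    t_last = max((t for t, _, _ in result_profile.doses), default=0.0)
    return result_profile.window(t_last)


def run_ddi_study(
    design: StudyDesign,
    compounds: Mapping[str, CompoundModel],
    system: Optional[SystemParameters] = None,
    seed: Optional[int] = None,
    options: Optional[EngineOptions] = None,
    cv_spec: Optional[dict[str, float]] = None,
    population: Optional[list[Individual]] = None,
) -> DDIStudyResult:
    """Run a full (optionally two-arm) virtual DDI study.

    The same population (same seed) underlies both arms, so the contrast is
    within-subject; a perpetrator with an empty interaction surface
    therefore yields bit-identical arms and a GMR of exactly 1.
    """
    from .compound_io import validate_study

    report = validate_study(design, compounds)
    if report:
        raise ValueError(f"study not runnable: {report}")
    sysd = system if system is not None else default_system()
    if population is None:
        population = sample_population(
            design, sysd, cv_spec if cv_spec is not None else default_cv_spec(),
            seed,
        )
    victim = compounds[design.victim.compound]
    perp = (
        compounds[design.perpetrator.compound]
        if design.perpetrator is not None
        else None
    )

    ref_metrics: list[PKMetrics] = []
    test_metrics: list[PKMetrics] = []
    for ind in population:
        ref = simulate(victim, design, ind, None, options, default_system=sysd)
        ref_metrics.append(
            nca(_victim_window(ref.victim), ind.id)
        )
        if perp is not None:
            tst = simulate(victim, design, ind, perp, options, default_system=sysd)
            test_metrics.append(
                nca(_victim_window(tst.victim), ind.id)
            )

    res = DDIStudyResult(design.name, ref_metrics, test_metrics)
    res.summary["ref_cmax_gm"] = geometric_mean([m.cmax for m in ref_metrics])
    res.summary["ref_auc_inf_gm"] = geometric_mean(
        [m.auc_0_inf for m in ref_metrics if m.auc_0_inf]
    )
    if perp is not None:
        res.summary["test_cmax_gm"] = geometric_mean(
            [m.cmax for m in test_metrics]
        )
        res.summary["test_auc_inf_gm"] = geometric_mean(
            [m.auc_0_inf for m in test_metrics if m.auc_0_inf]
        )
        res.gmr_cmax = gmr(
            [m.cmax for m in test_metrics], [m.cmax for m in ref_metrics]
        )
        pairs = [
            (t.auc_0_inf, r.auc_0_inf)
            for t, r in zip(test_metrics, ref_metrics)
            if t.auc_0_inf is not None and r.auc_0_inf is not None
        ]
        if not pairs:
            raise ValueError("no subject pair with estimable AUC0-inf")
        res.gmr_auc = gmr([a for a, _ in pairs], [b for _, b in pairs])
    return res
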