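"""Packaged fixture library and synthetic-profile generators.

The library ships one compound file per drug: the reference victim
(parameterized field-for-field from its published final input-parameter
table) plus the index CYP3A inhibitors/inducers and probe substrates used
by the packaged study designs.  Each file carries a ``provenance`` note
stating which values are published compound parameters, which are
literature-sourced defaults, and which were calibrated once against a
public benchmark interaction and then frozen.

``synth_profile`` generates noisy concentration-time profiles with known
closed-form AUC/Cmax for exercising the NCA machinery.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .compound_io import CompoundModel, StudyDesign, load_compound, load_study
from .pbpk_engine import ConcProfile, EngineOptions
from .population import SystemParameters

_DATA = importlib.resources.files("pbpkddi") / "data"


class UnknownFixtureError(KeyError):
    pass


def list_compounds() -> list[str]:
    return sorted(
        p.name.removesuffix(".yaml")
        for p in (_DATA / "compounds").iterdir()
        if p.name.endswith(".yaml")
    )


def list_studies() -> list[str]:
    return sorted(
        p.name.removesuffix(".yaml")
        for p in (_DATA / "studies").iterdir()
        if p.name.endswith(".yaml")
    )


def builtin_compound(name: str) -> CompoundModel:
    """Load and validate a packaged compound file."""
    path = _DATA / "compounds" / f"{name}.yaml"
    if not path.is_file():
        raise UnknownFixtureError(
            f"no fixture {name!r}; available: {', '.join(list_compounds())}"
        )
    with importlib.resources.as_file(path) as p:
        return load_compound(p)


def compound_library(names: Optional[Sequence[str]] = None) -> dict[str, CompoundModel]:
    return {n: builtin_compound(n) for n in (names or list_compounds())}


def builtin_study(name: str) -> StudyDesign:
    path = _DATA / "studies" / f"{name}.yaml"
    if not path.is_file():
        raise UnknownFixtureError(
            f"no study {name!r}; available: {', '.join(list_studies())}"
        )
    with importlib.resources.as_file(path) as p:
        return load_study(p)


# --------------------------------------------------------------------------
# perpetrator calibration report


@dataclass
class CalibrationBenchmark:
    """A runnable public-benchmark interaction with an acceptance window on
    the AUC GMR (e.g. the itraconazole-midazolam AUC-ratio range)."""

    study: str | StudyDesign
    window: tuple[float, float]
    metric: str = "auc_gmr"


@dataclass
class CalibrationReport:
    perpetrator: str
    benchmark: str
    simulated: float
    window: tuple[float, float]
    passed: bool


def calibrate_perpetrator(
    name: str,
    benchmark: CalibrationBenchmark,
    seed: int = 0,
    system: Optional[SystemParameters] = None,
    options: Optional[EngineOptions] = None,
) -> CalibrationReport:
    """Run a benchmark study for a perpetrator fixture and report the
    simulated value against the acceptance window.  Fixture files are never
    modified by this function; recalibration is a manual, one-time act."""
    from .trial_stats import run_ddi_study

    design = (
        builtin_study(benchmark.study)
        if isinstance(benchmark.study, str)
        else benchmark.study
    )
    if design.perpetrator is None or design.perpetrator.compound != name:
        raise ValueError(f"benchmark study does not use {name!r} as perpetrator")
    comps = compound_library([design.victim.compound, name])
    res = run_ddi_study(design, comps, system=system, seed=seed, options=options)
    value = res.table()[benchmark.metric]
    lo, hi = benchmark.window
    return CalibrationReport(
        perpetrator=name,
        benchmark=design.name,
        simulated=value,
        window=benchmark.window,
        passed=lo <= value <= hi,
    )


# --------------------------------------------------------------------------
# synthetic profiles with closed-form truth


@dataclass
class SynthTruth:
    auc_0_inf: float
    cmax: float
    lambda_z: float
    terms: list[tuple[float, float]] = field(default_factory=list)


def synth_profile(
    terms: Sequence[tuple[float, float]],
    t_end: float = 48.0,
    dt: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    mw: float = 373.45,
    name: str = "synthetic",
) -> tuple[ConcProfile, SynthTruth]:
    """Sum-of-exponentials profile C(t) = sum_i A_i exp(-k_i t) (A in ng/mL,
    k in 1/h) with optional multiplicative lognormal noise, plus its exact
    AUC0-inf, Cmax and terminal slope."""
    terms = [(float(a), float(k)) for a, k in terms]
    if not terms or any(k <= 0 for _, k in terms):
        raise ValueError("each term needs a positive rate constant")
    t = np.arange(0.0, t_end + dt / 2, dt)
    c = np.zeros_like(t)
    for a, k in terms:
        c = c + a * np.exp(-k * t)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1 + noise_cv**2))
        c = c * np.exp(sigma * rng.standard_normal(len(c)) - sigma**2 / 2)
    dense = np.linspace(0, t_end, 4001)
    cd = np.zeros_like(dense)
    for a, k in terms:
        cd = cd + a * np.exp(-k * dense)
    truth = SynthTruth(
        auc_0_inf=sum(a / k for a, k in terms),
        cmax=float(cd.max()),
        lambda_z=min(k for _, k in terms),
        terms=list(terms),
    )
    prof = ConcProfile(
        compound=name,
        mw=mw,
        time=t,
        plasma=c,
        enterocyte_u=np.zeros_like(t),
        liver_u=np.zeros_like(t),
        doses=[(0.0, 0.0, "oral")],
    )
    return prof, truth
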