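"""Controlled vocabulary for enzymes/transporters and shared unit constants.

Every enzyme named anywhere in a compound or system file must be listed
here, because the population system file must supply a liver/gut/kidney
abundance for it.  Unknown names are schema errors, never silently ignored.
"""

from __future__ import annotations

# Enzymes (metabolic) and transporters (non-metabolic) the engine knows about.
ENZYMES: tuple[str, ...] = (
    "CYP1A2",
    "CYP2B6",
    "CYP2C8",
    "CYP2C9",
    "CYP2C19",
    "CYP2D6",
    "CYP3A4",
    "UGT1A1",
    "UGT1A9",
    "UGT2B4",
    "UserUGT1",
)

TRANSPORTERS: tuple[str, ...] = ("P-gp",)

#: Pseudo-pathway for the uninhibitable remainder (1 - sum fm) of hepatic
#: metabolic clearance.  Not part of the user-facing vocabulary.
OTHER_PATHWAY = "__other__"

ALL_TARGETS: tuple[str, ...] = ENZYMES + TRANSPORTERS

#: Default tissue expression scalars (liver / intestine / kidney).  A compound
#: file may override these per enzyme (Table-style "rUGT scalar" entries).
DEFAULT_TISSUE_SCALARS: dict[str, dict[str, float]] = {
    "CYP1A2": {"liver": 1.0, "intestine": 0.0, "kidney": 0.0},
    "CYP2B6": {"liver": 1.0, "intestine": 0.0, "kidney": 0.0},
    "CYP2C8": {"liver": 1.0, "intestine": 0.0, "kidney": 0.0},
    "CYP2C9": {"liver": 1.0, "intestine": 1.0, "kidney": 0.0},
    "CYP2C19": {"liver": 1.0, "intestine": 1.0, "kidney": 0.0},
    "CYP2D6": {"liver": 1.0, "intestine": 0.0, "kidney": 0.0},
    "CYP3A4": {"liver": 1.0, "intestine": 1.0, "kidney": 0.0},
    "UGT1A1": {"liver": 1.0, "intestine": 1.0, "kidney": 0.0},
    "UGT1A9": {"liver": 1.0, "intestine": 0.0, "kidney": 1.0},
    "UGT2B4": {"liver": 1.0, "intestine": 0.0, "kidney": 1.0},
    "UserUGT1": {"liver": 0.0, "intestine": 1.0, "kidney": 0.0},
}

TISSUES: tuple[str, ...] = ("liver", "intestine", "kidney")

# --- unit chain -----------------------------------------------------------
# Per-enzyme intrinsic clearances are carried in uL/min/pmol of isoform.
# Scaling to whole-organ L/h:
#   uL/min/pmol * pmol(total) = uL/min;  uL/min * 60 / 1e6 = L/h
UL_PER_MIN_TO_L_PER_H = 60.0 / 1.0e6


def scale_clint(clint_ul_min_pmol: float, total_pmol: float) -> float:
    """Whole-organ intrinsic clearance (L/h) from a per-pmol value."""
    return clint_ul_min_pmol * total_pmol * UL_PER_MIN_TO_L_PER_H
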