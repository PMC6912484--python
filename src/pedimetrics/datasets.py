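"""Published breed-level summary tables bundled as worked-example inputs.

These are pedigree-derived population parameters for eight Italian beef
cattle breeds — three small Tuscan breeds under extinction (Calvana CAL,
Mucca Pisana MUP, Pontremolese PON), three larger unselected Sardinian
breeds (Sarda SAR, Sardo Bruna SAB, Sardo Modicana SAM) and the two
cosmopolitan breeds reared in the same regions (Charolais CHA, Limousine
LIM).  The underlying herdbooks are proprietary; the breed-level
summaries below are public and serve as inputs for identity checks and
for the breed-parameter PCA.
"""

from __future__ import annotations

import pandas as pd

BREEDS = ("CAL", "MUP", "PON", "SAR", "SAB", "SAM", "CHA", "LIM")

_PARAMETERS = {
    # average inbreeding coefficient, %
    "AVG_F": [5.10, 7.25, 3.64, 1.90, 1.23, 1.66, 0.96, 0.71],
    # true mean inbreeding (animals with >= 3 full generations), %
    "TMI": [6.00, 8.00, 5.60, 5.10, 5.10, 2.80, 1.30, 0.90],
    # average relatedness, %
    "AR": [6.39, 10.54, 7.15, 0.04, 0.05, 0.37, 0.20, 0.20],
    # realized effective population size (regression on equivalent generations)
    "Ne": [19.68, 18.52, 14.62, 16.64, 18.91, 39.79, 90.29, 132.65],
    # effective founders over effective ancestors
    "fe_fa_ratio": [1.1, 1.1, 1.1, 1.2, 1.2, 1.2, 3.0, 2.1],
    # number of ancestors explaining 50% of the reference gene pool
    "ANC_50": [8, 5, 5, 542, 294, 96, 219, 330],
    # first-generation pedigree content, %
    "P_CONT": [92, 94, 73, 61, 48, 78, 77, 83],
    # average population size ratio across years and its SD
    "APSR": [1.40, -1.42, -103.23, -4.03, 2.26, -4.38, 3.60, 6.04],
    "APSSD": [14.34, 27.57, 454.11, 21.85, 20.08, 9.50, 7.05, 6.25],
    # total generation interval (all-progeny measure), years
    "GI": [10.29, 8.94, 12.51, 10.60, 13.30, 7.80, 6.69, 7.05],
}

# rate of inbreeding per generation, %, as published alongside Ne
_DELTA_F_PCT = [2.54, 2.70, 3.42, 3.00, 2.64, 1.26, 0.55, 0.37]


def italian_beef_parameters() -> pd.DataFrame:
    """The 8 × 10 breed-parameter table used in the worked PCA example."""
    return pd.DataFrame(_PARAMETERS, index=list(BREEDS), dtype=float)


def italian_beef_ne_delta_f() -> pd.DataFrame:
    """Published Ne and ΔF (%) per breed, for the ΔF = 1/(2Ne) identity.

    Note the LIM row is internally inconsistent in the source summary
    (its ΔF of 0.37% corresponds to Ne = 135.65 rather than the tabulated
    132.65); the seven other rows satisfy the identity to the printed
    precision.
    """
    return pd.DataFrame(
        {"Ne": _PARAMETERS["Ne"], "delta_f_pct": _DELTA_F_PCT}, index=list(BREEDS)
    )
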