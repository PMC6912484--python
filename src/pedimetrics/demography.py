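"""Demographic structure: generation intervals, sex ratios, close-relative
matings and census trajectories.

The generation interval is the average age of a parent at the birth of its
progeny, split into the four classical pathways (father–son,
father–daughter, mother–son, mother–daughter).  Two progeny definitions
are supported: all recorded progeny, or only progeny that themselves left
offspring (the reproductive pathway actually driving generation turnover).

Close-relative matings are classified on distinct (sire, dam) pairs with
mutually exclusive classes and precedence parent–offspring > full-sib >
half-sib.  Pairs with missing parents are classified from the known links
only, which can under-count but never over-count relationship classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .completeness import _recursion_arrays
from .errors import PedigreeError
from .pedigree import Pedigree

PATHWAYS = ("father_son", "father_daughter", "mother_son", "mother_daughter")
MATING_CLASSES = ("parent_offspring", "full_sib", "half_sib")


def generation_intervals(ped: Pedigree, measure: str = "all_progeny") -> pd.DataFrame:
    """Mean/SD parent age at progeny birth per pathway plus the total.

    ``measure='reproductive_progeny'`` keeps only progeny that appear as a
    parent themselves.  Progeny of unknown sex contribute to no pathway
    (and hence not to the total, which is the progeny-weighted pool of the
    four pathways).  Raises when no (parent, progeny) pair has both birth
    years and the progeny sex recorded.
    """
    if measure not in ("all_progeny", "reproductive_progeny"):
        raise PedigreeError(f"unknown generation-interval measure {measure!r}")
    year = ped.birth_year
    sex = ped.sex
    reproduced = np.zeros(len(ped), dtype=bool)
    reproduced[ped.sire_idx[ped.sire_idx >= 0]] = True
    reproduced[ped.dam_idx[ped.dam_idx >= 0]] = True

    ages: dict[str, list[float]] = {p: [] for p in PATHWAYS}
    for child in range(len(ped)):
        if np.isnan(year[child]) or sex[child] == "U":
            continue
        if measure == "reproductive_progeny" and not reproduced[child]:
            continue
        suffix = "son" if sex[child] == "M" else "daughter"
        for parent, prefix in ((ped.sire_idx[child], "father"), (ped.dam_idx[child], "mother")):
            if parent < 0 or np.isnan(year[parent]):
                continue
            ages[f"{prefix}_{suffix}"].append(float(year[child] - year[parent]))

    pooled = [a for v in ages.values() for a in v]
    if not pooled:
        raise PedigreeError("no usable (parent, progeny) pairs with birth years")
    rows = []
    for pathway in PATHWAYS:
        v = np.asarray(ages[pathway])
        rows.append(
            {
                "pathway": pathway,
                "n": v.size,
                "mean": v.mean() if v.size else np.nan,
                "sd": v.std(ddof=1) if v.size > 1 else np.nan,
            }
        )
    pooled_arr = np.asarray(pooled)
    rows.append(
        {
            "pathway": "total",
            "n": pooled_arr.size,
            "mean": pooled_arr.mean(),
            "sd": pooled_arr.std(ddof=1) if pooled_arr.size > 1 else np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("pathway")


def sex_ratio_by_generation(ped: Pedigree, binning: str = "equiGen-floor") -> pd.DataFrame:
    """Male/female/unknown counts per generation bin, plus the M/F ratio."""
    rec = _recursion_arrays(ped)
    if binning == "equiGen-floor":
        bins = np.floor(rec["equi"]).astype(np.int64)
    elif binning == "maxGen":
        bins = rec["max"]
    else:
        raise PedigreeError(f"unknown binning {binning!r}")
    frame = pd.DataFrame({"generation": bins, "sex": ped.sex})
    counts = (
        frame.pivot_table(index="generation", columns="sex", aggfunc="size", fill_value=0)
        .reindex(columns=["M", "F", "U"], fill_value=0)
        .rename(columns={"M": "males", "F": "females", "U": "unknown"})
        .reset_index()
    )
    counts["ratio"] = np.where(
        counts["females"] > 0, counts["males"] / counts["females"], np.nan
    )
    return counts


@dataclass
class MatingSummary:
    """Counts and percentages of close-relative matings.

    The denominator ``n_matings`` is the number of classified units:
    distinct (sire, dam) pairs with both parents recorded by default, or
    progeny records when ``unit='progeny'``.
    """

    n_matings: int
    counts: dict = field(default_factory=dict)
    unit: str = "matings"

    @property
    def percentages(self) -> dict:
        if self.n_matings == 0:
            return {c: 0.0 for c in MATING_CLASSES}
        return {c: 100.0 * self.counts[c] / self.n_matings for c in MATING_CLASSES}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "class": list(MATING_CLASSES),
                "count": [self.counts[c] for c in MATING_CLASSES],
                "percent": [pct[c] for c in MATING_CLASSES],
            }
        )


def _classify_pair(ped: Pedigree, sire: int, dam: int) -> str | None:
    s_par = (ped.sire_idx[sire], ped.dam_idx[sire])
    d_par = (ped.sire_idx[dam], ped.dam_idx[dam])
    if sire in d_par or dam in s_par:
        return "parent_offspring"
    shared = sum(
        1
        for a, b in ((s_par[0], d_par[0]), (s_par[1], d_par[1]))
        if a >= 0 and a == b
    )
    if shared == 2:
        return "full_sib"
    if shared == 1:
        return "half_sib"
    return None


def close_matings(ped: Pedigree, unit: str = "matings") -> MatingSummary:
    """Classify matings as parent–offspring, full-sib or half-sib.

    Full sibs share both (known) parents; half sibs share exactly one
    known parent.  ``unit='matings'`` counts each distinct (sire, dam)
    pair once regardless of how many progeny it produced;
    ``unit='progeny'`` weights pairs by progeny number.
    """
    if unit not in ("matings", "progeny"):
        raise PedigreeError(f"unknown mating unit {unit!r}")
    both = (ped.sire_idx >= 0) & (ped.dam_idx >= 0)
    pairs = pd.DataFrame(
        {"sire": ped.sire_idx[both], "dam": ped.dam_idx[both]}
    ).value_counts()
    counts = {c: 0 for c in MATING_CLASSES}
    total = 0
    for (s, d), n_progeny in pairs.items():
        weight = int(n_progeny) if unit == "progeny" else 1
        total += weight
        klass = _classify_pair(ped, int(s), int(d))
        if klass is not None:
            counts[klass] += weight
    return MatingSummary(n_matings=total, counts=counts, unit=unit)


@dataclass
class CensusTrajectory:
    """Birth-cohort census and its year-to-year ratio statistics.

    ``apsr`` is the mean of (N_y / N_{y+1} × 100) − 100 over consecutive
    years in range; ``apssd`` is the sample SD of the same terms.  Years
    with an empty following cohort are skipped and counted.  With this
    orientation a shrinking population yields positive terms; pass
    ``orientation='growth'`` to :func:`census_stats` for the reversed
    ratio.
    """

    counts: pd.Series
    ratios: pd.Series
    apsr: float
    apssd: float
    n_skipped: int
    orientation: str = "as_printed"

    def to_frame(self) -> pd.DataFrame:
        frame = self.counts.rename("n").to_frame()
        frame["ratio_term"] = self.ratios.reindex(frame.index)
        return frame.reset_index(names="year")


def census_stats(
    ped: Pedigree,
    year_range: tuple[int, int] | None = None,
    orientation: str = "as_printed",
) -> CensusTrajectory:
    """Population-size trajectory statistics from birth-year counts."""
    if orientation not in ("as_printed", "growth"):
        raise PedigreeError(f"unknown orientation {orientation!r}")
    years = ped.birth_year
    known = years[~np.isnan(years)].astype(np.int64)
    if known.size == 0:
        raise PedigreeError("no birth years recorded")
    if year_range is None:
        year_range = (int(known.min()), int(known.max()))
    y0, y1 = int(year_range[0]), int(year_range[1])
    index = pd.RangeIndex(y0, y1 + 1, name="year")
    counts = pd.Series(known, dtype=np.int64).value_counts().reindex(index, fill_value=0)
    if int((counts > 0).sum()) < 2:
        raise PedigreeError("need at least 2 years with animals in range")

    terms = {}
    skipped = 0
    for y in range(y0, y1):
        n_now, n_next = counts[y], counts[y + 1]
        num, den = (n_now, n_next) if orientation == "as_printed" else (n_next, n_now)
        if den == 0:
            skipped += 1
            continue
        terms[y] = num / den * 100.0 - 100.0
    ratios = pd.Series(terms, dtype=float, name="ratio_term")
    apsr = float(ratios.mean()) if len(ratios) else float("nan")
    apssd = float(ratios.std(ddof=1)) if len(ratios) > 1 else float("nan")
    return CensusTrajectory(
        counts=counts, ratios=ratios, apsr=apsr, apssd=apssd,
        n_skipped=skipped, orientation=orientation,
    )
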