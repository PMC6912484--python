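"""Probability-of-gene-origin statistics and realized effective size.

Gene-origin statistics trace where the genes of a reference population
come from:

* Founder contributions ``q_k`` are expected proportional contributions
  obtained by propagating each reference animal's genome upward, half to
  each known parent.  Mass hitting an unrecorded parent link stays with
  the animal as a *pseudo-founder* contribution, so Σq = 1 even under
  missing ancestry.  The effective number of founders is fe = 1/Σq².
* Ancestor contributions are *marginal*: ancestors (founders or not) are
  selected greedily, each round picking the animal explaining the largest
  share of reference genes not yet explained by the ancestors already
  chosen.  Upward propagation is absorbed at selected ancestors and a
  candidate's raw arrival is discounted by the fraction of its own genome
  the selected set already explains.  fa = 1/Σp² over the marginal
  contributions, and ANC_50 is the number of top ancestors jointly
  explaining half of the reference gene pool.  fa < fe signals a
  bottleneck; fa = fe means contributions are balanced.

The realized effective population size is estimated from the regression
of individual inbreeding F on individual equivalent generations over the
reference: with slope b, Ne = 1/(2b) and the per-generation rate of
inbreeding is ΔF = b.  Using equivalent generations as the time axis
compensates for uneven pedigree depth across animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .completeness import _recursion_arrays
from .errors import PedigreeError
from .pedigree import Pedigree
from .relatedness import _inbreeding_array


@dataclass
class ReferencePopulation:
    """Subset of the pedigree over which gene-origin statistics are expressed."""

    rows: np.ndarray  # row indices into the pedigree
    description: str = "custom"

    def __len__(self) -> int:
        return int(self.rows.size)


def reference_population(
    ped: Pedigree,
    rule: str = "both_parents_known",
    birth_year_window: tuple[float, float] | None = None,
) -> ReferencePopulation:
    """Build the reference set: both-parents-known animals by default,
    optionally restricted to a birth-year window; ``rule='all'`` keeps
    every animal."""
    if rule == "both_parents_known":
        mask = (ped.sire_idx >= 0) & (ped.dam_idx >= 0)
    elif rule == "all":
        mask = np.ones(len(ped), dtype=bool)
    else:
        raise PedigreeError(f"unknown reference rule {rule!r}")
    desc = rule
    if birth_year_window is not None:
        lo, hi = birth_year_window
        year = ped.birth_year
        mask &= ~np.isnan(year) & (year >= lo) & (year <= hi)
        desc += f", born {lo}-{hi}"
    rows = np.nonzero(mask)[0]
    if rows.size == 0:
        raise PedigreeError("reference population is empty")
    return ReferencePopulation(rows=rows, description=desc)


def _as_reference(ped: Pedigree, ref) -> ReferencePopulation:
    if ref is None:
        return reference_population(ped)
    if isinstance(ref, ReferencePopulation):
        if len(ref) == 0:
            raise PedigreeError("reference population is empty")
        return ref
    rows = np.array([ped.index_of(a) for a in ref])
    if rows.size == 0:
        raise PedigreeError("reference population is empty")
    return ReferencePopulation(rows=rows)


@dataclass
class GeneOriginStats:
    """Founder/ancestor contribution summary for a reference population."""

    founder_contributions: pd.Series | None = None  # q_k, Σ = 1
    fe: float | None = None
    ancestor_contributions: pd.Series | None = None  # marginal p_j in pick order
    fa: float | None = None
    anc_50: int | None = None
    n_reference: int = 0
    notes: list = field(default_factory=list)

    @property
    def fe_fa_ratio(self) -> float | None:
        if self.fe is None or self.fa is None or self.fa == 0:
            return None
        return self.fe / self.fa


# ---------------------------------------------------------------------------
# level structure for vectorized up/down passes


def _levels(ped: Pedigree) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Animals grouped by longest-path depth: from founders (down passes)
    and from childless animals (up passes)."""
    if "levels" in ped._cache:
        return ped._cache["levels"]
    n = len(ped)
    order = ped._topo_positions()
    sire, dam = ped.sire_idx, ped.dam_idx
    depth_down = np.zeros(n, dtype=np.int64)
    for i in order:
        for p in (sire[i], dam[i]):
            if p >= 0:
                depth_down[i] = max(depth_down[i], depth_down[p] + 1)
    depth_up = np.zeros(n, dtype=np.int64)
    for i in order[::-1]:
        for p in (sire[i], dam[i]):
            if p >= 0:
                depth_up[p] = max(depth_up[p], depth_up[i] + 1)
    down = [np.nonzero(depth_down == k)[0] for k in range(depth_down.max() + 1)]
    up = [np.nonzero(depth_up == k)[0] for k in range(depth_up.max() + 1)]
    ped._cache["levels"] = (down, up)
    return down, up


def _upward_arrivals(
    ped: Pedigree,
    ref_rows: np.ndarray,
    absorb: np.ndarray | None = None,
    collect_missing: np.ndarray | None = None,
) -> np.ndarray:
    """Total expected gene mass from the reference arriving at each animal.

    Each animal forwards half of its arriving mass to each known parent.
    Animals flagged in ``absorb`` receive but do not forward.  When
    ``collect_missing`` is given, mass meeting an unknown parent link is
    accumulated there (pseudo-founder mass).
    """
    n = len(ped)
    _, up = _levels(ped)
    sire, dam = ped.sire_idx, ped.dam_idx
    a = np.zeros(n)
    a[ref_rows] += 1.0 / ref_rows.size
    for group in up:
        active = group if absorb is None else group[~absorb[group]]
        if active.size == 0:
            continue
        half = 0.5 * a[active]
        for parent_idx in (sire, dam):
            p = parent_idx[active]
            known = p >= 0
            if known.any():
                np.add.at(a, p[known], half[known])
            if collect_missing is not None and (~known).any():
                np.add.at(collect_missing, active[~known], half[~known])
    return a


def founder_contributions(ped: Pedigree, ref=None) -> GeneOriginStats:
    """Expected founder contributions q_k to the reference and fe = 1/Σq²."""
    ref = _as_reference(ped, ref)
    n = len(ped)
    q = np.zeros(n)
    # founders deposit their full arriving mass into q through their two
    # unknown parent links; partially recorded animals deposit the
    # unknown-side halves (pseudo-founder mass)
    _upward_arrivals(ped, ref.rows, collect_missing=q)
    total = q.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise AssertionError(f"founder contributions sum to {total}, expected 1")
    holders = q > 0
    series = pd.Series(q[holders], index=ped.ids[holders], name="q").sort_values(
        ascending=False
    )
    return GeneOriginStats(
        founder_contributions=series,
        fe=float(1.0 / np.square(q).sum()),
        n_reference=len(ref),
    )


def _explained_fraction(ped: Pedigree, selected_mask: np.ndarray) -> np.ndarray:
    """Fraction of each animal's genome expected from the selected set."""
    n = len(ped)
    down, _ = _levels(ped)
    sire, dam = ped.sire_idx, ped.dam_idx
    g = np.zeros(n)
    g[selected_mask] = 1.0
    for group in down[1:] if len(down) > 1 else []:
        grp = group[~selected_mask[group]]
        if grp.size == 0:
            continue
        acc = np.zeros(grp.size)
        for parent_idx in (sire, dam):
            p = parent_idx[grp]
            known = p >= 0
            acc[known] += 0.5 * g[p[known]]
        g[grp] = acc
    return g


def ancestor_contributions(
    ped: Pedigree,
    ref=None,
    max_ancestors: int | None = None,
    tol: float = 1e-9,
) -> GeneOriginStats:
    """Greedy marginal ancestor contributions, fa and ANC_50.

    Candidates are animals with recorded progeny.  Ties in the marginal
    contribution break by earlier birth year (unknown last) then id.
    Selection stops when contributions are exhausted (max marginal < tol
    or cumulative ≥ 1 − tol) or ``max_ancestors`` is reached.
    """
    ref = _as_reference(ped, ref)
    n = len(ped)
    is_parent = np.zeros(n, dtype=bool)
    is_parent[ped.sire_idx[ped.sire_idx >= 0]] = True
    is_parent[ped.dam_idx[ped.dam_idx >= 0]] = True
    if not is_parent.any():
        raise PedigreeError("no candidate ancestors: nobody has recorded progeny")

    year = ped.birth_year
    year_key = np.where(np.isnan(year), np.inf, year)
    ids = ped.ids

    selected_mask = np.zeros(n, dtype=bool)
    picks: list[int] = []
    marginals: list[float] = []
    limit = max_ancestors if max_ancestors is not None else int(is_parent.sum())
    cumulative = 0.0
    while len(picks) < limit and cumulative < 1.0 - tol:
        arrivals = _upward_arrivals(ped, ref.rows, absorb=selected_mask)
        g = _explained_fraction(ped, selected_mask)
        score = np.where(is_parent & ~selected_mask, arrivals * (1.0 - g), -1.0)
        best = score.max()
        if best < tol:
            break
        tied = np.nonzero(score >= best - 1e-15)[0]
        if tied.size > 1:
            tie_order = sorted(tied, key=lambda i: (year_key[i], str(ids[i])))
            pick = tie_order[0]
        else:
            pick = int(tied[0])
        selected_mask[pick] = True
        picks.append(pick)
        marginals.append(float(score[pick]))
        cumulative += float(score[pick])

    p = np.asarray(marginals)
    series = pd.Series(p, index=ids[picks], name="p")
    cum = np.cumsum(p)
    # tolerance guards against float error when a contribution is exactly 1/2
    reach = cum >= 0.5 - 1e-9
    anc50 = int(np.argmax(reach) + 1) if reach.any() else None

    # genome shares no recorded ancestor can explain (unknown-parent mass of
    # the reference animals) enter the denominator as pseudo-ancestor
    # contributions, mirroring the pseudo-founder convention of fe; without
    # them fa could nominally exceed fe on incomplete pedigrees
    g_final = _explained_fraction(ped, selected_mask)
    residual = (1.0 - g_final[ref.rows]) / ref.rows.size
    residual = residual[residual > tol]
    denom = float(np.square(p).sum() + np.square(residual).sum())
    return GeneOriginStats(
        ancestor_contributions=series,
        fa=float(1.0 / denom) if denom > 0 else None,
        anc_50=anc50,
        n_reference=len(ref),
        notes=[f"unexplained_mass={float(residual.sum()):.6f}"] if residual.size else [],
    )


def gene_origin(
    ped: Pedigree, ref=None, max_ancestors: int | None = None
) -> GeneOriginStats:
    """Combined founder and ancestor gene-origin statistics."""
    ref = _as_reference(ped, ref)
    fe_part = founder_contributions(ped, ref)
    fa_part = ancestor_contributions(ped, ref, max_ancestors=max_ancestors)
    return GeneOriginStats(
        founder_contributions=fe_part.founder_contributions,
        fe=fe_part.fe,
        ancestor_contributions=fa_part.ancestor_contributions,
        fa=fa_part.fa,
        anc_50=fa_part.anc_50,
        n_reference=len(ref),
    )


# ---------------------------------------------------------------------------
# effective size


def ne_from_delta_f(delta_f: float) -> float:
    """Ne = 1/(2ΔF); ΔF on the proportion scale."""
    return 1.0 / (2.0 * delta_f)


def delta_f_from_ne(ne: float) -> float:
    """ΔF = 1/(2Ne); inverse of :func:`ne_from_delta_f`."""
    return 1.0 / (2.0 * ne)


@dataclass
class EffectiveSizeResult:
    """Realized Ne from the regression of F on equivalent generations."""

    slope: float
    slope_se: float
    intercept: float
    n: int
    ne: float  # NaN when the slope is not positive
    delta_f: float  # = slope, per-generation proportion

    @property
    def delta_f_pct(self) -> float:
        return 100.0 * self.delta_f

    def __str__(self) -> str:
        ne = f"{self.ne:.2f}" if np.isfinite(self.ne) else "undefined"
        return (
            f"EffectiveSizeResult(Ne={ne}, dF={self.delta_f_pct:.3f}%/gen, "
            f"b={self.slope:.5f}±{self.slope_se:.5f}, n={self.n})"
        )


def effective_size(ped: Pedigree, ref=None) -> EffectiveSizeResult:
    """OLS of individual F on individual equiGen over the reference.

    Ne = 1/(2b) for slope b > 0; a non-positive slope leaves Ne undefined
    (NaN) with diagnostics intact.  Degenerate regressions (constant
    equiGen) raise.
    """
    ref = _as_reference(ped, ref)
    x = _recursion_arrays(ped)["equi"][ref.rows]
    y = _inbreeding_array(ped)[ref.rows]
    if np.unique(x).size < 2:
        raise PedigreeError("equiGen is constant over the reference; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    b = float(model.params[1])
    return EffectiveSizeResult(
        slope=b,
        slope_se=float(model.bse[1]),
        intercept=float(model.params[0]),
        n=int(ref.rows.size),
        ne=ne_from_delta_f(b) if b > 0 else float("nan"),
        delta_f=b,
    )
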