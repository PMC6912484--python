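"""Inbreeding and additive-relationship statistics.

The inbreeding coefficient F of an animal is the probability that its two
alleles at a locus are identical by descent; it equals the kinship of its
parents.  F is computed here with the ancestral-path recursion of the
Meuwissen–Luo algorithm, which traces each animal's gene-flow row
L (the T factor of A = T D T') together with the Mendelian-sampling
variances D, giving a_ii = Σ_j L_ij² D_j without ever materializing the
relationship matrix — feasible for pedigrees of hundreds of thousands of
animals.

The dense tabular relationship matrix is also provided for small
pedigrees; it serves as the independent oracle for both F (diag(A) − 1)
and the average relatedness AR.

AR of animal i is the mean additive relationship of i with every animal
in the pedigree (itself included) on a probability scale: the probability
that an allele drawn at random from the whole population descends from i.
That is half the mean of row i of A, computed by two linear passes over
the factorization (descendant totals v = T'1, then row sums s = T D v)
rather than from the matrix itself.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .completeness import _recursion_arrays
from .errors import PedigreeError
from .pedigree import Pedigree

ORACLE_SIZE_LIMIT = 2000


def _inbreeding_array(ped: Pedigree) -> np.ndarray:
    """Per-animal F in row order, by the ancestral-path recursion."""
    if "inbreeding" in ped._cache:
        return ped._cache["inbreeding"]
    n = len(ped)
    order = ped._topo_positions()
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    sire, dam = ped.sire_idx, ped.dam_idx

    F = np.zeros(n)
    D = np.ones(n)  # Mendelian sampling variance, filled in topo order
    memo: dict[tuple[int, int], float] = {}

    def mendelian_variance(i: int) -> float:
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            return 0.5 - 0.25 * (F[s] + F[d])
        if s >= 0:
            return 0.75 - 0.25 * F[s]
        if d >= 0:
            return 0.75 - 0.25 * F[d]
        return 1.0

    for i in order:
        s, d = sire[i], dam[i]
        D[i] = mendelian_variance(i)  # depends only on parental F, known by now
        if s < 0 or d < 0:
            F[i] = 0.0
        else:
            key = (min(s, d), max(s, d))
            if key in memo:
                F[i] = memo[key]
            else:
                # trace L_i over the ancestors of i, highest topo rank first
                weights = {i: 1.0}
                heap = [(-rank[i], i)]
                total = 0.0
                while heap:
                    _, j = heapq.heappop(heap)
                    w = weights.pop(j, 0.0)
                    if w == 0.0:
                        continue
                    total += w * w * D[j]
                    for p in (sire[j], dam[j]):
                        if p >= 0:
                            if p not in weights:
                                heapq.heappush(heap, (-rank[p], p))
                                weights[p] = 0.0
                            weights[p] += 0.5 * w
                    # duplicates of j already merged via the dict
                F[i] = total - 1.0
                memo[key] = F[i]
    ped._cache["inbreeding"] = F
    ped._cache["mendelian_variance"] = D
    return F


def inbreeding(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficient per animal, indexed by id."""
    return pd.Series(_inbreeding_array(ped), index=ped.ids, name="F")


@dataclass
class InbreedingResult:
    """Population-level inbreeding summary.

    ``tmi_pct`` (true mean inbreeding) averages F over animals whose
    pedigree is fully known for at least ``tmi_min_full_gen`` generations,
    limiting the downward bias of missing ancestry.
    """

    f: pd.Series
    mean_f_pct: float
    tmi_pct: float
    n_tmi: int
    tmi_min_full_gen: int


def inbreeding_result(ped: Pedigree, tmi_min_full_gen: int = 3) -> InbreedingResult:
    f = inbreeding(ped)
    fullg = _recursion_arrays(ped)["full"]
    gate = fullg >= tmi_min_full_gen
    tmi = float(f.values[gate].mean() * 100.0) if gate.any() else float("nan")
    return InbreedingResult(
        f=f,
        mean_f_pct=float(f.mean() * 100.0),
        tmi_pct=tmi,
        n_tmi=int(gate.sum()),
        tmi_min_full_gen=tmi_min_full_gen,
    )


def relationship_matrix(ped: Pedigree, size_limit: int = ORACLE_SIZE_LIMIT) -> pd.DataFrame:
    """Dense additive relationship matrix by the tabular method.

    Intended as an oracle on small pedigrees; raises once the pedigree
    exceeds ``size_limit`` animals (use the recursive functions instead).
    """
    n = len(ped)
    if n > size_limit:
        raise PedigreeError(
            f"pedigree has {n} animals, above the dense-matrix bound {size_limit}; "
            "use inbreeding()/average_relatedness() instead"
        )
    order = ped._topo_positions()
    sire, dam = ped.sire_idx, ped.dam_idx
    A = np.zeros((n, n))
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    for t, i in enumerate(order):
        s, d = sire[i], dam[i]
        if t > 0:
            row = np.zeros(t)
            if s >= 0:
                row += A[pos[s], :t]
            if d >= 0:
                row += A[pos[d], :t]
            row *= 0.5
            A[t, :t] = row
            A[:t, t] = row
        a_sd = A[pos[s], pos[d]] if (s >= 0 and d >= 0) else 0.0
        A[t, t] = 1.0 + 0.5 * a_sd
    # back to original row order
    A = A[np.ix_(pos, pos)]
    return pd.DataFrame(A, index=ped.ids, columns=ped.ids)


@dataclass
class RelatednessResult:
    ar: pd.Series  # probability scale, in (0, 1]
    mean_ar_pct: float


def average_relatedness(ped: Pedigree) -> RelatednessResult:
    """AR per animal: half the mean of its relationship-matrix row.

    Computed in O(N) passes over the gene-flow factorization, matching the
    dense oracle to numerical precision.  Note the probability scale: a
    lone founder has AR 0.5 and, in a large population of unrelated
    animals, founder AR approaches 1/(2N).
    """
    n = len(ped)
    _inbreeding_array(ped)  # ensures D is cached
    D = ped._cache["mendelian_variance"]
    order = ped._topo_positions()
    sire, dam = ped.sire_idx, ped.dam_idx

    # v = T'1: expected number of gene copies i passes to itself + descendants
    v = np.ones(n)
    for i in order[::-1]:
        for p in (sire[i], dam[i]):
            if p >= 0:
                v[p] += 0.5 * v[i]
    # s = T (D v): row sums of A
    s = np.empty(n)
    for i in order:
        total = D[i] * v[i]
        if sire[i] >= 0:
            total += 0.5 * s[sire[i]]
        if dam[i] >= 0:
            total += 0.5 * s[dam[i]]
        s[i] = total
    ar = s / (2.0 * n)
    series = pd.Series(ar, index=ped.ids, name="AR")
    return RelatednessResult(ar=series, mean_ar_pct=float(series.mean() * 100.0))


def inbreeding_by_generation(
    ped: Pedigree, binning: str = "equiGen-floor", min_bin_size: int = 5
) -> pd.DataFrame:
    """Mean F and the classical rate of inbreeding per generation bin.

    Animals are binned by floor(equiGen) (default) or by maxGen; the rate
    between consecutive bins is ΔF_t = (F̄_t − F̄_{t−1}) / (1 − F̄_{t−1}).
    Bins smaller than ``min_bin_size`` are flagged, not dropped.
    """
    rec = _recursion_arrays(ped)
    if binning == "equiGen-floor":
        bins = np.floor(rec["equi"]).astype(np.int64)
    elif binning == "maxGen":
        bins = rec["max"]
    else:
        raise PedigreeError(f"unknown binning {binning!r}")
    f = _inbreeding_array(ped)
    table = (
        pd.DataFrame({"generation": bins, "F": f})
        .groupby("generation")["F"]
        .agg(n="size", mean_f="mean")
        .reset_index()
        .sort_values("generation", ignore_index=True)
    )
    if len(table) < 2:
        raise PedigreeError("need at least 2 nonempty generation bins for a trend")
    prev = table["mean_f"].shift(1)
    table["delta_f"] = (table["mean_f"] - prev) / (1.0 - prev)
    table["small_bin"] = table["n"] < min_bin_size
    return table
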