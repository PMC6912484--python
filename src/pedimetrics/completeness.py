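"""Pedigree completeness metrics.

For each animal the depth and quality of its recorded ancestry is
summarized by four standard measures:

* ``equi_gen`` — equivalent complete generations: the sum of (1/2)^n over
  every known-ancestor slot at depth n, i.e. each known ancestor weighted
  by its expected genomic contribution.  A fully known pedigree to depth g
  scores exactly g.
* ``max_gen`` — longest recorded ancestral path.
* ``full_gen`` — deepest generation in which *every* ancestor slot is
  known.
* ``pci`` — completeness index over a horizon of d generations,
  4·Cs·Cd/(Cs+Cd), the harmonic-mean combination of the paternal and
  maternal line completeness Cs, Cd = (1/d)·Σ g_i, where g_i is the
  proportion of known ancestors in generation i.  Each generation's
  proportion is taken over all 2^i slots, so a single line contributes at
  most 0.5 and the index lives in [0, 1].

Pedigree content — the proportion of known ancestors per generation,
overall and split by parental line — backs breed-level reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PedigreeError
from .pedigree import Pedigree

DEFAULT_PCI_DEPTH = 5


def _recursion_arrays(ped: Pedigree) -> dict[str, np.ndarray]:
    """Per-animal equi/max/full generations via the parent recursions."""
    if "completeness" in ped._cache:
        return ped._cache["completeness"]
    n = len(ped)
    order = ped._topo_positions()
    sire, dam = ped.sire_idx, ped.dam_idx
    equi = np.zeros(n)
    maxg = np.zeros(n, dtype=np.int64)
    fullg = np.zeros(n, dtype=np.int64)
    for i in order:
        s, d = sire[i], dam[i]
        e = 0.0
        m = 0
        if s >= 0:
            e += 0.5 * (1.0 + equi[s])
            m = max(m, 1 + maxg[s])
        if d >= 0:
            e += 0.5 * (1.0 + equi[d])
            m = max(m, 1 + maxg[d])
        equi[i] = e
        maxg[i] = m
        fullg[i] = 1 + min(fullg[s], fullg[d]) if (s >= 0 and d >= 0) else 0
    out = {"equi": equi, "max": maxg, "full": fullg}
    ped._cache["completeness"] = out
    return out


def _known_slot_counts(ped: Pedigree, depth: int) -> np.ndarray:
    """K[i, g-1] = number of known ancestor slots of animal i at depth g."""
    key = ("slots", depth)
    if key in ped._cache:
        return ped._cache[key]
    n = len(ped)
    order = ped._topo_positions()
    sire, dam = ped.sire_idx, ped.dam_idx
    K = np.zeros((n, depth), dtype=np.int64)
    for i in order:
        s, d = sire[i], dam[i]
        if s >= 0:
            K[i, 0] += 1
            K[i, 1:] += K[s, :-1]
        if d >= 0:
            K[i, 0] += 1
            K[i, 1:] += K[d, :-1]
    ped._cache[key] = K
    return K


def _line_slot_counts(ped: Pedigree, depth: int) -> tuple[np.ndarray, np.ndarray]:
    """Known-slot counts restricted to the sire and dam lines."""
    K = _known_slot_counts(ped, depth)
    sire, dam = ped.sire_idx, ped.dam_idx
    n = len(ped)
    ks = np.zeros((n, depth), dtype=np.int64)
    kd = np.zeros((n, depth), dtype=np.int64)
    has_s, has_d = sire >= 0, dam >= 0
    ks[has_s, 0] = 1
    kd[has_d, 0] = 1
    if depth > 1:
        ks[has_s, 1:] = K[sire[has_s], :-1]
        kd[has_d, 1:] = K[dam[has_d], :-1]
    return ks, kd


def equivalent_generations(ped: Pedigree, animal_id) -> float:
    """Sum of (1/2)^n over all known-ancestor slots; founders score 0."""
    return float(_recursion_arrays(ped)["equi"][ped.index_of(animal_id)])


def max_generations(ped: Pedigree, animal_id) -> int:
    """Length of the longest path to any known ancestor."""
    return int(_recursion_arrays(ped)["max"][ped.index_of(animal_id)])


def full_generations(ped: Pedigree, animal_id) -> int:
    """Deepest k with all 2^j ancestor slots known for every j <= k."""
    return int(_recursion_arrays(ped)["full"][ped.index_of(animal_id)])


def _pci_components(ped: Pedigree, depth: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if depth < 1:
        raise PedigreeError("PCI depth must be >= 1")
    ks, kd = _line_slot_counts(ped, depth)
    weights = 0.5 ** np.arange(1, depth + 1)  # 1 / 2^i
    c_sire = (ks * weights).sum(axis=1) / depth
    c_dam = (kd * weights).sum(axis=1) / depth
    total = c_sire + c_dam
    with np.errstate(invalid="ignore", divide="ignore"):
        pci = np.where(total > 0, 4.0 * c_sire * c_dam / total, 0.0)
    return pci, c_sire, c_dam


def pci(ped: Pedigree, animal_id, depth_d: int = DEFAULT_PCI_DEPTH) -> float:
    """Pedigree completeness index over ``depth_d`` generations, in [0, 1]."""
    values, _, _ = _pci_components(ped, depth_d)
    return float(values[ped.index_of(animal_id)])


def completeness_table(ped: Pedigree, pci_depth: int = DEFAULT_PCI_DEPTH) -> pd.DataFrame:
    """Per-animal metrics: id, equi_gen, max_gen, full_gen, pci, c_sire, c_dam."""
    rec = _recursion_arrays(ped)
    pci_vals, c_sire, c_dam = _pci_components(ped, pci_depth)
    return pd.DataFrame(
        {
            "id": ped.ids,
            "equi_gen": rec["equi"],
            "max_gen": rec["max"],
            "full_gen": rec["full"],
            "pci": pci_vals,
            "c_sire": c_sire,
            "c_dam": c_dam,
        }
    )


@dataclass
class PedigreeContent:
    """Proportion of known ancestors per generation, averaged over a
    reference set, overall and split by parental line."""

    overall: np.ndarray
    sire_line: np.ndarray
    dam_line: np.ndarray
    n_reference: int

    def to_frame(self) -> pd.DataFrame:
        gens = np.arange(1, len(self.overall) + 1)
        return pd.DataFrame(
            {
                "generation": gens,
                "overall": self.overall,
                "sire_line": self.sire_line,
                "dam_line": self.dam_line,
            }
        )


def pedigree_content(
    ped: Pedigree, reference_ids=None, max_depth: int = 5
) -> PedigreeContent:
    """Mean proportion of known ancestor slots per generation (1..max_depth).

    The overall proportion at generation k uses all 2^k slots; within a
    line the denominator is the line's 2^(k-1) slots.
    """
    if reference_ids is None:
        rows = np.arange(len(ped))
    else:
        reference_ids = list(reference_ids)
        if not reference_ids:
            raise PedigreeError("reference population is empty")
        rows = np.array([ped.index_of(a) for a in reference_ids])
    if rows.size == 0:
        raise PedigreeError("reference population is empty")
    K = _known_slot_counts(ped, max_depth)[rows]
    ks, kd = _line_slot_counts(ped, max_depth)
    ks, kd = ks[rows], kd[rows]
    denom = 2.0 ** np.arange(1, max_depth + 1)
    return PedigreeContent(
        overall=(K / denom).mean(axis=0),
        sire_line=(ks / (denom / 2.0)).mean(axis=0),
        dam_line=(kd / (denom / 2.0)).mean(axis=0),
        n_reference=rows.size,
    )
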