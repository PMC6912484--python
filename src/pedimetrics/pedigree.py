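"""Core pedigree container and graph primitives.

A :class:`Pedigree` wraps a validated genealogy table (one row per animal
with sire/dam links, sex and birth year) and exposes the traversal
primitives every downstream statistic builds on: deterministic topological
ordering, founder identification and per-generation ancestor-slot
expansion.

Missing parents are encoded internally as the integer index ``-1``; on
text input ``""``, ``"0"``, ``"NA"`` (case-insensitive) and friends are
accepted, and ``"0"`` is written on output, the common herdbook
convention.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CycleError, PedigreeError

MISSING = -1
MISSING_TOKENS = {"", "0", "na", "n/a", "nan", "none", ".", "-", "*"}

_MALE_TOKENS = {"m", "male", "1", "s", "sire", "bull"}
_FEMALE_TOKENS = {"f", "female", "2", "d", "dam", "cow"}


def normalize_parent(value) -> str | None:
    """Map the many herdbook spellings of 'unknown parent' to ``None``."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    text = str(value).strip()
    if text.lower() in MISSING_TOKENS:
        return None
    return text


def normalize_sex(value) -> str:
    if value is None:
        return "U"
    if isinstance(value, float) and np.isnan(value):
        return "U"
    text = str(value).strip().lower()
    if text in _MALE_TOKENS:
        return "M"
    if text in _FEMALE_TOKENS:
        return "F"
    return "U"


@dataclass
class ValidationReport:
    """Findings of :meth:`Pedigree.validate`; empty iff analysis-ready.

    ``cycles`` holds one offending id path per detected cycle;
    ``sex_conflicts`` lists (animal, recorded_sex, used_as) triples;
    ``birth_order_conflicts`` lists (parent, child) pairs where the child
    is born before the parent (both years known).
    """

    cycles: list[list[str]] = field(default_factory=list)
    sex_conflicts: list[tuple[str, str, str]] = field(default_factory=list)
    birth_order_conflicts: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.cycles or self.sex_conflicts or self.birth_order_conflicts)

    def __str__(self) -> str:
        if self.ok:
            return "ValidationReport: no issues"
        lines = ["ValidationReport:"]
        for c in self.cycles:
            lines.append(f"  cycle: {' -> '.join(c)}")
        for animal, sex, used_as in self.sex_conflicts:
            lines.append(f"  sex conflict: {animal} recorded {sex} but used as {used_as}")
        for parent, child in self.birth_order_conflicts:
            lines.append(f"  birth order: child {child} born before parent {parent}")
        return "\n".join(lines)


class Pedigree:
    """A closed genealogy table with integer-indexed parent links.

    Parameters
    ----------
    frame
        DataFrame with columns ``id``, ``sire``, ``dam`` and optionally
        ``sex`` and ``birth_year``.  Parent ids absent from the ``id``
        column are appended as phantom founder records (unknown sex and
        year), so the pedigree is always closed.  Duplicate ids raise
        :class:`PedigreeError`.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"id", "sire", "dam"}
        missing_cols = required - set(frame.columns)
        if missing_cols:
            raise PedigreeError(f"missing required columns: {sorted(missing_cols)}")

        ids = [str(x).strip() for x in frame["id"]]
        dup = pd.Series(ids)
        dup = sorted(dup[dup.duplicated()].unique())
        if dup:
            raise PedigreeError(f"duplicate animal ids: {dup}")
        bad = [i for i in ids if i.lower() in MISSING_TOKENS]
        if bad:
            raise PedigreeError(f"animal ids collide with missing-value tokens: {bad}")

        sires = [normalize_parent(x) for x in frame["sire"]]
        dams = [normalize_parent(x) for x in frame["dam"]]
        if "sex" in frame.columns:
            sexes = [normalize_sex(x) for x in frame["sex"]]
        else:
            sexes = ["U"] * len(ids)
        if "birth_year" in frame.columns:
            years = [None if pd.isna(y) else float(y) for y in frame["birth_year"]]
        else:
            years = [None] * len(ids)

        # closure: referenced-but-absent parents become phantom founders
        known = set(ids)
        for p in sires + dams:
            if p is not None and p not in known:
                known.add(p)
                ids.append(p)
                sires.append(None)
                dams.append(None)
                sexes.append("U")
                years.append(None)

        self._ids = np.asarray(ids, dtype=object)
        self._index = {a: i for i, a in enumerate(ids)}
        self._sire = np.array(
            [self._index[p] if p is not None else MISSING for p in sires], dtype=np.int64
        )
        self._dam = np.array(
            [self._index[p] if p is not None else MISSING for p in dams], dtype=np.int64
        )
        self._sex = np.asarray(sexes, dtype=object)
        self._year = np.array(
            [np.nan if y is None else y for y in years], dtype=float
        )
        self._cache: dict = {}

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], columns: Sequence[str] = ("id", "sire", "dam", "sex", "birth_year")
    ) -> "Pedigree":
        return cls(pd.DataFrame.from_records(list(records), columns=list(columns)))

    # -- basic accessors -----------------------------------------------------

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, animal_id) -> bool:
        return str(animal_id) in self._index

    @property
    def ids(self) -> np.ndarray:
        return self._ids

    @property
    def sire_idx(self) -> np.ndarray:
        """Row index of each animal's sire (``-1`` when unknown)."""
        return self._sire

    @property
    def dam_idx(self) -> np.ndarray:
        return self._dam

    @property
    def sex(self) -> np.ndarray:
        return self._sex

    @property
    def birth_year(self) -> np.ndarray:
        """Birth year per animal as float (NaN when unknown)."""
        return self._year

    def index_of(self, animal_id) -> int:
        key = str(animal_id)
        if key not in self._index:
            raise PedigreeError(f"unknown animal id: {animal_id!r}")
        return self._index[key]

    @property
    def founder_mask(self) -> np.ndarray:
        return (self._sire == MISSING) & (self._dam == MISSING)

    @property
    def founders(self) -> np.ndarray:
        """Ids of animals with both parents unknown."""
        return self._ids[self.founder_mask]

    def to_frame(self) -> pd.DataFrame:
        """Normalized table (id, sire, dam, sex, birth_year), NaN = missing."""
        sire = np.where(self._sire >= 0, self._ids[np.clip(self._sire, 0, None)], None)
        dam = np.where(self._dam >= 0, self._ids[np.clip(self._dam, 0, None)], None)
        return pd.DataFrame(
            {
                "id": self._ids,
                "sire": sire,
                "dam": dam,
                "sex": self._sex,
                "birth_year": self._year,
            }
        )

    # -- ordering ------------------------------------------------------------

    def _topo_positions(self) -> np.ndarray:
        """Row indices in topological order (parents first); cached."""
        if "topo" in self._cache:
            return self._cache["topo"]
        n = len(self)
        children: list[list[int]] = [[] for _ in range(n)]
        pending = np.zeros(n, dtype=np.int64)
        for child in range(n):
            for parent in (self._sire[child], self._dam[child]):
                if parent >= 0:
                    children[parent].append(child)
                    pending[child] += 1

        def key(i: int):
            y = self._year[i]
            return (np.isnan(y), y if not np.isnan(y) else 0.0, str(self._ids[i]))

        heap = [(key(i), i) for i in range(n) if pending[i] == 0]
        heapq.heapify(heap)
        order = np.empty(n, dtype=np.int64)
        filled = 0
        while heap:
            _, i = heapq.heappop(heap)
            order[filled] = i
            filled += 1
            for c in children[i]:
                pending[c] -= 1
                if pending[c] == 0:
                    heapq.heappush(heap, (key(c), c))
        if filled < n:
            member = self._ids[int(np.nonzero(pending > 0)[0][0])]
            raise CycleError(f"pedigree contains a cycle involving {member!r}")
        self._cache["topo"] = order
        return order

    def topological_order(self) -> np.ndarray:
        """Animal ids ordered so that every parent precedes its offspring.

        Deterministic: ties are broken by ascending birth year (unknown
        years last) then id.  Raises :class:`CycleError` on cyclic input.
        """
        return self._ids[self._topo_positions()]

    # -- validation ----------------------------------------------------------

    def validate(self) -> ValidationReport:
        report = ValidationReport()

        # cycles: animals never emitted by Kahn's algorithm
        try:
            self._topo_positions()
        except CycleError:
            report.cycles = self._find_cycles()

        used_as_sire = np.unique(self._sire[self._sire >= 0])
        used_as_dam = np.unique(self._dam[self._dam >= 0])
        for i in used_as_sire:
            if self._sex[i] == "F":
                report.sex_conflicts.append((str(self._ids[i]), "F", "sire"))
        for i in used_as_dam:
            if self._sex[i] == "M":
                report.sex_conflicts.append((str(self._ids[i]), "M", "dam"))

        for child in range(len(self)):
            cy = self._year[child]
            if np.isnan(cy):
                continue
            for parent in (self._sire[child], self._dam[child]):
                if parent >= 0 and not np.isnan(self._year[parent]) and cy < self._year[parent]:
                    report.birth_order_conflicts.append(
                        (str(self._ids[parent]), str(self._ids[child]))
                    )
        return report

    def _find_cycles(self) -> list[list[str]]:
        """One representative id path per strongly-connected cycle."""
        n = len(self)
        color = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 in stack, 2 done
        cycles: list[list[str]] = []
        for start in range(n):
            if color[start]:
                continue
            stack: list[tuple[int, int]] = [(start, 0)]
            path: list[int] = []
            while stack:
                node, stage = stack.pop()
                if stage == 0:
                    if color[node] == 2:
                        continue
                    if color[node] == 1:
                        continue
                    color[node] = 1
                    path.append(node)
                    stack.append((node, 1))
                    for parent in (self._sire[node], self._dam[node]):
                        if parent < 0:
                            continue
                        if color[parent] == 1:
                            k = path.index(parent)
                            cyc = [str(self._ids[p]) for p in path[k:]] + [str(self._ids[parent])]
                            cycles.append(cyc)
                        elif color[parent] == 0:
                            stack.append((parent, 0))
                else:
                    color[node] = 2
                    path.pop()
        return cycles

    # -- ancestor expansion ----------------------------------------------------

    def ancestors_by_generation(self, animal_id, max_depth: int) -> list[list[str | None]]:
        """Ancestor slots per generation, parents first.

        Generation ``k`` has ``2**k`` slots; a slot holds the occupying
        ancestor's id or ``None`` when that line is unrecorded.  An
        ancestor reached through several paths occupies several slots.
        """
        if max_depth < 1:
            raise PedigreeError("max_depth must be >= 1")
        i = self.index_of(animal_id)
        generations: list[list[str | None]] = []
        current: list[int] = [i]
        for _ in range(max_depth):
            nxt: list[int] = []
            for slot in current:
                if slot < 0:
                    nxt.extend((MISSING, MISSING))
                else:
                    nxt.extend((self._sire[slot], self._dam[slot]))
            generations.append([str(self._ids[s]) if s >= 0 else None for s in nxt])
            current = nxt
        return generations
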