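"""Model-style facade over the per-metric modules.

:class:`PedigreeAnalysis` is constructed from a pedigree (or a file) with
the analysis options as keyword parameters; :meth:`PedigreeAnalysis.fit`
runs the whole pipeline — validation, completeness, inbreeding and
relatedness, demography, gene-origin statistics and the effective-size
regression — and returns a :class:`PedigreeAnalysisResults` carrying the
estimates, their diagnostics and a ``summary()`` table.  One fitted
results object contributes one row to the breed-parameter PCA via
``parameter_row``.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__ as _version
from .completeness import (
    DEFAULT_PCI_DEPTH,
    PedigreeContent,
    completeness_table,
    pedigree_content,
)
from .demography import (
    CensusTrajectory,
    MatingSummary,
    census_stats,
    close_matings,
    generation_intervals,
    sex_ratio_by_generation,
)
from .diversity import (
    EffectiveSizeResult,
    GeneOriginStats,
    effective_size,
    gene_origin,
    reference_population,
)
from .errors import PedigreeError
from .pedigree import Pedigree, ValidationReport
from .relatedness import (
    InbreedingResult,
    average_relatedness,
    inbreeding_by_generation,
    inbreeding_result,
)


class PedigreeAnalysis:
    """Full pedigree-based population-structure analysis.

    Parameters
    ----------
    pedigree
        A :class:`~pedimetrics.pedigree.Pedigree`.
    pci_depth, content_depth
        Horizon (generations) for the completeness index and the
        pedigree-content profile.
    reference_rule, birth_year_window
        How the reference population for gene-origin statistics and the
        effective-size regression is chosen (default: animals with both
        parents known).
    tmi_min_full_gen
        Minimum number of fully known generations for an animal to enter
        the true-mean-inbreeding average.
    gi_measure
        ``all_progeny`` or ``reproductive_progeny``.
    generation_binning
        ``equiGen-floor`` or ``maxGen`` for per-generation trends.
    census_year_range
        (first, last) birth years for the census-trajectory statistics;
        defaults to the observed range.
    max_ancestors
        Cap on the greedy ancestor selection (None = run to exhaustion).
    mating_unit
        ``matings`` (distinct pairs) or ``progeny`` for close-relative
        mating percentages.
    """

    def __init__(
        self,
        pedigree: Pedigree,
        *,
        pci_depth: int = DEFAULT_PCI_DEPTH,
        content_depth: int = 5,
        reference_rule: str = "both_parents_known",
        birth_year_window: tuple[float, float] | None = None,
        tmi_min_full_gen: int = 3,
        gi_measure: str = "all_progeny",
        generation_binning: str = "equiGen-floor",
        census_year_range: tuple[int, int] | None = None,
        max_ancestors: int | None = None,
        mating_unit: str = "matings",
    ):
        self.pedigree = pedigree
        self.pci_depth = pci_depth
        self.content_depth = content_depth
        self.reference_rule = reference_rule
        self.birth_year_window = birth_year_window
        self.tmi_min_full_gen = tmi_min_full_gen
        self.gi_measure = gi_measure
        self.generation_binning = generation_binning
        self.census_year_range = census_year_range
        self.max_ancestors = max_ancestors
        self.mating_unit = mating_unit

    @classmethod
    def from_file(cls, path, *, read_kwargs: dict | None = None, **options) -> "PedigreeAnalysis":
        from .io import read_pedigree

        return cls(read_pedigree(path, **(read_kwargs or {})), **options)

    def config(self) -> dict[str, Any]:
        return {
            "pci_depth": self.pci_depth,
            "content_depth": self.content_depth,
            "reference_rule": self.reference_rule,
            "birth_year_window": self.birth_year_window,
            "tmi_min_full_gen": self.tmi_min_full_gen,
            "gi_measure": self.gi_measure,
            "generation_binning": self.generation_binning,
            "census_year_range": self.census_year_range,
            "max_ancestors": self.max_ancestors,
            "mating_unit": self.mating_unit,
        }

    def fit(self) -> "PedigreeAnalysisResults":
        ped = self.pedigree
        validation = ped.validate()
        if validation.cycles:
            raise PedigreeError(
                "pedigree contains cycles; see validate(): "
                + "; ".join(" -> ".join(c) for c in validation.cycles)
            )
        notes: list[str] = []

        per_animal = completeness_table(ped, pci_depth=self.pci_depth)
        inb = inbreeding_result(ped, tmi_min_full_gen=self.tmi_min_full_gen)
        rel = average_relatedness(ped)
        per_animal["F"] = inb.f.values
        per_animal["AR"] = rel.ar.values

        try:
            ref = reference_population(
                ped, rule=self.reference_rule, birth_year_window=self.birth_year_window
            )
        except PedigreeError as exc:
            raise PedigreeError(f"reference population: {exc}") from exc

        origin = gene_origin(ped, ref, max_ancestors=self.max_ancestors)
        try:
            ne = effective_size(ped, ref)
        except PedigreeError as exc:
            ne = None
            notes.append(f"effective size: {exc}")

        # content over all animals: a both-parents-known reference would make
        # first-generation content identically 100%
        content = pedigree_content(ped, max_depth=self.content_depth)
        mating = close_matings(ped, unit=self.mating_unit)
        try:
            gi = generation_intervals(ped, measure=self.gi_measure)
        except PedigreeError as exc:
            gi = None
            notes.append(f"generation intervals: {exc}")
        try:
            census = census_stats(ped, year_range=self.census_year_range)
        except PedigreeError as exc:
            census = None
            notes.append(f"census: {exc}")
        try:
            trend = inbreeding_by_generation(ped, binning=self.generation_binning)
        except PedigreeError as exc:
            trend = None
            notes.append(f"inbreeding trend: {exc}")
        sex_ratio = sex_ratio_by_generation(ped, binning=self.generation_binning)

        return PedigreeAnalysisResults(
            model=self,
            validation=validation,
            per_animal=per_animal,
            inbreeding=inb,
            mean_ar_pct=rel.mean_ar_pct,
            gene_origin=origin,
            effective_size=ne,
            pedigree_content=content,
            mating_summary=mating,
            generation_intervals=gi,
            census=census,
            inbreeding_trend=trend,
            sex_ratio=sex_ratio,
            notes=notes,
        )


@dataclass
class PedigreeAnalysisResults:
    """Fitted estimates and diagnostics of a :class:`PedigreeAnalysis`."""

    model: PedigreeAnalysis
    validation: ValidationReport
    per_animal: pd.DataFrame
    inbreeding: InbreedingResult
    mean_ar_pct: float
    gene_origin: GeneOriginStats
    effective_size: EffectiveSizeResult | None
    pedigree_content: PedigreeContent
    mating_summary: MatingSummary
    generation_intervals: pd.DataFrame | None
    census: CensusTrajectory | None
    inbreeding_trend: pd.DataFrame | None
    sex_ratio: pd.DataFrame
    notes: list = field(default_factory=list)

    # -- headline numbers ----------------------------------------------------

    @property
    def mean_f_pct(self) -> float:
        return self.inbreeding.mean_f_pct

    @property
    def tmi_pct(self) -> float:
        return self.inbreeding.tmi_pct

    @property
    def p_cont_pct(self) -> float:
        """First-generation pedigree content of the reference, %."""
        return float(self.pedigree_content.overall[0] * 100.0)

    def parameter_row(self) -> pd.Series:
        """One row of the breed-parameter table for the PCA."""
        gi_total = (
            float(self.generation_intervals.loc["total", "mean"])
            if self.generation_intervals is not None
            else np.nan
        )
        return pd.Series(
            {
                "AVG_F": self.mean_f_pct,
                "TMI": self.tmi_pct,
                "AR": self.mean_ar_pct,
                "Ne": self.effective_size.ne if self.effective_size else np.nan,
                "fe_fa_ratio": self.gene_origin.fe_fa_ratio,
                "ANC_50": self.gene_origin.anc_50,
                "P_CONT": self.p_cont_pct,
                "APSR": self.census.apsr if self.census else np.nan,
                "APSSD": self.census.apssd if self.census else np.nan,
                "GI": gi_total,
            }
        )

    # -- presentation ---------------------------------------------------------

    def summary(self) -> str:
        ped = self.model.pedigree
        per = self.per_animal
        lines = [
            "Pedigree population-structure analysis",
            "=" * 54,
            f"Animals: {len(ped)}   founders: {len(ped.founders)}   "
            f"reference: {self.gene_origin.n_reference} ({self.model.reference_rule})",
            "",
            "Completeness (means over all animals)",
            f"  equiGen {per['equi_gen'].mean():8.3f}   maxGen {per['max_gen'].mean():6.2f}   "
            f"fullGen {per['full_gen'].mean():6.2f}   PCI {per['pci'].mean() * 100:6.2f}%",
            "",
            "Inbreeding and relatedness",
            f"  mean F {self.mean_f_pct:7.3f}%   TMI {self.tmi_pct:7.3f}% "
            f"(fullGen >= {self.inbreeding.tmi_min_full_gen}, n={self.inbreeding.n_tmi})   "
            f"mean AR {self.mean_ar_pct:7.3f}%",
        ]
        if self.effective_size is not None:
            es = self.effective_size
            ne = f"{es.ne:.2f}" if np.isfinite(es.ne) else "undefined"
            lines += [
                "",
                "Effective population size (F on equiGen regression)",
                f"  b = {es.slope:.5f} (SE {es.slope_se:.5f}, n={es.n})   "
                f"Ne = {ne}   dF = {es.delta_f_pct:.3f}%/generation",
            ]
        go = self.gene_origin
        ratio = f"{go.fe_fa_ratio:.2f}" if go.fe_fa_ratio else "n/a"
        lines += [
            "",
            "Gene origin",
            f"  fe = {go.fe:.2f}   fa = {go.fa:.2f}   fe/fa = {ratio}   "
            f"ANC_50 = {go.anc_50}",
            "",
            "Close-relative matings "
            f"({self.mating_summary.n_matings} {self.mating_summary.unit})",
        ]
        pct = self.mating_summary.percentages
        for klass in ("parent_offspring", "full_sib", "half_sib"):
            lines.append(
                f"  {klass:<17} {self.mating_summary.counts[klass]:6d}  {pct[klass]:6.2f}%"
            )
        if self.census is not None:
            lines += [
                "",
                f"Census trajectory: APSR = {self.census.apsr:.2f}   "
                f"APSSD = {self.census.apssd:.2f}  "
                f"({len(self.census.ratios)} year ratios, {self.census.n_skipped} skipped)",
            ]
        if self.generation_intervals is not None:
            gi = self.generation_intervals
            lines += ["", "Generation intervals (years)"]
            for pathway, row in gi.iterrows():
                sd = f"{row['sd']:.2f}" if np.isfinite(row["sd"]) else "--"
                lines.append(
                    f"  {pathway:<16} mean {row['mean']:6.2f}  SD {sd:>6}  n {int(row['n'])}"
                )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def plot_inbreeding_trend(self, ax=None):
        """Mean F per generation bin with the per-step rate of inbreeding."""
        if self.inbreeding_trend is None:
            raise PedigreeError("no inbreeding trend available")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        t = self.inbreeding_trend
        ax.plot(t["generation"], t["mean_f"] * 100, marker="o", label="mean F (%)")
        ax.set_xlabel("generation (" + self.model.generation_binning + ")")
        ax.set_ylabel("mean F (%)")
        ax2 = ax.twinx()
        ax2.plot(t["generation"], t["delta_f"] * 100, marker="s", color="tab:red",
                 alpha=0.6, label="dF (%)")
        ax2.set_ylabel("dF per generation (%)")
        return ax

    # -- persistence -----------------------------------------------------------

    def to_directory(self, outdir: str | os.PathLike) -> None:
        """Write all result tables as TSV plus a JSON run log."""
        os.makedirs(outdir, exist_ok=True)
        join = lambda name: os.path.join(outdir, name)  # noqa: E731
        self.per_animal.to_csv(join("per_animal.tsv"), sep="\t", index=False)
        self.pedigree_content.to_frame().to_csv(
            join("pedigree_content.tsv"), sep="\t", index=False
        )
        self.mating_summary.to_frame().to_csv(
            join("mating_summary.tsv"), sep="\t", index=False
        )
        self.sex_ratio.to_csv(join("sex_ratio.tsv"), sep="\t", index=False)
        if self.generation_intervals is not None:
            self.generation_intervals.to_csv(join("generation_intervals.tsv"), sep="\t")
        if self.census is not None:
            self.census.to_frame().to_csv(join("census.tsv"), sep="\t", index=False)
        if self.inbreeding_trend is not None:
            self.inbreeding_trend.to_csv(
                join("inbreeding_trend.tsv"), sep="\t", index=False
            )
        go = self.gene_origin
        if go.founder_contributions is not None:
            frame = go.founder_contributions.rename("contribution").to_frame()
            frame["cumulative"] = frame["contribution"].cumsum()
            frame.to_csv(join("founder_contributions.tsv"), sep="\t")
        if go.ancestor_contributions is not None:
            frame = go.ancestor_contributions.rename("marginal_contribution").to_frame()
            frame["cumulative"] = frame["marginal_contribution"].cumsum()
            frame.to_csv(join("ancestor_contributions.tsv"), sep="\t")
        self.parameter_row().rename("value").to_frame().to_csv(
            join("parameter_row.tsv"), sep="\t"
        )
        with open(join("summary.txt"), "w") as fh:
            fh.write(self.summary() + "\n")
        config = self.model.config()
        log = {
            "pedimetrics_version": _version,
            "n_animals": len(self.model.pedigree),
            "config": config,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "validation_ok": self.validation.ok,
            "notes": self.notes,
        }
        with open(join("run_log.json"), "w") as fh:
            json.dump(log, fh, indent=2, default=str)
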