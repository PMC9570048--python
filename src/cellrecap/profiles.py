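"""Assemble per-stratum contrasts into evolutionary, slope and ontogenetic profiles.

An evolutionary profile is the vector of intercept contrasts (contrast minus
reference population, at equal slopes) across the 17 phylostrata; a slope
profile is the per-stratum regression slope within one population; an
ontogenetic profile tracks one gene group (by default the unicellular-origin
genes) across an ordered list of developmental stages against a fixed
reference stage. Each per-stratum contrast carries a qualitative call from
its confidence interval: 'down' when the CI lies below 0, 'up' when above,
'null' otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .ancova import (
    InterceptContrast,
    RegressionFit,
    fit_group_regression,
    intercept_contrast,
)
from .datatypes import ExpressionMatrix, N_STRATA, PhylostratumMap
from .preprocess import cell_cycle_signal, group_mean_per_cell, quantile_normalize

#: strata with fewer dated genes than this are flagged low-power, not dropped
MIN_GENES_PER_STRATUM = 5


@dataclass
class EvolutionaryProfile:
    """Ordered per-stratum intercept contrasts for one population pair."""

    contrast_population: str
    reference_population: str
    contrasts: list[InterceptContrast | None]   # index = stratum - 1
    flags: list[str] = field(default_factory=list)

    @property
    def calls(self) -> list[str]:
        return [c.call if c is not None else "empty" for c in self.contrasts]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, c in enumerate(self.contrasts, start=1):
            flag = self.flags[s - 1] if self.flags else ""
            if c is None:
                rows.append((s, np.nan, np.nan, np.nan, np.nan, np.nan,
                             np.nan, "empty", flag))
            else:
                rows.append((s, c.delta_intercept, c.se, c.ci[0], c.ci[1],
                             c.p_value, c.common_slope, c.call, flag))
        return pd.DataFrame(rows, columns=[
            "stratum", "delta_intercept", "se", "ci_low", "ci_high",
            "p_value", "common_slope", "call", "flag"])


@dataclass
class SlopeProfile:
    """Ordered per-stratum regression slopes (with CIs) for one population."""

    population: str
    fits: list[RegressionFit | None]
    flags: list[str] = field(default_factory=list)

    @property
    def slopes(self) -> list[float]:
        return [f.slope if f is not None else np.nan for f in self.fits]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, f in enumerate(self.fits, start=1):
            flag = self.flags[s - 1] if self.flags else ""
            if f is None:
                rows.append((s, np.nan, np.nan, np.nan, np.nan, np.nan, flag))
            else:
                rows.append((s, f.slope, f.slope_se, f.slope_ci[0],
                             f.slope_ci[1], f.r_squared, flag))
        return pd.DataFrame(rows, columns=[
            "stratum", "slope", "se", "ci_low", "ci_high", "r_squared",
            "flag"])


@dataclass
class OntogeneticProfile:
    """One gene group contrasted across ordered stages vs a reference stage."""

    group_name: str
    reference_stage: str
    stages: list[str]
    contrasts: list[InterceptContrast]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage, c in zip(self.stages, self.contrasts):
            rows.append((stage, c.delta_intercept, c.se, c.ci[0], c.ci[1],
                         c.p_value, c.call))
        return pd.DataFrame(rows, columns=[
            "stage", "delta_intercept", "se", "ci_low", "ci_high",
            "p_value", "call"])

    def peak_stage(self) -> str:
        """Stage with the largest intercept contrast."""
        deltas = [c.delta_intercept for c in self.contrasts]
        return self.stages[int(np.argmax(deltas))]


def _maybe_log(sig, log_scale: bool, log_offset: float):
    """Optionally move a signal back to the log2 scale for exact recovery
    diagnostics (the analysis default is the back-transformed linear scale)."""
    if not log_scale:
        return sig
    from dataclasses import replace

    vals = sig.values + log_offset
    if (vals <= 0).any():
        raise ValueError("log-scale regression needs positive signals")
    return replace(sig, values=np.log2(vals))


def _prepare(matrix: ExpressionMatrix, cc_genes: Iterable[str],
             normalize: bool, log_offset: float, log_scale: bool = False):
    if normalize:
        matrix = quantile_normalize(matrix)
    cc_sig = group_mean_per_cell(matrix, cc_genes, log_offset=log_offset,
                                 group_name="cell_cycle_signature")
    return matrix, _maybe_log(cc_sig, log_scale, log_offset)


def evolutionary_profile(matrix: ExpressionMatrix,
                         strata_map: PhylostratumMap,
                         cc_genes: Iterable[str],
                         contrast_pop: str, reference_pop: str,
                         *, alpha: float = 0.05, log_offset: float = 1.0,
                         remove_overlap: bool = True, normalize: bool = True,
                         log_scale: bool = False) -> EvolutionaryProfile:
    """Per-stratum intercept contrasts between two populations.

    Normalization and the signature signal are computed once on the full
    matrix; each stratum's gene group is then averaged per cell and
    contrasted. Strata left empty after overlap removal are flagged, never
    silently dropped.
    """
    cc_genes = frozenset(cc_genes)
    matrix, cc_sig = _prepare(matrix, cc_genes, normalize, log_offset,
                              log_scale)
    contrasts: list[InterceptContrast | None] = []
    flags: list[str] = []
    matrix_genes = set(matrix.gene_ids)
    for s in range(1, N_STRATA + 1):
        group = strata_map.stratum_genes(s) & matrix_genes
        if remove_overlap:
            group = group - cc_genes
        if not group:
            contrasts.append(None)
            flags.append("empty")
            continue
        flags.append("low_power" if len(group) < MIN_GENES_PER_STRATUM else "")
        sig = _maybe_log(
            group_mean_per_cell(matrix, group, log_offset=log_offset,
                                group_name=f"stratum_{s:02d}"),
            log_scale, log_offset)
        contrasts.append(intercept_contrast(
            sig, cc_sig, contrast_pop, reference_pop, alpha=alpha,
            group_name=f"stratum_{s:02d}"))
    return EvolutionaryProfile(contrast_population=contrast_pop,
                               reference_population=reference_pop,
                               contrasts=contrasts, flags=flags)


def slope_profile(matrix: ExpressionMatrix, strata_map: PhylostratumMap,
                  cc_genes: Iterable[str], population: str,
                  *, alpha: float = 0.05, log_offset: float = 1.0,
                  remove_overlap: bool = True, normalize: bool = True,
                  log_scale: bool = False) -> SlopeProfile:
    """Per-stratum slope of the group-on-signature regression in one population."""
    cc_genes = frozenset(cc_genes)
    matrix, cc_sig = _prepare(matrix, cc_genes, normalize, log_offset,
                              log_scale)
    fits: list[RegressionFit | None] = []
    flags: list[str] = []
    matrix_genes = set(matrix.gene_ids)
    for s in range(1, N_STRATA + 1):
        group = strata_map.stratum_genes(s) & matrix_genes
        if remove_overlap:
            group = group - cc_genes
        if not group:
            fits.append(None)
            flags.append("empty")
            continue
        flags.append("low_power" if len(group) < MIN_GENES_PER_STRATUM else "")
        sig = _maybe_log(
            group_mean_per_cell(matrix, group, log_offset=log_offset,
                                group_name=f"stratum_{s:02d}"),
            log_scale, log_offset)
        fits.append(fit_group_regression(sig, cc_sig, population, alpha=alpha))
    return SlopeProfile(population=population, fits=fits, flags=flags)


def ontogenetic_profile(matrix: ExpressionMatrix,
                        strata_map: PhylostratumMap,
                        cc_genes: Iterable[str],
                        stage_order: list[str], reference_stage: str,
                        group: Iterable[str] | None = None,
                        *, alpha: float = 0.05, log_offset: float = 1.0,
                        remove_overlap: bool = True, normalize: bool = True
                        ) -> OntogeneticProfile:
    """One gene group (default: UC genes) contrasted per stage vs a reference.

    The reference stage is contrasted against itself, which yields an
    identically zero intercept difference, so the profile is anchored at 0.
    """
    known = set(matrix.cell_labels)
    unknown = [s for s in stage_order if s not in known]
    if unknown:
        raise KeyError(f"unknown stage labels: {unknown}")
    if reference_stage not in known:
        raise KeyError(f"unknown reference stage {reference_stage!r}")
    cc_genes = frozenset(cc_genes)
    if group is None:
        group = strata_map.uc_genes()
        group_name = "UC"
    else:
        group = frozenset(group)
        group_name = "group"
    matrix, cc_sig = _prepare(matrix, cc_genes, normalize, log_offset)
    tested = set(group) & set(matrix.gene_ids)
    if remove_overlap:
        tested -= cc_genes
    if not tested:
        raise ValueError(f"gene group {group_name!r} empty after filtering")
    sig = group_mean_per_cell(matrix, tested, log_offset=log_offset,
                              group_name=group_name)
    contrasts = [
        intercept_contrast(sig, cc_sig, stage, reference_stage, alpha=alpha,
                           group_name=group_name)
        for stage in stage_order
    ]
    return OntogeneticProfile(group_name=group_name,
                              reference_stage=reference_stage,
                              stages=list(stage_order), contrasts=contrasts)


def plot_profile(frame: pd.DataFrame, path: str, *, x: str = "stratum",
                 y: str = "delta_intercept", title: str = "") -> None:
    """Point + CI plot of a profile table (one row per stratum or stage)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = np.arange(len(frame))
    fig, ax = plt.subplots(figsize=(7, 3.5))
    yerr = np.vstack([frame[y] - frame["ci_low"], frame["ci_high"] - frame[y]])
    ax.errorbar(xs, frame[y], yerr=yerr, fmt="o", capsize=3)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xticks(xs)
    ax.set_xticklabels(frame[x], rotation=90, fontsize=7)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
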