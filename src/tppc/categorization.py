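"""Permutation testing and TPC/PPC classification of metabolite pairs.

For every unordered metabolite pair three statistics are computed: the
Pearson correlation ``r_XY``, the partial correlation ``r_XY.V`` controlling
on the first *p* transcript PC scores, and the difference ``d = |r_XY -
r_XY.V|``. Significance comes from a component-wise permutation null: each
variable of both layers is independently shuffled across samples, PCA is
refit on the permuted transcripts, and all three statistics recomputed —
repeated ``n_permutations`` times (paper-scale default 5,000). Empirical
p-values use the add-one estimator ``(1 + #{|null| >= |obs|}) /
(n_permutations + 1)`` per pair, and Benjamini-Hochberg correction is applied
separately within each statistic family across all pairs.

Classification at level ``alpha`` (default 0.01):

* **TPC** (transcriptionally controlled): significant Pearson, non-significant
  partial, significant difference.
* **PPC** (post-transcriptionally controlled): significant partial and
  significant difference (optionally also a significant Pearson).
* everything else: **none**.

TPC and PPC are disjoint by construction (TPC needs ``q_partial > alpha``,
PPC needs ``q_partial <= alpha``).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    CollinearityError,
    DegenerateInputError,
    DimensionError,
    SpecificationError,
    TPPCError,
)
from .io_data import MatchedDataset, OmicsMatrix
from .partial_correlation import ControlSet, partial_pairs, pearson_pairs
from .pc_selection import PCSelection, fit_pca, select_num_pcs

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "PermutationNull",
    "PairStatistics",
    "AnalysisResult",
    "permute_componentwise",
    "build_null",
    "empirical_pvalue",
    "bh_adjust",
    "compute_pair_statistics",
    "classify_pairs",
    "summarize_direction_changes",
    "count_thresholds",
    "run_analysis",
]

#: Fraction of redrawn permutations above which a warning is logged.
REDRAW_WARN_FRACTION = 0.01


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the TPC/PPC pipeline.

    ``n_pcs=None`` defers the choice to the three retention criteria
    (maximum of the counts, floored at 1); the default of 3 follows common
    practice for these data shapes. ``permute_layers`` selects whether the
    permutation null shuffles both layers (default) or only the metabolites
    against the observed transcript PCs.
    """

    n_pcs: int | None = 3
    n_permutations: int = 5000
    alpha: float = 0.01
    horn_randomizations: int = 1000
    horn_percentile: float = 99.0
    seed: int = 0
    standardize: bool = True
    ppc_require_pearson: bool = False
    min_samples: int = 5
    permute_layers: str = "both"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise SpecificationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_permutations < 100:
            raise SpecificationError(
                f"n_permutations must be >= 100, got {self.n_permutations}"
            )
        if self.n_pcs is not None and self.n_pcs < 1:
            raise SpecificationError(f"n_pcs must be >= 1, got {self.n_pcs}")
        if self.permute_layers not in ("both", "metabolites"):
            raise SpecificationError(
                f"permute_layers must be 'both' or 'metabolites', got {self.permute_layers!r}"
            )


@dataclass(frozen=True)
class PermutationNull:
    """Per-pair null statistics from component-wise permutation.

    Arrays have shape ``(n_permutations, n_pairs)`` with pairs ordered as in
    ``pair_index`` (upper-triangle order of the metabolite matrix).
    """

    null_pearson: np.ndarray
    null_partial: np.ndarray
    null_diff: np.ndarray
    pair_index: tuple[tuple[str, str], ...]
    n_permutations: int
    n_redraws: int = 0


@dataclass(frozen=True)
class PairStatistics:
    """Observed statistics, p/q-values and category for one metabolite pair."""

    metabolite_1: str
    metabolite_2: str
    r_pearson: float
    r_partial: float
    p_pearson: float = float("nan")
    p_partial: float = float("nan")
    p_diff: float = float("nan")
    q_pearson: float = float("nan")
    q_partial: float = float("nan")
    q_diff: float = float("nan")
    category: str = "none"

    def __post_init__(self) -> None:
        if self.metabolite_1 >= self.metabolite_2:
            raise SpecificationError(
                "pair identifiers must satisfy metabolite_1 < metabolite_2 "
                f"(got {self.metabolite_1!r}, {self.metabolite_2!r})"
            )


@dataclass(frozen=True)
class AnalysisResult:
    """Full pipeline output: classified pairs plus reproducibility metadata."""

    pairs: tuple[PairStatistics, ...]
    pc_selection: PCSelection
    n_pcs_used: int
    n_redraws: int
    config: AnalysisConfig


def permute_componentwise(dataset: MatchedDataset, rng: np.random.Generator) -> MatchedDataset:
    """Independently permute every variable of both layers across samples.

    Destroys all between-variable dependence while preserving each variable's
    value multiset; shapes and identifiers are unchanged.
    """
    t, m = dataset.transcripts, dataset.metabolites
    return MatchedDataset(
        transcripts=OmicsMatrix(
            rng.permuted(t.values, axis=1), t.variable_ids, t.sample_ids, t.layer
        ),
        metabolites=OmicsMatrix(
            rng.permuted(m.values, axis=1), m.variable_ids, m.sample_ids, m.layer
        ),
    )


def _pair_index(metabolites: OmicsMatrix) -> tuple[tuple[str, str], ...]:
    ids = metabolites.variable_ids
    return tuple(
        tuple(sorted((ids[i], ids[j])))
        for i, j in itertools.combinations(range(len(ids)), 2)
    )


def _pair_statistics_arrays(
    dataset: MatchedDataset, n_pcs: int, standardize: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pearson, partial, diff) vectors over the upper-triangle pair order."""
    fit = fit_pca(dataset.transcripts, standardize=standardize)
    if n_pcs > fit.n_components:
        raise DimensionError(
            f"requested {n_pcs} PCs but the transcript layer yields only "
            f"{fit.n_components} components"
        )
    controls = ControlSet.from_scores(fit.scores, n_pcs)
    iu = np.triu_indices(dataset.metabolites.n_variables, k=1)
    r_pearson = pearson_pairs(dataset.metabolites)[iu]
    r_partial = partial_pairs(dataset.metabolites, controls)[iu]
    return r_pearson, r_partial, np.abs(r_pearson - r_partial)


def build_null(
    dataset: MatchedDataset,
    config: AnalysisConfig,
    n_pcs: int | None = None,
) -> PermutationNull:
    """Component-wise permutation null for all three statistic families.

    Each permutation uses an independent, counter-derived random substream
    (``[seed, permutation_index, attempt]``), so results are reproducible and
    independent of execution order. Permutations that raise a collinearity or
    degeneracy error are redrawn with a fresh substream; redraws are counted
    and a warning is logged if they exceed 1% of permutations.
    """
    p = int(n_pcs if n_pcs is not None else (config.n_pcs or 0))
    if p < 1:
        raise SpecificationError("build_null needs an explicit number of PCs >= 1")
    if dataset.n_samples - 2 - p < 1:
        raise DimensionError(
            f"insufficient degrees of freedom: n={dataset.n_samples}, n_pcs={p}"
        )
    n_perm = config.n_permutations
    pair_index = _pair_index(dataset.metabolites)
    n_pairs = len(pair_index)
    null_pearson = np.empty((n_perm, n_pairs))
    null_partial = np.empty((n_perm, n_pairs))
    null_diff = np.empty((n_perm, n_pairs))
    fixed_controls = None
    if config.permute_layers == "metabolites":
        fit = fit_pca(dataset.transcripts, standardize=config.standardize)
        fixed_controls = ControlSet.from_scores(fit.scores, p)
    n_redraws = 0
    for b in range(n_perm):
        for attempt in range(100):
            rng = np.random.default_rng([config.seed, b, attempt])
            try:
                permuted = permute_componentwise(dataset, rng)
                if fixed_controls is not None:
                    iu = np.triu_indices(permuted.metabolites.n_variables, k=1)
                    rp = pearson_pairs(permuted.metabolites)[iu]
                    rq = partial_pairs(permuted.metabolites, fixed_controls)[iu]
                    stats = (rp, rq, np.abs(rp - rq))
                else:
                    stats = _pair_statistics_arrays(permuted, p, config.standardize)
            except (CollinearityError, DegenerateInputError):
                n_redraws += 1
                continue
            null_pearson[b], null_partial[b], null_diff[b] = stats
            break
        else:  # pragma: no cover - would need pathological data
            raise TPPCError(f"permutation {b} failed after 100 redraw attempts")
        if (b + 1) % 500 == 0:
            logger.info("permutation %d/%d complete", b + 1, n_perm)
    if n_redraws > REDRAW_WARN_FRACTION * n_perm:
        logger.warning(
            "%d of %d permutations redrawn (> %.0f%%); null may be distorted",
            n_redraws, n_perm, 100 * REDRAW_WARN_FRACTION,
        )
    return PermutationNull(
        null_pearson=null_pearson,
        null_partial=null_partial,
        null_diff=null_diff,
        pair_index=pair_index,
        n_permutations=n_perm,
        n_redraws=n_redraws,
    )


def empirical_pvalue(observed: float, null_samples) -> float:
    """Two-sided empirical p-value with the add-one estimator.

    ``p = (1 + #{|null| >= |observed|}) / (n_null + 1)``, guaranteed in
    ``(0, 1]``.
    """
    null = np.asarray(null_samples, dtype=float).ravel()
    if null.size == 0:
        raise SpecificationError("empty null sample")
    if null.size < 100:
        raise SpecificationError(
            f"need >= 100 null samples for a stable p-value, got {null.size}"
        )
    exceed = int(np.sum(np.abs(null) >= abs(float(observed))))
    return (1 + exceed) / (null.size + 1)


def _empirical_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Vectorised per-pair version of :func:`empirical_pvalue`."""
    exceed = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    return (1 + exceed) / (null.shape[0] + 1)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise SpecificationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_pair_statistics(
    dataset: MatchedDataset,
    config: AnalysisConfig,
    null: PermutationNull | None = None,
    n_pcs: int | None = None,
) -> list[PairStatistics]:
    """Observed statistics plus permutation p-values and BH q-values.

    Categories are left as ``"none"``; apply :func:`classify_pairs` next.
    A precomputed ``null`` may be supplied to reuse permutations.
    """
    p = int(n_pcs if n_pcs is not None else (config.n_pcs or 0))
    if p < 1:
        raise SpecificationError("compute_pair_statistics needs n_pcs >= 1")
    r_pearson, r_partial, diff = _pair_statistics_arrays(dataset, p, config.standardize)
    if null is None:
        null = build_null(dataset, config, n_pcs=p)
    pair_index = _pair_index(dataset.metabolites)
    if null.pair_index != pair_index:
        raise SpecificationError("permutation null was built for a different pair set")
    p_pearson = _empirical_pvalues(r_pearson, null.null_pearson)
    p_partial = _empirical_pvalues(r_partial, null.null_partial)
    p_diff = _empirical_pvalues(diff, null.null_diff)
    q_pearson = bh_adjust(p_pearson)
    q_partial = bh_adjust(p_partial)
    q_diff = bh_adjust(p_diff)
    return [
        PairStatistics(
            metabolite_1=m1,
            metabolite_2=m2,
            r_pearson=float(r_pearson[k]),
            r_partial=float(r_partial[k]),
            p_pearson=float(p_pearson[k]),
            p_partial=float(p_partial[k]),
            p_diff=float(p_diff[k]),
            q_pearson=float(q_pearson[k]),
            q_partial=float(q_partial[k]),
            q_diff=float(q_diff[k]),
        )
        for k, (m1, m2) in enumerate(pair_index)
    ]


def classify_pairs(
    stats: list[PairStatistics], config: AnalysisConfig
) -> list[PairStatistics]:
    """Assign TPC / PPC / none categories from the q-values.

    TPC requires a significant Pearson correlation that *loses* significance
    after partialling out the transcript PCs, with a significant difference;
    PPC requires the partial correlation to *stay* significant, again with a
    significant difference. The two sets are disjoint because they demand
    opposite outcomes for ``q_partial``.
    """
    a = config.alpha
    out = []
    for s in stats:
        sig_pearson = s.q_pearson <= a
        sig_partial = s.q_partial <= a
        sig_diff = s.q_diff <= a
        if sig_pearson and not sig_partial and sig_diff:
            category = "TPC"
        elif sig_partial and sig_diff and (sig_pearson or not config.ppc_require_pearson):
            category = "PPC"
        else:
            category = "none"
        out.append(dataclasses.replace(s, category=category))
    return out


def summarize_direction_changes(stats: list[PairStatistics]) -> pd.DataFrame:
    """Fractions of |r| increases/decreases from Pearson to partial.

    One row per (category, sign of the Pearson correlation); empty cells are
    NaN rather than 0 so "no pairs" is distinguishable from "no increases".
    """
    rows = []
    for category in ("TPC", "PPC"):
        for sign, pred in (("+", lambda r: r > 0), ("-", lambda r: r < 0)):
            members = [
                s for s in stats if s.category == category and pred(s.r_pearson)
            ]
            n = len(members)
            if n == 0:
                rows.append(
                    dict(category=category, sign=sign, n_pairs=0,
                         frac_increased=np.nan, frac_decreased=np.nan,
                         frac_tied=np.nan)
                )
                continue
            inc = sum(abs(s.r_partial) > abs(s.r_pearson) for s in members)
            dec = sum(abs(s.r_partial) < abs(s.r_pearson) for s in members)
            rows.append(
                dict(category=category, sign=sign, n_pairs=n,
                     frac_increased=inc / n, frac_decreased=dec / n,
                     frac_tied=(n - inc - dec) / n)
            )
    return pd.DataFrame(rows)


def count_thresholds(stats: list[PairStatistics], thresholds) -> pd.DataFrame:
    """Counts of categorized pairs with partial correlation beyond thresholds.

    Positive thresholds count pairs with ``r_partial > t``; negative ones
    count ``r_partial < t``; per category.
    """
    rows = []
    for t in thresholds:
        t = float(t)
        if t == 0:
            raise SpecificationError("thresholds must be nonzero")
        row = {"threshold": t}
        for category in ("TPC", "PPC"):
            vals = [s.r_partial for s in stats if s.category == category]
            row[category] = (
                sum(v > t for v in vals) if t > 0 else sum(v < t for v in vals)
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=["threshold", "TPC", "PPC"])


def run_analysis(dataset: MatchedDataset, config: AnalysisConfig) -> AnalysisResult:
    """End-to-end pipeline: PC selection, statistics, testing, classification."""
    if dataset.n_samples < config.min_samples:
        raise DimensionError(
            f"dataset has {dataset.n_samples} samples; "
            f"min_samples={config.min_samples}"
        )
    selection = select_num_pcs(dataset.transcripts, config)
    p = selection.chosen_p
    null = build_null(dataset, config, n_pcs=p)
    stats = compute_pair_statistics(dataset, config, null=null, n_pcs=p)
    classified = classify_pairs(stats, config)
    return AnalysisResult(
        pairs=tuple(classified),
        pc_selection=selection,
        n_pcs_used=p,
        n_redraws=null.n_redraws,
        config=config,
    )
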