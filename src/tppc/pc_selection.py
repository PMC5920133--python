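"""PCA of the transcript layer and component-retention criteria.

The pipeline controls metabolite-pair correlations on the leading principal
components of the transcript matrix. How many components carry signal is
estimated by three classical criteria:

* **Broken-Stick** -- compare the proportion of variance of component *i*
  against the expected length ``b_i = sum_{k=i}^{p} 1/k`` (scaled by ``1/p``)
  of the *i*-th largest piece of a unit stick broken at random into *p*
  pieces, where *p* is the number of variables.
* **Kaiser-Guttman** -- retain components whose eigenvalue exceeds the mean
  eigenvalue (exactly 1 for correlation-matrix PCA).
* **Horn's parallel analysis** -- retain components whose eigenvalue exceeds
  a high percentile (default 99th over 1,000 randomizations) of the
  eigenvalues obtained after independently permuting every variable across
  samples.

PCA is computed by singular value decomposition of the centered (and, by
default, per-variable standardized) data with divisor ``n - 1``, which is
numerically stable in the typical regime of many more variables than samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .exceptions import (
    DegenerateInputError,
    DimensionError,
    InsufficientNullError,
)
from .io_data import OmicsMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .categorization import AnalysisConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PCADecomposition",
    "PCSelection",
    "fit_pca",
    "broken_stick_proportions",
    "broken_stick_count",
    "kaiser_guttman_count",
    "horn_parallel_count",
    "select_num_pcs",
]


@dataclass(frozen=True)
class PCADecomposition:
    """Eigenvalues and per-sample component scores of a PCA fit.

    ``scores`` has shape ``(n_samples, n_components)``; its columns are the
    controlling variables handed to the partial-correlation stage. The
    eigenvalue of component *i* equals the sample variance (ddof=1) of score
    column *i*.
    """

    eigenvalues: np.ndarray
    scores: np.ndarray
    proportion_variance: np.ndarray
    n_variables: int
    dropped_variables: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class PCSelection:
    """Component counts suggested by the three criteria plus the chosen p."""

    broken_stick_count: int
    kaiser_guttman_count: int
    horn_count: int
    chosen_p: int


def _standardized_data(matrix: OmicsMatrix, standardize: bool):
    """Return (samples x variables centered/scaled data, kept variable ids)."""
    X = matrix.values
    sd = X.std(axis=1, ddof=1)
    if standardize:
        keep = sd > 0
        dropped = tuple(
            v for v, k in zip(matrix.variable_ids, keep) if not k
        )
        if dropped:
            logger.warning(
                "dropping %d zero-variance variable(s) before PCA: %s%s",
                len(dropped),
                ", ".join(dropped[:5]),
                "..." if len(dropped) > 5 else "",
            )
        X = X[keep]
        M = (X - X.mean(axis=1, keepdims=True)) / sd[keep][:, None]
        kept = tuple(v for v, k in zip(matrix.variable_ids, keep) if k)
    else:
        M = X - X.mean(axis=1, keepdims=True)
        kept = matrix.variable_ids
        dropped = ()
    return M.T, kept, dropped


def fit_pca(matrix: OmicsMatrix, standardize: bool = True) -> PCADecomposition:
    """PCA over samples-as-observations, variables-as-features.

    With ``standardize=True`` each variable is z-scored first (correlation
    PCA), so the eigenvalues sum to the number of retained variables.
    """
    n = matrix.n_samples
    if n < 3:
        raise DimensionError(f"PCA needs at least 3 samples, got {n}")
    M, kept, dropped = _standardized_data(matrix, standardize)
    if M.shape[1] == 0:
        raise DegenerateInputError("no variables left after dropping zero-variance rows")
    n_components = min(M.shape[1], n - 1)
    U, S, _ = np.linalg.svd(M, full_matrices=False)
    U, S = U[:, :n_components], S[:n_components]
    eigenvalues = S**2 / (n - 1)
    scores = U * S
    total = eigenvalues.sum()
    if total <= 0:
        raise DegenerateInputError("all eigenvalues are zero")
    return PCADecomposition(
        eigenvalues=eigenvalues,
        scores=scores,
        proportion_variance=eigenvalues / total,
        n_variables=len(kept),
        dropped_variables=dropped,
    )


def broken_stick_proportions(p: int) -> np.ndarray:
    """Expected ordered piece lengths ``b_i / p`` of a randomly broken unit stick."""
    inv = 1.0 / np.arange(1, p + 1)
    b = np.cumsum(inv[::-1])[::-1]  # b_i = sum_{k=i}^{p} 1/k
    return b / p


def _check_eigenvalues(eigenvalues) -> np.ndarray:
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.ndim != 1 or len(eig) == 0:
        raise DegenerateInputError("eigenvalues must be a non-empty 1-D sequence")
    if np.any(eig < -1e-12) or np.any(np.diff(eig) > 1e-12):
        raise DegenerateInputError("eigenvalues must be nonnegative and sorted descending")
    if not np.any(eig > 0):
        raise DegenerateInputError("all eigenvalues are zero")
    return np.clip(eig, 0.0, None)


def _leading_run(flags: np.ndarray) -> int:
    count = 0
    for f in flags:
        if not f:
            break
        count += 1
    return count


def broken_stick_count(eigenvalues, n_variables: int | None = None) -> int:
    """Number of leading components beating the broken-stick expectation.

    ``n_variables`` is the *p* of the broken-stick distribution (the number of
    variables in the data); it defaults to the number of eigenvalues, which is
    only correct when the decomposition is full rank.
    """
    eig = _check_eigenvalues(eigenvalues)
    p = int(n_variables) if n_variables is not None else len(eig)
    if p < len(eig):
        raise DegenerateInputError(
            f"n_variables={p} smaller than the number of eigenvalues ({len(eig)})"
        )
    expected = broken_stick_proportions(p)[: len(eig)]
    proportions = eig / eig.sum()
    return _leading_run(proportions > expected)


def kaiser_guttman_count(eigenvalues, n_variables: int | None = None) -> int:
    """Number of eigenvalues strictly above the mean eigenvalue.

    For correlation-matrix PCA the full spectrum (including structural zeros
    when variables outnumber samples) averages exactly 1; passing
    ``n_variables`` accounts for those zeros, making the criterion the
    classical "eigenvalue > 1" rule.
    """
    eig = _check_eigenvalues(eigenvalues)
    p = int(n_variables) if n_variables is not None else len(eig)
    if p < len(eig):
        raise DegenerateInputError(
            f"n_variables={p} smaller than the number of eigenvalues ({len(eig)})"
        )
    mean = eig.sum() / p
    return int(np.sum(eig > mean))


def horn_parallel_count(
    matrix: OmicsMatrix,
    n_randomizations: int = 1000,
    percentile: float = 99.0,
    seed: int | None = None,
    standardize: bool = True,
) -> int:
    """Horn's parallel analysis by per-variable permutation.

    Every variable's values are independently permuted across samples in each
    randomization and the eigenvalue spectrum recomputed; component *i* is
    significant if its observed eigenvalue strictly exceeds the requested
    percentile of the *i*-th randomized eigenvalues. Returns the length of the
    leading run of significant components. Deterministic given ``seed``.
    """
    if n_randomizations < 20:
        raise InsufficientNullError(
            f"Horn's parallel analysis needs >= 20 randomizations, got {n_randomizations}"
        )
    if not 0 < percentile < 100:
        raise DegenerateInputError(f"percentile must be in (0, 100), got {percentile}")
    fit = fit_pca(matrix, standardize=standardize)
    n = matrix.n_samples
    M, _, _ = _standardized_data(matrix, standardize)  # samples x variables
    X = M.T  # variables x samples; permuting rows preserves their mean/scale
    n_components = fit.n_components
    rng = np.random.default_rng(seed)
    null = np.empty((n_randomizations, n_components))
    for b in range(n_randomizations):
        # permuting within a centered row keeps it centered, so no re-centering
        S = np.linalg.svd(rng.permuted(X, axis=1).T, compute_uv=False)
        null[b] = (S[:n_components] ** 2) / (n - 1)
    thresholds = np.percentile(null, percentile, axis=0)
    return _leading_run(fit.eigenvalues > thresholds)


def select_num_pcs(matrix: OmicsMatrix, config: "AnalysisConfig") -> PCSelection:
    """Run all three retention criteria and pick the number of PCs to use.

    If ``config.n_pcs`` is set (default 3) it wins; otherwise the maximum of
    the three criterion counts is used, floored at 1.
    """
    fit = fit_pca(matrix, standardize=config.standardize)
    bs = broken_stick_count(fit.eigenvalues, n_variables=fit.n_variables)
    kg = kaiser_guttman_count(fit.eigenvalues, n_variables=fit.n_variables)
    horn = horn_parallel_count(
        matrix,
        n_randomizations=config.horn_randomizations,
        percentile=config.horn_percentile,
        seed=config.seed,
        standardize=config.standardize,
    )
    if config.n_pcs is not None:
        chosen = int(config.n_pcs)
    else:
        chosen = max(bs, kg, horn, 1)
    logger.info(
        "PC selection: broken-stick=%d kaiser-guttman=%d horn=%d chosen_p=%d",
        bs, kg, horn, chosen,
    )
    return PCSelection(
        broken_stick_count=bs,
        kaiser_guttman_count=kg,
        horn_count=horn,
        chosen_p=chosen,
    )
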