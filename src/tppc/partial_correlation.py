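"""Pearson and higher-order partial correlations of metabolite pairs.

The partial correlation of metabolites *X* and *Y* given a control set *V*
(here: leading PC score vectors of the transcript layer) is defined by the
classical recursion

    r_XY.V = (r_XY.V\\Z - r_XZ.V\\Z * r_YZ.V\\Z)
             / sqrt((1 - r_XZ.V\\Z^2) * (1 - r_YZ.V\\Z^2)),   Z in V,

removing one control at a time until order zero, which is the plain Pearson
correlation. Three equivalent formulations are kept side by side:

* :func:`partial_correlation` -- the recursion above (reference form);
* :func:`partial_correlation_oracle` -- Pearson correlation of least-squares
  residuals after projecting onto the controls plus an intercept (used in
  tests and ``--verify`` style checks);
* :func:`partial_pairs` -- all pairs at once via the Schur complement of the
  joint correlation matrix (conditional covariance renormalised), the fast
  path used by the pipeline.

Their agreement to 1e-8 on random instances is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CollinearityError, DegenerateInputError, DimensionError
from .io_data import OmicsMatrix

__all__ = [
    "ControlSet",
    "COLLINEARITY_GUARD",
    "pearson_pairs",
    "partial_correlation",
    "partial_correlation_oracle",
    "partial_pairs",
]

#: Any (1 - r^2) denominator factor or residual variance below this raises
#: :class:`CollinearityError` instead of silently dividing by ~0.
COLLINEARITY_GUARD = 1e-12


@dataclass(frozen=True)
class ControlSet:
    """Ordered controlling variables (PC score columns), one row per control."""

    vectors: np.ndarray  # shape (order, n_samples)

    def __post_init__(self) -> None:
        vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if vectors.size == 0:
            vectors = vectors.reshape(0, vectors.shape[-1] if vectors.ndim == 2 else 0)
        object.__setattr__(self, "vectors", vectors)
        for i, v in enumerate(vectors):
            if np.ptp(v) == 0:
                raise DegenerateInputError(f"control vector {i} is constant")

    @property
    def order(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_samples(self) -> int:
        return self.vectors.shape[1]

    @classmethod
    def empty(cls, n_samples: int = 0) -> "ControlSet":
        return cls(np.empty((0, n_samples)))

    @classmethod
    def from_scores(cls, scores: np.ndarray, n_controls: int | None = None) -> "ControlSet":
        """Build a control set from a (samples x components) score matrix."""
        scores = np.asarray(scores, dtype=float)
        if n_controls is not None:
            if n_controls > scores.shape[1]:
                raise DimensionError(
                    f"requested {n_controls} controls but only "
                    f"{scores.shape[1]} score columns available"
                )
            scores = scores[:, :n_controls]
        return cls(scores.T)


def _check_not_constant(values: np.ndarray, ids) -> None:
    sd = values.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ids[i] for i in bad[:5]]
        raise DegenerateInputError(
            f"constant metabolite profile(s): {names}"
            f"{'...' if bad.size > 5 else ''}; exclude them before pairing"
        )


def pearson_pairs(metabolites: OmicsMatrix) -> np.ndarray:
    """All-pairs Pearson correlation matrix (zero-order partial correlation)."""
    if metabolites.n_samples < 3:
        raise DimensionError(
            f"need at least 3 samples for correlation, got {metabolites.n_samples}"
        )
    _check_not_constant(metabolites.values, metabolites.variable_ids)
    R = np.corrcoef(metabolites.values)
    R = np.atleast_2d(R)
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return R


def _pcor_recursive(R: np.ndarray, i: int, j: int, controls: tuple[int, ...], cache: dict) -> float:
    """Evaluate the recursion on a precomputed correlation matrix."""
    if not controls:
        return R[i, j]
    key = (i, j, controls)
    hit = cache.get(key)
    if hit is not None:
        return hit
    z, rest = controls[-1], controls[:-1]
    r_ij = _pcor_recursive(R, i, j, rest, cache)
    r_iz = _pcor_recursive(R, i, z, rest, cache)
    r_jz = _pcor_recursive(R, j, z, rest, cache)
    fac_i = 1.0 - r_iz**2
    fac_j = 1.0 - r_jz**2
    if fac_i < COLLINEARITY_GUARD or fac_j < COLLINEARITY_GUARD:
        raise CollinearityError(
            f"control {z - 2} is (near-)collinear with one of the pair "
            f"(1 - r^2 factors {fac_i:.3e}, {fac_j:.3e})"
        )
    value = (r_ij - r_iz * r_jz) / np.sqrt(fac_i * fac_j)
    cache[key] = value
    return value


def _validate_xy_controls(x, y, controls: ControlSet):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise DimensionError(f"x and y lengths differ ({len(x)} vs {len(y)})")
    if controls.order and controls.n_samples != len(x):
        raise DimensionError(
            f"controls have {controls.n_samples} samples but data has {len(x)}"
        )
    if len(x) - 2 - controls.order < 1:
        raise DimensionError(
            f"insufficient residual degrees of freedom: n={len(x)}, "
            f"order={controls.order}"
        )
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise DegenerateInputError(f"{name} is constant")
    return x, y


def partial_correlation(x, y, controls: ControlSet | None = None) -> float:
    """Partial correlation of ``x`` and ``y`` given the control set.

    Controls are eliminated recursively in their stored order (last element
    first); the result is order-invariant, which the test suite asserts. An
    empty control set returns the Pearson correlation.
    """
    controls = controls if controls is not None else ControlSet.empty()
    x, y = _validate_xy_controls(x, y, controls)
    stack = np.vstack([x, y, controls.vectors]) if controls.order else np.vstack([x, y])
    R = np.corrcoef(stack)
    value = _pcor_recursive(R, 0, 1, tuple(range(2, 2 + controls.order)), {})
    return float(np.clip(value, -1.0, 1.0))


def partial_correlation_oracle(x, y, controls: ControlSet | None = None) -> float:
    """Residual-regression formulation; independent check of the recursion.

    Regresses ``x`` and ``y`` on the controls plus an intercept and returns
    the Pearson correlation of the two residual vectors.
    """
    controls = controls if controls is not None else ControlSet.empty()
    x, y = _validate_xy_controls(x, y, controls)
    n = len(x)
    design = np.ones((n, 1))
    if controls.order:
        design = np.column_stack([design, controls.vectors.T])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("rank-deficient control design matrix")
    coeffs, _, _, _ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ coeffs
    var = resid.var(axis=0)
    if np.any(var < COLLINEARITY_GUARD):
        which = "x" if var[0] < COLLINEARITY_GUARD else "y"
        raise CollinearityError(
            f"{which} is (near-)exactly explained by the controls; "
            "degenerate residual"
        )
    r = np.corrcoef(resid[:, 0], resid[:, 1])[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def partial_pairs(metabolites: OmicsMatrix, controls: ControlSet | None = None) -> np.ndarray:
    """All-pairs partial correlation matrix given the control set.

    Computed in one shot from the Schur complement of the joint
    (metabolites + controls) correlation matrix: the conditional covariance
    ``R_mm - R_mv R_vv^{-1} R_vm`` renormalised to unit diagonal. With an
    empty control set this is exactly :func:`pearson_pairs`.
    """
    controls = controls if controls is not None else ControlSet.empty()
    if controls.order == 0:
        return pearson_pairs(metabolites)
    n = metabolites.n_samples
    if controls.n_samples != n:
        raise DimensionError(
            f"controls have {controls.n_samples} samples but data has {n}"
        )
    if n - 2 - controls.order < 1:
        raise DimensionError(
            f"insufficient residual degrees of freedom: n={n}, order={controls.order}"
        )
    _check_not_constant(metabolites.values, metabolites.variable_ids)
    m = metabolites.n_variables
    R = np.corrcoef(np.vstack([metabolites.values, controls.vectors]))
    Rmm, Rmv, Rvv = R[:m, :m], R[:m, m:], R[m:, m:]
    # guard against collinear controls before solving
    if np.linalg.cond(Rvv) > 1.0 / COLLINEARITY_GUARD:
        raise CollinearityError("control vectors are (near-)collinear with each other")
    cond = Rmm - Rmv @ np.linalg.solve(Rvv, Rmv.T)
    diag = np.diag(cond).copy()
    bad = np.flatnonzero(diag < COLLINEARITY_GUARD)
    if bad.size:
        names = [metabolites.variable_ids[i] for i in bad[:5]]
        raise CollinearityError(
            f"metabolite(s) {names} are (near-)exact linear combinations of the controls"
        )
    P = cond / np.sqrt(np.outer(diag, diag))
    np.clip(P, -1.0, 1.0, out=P)
    np.fill_diagonal(P, 1.0)
    return 0.5 * (P + P.T)
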