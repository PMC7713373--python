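"""Low-rank thin-plate regression spline basis for a 1-D covariate.

The nonlinear drought response f(CWB) is represented as a rank-k thin-plate
regression spline: the full thin-plate spline at the observed covariate values
is truncated to its k leading eigen-directions, the constant/linear null space
is removed (intercept and linear CWB effect enter the model through their own
terms), and the basis is rescaled so the smoothing penalty becomes the
identity.  Under that rescaling the degree of smoothing is controlled by a
single variance: independent ``gamma_j ~ N(0, sigma2_smooth)`` priors on the
basis weights are exactly the thin-plate penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ThinPlateBasis", "thin_plate_basis"]


def _radial(x, knots):
    # 1-D thin-plate radial function, eta(r) = |r|^3 (order-2 penalty)
    return np.abs(x[:, None] - knots[None, :]) ** 3


@dataclass(frozen=True)
class ThinPlateBasis:
    """A fitted rank-k thin-plate spline basis; callable at new points."""

    knots: np.ndarray
    coef_map: np.ndarray  # (n_knots, k): delta = coef_map @ gamma
    lin_adjust: np.ndarray  # (2, k): removal of span{1, x} fitted at knots
    k: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "k", self.coef_map.shape[1])

    def __call__(self, x):
        """Evaluate the k basis functions at points ``x`` -> (len(x), k)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        raw = _radial(x, self.knots) @ self.coef_map
        null = np.column_stack([np.ones_like(x), x])
        return raw - null @ self.lin_adjust


def thin_plate_basis(x, k=10, max_knots=200):
    """Construct a rank-``k`` thin-plate regression spline basis on ``x``.

    Parameters
    ----------
    x : array_like
        Covariate values (the CWB z-scores); must contain at least ``k``
        distinct values.
    k : int
        Number of basis columns (default 10).
    max_knots : int
        The full spline uses the unique values of ``x`` as knots, thinned to
        at most ``max_knots`` quantiles for large data.

    Returns
    -------
    ThinPlateBasis
        Callable basis.  ``basis(x)`` has exactly ``k`` columns, each
        orthogonal (at the knots) to the constant and linear functions, and
        scaled so the thin-plate roughness penalty on the weights is the
        identity matrix.
    """
    x = np.asarray(x, dtype=float).ravel()
    knots = np.unique(x)
    if knots.size < k:
        raise ValueError(
            f"need at least k={k} distinct covariate values, got {knots.size}"
        )
    if knots.size > max_knots:
        knots = np.unique(np.quantile(x, np.linspace(0, 1, max_knots)))
    m = knots.size

    E = _radial(knots, knots)
    T = np.column_stack([np.ones(m), knots])

    # truncate the spline space to its k+2 leading eigen-directions, then
    # absorb the two null-space constraints T' delta = 0
    kk = min(k + 2, m)
    vals, vecs = np.linalg.eigh(E)
    order = np.argsort(np.abs(vals))[::-1][:kk]
    U = vecs[:, order]

    C = T.T @ U  # (2, kk)
    _, _, vh = np.linalg.svd(C)
    Z = vh[2:].T  # (kk, kk-2): null space of the constraint

    P = Z.T @ (U.T @ (E @ U)) @ Z  # penalty in constrained coords
    P = 0.5 * (P + P.T)
    pvals, pvecs = np.linalg.eigh(P)
    if np.any(pvals <= 0):
        raise np.linalg.LinAlgError("thin-plate penalty not positive definite")
    keep = np.argsort(pvals)[::-1][:k]
    whiten = pvecs[:, keep] / np.sqrt(pvals[keep])  # penalty -> identity

    coef_map = U @ (Z @ whiten)  # (m, k)

    # centering: project span{1, x} (at the knots) out of the basis columns so
    # the smooth cannot leak into the separately modelled intercept/slope
    raw_at_knots = E @ coef_map
    null = np.column_stack([np.ones(m), knots])
    lin_adjust, *_ = np.linalg.lstsq(null, raw_at_knots, rcond=None)
    return ThinPlateBasis(knots=knots, coef_map=coef_map, lin_adjust=lin_adjust)
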