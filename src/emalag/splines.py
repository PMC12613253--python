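"""Restricted cubic spline (natural spline) bases for exposure-effect curves.

The exposure–symptom dose–response curves are modelled with restricted cubic
splines in the truncated-power parameterisation: a single linear column plus
``k - 2`` nonlinear columns for ``k`` knots.  The basis is linear beyond the
boundary knots, which keeps extrapolated effect curves tame on the bounded
0–10 scale.  The column split into a "linear" and a "nonlinear" component is
what the joint Wald test of an exposure's total contribution operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineSpec", "default_knots", "rcs_basis", "component_index"]

#: quantile conventions for knot placement, per knot count
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


@dataclass(frozen=True)
class SplineSpec:
    """Knot configuration for one exposure's restricted cubic spline.

    Parameters
    ----------
    n_knots
        Number of knots, at least 3.  Three knots give the smallest basis
        with both a linear and a nonlinear component.
    knots
        Explicit knot locations on the raw 0–10 exposure scale.  When
        ``None`` they are placed at the conventional quantiles of the
        observed exposure distribution by :func:`default_knots`.
    """

    n_knots: int = 3
    knots: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_knots < 3:
            raise ValueError("a restricted cubic spline needs at least 3 knots")
        if self.knots is not None:
            k = np.asarray(self.knots, dtype=float)
            if k.size != self.n_knots:
                raise ValueError("len(knots) must equal n_knots")
            if np.any(np.diff(k) <= 0):
                raise ValueError("knots must be strictly increasing")

    @property
    def n_nonlinear(self) -> int:
        return self.n_knots - 2

    def resolve_knots(self, values: np.ndarray | None = None) -> np.ndarray:
        """Return explicit knots, deriving them from ``values`` if needed."""
        if self.knots is not None:
            return np.asarray(self.knots, dtype=float)
        if values is None:
            raise ValueError("knots unspecified and no sample given")
        return default_knots(values, self.n_knots)


def default_knots(values: np.ndarray, n_knots: int = 3) -> np.ndarray:
    """Place knots at the standard equally-spaced quantile positions.

    Three knots sit at the 10th/50th/90th percentiles; larger counts follow
    the usual published quantile tables.  Raises if ties in the sample
    collapse two knots onto the same value.
    """
    if n_knots not in _KNOT_QUANTILES:
        raise ValueError(f"unsupported knot count {n_knots}; use 3-7")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < n_knots:
        raise ValueError(
            f"need at least {n_knots} distinct values to place {n_knots} knots"
        )
    knots = np.quantile(x, _KNOT_QUANTILES[n_knots])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "tied quantiles collapse knots; use fewer knots or supply them explicitly"
        )
    return knots


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at ``x``.

    For knots ``t_1 < ... < t_k`` the basis has ``k - 1`` columns: column 0
    is ``x`` itself, and nonlinear column ``j`` (for ``j = 1..k-2``, using
    1-based knot indices) is

    ``[(x - t_j)+^3 - (x - t_{k-1})+^3 (t_k - t_j)/(t_k - t_{k-1})
       + (x - t_k)+^3 (t_{k-1} - t_j)/(t_k - t_{k-1})] / (t_k - t_1)^2``

    which is zero below ``t_1`` and linear in ``x`` above ``t_k`` — the
    "restricted"/natural constraint.  The division by the squared knot range
    keeps nonlinear columns on roughly the scale of ``x``.
    """
    t = np.asarray(knots, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    k = t.size
    scale = (t[-1] - t[0]) ** 2
    span = t[-1] - t[-2]

    def cube(v: np.ndarray) -> np.ndarray:
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        col = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / span
            + cube(x - t[-1]) * (t[-2] - t[j]) / span
        ) / scale
        cols.append(col)
    return np.column_stack(cols) if x.ndim else np.array(cols)


def component_index(spec: SplineSpec) -> dict[str, list[int]]:
    """Partition basis columns into the linear and nonlinear components.

    The joint exposure test pools both sets; the linear-only contrast uses
    just column 0.
    """
    return {
        "linear": [0],
        "nonlinear": list(range(1, spec.n_knots - 1)),
    }
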