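"""Linear correction of systematic count bias.

Raw density-summation counts regress toward the mean of the training
counts: low-count vials are over-estimated and high-count vials
under-estimated.  Because the effect is linear in the predicted count, an
affine map ``CC = beta * PC + c`` fitted by ordinary least squares of the
actual region counts (AC) on the predicted region counts (PC) removes most
of it.  The fit needs at least three labelled regions; prediction
intervals on corrected counts come from the standard OLS
new-observation formula with n - 2 degrees of freedom.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

MIN_PAIRS = 3  # bias correction is only offered once >= 3 regions are labelled


@dataclass(frozen=True)
class RegionPair:
    """Predicted vs actual count for one labelled region of one image."""

    pc: float
    ac: float
    region_id: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.pc):
            raise ValueError(f"predicted count must be finite, got {self.pc}")
        if self.ac < 0:
            raise ValueError(f"actual count must be >= 0, got {self.ac}")


@dataclass
class BiasModel:
    """Slope/offset of the correction line plus residual statistics."""

    beta: float
    c: float
    pairs: List[RegionPair] = field(default_factory=list)
    # residual statistics for prediction intervals
    n: int = 0
    pc_mean: float = 0.0
    s_xx: float = 0.0
    residual_var: float = 0.0  # SSE / (n - 2)

    @property
    def degenerate(self) -> bool:
        """True when the pairs are exactly collinear (zero residual variance)."""
        return self.residual_var <= 0.0

    def to_json(self) -> str:
        return json.dumps({"beta": self.beta, "c": self.c, "n_pairs": self.n},
                          indent=0)


def fit_bias(pairs: Sequence[RegionPair]) -> BiasModel:
    """OLS of actual on predicted region counts: minimises sum (beta*pc + c - ac)^2."""
    if len(pairs) < MIN_PAIRS:
        raise ValueError(
            f"bias correction needs at least {MIN_PAIRS} labelled regions, "
            f"got {len(pairs)}")
    pc = np.array([p.pc for p in pairs], dtype=np.float64)
    ac = np.array([p.ac for p in pairs], dtype=np.float64)
    if np.ptp(pc) == 0.0:
        raise ValueError(
            "all predicted counts are identical; the correction slope is undefined")
    beta, c = np.polyfit(pc, ac, 1)
    n = len(pairs)
    resid = ac - (beta * pc + c)
    sse = float(resid @ resid)
    # exactly collinear pairs leave only floating-point round-off behind
    if sse <= 1e-20 * n * max(1.0, float((ac * ac).mean())):
        sse = 0.0
    return BiasModel(
        beta=float(beta), c=float(c), pairs=list(pairs),
        n=n, pc_mean=float(pc.mean()),
        s_xx=float(((pc - pc.mean()) ** 2).sum()),
        residual_var=sse / (n - 2) if n > 2 else 0.0,
    )


def apply_bias(b: BiasModel, pc: float) -> float:
    """Corrected count ``CC = beta * pc + c``; never silently clamped."""
    if not np.isfinite(pc):
        raise ValueError(f"predicted count must be finite, got {pc}")
    cc = b.beta * pc + b.c
    if cc < 0:
        warnings.warn(
            f"corrected count {cc:.3f} is negative (pc={pc:.3f}); the input lies "
            "far outside the range of the training regions", stacklevel=2)
    return cc


def corrected_count_interval(b: BiasModel, pc: float,
                             level: float = 0.95) -> Tuple[float, float]:
    """Prediction interval for the corrected count of a new image.

    A new-observation interval (not a confidence interval for the mean):
    the uncertainty fed back to the user concerns a single new vial.  For
    exactly collinear pairs the residual variance is zero and the interval
    collapses to a point; :attr:`BiasModel.degenerate` flags that case.
    """
    cc = b.beta * pc + b.c
    if b.degenerate:
        return (cc, cc)
    se = np.sqrt(b.residual_var * (1.0 + 1.0 / b.n + (pc - b.pc_mean) ** 2 / b.s_xx))
    t = stats.t.ppf(0.5 + level / 2.0, df=b.n - 2)
    return (cc - t * se, cc + t * se)
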