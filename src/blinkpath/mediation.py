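"""Saturated standardized mediation path model with suppression detection.

The model is the classic single-mediator triangle X → M → Y with a direct
path X → Y.  With standardized variables and a saturated (0 df) model the
maximum-likelihood point estimates coincide with the OLS normal-equation
solutions, so all paths have closed forms in the three pairwise
correlations:

    a  = r_xm                                   (X → M)
    b  = (r_my − r_xm·r_xy) / (1 − r_xm²)       (M → Y | X)
    c′ = (r_xy − r_xm·r_my) / (1 − r_xm²)       (X → Y | M)
    c  = r_xy = c′ + a·b                        (total effect; exact identity)

R² of the mediator equation is a², of the outcome equation c′·r_xy + b·r_my.
t statistics use finite-sample OLS forms (df n−2 for a; n−3 for b, c′);
SEM software reports asymptotic critical ratios instead, so t values agree
only approximately while point estimates agree exactly.

Suppression is classified when significant direct and indirect effects
carry opposite signs — the direct path strengthens and/or flips sign once
the mediator enters.  Inconsistent ("indirect-only") mediation is a
significant indirect pathway with a non-significant direct path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationInput",
    "MediationModel",
    "corr_from_data",
    "fit_mediation",
    "fit_mediation_from_data",
    "classify_effect",
    "bootstrap_indirect",
    "BootstrapCI",
]

_PSD_TOL = -1e-10


@dataclass(frozen=True)
class CorrelationInput:
    """The three pairwise correlations among X (predictor), M (mediator),
    Y (outcome), plus the sample size behind them."""

    r_xm: float
    r_xy: float
    r_my: float
    n: int

    def __post_init__(self) -> None:
        for name in ("r_xm", "r_xy", "r_my"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if self.n < 4:
            raise ValueError("n must be at least 4")
        if min(np.linalg.eigvalsh(self.matrix())) < _PSD_TOL:
            raise ValueError("correlation triple is not positive semi-definite")

    def matrix(self) -> np.ndarray:
        """The implied 3×3 correlation matrix, ordered (X, M, Y)."""
        return np.array(
            [
                [1.0, self.r_xm, self.r_xy],
                [self.r_xm, 1.0, self.r_my],
                [self.r_xy, self.r_my, 1.0],
            ]
        )


@dataclass(frozen=True)
class MediationModel:
    """Fitted standardized paths, variance explained, tests and classification."""

    a: float
    b: float
    c_prime: float
    c_total: float
    indirect: float
    r2_m: float
    r2_y: float
    t_a: float
    t_b: float
    t_cprime: float
    p_a: float
    p_b: float
    p_cprime: float
    n: int
    classification: str

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c_prime": self.c_prime,
            "c_total": self.c_total, "indirect": self.indirect,
            "r2_m": self.r2_m, "r2_y": self.r2_y,
            "t_a": self.t_a, "t_b": self.t_b, "t_cprime": self.t_cprime,
            "p_a": self.p_a, "p_b": self.p_b, "p_cprime": self.p_cprime,
            "n": self.n, "classification": self.classification,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def corr_from_data(x, m, y) -> CorrelationInput:
    """Pairwise Pearson correlations of three equal-length raw vectors."""
    x, m, y = (np.asarray(v, dtype=float) for v in (x, m, y))
    if not (x.shape == m.shape == y.shape) or x.ndim != 1:
        raise ValueError("x, m, y must be equal-length 1-d vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if np.std(v) == 0:
            raise ValueError(f"zero-variance input: {name}")
    c = np.corrcoef(np.vstack([x, m, y]))
    return CorrelationInput(r_xm=float(c[0, 1]), r_xy=float(c[0, 2]),
                            r_my=float(c[1, 2]), n=n)


def _paths(r_xm: float, r_xy: float, r_my: float):
    denom = 1.0 - r_xm * r_xm
    c_prime = (r_xy - r_xm * r_my) / denom
    b = (r_my - r_xm * r_xy) / denom
    return c_prime, b


def fit_mediation(c: CorrelationInput, alpha: float = 0.05) -> MediationModel:
    """Fit the saturated standardized mediation model from a correlation triple.

    Point estimates are the closed-form OLS/ML solutions; the total effect
    decomposes exactly as c = c′ + a·b.  Raises on |r_xm| = 1 (the mediator
    equation is collinear).
    """
    if abs(c.r_xm) >= 1.0:
        raise ValueError("collinear predictor and mediator (|r_xm| = 1)")
    a = c.r_xm
    c_prime, b = _paths(c.r_xm, c.r_xy, c.r_my)
    indirect = a * b
    c_total = c.r_xy
    r2_m = a * a
    r2_y = c_prime * c.r_xy + b * c.r_my

    n = c.n
    t_a = a * math.sqrt(n - 2) / math.sqrt(1.0 - a * a)
    se_y = math.sqrt((1.0 - r2_y) / ((n - 3) * (1.0 - c.r_xm ** 2)))
    t_b = b / se_y
    t_cprime = c_prime / se_y
    p_a = 2.0 * stats.t.sf(abs(t_a), df=n - 2)
    p_b = 2.0 * stats.t.sf(abs(t_b), df=n - 3)
    p_cprime = 2.0 * stats.t.sf(abs(t_cprime), df=n - 3)

    model = MediationModel(
        a=a, b=b, c_prime=c_prime, c_total=c_total, indirect=indirect,
        r2_m=r2_m, r2_y=r2_y, t_a=t_a, t_b=t_b, t_cprime=t_cprime,
        p_a=p_a, p_b=p_b, p_cprime=p_cprime, n=n, classification="",
    )
    object.__setattr__(model, "classification", classify_effect(model, alpha))
    return model


def fit_mediation_from_data(x, m, y, alpha: float = 0.05) -> MediationModel:
    """Convenience: correlations from raw vectors, then :func:`fit_mediation`."""
    return fit_mediation(corr_from_data(x, m, y), alpha=alpha)


def classify_effect(model: MediationModel, alpha: float = 0.05) -> str:
    """Classify the fitted triangle.

    - ``suppression``: significant indirect pathway (both a and b) and a
      significant direct path of opposite sign — including the mediator
      strengthens/reverses the direct association.
    - ``indirect-only``: significant indirect pathway, non-significant
      direct path (inconsistent mediation).
    - ``consistent-mediation``: significant indirect pathway and direct
      path sharing its sign.
    - ``no-effect``: anything else.
    """
    indirect_sig = model.p_a < alpha and model.p_b < alpha
    direct_sig = model.p_cprime < alpha
    if indirect_sig and direct_sig:
        if math.copysign(1, model.indirect) != math.copysign(1, model.c_prime):
            return "suppression"
        return "consistent-mediation"
    if indirect_sig:
        return "indirect-only"
    return "no-effect"


class BootstrapCI(NamedTuple):
    estimate: float
    lower: float
    upper: float
    level: float
    replicates: int


def bootstrap_indirect(
    x, m, y,
    replicates: int = 5000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> BootstrapCI:
    """Seeded percentile bootstrap interval for the indirect effect a·b.

    Resamples participants with replacement; each replicate refits the
    closed-form standardized paths on the resampled correlation triple.
    Vectorized over replicates.
    """
    if replicates < 1000:
        raise ValueError("use at least 1000 bootstrap replicates")
    x, m, y = (np.asarray(v, dtype=float) for v in (x, m, y))
    n = x.size
    if n < 10:
        raise ValueError("insufficient n for bootstrap")
    point = fit_mediation_from_data(x, m, y).indirect

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(replicates, n))
    data = np.stack([x, m, y], axis=1)  # (n, 3)
    samp = data[idx]  # (replicates, n, 3)
    mu = samp.mean(axis=1, keepdims=True)
    d = samp - mu
    cov = np.einsum("rni,rnj->rij", d, d) / (n - 1)
    sd = np.sqrt(np.einsum("rii->ri", cov))
    r_xm = cov[:, 0, 1] / (sd[:, 0] * sd[:, 1])
    r_xy = cov[:, 0, 2] / (sd[:, 0] * sd[:, 2])
    r_my = cov[:, 1, 2] / (sd[:, 1] * sd[:, 2])
    denom = 1.0 - r_xm ** 2
    # degenerate resamples (collinear) are excluded from the percentile pool
    ok = denom > 1e-12
    b = (r_my[ok] - r_xm[ok] * r_xy[ok]) / denom[ok]
    indirect = r_xm[ok] * b
    lo, hi = np.quantile(indirect, [(1 - level) / 2, 1 - (1 - level) / 2])
    return BootstrapCI(float(point), float(lo), float(hi), level, int(ok.sum()))
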