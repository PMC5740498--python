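"""Cross-platform rescaling and confidence-weighted joining of scores.

BarSeq and TileSeq scores do not scale linearly to each other.  A
monotonic transform

    f(x) = a * exp(x) + b * x + c,    a >= 0, b > 0

is fitted by least squares between shared variants, standard deviations
are propagated through f by a first-order (Taylor) approximation

    sd' = sd * (a * exp(x) + b),

and matched measurements are then combined by weights inversely
proportional to their standard errors:

    w0 = 1 / (1 + se0/se1),  w1 = 1 / (1 + se1/se0)
    mu_joint     = w0*mu0 + w1*mu1
    sigma_joint^2= w0*(sigma0^2 + mu0^2) + w1*(sigma1^2 + mu1^2) - mu_joint^2
    se_joint     = sigma_joint / sqrt(df0 + df1)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .maps import variant_key

__all__ = [
    "RescaleFit",
    "RescaleModel",
    "fit_rescale",
    "apply_rescale",
    "JoinedScore",
    "join_scores",
    "join_score_maps",
]

logger = logging.getLogger(__name__)

_B_MIN = 1e-9


@dataclass(frozen=True)
class RescaleFit:
    """Coefficients of the monotonic transform f(x) = a e^x + b x + c."""

    a: float
    b: float
    c: float
    rss: float
    n: int

    def __call__(self, x):
        return self.a * np.exp(x) + self.b * x + self.c

    def derivative(self, x):
        return self.a * np.exp(x) + self.b


class RescaleModel:
    """Least-squares fit of the cross-platform transform.

    ``x`` is the platform to be rescaled (TileSeq), ``y`` the target
    scale (BarSeq).  Multi-start constrained least squares: one start
    from an OLS line, one from (0.1, 1, 0).
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, min_pairs: int = 20):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_pairs:
            raise ValueError(f"need >= {min_pairs} shared variants, have {ok.sum()}")
        if np.ptp(x[ok]) == 0:
            raise ValueError("degenerate x range")
        self.x, self.y = x[ok], y[ok]

    def fit(self, tol: float = 1e-10) -> RescaleFit:
        x, y = self.x, self.y
        slope, intercept = np.polyfit(x, y, 1)
        starts = [
            (0.0, max(slope, _B_MIN * 10), intercept),
            (0.1, 1.0, 0.0),
        ]

        def resid(p):
            a, b, c = p
            return a * np.exp(x) + b * x + c - y

        best = None
        for p0 in starts:
            sol = least_squares(
                resid,
                p0,
                bounds=([0.0, _B_MIN, -np.inf], [np.inf, np.inf, np.inf]),
                xtol=tol, ftol=tol, gtol=tol,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success and best.cost > 1e-6:
            raise RuntimeError("rescale fit did not converge")
        a, b, c = best.x
        return RescaleFit(float(a), float(b), float(c), float(2 * best.cost), len(x))


def fit_rescale(pairs) -> RescaleFit:
    """Fit f from (tileseq score, barseq score) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    return RescaleModel(arr[:, 0], arr[:, 1]).fit()


def apply_rescale(score, sd, fit: RescaleFit):
    """Transform a score and its sd through the fitted f."""
    score = np.asarray(score, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out_score = fit(score)
    out_sd = sd * fit.derivative(score)
    if out_score.ndim == 0:
        return float(out_score), float(out_sd)
    return out_score, out_sd


@dataclass(frozen=True)
class JoinedScore:
    mu_joint: float
    sigma_joint: float
    se_joint: float
    df_joint: float
    w0: float
    w1: float


def join_scores(mu0, sigma0, se0, df0, mu1, sigma1, se1, df1) -> JoinedScore:
    """Confidence-weighted combination of two measurements of one variant."""
    mu0, sigma0, se0 = float(mu0), float(sigma0), float(se0)
    mu1, sigma1, se1 = float(mu1), float(sigma1), float(se1)
    if se0 <= 0 or se1 <= 0:
        raise ValueError("standard errors must be positive")
    w0 = 1.0 / (1.0 + se0 / se1)
    w1 = 1.0 / (1.0 + se1 / se0)
    mu = w0 * mu0 + w1 * mu1
    var = w0 * (sigma0**2 + mu0**2) + w1 * (sigma1**2 + mu1**2) - mu**2
    floor = w0 * sigma0**2 + w1 * sigma1**2
    if var < floor:
        # floating-point cancellation can push the mixture variance
        # below its guaranteed lower bound
        logger.warning("sigma_joint^2 clamped at mixture floor (%g < %g)", var, floor)
        var = floor
    sigma = float(np.sqrt(var))
    df = float(df0) + float(df1)
    return JoinedScore(mu, sigma, sigma / np.sqrt(df), df, w0, w1)


def join_score_maps(
    barseq_map: pd.DataFrame,
    tileseq_map: pd.DataFrame,
    fit: RescaleFit | None = None,
) -> pd.DataFrame:
    """Join two score maps variant-by-variant on the BarSeq scale.

    The TileSeq map is first rescaled through ``fit`` (fitted on shared
    variants if not supplied).  Variants present on only one platform
    keep that platform's values; shared variants get joint estimates.
    """
    b = barseq_map.copy()
    t = tileseq_map.copy()
    b["_k"] = variant_key(b)
    t["_k"] = variant_key(t)
    shared = pd.merge(b, t, on="_k", suffixes=("_b", "_t"))
    if fit is None:
        fit = RescaleModel(
            shared["score_t"].to_numpy(), shared["score_b"].to_numpy()
        ).fit()

    t["score"], t["sd"] = apply_rescale(t["score"].to_numpy(), t["sd"].to_numpy(), fit)
    t["se"] = t["se"].to_numpy() * fit.derivative(
        tileseq_map["score"].to_numpy()
    )

    rows = []
    t_idx = t.set_index("_k")
    b_idx = b.set_index("_k")
    for k in sorted(set(b["_k"]) | set(t["_k"])):
        in_b, in_t = k in b_idx.index, k in t_idx.index
        if in_b and in_t:
            rb, rt = b_idx.loc[k], t_idx.loc[k]
            j = join_scores(
                rb.score, rb.sd, rb.se, rb.df, rt.score, rt.sd, rt.se, rt.df
            )
            rows.append(
                {
                    "gene": rb.gene,
                    "position": int(rb.position),
                    "wt_aa": rb.wt_aa,
                    "mut_aa": rb.mut_aa,
                    "score": j.mu_joint,
                    "sd": j.sigma_joint,
                    "se": j.se_joint,
                    "df": j.df_joint,
                    "provenance": "joint",
                }
            )
        else:
            r = b_idx.loc[k] if in_b else t_idx.loc[k]
            rows.append(
                {
                    "gene": r.gene,
                    "position": int(r.position),
                    "wt_aa": r.wt_aa,
                    "mut_aa": r.mut_aa,
                    "score": r.score,
                    "sd": r.sd,
                    "se": r.se,
                    "df": r.df,
                    "provenance": "measured",
                }
            )
    return (
        pd.DataFrame(rows).sort_values(["position", "mut_aa"]).reset_index(drop=True)
    )
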