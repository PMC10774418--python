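"""Quantification formulas for the wet-lab readouts the pipeline mirrors.

Three unrelated but simple quantifications live here:

* ChIP-qPCR relative fold enrichment, ``2^(-dCt)`` with
  ``dCt = Ct_input - Ct_IgG`` (implemented literally; a percent-of-input
  convention is available separately since the literal formula omits the
  specific-antibody Ct).
* Modified-histone array scoring: per-modification binding score = mean
  spot intensity over the mean negative-control intensity, plus the squared
  Pearson correlation of left/right duplicate spots as a concordance check.
* A 1:1 Langmuir binding isotherm fit, ``response = baseline +
  amplitude * c / (Kd + c)``, for titration series (e.g. microscale
  thermophoresis). Amplitude sign is free — an inverted response direction
  is as identifiable as a positive one. Ligand depletion is neglected
  (labeled-partner concentration assumed well below Kd).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class FoldEnrichment:
    """ChIP-qPCR fold enrichment of one target."""

    target: str
    ct_input: float
    ct_igg: float
    delta_ct: float
    fold: float


@dataclass(frozen=True)
class ArrayScores:
    """Per-modification binding scores and duplicate-spot concordance."""

    binding_score: Mapping[str, float]
    duplicate_r2: float


@dataclass(frozen=True)
class TitrationFit:
    """1:1 isotherm fit result; ``converged=False`` marks n.d. (no binding)."""

    kd: float
    amplitude: float
    baseline: float
    rss: float
    converged: bool
    kd_ci: tuple[float, float]


def fold_enrichment(ct_input: float, ct_igg: float, target: str = "") -> FoldEnrichment:
    """Relative fold enrichment ``2^(-dCt)``, ``dCt = Ct_input - Ct_IgG``."""
    if not (math.isfinite(ct_input) and math.isfinite(ct_igg)):
        raise ValueError(f"non-finite Ct values: input={ct_input}, IgG={ct_igg}")
    delta = ct_input - ct_igg
    return FoldEnrichment(target, ct_input, ct_igg, delta, 2.0 ** (-delta))


def percent_of_input(ct_target: float, ct_input: float, input_adjust_cycles: float = 0.0) -> float:
    """Percent-of-input ChIP quantification, ``100 * 2^(Ct_input_adj - Ct_target)``.

    ``input_adjust_cycles`` subtracts the dilution factor of the input
    aliquot (e.g. log2(100) for a 1% input). This is the conventional
    alternative to the literal delta-Ct formula above.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_input)):
        raise ValueError("non-finite Ct values")
    return 100.0 * 2.0 ** ((ct_input - input_adjust_cycles) - ct_target)


def array_scores(table: pd.DataFrame) -> ArrayScores:
    """Score a duplicate-spot array intensity table.

    Expects columns spot_id, modification, left_intensity, right_intensity,
    is_negative_control. The binding score of a modification is the mean of
    its duplicate intensities divided by the mean of all negative-control
    intensities; duplicate_r2 is the squared Pearson correlation of
    (left, right) over all spots.
    """
    required = {"spot_id", "modification", "left_intensity", "right_intensity",
                "is_negative_control"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    for col in ("left_intensity", "right_intensity"):
        bad = table[col].isna()
        if bad.any():
            spot = table.loc[bad.idxmax(), "spot_id"]
            raise ValueError(f"unpaired duplicate: spot {spot!r} lacks {col}")
    neg = table[table["is_negative_control"]]
    if neg.empty:
        raise ValueError("no negative-control spots")
    neg_mean = float(
        np.concatenate([neg["left_intensity"], neg["right_intensity"]]).mean()
    )
    if neg_mean <= 0:
        raise ValueError(f"non-positive negative-control mean intensity: {neg_mean}")
    scores: dict[str, float] = {}
    pos = table[~table["is_negative_control"]]
    for mod, grp in pos.groupby("modification", sort=True):
        mod_mean = float(
            np.concatenate([grp["left_intensity"], grp["right_intensity"]]).mean()
        )
        scores[str(mod)] = mod_mean / neg_mean
    left = table["left_intensity"].to_numpy(dtype=float)
    right = table["right_intensity"].to_numpy(dtype=float)
    if np.ptp(left) == 0 or np.ptp(right) == 0:
        r2 = 1.0 if np.array_equal(left, right) else 0.0
    else:
        r2 = float(np.corrcoef(left, right)[0, 1] ** 2)
    return ArrayScores(binding_score=scores, duplicate_r2=r2)


# ---------------------------------------------------------------------------
# 1:1 binding isotherm


def _isotherm_rss(log_kd: float, c: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Profile RSS over (baseline, amplitude) at fixed Kd; linear sub-problem."""
    f = c / (np.exp(log_kd) + c)
    design = np.column_stack([np.ones_like(c), f])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


def fit_kd(
    table: pd.DataFrame,
    start_grid: Sequence[float] | None = None,
    nd_alpha: float = 0.05,
    ci_level: float = 0.95,
) -> TitrationFit:
    """Least-squares 1:1 isotherm fit of a concentration/response table.

    Kd positivity is enforced by fitting on log Kd; a log-spaced multi-start
    grid (default: two decades beyond the sampled concentration range)
    guards against local minima, followed by scalar refinement. Baseline and
    amplitude are profiled out linearly at each Kd.

    "No binding" (n.d., ``converged=False``) is declared when the isotherm
    does not improve on a flat line: an F-test of the two extra parameters
    at level ``nd_alpha``. The Kd confidence interval is a profile interval
    from the F threshold on the RSS ratio; bounds touching the search grid
    indicate an unidentifiable side.
    """
    c = table["concentration"].to_numpy(dtype=float)
    y = table["response"].to_numpy(dtype=float)
    if np.any(~np.isfinite(c)) or np.any(~np.isfinite(y)):
        raise ValueError("non-finite concentration or response values")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    n = len(c)
    if n < 4:
        raise ValueError(f"need at least 4 points to fit 3 parameters, got {n}")
    if n < 6:
        warnings.warn("fewer than 6 titration points; fit may be poorly determined",
                      stacklevel=2)
    if start_grid is None:
        start_grid = np.geomspace(c.min() / 100.0, c.max() * 100.0, 60)
    log_grid = np.log(np.asarray(start_grid, dtype=float))

    rss_grid = np.array([_isotherm_rss(lk, c, y)[0] for lk in log_grid])
    i_best = int(np.argmin(rss_grid))
    lo = log_grid[max(0, i_best - 1)]
    hi = log_grid[min(len(log_grid) - 1, i_best + 1)]
    res = optimize.minimize_scalar(
        lambda lk: _isotherm_rss(lk, c, y)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    log_kd = float(res.x) if res.fun <= rss_grid[i_best] else float(log_grid[i_best])
    rss, baseline, amplitude = _isotherm_rss(log_kd, c, y)
    kd = float(np.exp(log_kd))

    # flat-line comparison: does the isotherm explain anything at all?
    rss_flat = float(np.sum((y - y.mean()) ** 2))
    dof = n - 3
    if rss_flat <= 0:
        converged = False
    elif rss <= 0:
        converged = True
    else:
        f_stat = ((rss_flat - rss) / 2.0) / (rss / dof)
        converged = bool(stats.f.sf(f_stat, 2, dof) < nd_alpha)

    # profile CI on Kd: crossing points of RSS(kd) with the F threshold
    if converged and rss > 0 and dof > 0:
        thresh = rss * (1.0 + stats.f.ppf(ci_level, 1, dof) / dof)

        def excess(lk: float) -> float:
            return _isotherm_rss(lk, c, y)[0] - thresh

        lo_bound = float(log_grid[0])
        hi_bound = float(log_grid[-1])
        ci_lo = math.exp(lo_bound)
        if excess(lo_bound) > 0:
            ci_lo = float(np.exp(optimize.brentq(excess, lo_bound, log_kd, xtol=1e-9)))
        ci_hi = math.exp(hi_bound)
        if excess(hi_bound) > 0:
            ci_hi = float(np.exp(optimize.brentq(excess, log_kd, hi_bound, xtol=1e-9)))
        kd_ci = (min(ci_lo, kd), max(ci_hi, kd))
    else:
        kd_ci = (math.nan, math.nan)

    return TitrationFit(
        kd=kd,
        amplitude=amplitude,
        baseline=baseline,
        rss=rss,
        converged=converged,
        kd_ci=kd_ci,
    )
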