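"""Reconstruction quality metrics and parameter-sweep ranking.

RMSE is evaluated against the ground-truth map over an evaluation mask;
CNR between inclusion and background regions is
``2 (mu_inc - mu_bkg)^2 / (var_inc + var_bkg)`` (population variances),
computed only for cases whose ground-truth contrast is at least 1%.  For
plane-wave results a 10% lateral margin is masked on both sides (angled-PW
apodization artifacts); the same region is used for diverging-wave results
for a fair comparison.  Parameter sweeps are ranked by mean RMSE
(ascending) and mean CNR (descending); the optimum minimizes the average
rank.  Method comparisons use a paired two-sided Wilcoxon signed-rank
test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import Grid
from .phantoms import SoSMap

__all__ = ["EvalResult", "rmse", "cnr", "pw_side_mask", "sweep_and_rank",
           "paired_compare", "CNR_MIN_CONTRAST"]

CNR_MIN_CONTRAST = 0.01  # inclusions below 1% contrast get no CNR


@dataclass
class EvalResult:
    rmse: float
    cnr: float | None
    case_id: int | str | None = None
    method: str | None = None
    params: dict | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def rmse(recon: SoSMap, truth: SoSMap, eval_mask: np.ndarray | None = None,
         ) -> float:
    """Root-mean-square error (m/s) over `eval_mask` (full grid if None)."""
    if recon.values.shape != truth.values.shape:
        raise ValueError("recon and truth grids must be congruent")
    mask = np.ones(recon.values.shape, bool) if eval_mask is None else eval_mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty evaluation mask")
    diff = recon.values[mask] - truth.values[mask]
    return float(np.sqrt(np.sum(diff * diff) / n))


def cnr(recon: SoSMap, inclusion_mask: np.ndarray,
        background_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio between inclusion and background regions."""
    if not inclusion_mask.any() or not background_mask.any():
        raise ValueError("both masks must be non-empty")
    if np.any(inclusion_mask & background_mask):
        raise ValueError("inclusion and background masks must be disjoint")
    inc = recon.values[inclusion_mask]
    bkg = recon.values[background_mask]
    var = inc.var() + bkg.var()  # population variances
    if var == 0:
        raise ValueError("CNR undefined: both region variances are zero")
    return float(2.0 * (inc.mean() - bkg.mean()) ** 2 / var)


def pw_side_mask(grid: Grid, fraction: float = 0.10) -> np.ndarray:
    """Evaluation mask excluding the leftmost and rightmost `fraction` of
    lateral columns."""
    if not 0.0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    ncut = int(np.floor(fraction * grid.nx))
    mask = np.zeros(grid.shape, dtype=bool)
    mask[ncut:grid.nx - ncut, :] = True
    return mask


def sweep_and_rank(results: list[EvalResult],
                   param_keys: tuple[str, ...] = ("lam", "delta")) -> dict:
    """Select the optimal parameter setting over a case sweep.

    `results` carries one EvalResult per (case, parameter setting); the
    setting is read from ``result.params`` at `param_keys`.  Mean RMSE and
    mean CNR per setting are ranked (RMSE ascending, CNR descending) and
    the setting with minimal average rank wins; ties break toward lower
    first key (lambda), then smaller second.
    """
    by_setting: dict[tuple, list[EvalResult]] = {}
    for r in results:
        key = tuple(r.params[k] for k in param_keys)
        by_setting.setdefault(key, []).append(r)
    if len(by_setting) < 2:
        raise ValueError("sweep needs at least 2 parameter settings")
    settings = sorted(by_setting)
    mean_rmse = np.array([np.mean([r.rmse for r in by_setting[s]])
                          for s in settings])
    mean_cnr = np.array([np.mean([r.cnr for r in by_setting[s]
                                  if r.cnr is not None] or [0.0])
                         for s in settings])
    rank_rmse = stats.rankdata(mean_rmse, method="average")
    rank_cnr = stats.rankdata(-mean_cnr, method="average")
    avg_rank = 0.5 * (rank_rmse + rank_cnr)
    best = min(range(len(settings)), key=lambda i: (avg_rank[i], settings[i]))
    return dict(optimum=settings[best],
                table={s: dict(mean_rmse=float(mean_rmse[i]),
                               mean_cnr=float(mean_cnr[i]),
                               avg_rank=float(avg_rank[i]))
                       for i, s in enumerate(settings)})


def paired_compare(results_a, results_b, alpha: float = 0.05
                   ) -> tuple[float, float, bool]:
    """Paired two-sided Wilcoxon signed-rank test on per-case metric values.

    Returns ``(statistic, p_value, significant at alpha)``; identical
    samples give p = 1 (no difference)."""
    a = np.asarray(results_a, dtype=float)
    b = np.asarray(results_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired comparison needs equal-length case sets")
    if a.size < 6:
        raise ValueError(f"paired test needs >= 6 cases, got {a.size}")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0, False
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox", mode="auto")
    return float(stat), float(p), bool(p < alpha)
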