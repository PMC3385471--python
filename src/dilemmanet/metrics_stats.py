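"""Population-level measurements and the statistical analyses of runs.

The central quantity is the selection gradient for intelligence: the
within-generation population covariance between fitness and intelligence, the
selection differential of the Price equation. Supporting analyses are

* a Gaussian-kernel-smoothed surface of that covariance over the plane of
  (current cooperation frequency, change in cooperation since the previous
  generation), with infeasible combinations masked;
* Spearman rank correlations between population summaries (mean intelligence
  vs cooperation; each canonical-strategy frequency vs the selection
  gradient), overall and stratified into low/high cooperation regimes; and
* a Breusch-Pagan test for cooperation variance increasing with mean
  intelligence, reported via the auxiliary regression's intercept and slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .strategy_analysis import STRATEGY_NAMES

__all__ = [
    "selection_gradient",
    "cooperation_frequency",
    "delta_series",
    "SelectionSurface",
    "build_selection_surface",
    "SpearmanResult",
    "BreuschPaganResult",
    "AnalysisReport",
    "analyze_runs",
]


def selection_gradient(
    fitnesses: Sequence[float], intelligences: Sequence[float]
) -> float:
    """Population covariance between fitness and intelligence.

    The divisor is ``n`` (not ``n-1``): this is the realised selection
    differential over the population, not an estimate of a parent
    distribution's covariance.
    """
    f = np.asarray(fitnesses, dtype=np.float64)
    i = np.asarray(intelligences, dtype=np.float64)
    if f.shape != i.shape or f.ndim != 1:
        raise ValueError("fitnesses and intelligences must be equal-length 1-d")
    if f.shape[0] < 2:
        raise ValueError("need at least 2 individuals for a covariance")
    return float(np.mean((f - f.mean()) * (i - i.mean())))


def cooperation_frequency(n_cooperate: int, n_moves: int) -> float:
    """Fraction of cooperative moves among all moves of a generation."""
    if n_moves <= 0:
        raise ValueError("no moves recorded")
    return n_cooperate / n_moves


def delta_series(frequencies: Sequence[float]) -> np.ndarray:
    """Per-generation change in cooperation frequency (NaN for the first)."""
    f = np.asarray(frequencies, dtype=np.float64)
    out = np.full_like(f, np.nan)
    out[1:] = f[1:] - f[:-1]
    return out


# ---------------------------------------------------------------------------
# selection surface


@dataclass
class SelectionSurface:
    """Smoothed selection gradient over (cooperation frequency, delta).

    ``values`` is NaN where ``mask`` is True: combinations where the implied
    previous-generation frequency ``freq - delta`` falls outside [0, 1] are
    impossible and never estimated.
    """

    freq_grid: np.ndarray  # (nf,)
    delta_grid: np.ndarray  # (nd,)
    values: np.ndarray  # (nf, nd)
    mask: np.ndarray  # (nf, nd) bool, True = impossible combination
    bandwidths: Tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        ff, dd = np.meshgrid(self.freq_grid, self.delta_grid, indexing="ij")
        return pd.DataFrame(
            {
                "cooperation_frequency": ff.ravel(),
                "delta_cooperation": dd.ravel(),
                "value": self.values.ravel(),
                "masked": self.mask.ravel(),
            }
        )


def _silverman(x: np.ndarray) -> float:
    n = x.shape[0]
    sd = float(np.std(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        return 0.1  # degenerate spread: fall back to a tenth of the unit axis
    return 0.9 * scale * n ** (-0.2)


def build_selection_surface(
    records: pd.DataFrame,
    bandwidths: Optional[Tuple[float, float]] = None,
    grid_size: Tuple[int, int] = (41, 81),
) -> SelectionSurface:
    """Nadaraya-Watson smoothing of ``cov_fitness_intelligence`` over the
    (cooperation_frequency, delta_cooperation) plane.

    ``records`` needs columns ``cooperation_frequency``, ``delta_cooperation``
    and ``cov_fitness_intelligence``; rows with NaN delta (first generations)
    are dropped. Bandwidths default to Silverman's rule per axis.
    """
    cols = ["cooperation_frequency", "delta_cooperation", "cov_fitness_intelligence"]
    data = records[cols].dropna()
    if len(data) == 0:
        raise ValueError("no usable records (all deltas NaN?)")
    f = data["cooperation_frequency"].to_numpy()
    d = data["delta_cooperation"].to_numpy()
    c = data["cov_fitness_intelligence"].to_numpy()
    if bandwidths is None:
        bandwidths = (_silverman(f), _silverman(d))
    hf, hd = bandwidths
    freq_grid = np.linspace(0.0, 1.0, grid_size[0])
    delta_grid = np.linspace(-1.0, 1.0, grid_size[1])
    # weights: (nf, nd, n) would be large; loop over the frequency axis
    values = np.empty((grid_size[0], grid_size[1]), dtype=np.float64)
    wd = np.exp(-0.5 * ((delta_grid[:, None] - d[None, :]) / hd) ** 2)  # (nd, n)
    for a, gf in enumerate(freq_grid):
        wf = np.exp(-0.5 * ((gf - f) / hf) ** 2)  # (n,)
        w = wd * wf[None, :]
        sw = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            values[a] = np.where(sw > 0, (w * c[None, :]).sum(axis=1) / sw, np.nan)
    prev = freq_grid[:, None] - delta_grid[None, :]
    mask = (prev < 0.0) | (prev > 1.0)
    values[mask] = np.nan
    return SelectionSurface(
        freq_grid=freq_grid,
        delta_grid=delta_grid,
        values=values,
        mask=mask,
        bandwidths=(float(hf), float(hd)),
    )


# ---------------------------------------------------------------------------
# correlation / heteroskedasticity report


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class BreuschPaganResult:
    """Auxiliary-regression view of the Breusch-Pagan test.

    ``intercept`` and ``slope`` come from regressing the squared OLS
    residuals of cooperation on mean intelligence; ``lm`` and ``p_value``
    are the LM statistic of the chosen variant ('classical' scales the
    squared residuals by their mean and uses ESS/2; 'koenker' uses n*R^2).
    """

    intercept: float
    slope: float
    lm: float
    p_value: float
    variant: str
    n: int


@dataclass
class AnalysisReport:
    intelligence_cooperation: SpearmanResult
    strategy_selection: Dict[str, Dict[str, Optional[SpearmanResult]]]
    breusch_pagan: BreuschPaganResult
    stratification_threshold: float

    def to_dict(self) -> dict:
        def sp(r):
            return None if r is None else {"rho": r.rho, "p_value": r.p_value, "n": r.n}

        return {
            "intelligence_cooperation": sp(self.intelligence_cooperation),
            "strategy_selection": {
                name: {stratum: sp(r) for stratum, r in strata.items()}
                for name, strata in self.strategy_selection.items()
            },
            "breusch_pagan": {
                "intercept": self.breusch_pagan.intercept,
                "slope": self.breusch_pagan.slope,
                "lm": self.breusch_pagan.lm,
                "p_value": self.breusch_pagan.p_value,
                "variant": self.breusch_pagan.variant,
                "n": self.breusch_pagan.n,
            },
            "stratification_threshold": self.stratification_threshold,
        }


def _spearman(x: np.ndarray, y: np.ndarray) -> Optional[SpearmanResult]:
    if x.shape[0] < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p), n=int(x.shape[0]))


def breusch_pagan(
    y: np.ndarray, x: np.ndarray, variant: Literal["classical", "koenker"] = "classical"
) -> BreuschPaganResult:
    """Breusch-Pagan test of Var(y|x) depending on x.

    Fits ``y ~ x`` by OLS, then the auxiliary regression of the squared
    residuals on x. The reported intercept/slope are from the raw squared
    residual regression (interpretable on the data's variance scale),
    whichever LM variant is requested.
    """
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    X = sm.add_constant(x)
    resid = sm.OLS(y, X).fit().resid
    e2 = resid**2
    aux_raw = sm.OLS(e2, X).fit()
    intercept, slope = (float(b) for b in aux_raw.params)
    if variant == "koenker":
        lm = n * aux_raw.rsquared
    elif variant == "classical":
        g = e2 / e2.mean()
        aux_g = sm.OLS(g, X).fit()
        lm = float(aux_g.ess / 2.0)
    else:
        raise ValueError(f"unknown Breusch-Pagan variant {variant!r}")
    p = float(stats.chi2.sf(lm, 1))
    return BreuschPaganResult(
        intercept=intercept, slope=slope, lm=float(lm), p_value=p, variant=variant, n=n
    )


def analyze_runs(
    records: pd.DataFrame,
    stratification_threshold: float = 0.5,
    bp_variant: Literal["classical", "koenker"] = "classical",
) -> AnalysisReport:
    """The standard correlation report over pooled per-generation records.

    ``records`` must carry columns ``cooperation_frequency``,
    ``mean_intelligence``, ``cov_fitness_intelligence`` and the four
    ``n_<strategy>`` count columns (counts are converted to frequencies by
    their per-row sum). Generations from multiple replicates may be pooled;
    pass a single replicate's frame for a per-replicate analysis.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 generations of records")
    coop = records["cooperation_frequency"].to_numpy(dtype=np.float64)
    mi = records["mean_intelligence"].to_numpy(dtype=np.float64)
    cov = records["cov_fitness_intelligence"].to_numpy(dtype=np.float64)
    count_cols = [f"n_{name}" for name in STRATEGY_NAMES]
    counts = records[count_cols].to_numpy(dtype=np.float64)
    pop = counts.sum(axis=1)
    freqs = counts / pop[:, None]

    strata_masks = {
        "overall": np.ones_like(coop, dtype=bool),
        "low_cooperation": coop < stratification_threshold,
        "high_cooperation": coop >= stratification_threshold,
    }
    strategy_selection: Dict[str, Dict[str, Optional[SpearmanResult]]] = {}
    for j, name in enumerate(STRATEGY_NAMES):
        strategy_selection[name] = {}
        for stratum, m in strata_masks.items():
            if m.sum() < 3:
                strategy_selection[name][stratum] = None
            else:
                strategy_selection[name][stratum] = _spearman(freqs[m, j], cov[m])

    return AnalysisReport(
        intelligence_cooperation=_spearman(mi, coop),
        strategy_selection=strategy_selection,
        breusch_pagan=breusch_pagan(coop, mi, bp_variant),
        stratification_threshold=stratification_threshold,
    )
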