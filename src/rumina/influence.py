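"""Cook's-distance censoring of taxon tables.

Each taxon's proportions are regressed (simple linear regression) against a
kinetic response across samples; taxa containing an observation whose Cook's
influence distance exceeds the chosen F quantile are removed.  Rare taxa that
are present in only one or two samples produce extreme leverage/residual
combinations and are the intended casualties of this filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

logger = logging.getLogger(__name__)


class InfluenceError(ValueError):
    """Raised on invalid influence-filter inputs."""


def cooks_distances(x, y) -> np.ndarray:
    """Cook's distance of every observation in the regression y ~ 1 + x.

    For simple linear regression with p = 2 coefficients,
    ``D_i = e_i^2 / (p s^2) * h_ii / (1 - h_ii)^2`` with ``s^2 = RSS/(n-2)``
    and ``h_ii`` the hat-matrix diagonal.  This equals the leave-one-out
    refit definition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InfluenceError("x and y must be aligned 1-d vectors")
    n = x.size
    if n < 4:
        raise InfluenceError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise InfluenceError("constant predictor: leverage undefined")

    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    beta1 = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    beta0 = float(y.mean() - beta1 * xbar)
    resid = y - (beta0 + beta1 * x)
    h = 1.0 / n + (x - xbar) ** 2 / sxx
    rss = float(np.sum(resid**2))
    p = 2
    s2 = rss / (n - p)
    if s2 == 0:
        return np.zeros(n)
    d = np.empty(n)
    # a leverage-one point (e.g. a taxon present in a single sample) fully
    # determines the slope: its influence is unbounded, not 0/0
    perfect = h >= 1.0 - 1e-12
    d[perfect] = np.inf
    with np.errstate(divide="ignore"):
        d[~perfect] = (
            resid[~perfect] ** 2 / (p * s2) * h[~perfect]
            / (1.0 - h[~perfect]) ** 2
        )
    return d


@dataclass
class InfluenceReport:
    """Per-taxon influence summary plus the global threshold used."""

    table: pd.DataFrame  # taxon, max_cooks_d, flagged_sample, removed, note
    threshold: float
    df: tuple[int, int]
    alpha: float
    n: int

    @property
    def removed(self) -> list[str]:
        return list(self.table.loc[self.table["removed"], "taxon"])


def filter_taxa(
    data: pd.DataFrame,
    response: pd.Series,
    alpha: float = 0.05,
    df: tuple[int, int] | None = None,
    renormalize: bool = False,
) -> tuple[pd.DataFrame, InfluenceReport]:
    """Remove taxa whose regression on ``response`` has a significant Cook's D.

    ``data`` is samples x taxa (proportions or clade sums); ``response`` must
    share the sample index.  The threshold is the upper ``alpha`` quantile of
    an F distribution with ``df`` degrees of freedom, default ``(2, n - 2)``;
    pass a fixed pair such as ``(2, 28)`` to reproduce a printed criterion
    regardless of n.  All taxa are tested simultaneously against the original
    response, so removal is order-independent.  Taxa with constant
    proportions cannot be regressed and are retained with a logged note.
    """
    if not 0 < alpha < 1:
        raise InfluenceError("alpha must be in (0, 1)")
    if set(data.index) != set(response.index):
        raise InfluenceError("sample keys of table and response do not align")
    response = response.reindex(data.index)
    n = len(data)
    df_pair = df if df is not None else (2, n - 2)
    if df_pair[0] <= 0 or df_pair[1] <= 0:
        raise InfluenceError(f"invalid degrees of freedom {df_pair}")
    threshold = float(f_dist.ppf(1.0 - alpha, *df_pair))

    y = response.to_numpy(float)
    records = []
    removed_cols = []
    for taxon in data.columns:
        x = data[taxon].to_numpy(float)
        if np.ptp(x) == 0:
            logger.info("taxon %s constant across samples; skipped", taxon)
            records.append(
                {
                    "taxon": taxon,
                    "max_cooks_d": np.nan,
                    "flagged_sample": "",
                    "removed": False,
                    "note": "constant",
                }
            )
            continue
        d = cooks_distances(x, y)
        i = int(np.argmax(d))
        is_removed = bool(d[i] > threshold)
        if is_removed:
            removed_cols.append(taxon)
        records.append(
            {
                "taxon": taxon,
                "max_cooks_d": float(d[i]),
                "flagged_sample": str(data.index[i]),
                "removed": is_removed,
                "note": "",
            }
        )
    report = InfluenceReport(
        table=pd.DataFrame.from_records(records),
        threshold=threshold,
        df=tuple(df_pair),
        alpha=alpha,
        n=n,
    )
    censored = data.drop(columns=removed_cols)
    if renormalize and len(censored.columns):
        sums = censored.sum(axis=1)
        censored = censored.div(sums.where(sums > 0, 1.0), axis=0)
    return censored, report
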