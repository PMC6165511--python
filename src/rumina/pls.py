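"""Partial least squares regression (NIPALS) with VIP scoring.

Implements PLS1/PLS2 from scratch: column standardisation, NIPALS extraction
with deflation of both blocks, leave-one-out PRESS selection of the number of
latent vectors, fraction of response variation explained, variable importance
in projection (VIP) scores and signed percentile association lists.

All model fitting operates on standardised matrices; the higher-level
wrappers (:func:`clade_comparison`, :func:`genus_associations`) handle
standardisation, cross-validation and report assembly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 10_000


class PLSError(ValueError):
    """Raised on invalid PLS inputs or a non-convergent inner loop."""


@dataclass
class StandardizationStats:
    """Per-column means/sds plus which columns survived (non-constant)."""

    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray  # boolean mask over the original columns
    dropped: list[int] = field(default_factory=list)

    def transform(self, M: np.ndarray) -> np.ndarray:
        return (np.asarray(M, float)[:, self.kept] - self.means) / self.sds

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) * self.sds + self.means


def standardize(M) -> tuple[np.ndarray, StandardizationStats]:
    """Center and scale columns to mean 0, sample sd 1 (ddof = 1).

    Constant columns cannot be scaled; they are dropped with a warning and
    recorded in the returned stats.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[0] < 2:
        raise PLSError("standardization needs at least 2 rows")
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    kept = sds > 0
    dropped = list(np.flatnonzero(~kept))
    if dropped:
        logger.warning("dropping %d constant column(s): %s", len(dropped), dropped)
    stats = StandardizationStats(means=means[kept], sds=sds[kept], kept=kept,
                                 dropped=dropped)
    return stats.transform(M), stats


@dataclass
class PLSModel:
    """Fitted NIPALS model on standardised blocks.

    ``W`` (p x A) holds unit-norm weight vectors, ``T`` (n x A) scores,
    ``P`` (p x A) X-loadings and ``Q`` (m x A) Y-loadings.  ``r2y_path``
    is the cumulative fraction of Y variance explained after 1..A
    components; ``press_by_A`` is filled by the cross-validated selector.
    """

    A: int
    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    r2y_path: np.ndarray
    x_stats: StandardizationStats | None = None
    y_stats: StandardizationStats | None = None
    press_by_A: np.ndarray | None = None

    @property
    def r2y_cum(self) -> float:
        return float(self.r2y_path[self.A - 1])

    def coefficients(self, A: int | None = None) -> np.ndarray:
        """Regression coefficients B (p x m) on the standardised scale.

        ``B = W (P'W)^{-1} Q'`` using the first ``A`` components.
        """
        A = self.A if A is None else A
        W, P, Q = self.W[:, :A], self.P[:, :A], self.Q[:, :A]
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def predict(self, Xz: np.ndarray, A: int | None = None) -> np.ndarray:
        """Predict standardised Y from standardised X rows."""
        return np.asarray(Xz, float) @ self.coefficients(A)


def fit_pls(X: np.ndarray, Y: np.ndarray, A: int) -> PLSModel:
    """NIPALS PLS with deflation of both X and Y.

    ``X`` (n x p) and ``Y`` (n x m) are assumed standardised.  For a single
    response the first weight vector is the normalised ``X'y`` (no inner
    iteration needed); for multiple responses the classical power iteration
    on (w, t, q, u) runs until the score direction stabilises.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = Y.shape[1]
    if not 1 <= A <= min(n - 1, p):
        raise PLSError(f"A={A} out of range [1, min(n-1, p)={min(n - 1, p)}]")

    ss_y_total = float(np.sum(Y**2))
    if ss_y_total == 0:
        raise PLSError("response block has zero variance")

    Xd, Yd = X.copy(), Y.copy()
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    Q = np.zeros((m, A))
    r2y_path = np.zeros(A)

    for a in range(A):
        if m == 1:
            w = Xd.T @ Yd[:, 0]
            norm = np.linalg.norm(w)
            if norm == 0:
                # no covariance left; stop extracting informative directions
                w = np.zeros(p)
                w[0] = 1.0
            else:
                w = w / norm
            t = Xd @ w
        else:
            u = Yd[:, int(np.argmax(np.sum(Yd**2, axis=0)))].copy()
            t = np.zeros(n)
            w = np.zeros(p)
            for it in range(_NIPALS_MAX_ITER):
                w_new = Xd.T @ u
                norm = np.linalg.norm(w_new)
                if norm == 0:
                    w_new = np.zeros(p)
                    w_new[0] = 1.0
                else:
                    w_new = w_new / norm
                t_new = Xd @ w_new
                q = Yd.T @ t_new
                qn = np.linalg.norm(q)
                if qn == 0:
                    break
                u = Yd @ q / qn
                if np.linalg.norm(t_new - t) <= _NIPALS_TOL * max(
                    1.0, np.linalg.norm(t_new)
                ):
                    w, t = w_new, t_new
                    break
                w, t = w_new, t_new
            else:
                raise PLSError(
                    f"NIPALS inner loop failed to converge at component {a + 1}"
                    f" after {_NIPALS_MAX_ITER} iterations"
                )
        tt = float(t @ t)
        if tt == 0:
            # deflated X is exhausted; keep zero vectors for remaining comps
            r2y_path[a:] = r2y_path[a - 1] if a else 0.0
            W[:, a] = w
            break
        p_load = Xd.T @ t / tt
        q_load = Yd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, q_load)
        W[:, a] = w
        T[:, a] = t
        P[:, a] = p_load
        Q[:, a] = q_load
        r2y_path[a] = 1.0 - float(np.sum(Yd**2)) / ss_y_total

    return PLSModel(A=A, W=W, T=T, P=P, Q=Q, r2y_path=r2y_path)


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection for each predictor.

    ``VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a)`` where
    ``SSY_a = |q_a|^2 (t_a' t_a)`` is the Y sum of squares captured by
    component ``a``.  The scores satisfy ``sum_j VIP_j^2 = p``.
    """
    A = model.A
    p = model.W.shape[0]
    ssy = np.array(
        [
            float(model.Q[:, a] @ model.Q[:, a]) * float(model.T[:, a] @ model.T[:, a])
            for a in range(A)
        ]
    )
    total = ssy.sum()
    if total <= 0:
        raise PLSError("zero explained response variance: VIP undefined")
    w2 = model.W[:, :A] ** 2
    return np.sqrt(p * (w2 @ ssy) / total)


def loo_select_components(
    X: np.ndarray,
    Y: np.ndarray,
    A_max: int,
    restandardize: bool = True,
) -> tuple[int, np.ndarray]:
    """Leave-one-out PRESS over candidate component counts.

    For each A in 1..A_max every sample is held out once, the model is
    refitted on the remainder (re-standardising within the training fold
    unless ``restandardize`` is False) and the held-out row predicted.
    PRESS sums squared prediction errors over all responses in original Y
    units.  Returns ``(A*, press_by_A)`` where A* minimises PRESS, ties
    resolved towards the smaller A.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n < 3:
        raise PLSError("leave-one-out selection needs at least 3 samples")
    hard_cap = min(n - 2, p)  # training folds have n-1 rows
    if A_max > hard_cap:
        logger.warning("A_max=%d truncated to %d (n=%d, p=%d)", A_max, hard_cap, n, p)
        A_max = hard_cap
    if A_max < 1:
        raise PLSError("no admissible component count")

    press = np.zeros(A_max)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, Y_tr = X[mask], Y[mask]
        if restandardize:
            Xz, xs = standardize(X_tr)
            Yz, ys = standardize(Y_tr)
            x_new = xs.transform(X[i : i + 1])
        else:
            Xz, Yz = X_tr, Y_tr
            xs = ys = None
            x_new = X[i : i + 1]
        model = fit_pls(Xz, Yz, A_max)
        for A in range(1, A_max + 1):
            yhat_z = model.predict(x_new, A)
            if restandardize:
                yhat = ys.inverse(yhat_z)
                y_true = Y[i : i + 1][:, ys.kept]
            else:
                yhat = yhat_z
                y_true = Y[i : i + 1]
            press[A - 1] += float(np.sum((y_true - yhat) ** 2))

    best = int(np.argmin(press)) + 1  # argmin takes the first (smallest A) tie
    return best, press


@dataclass
class AssociationReport:
    """Per-genus association summary for one response variable."""

    response: str
    table: pd.DataFrame  # genus, vip, coefficient, sign, important, percentile_list
    pct_explained: float
    q2: float
    n_components: int
    press_by_A: np.ndarray

    @property
    def important(self) -> list[str]:
        return list(self.table.loc[self.table["important"], "genus"])

    def percentile_list(self, which: str) -> list[str]:
        sub = self.table[self.table["percentile_list"] == which]
        return list(sub["genus"])


def _q2(press_value: float, Y: np.ndarray) -> float:
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    ss = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    return 1.0 - press_value / ss if ss > 0 else float("nan")


def genus_associations(
    X: pd.DataFrame,
    y: pd.Series,
    vip_threshold: float = 0.8,
    percentile: float = 95.0,
    A_max: int = 10,
) -> AssociationReport:
    """PLS1 of one kinetic response on genus proportions, with VIP lists.

    The component count is selected by leave-one-out PRESS.  Genera with
    VIP above ``vip_threshold`` are flagged important; genera at or above the
    ``percentile``-th percentile of VIP (at most ``ceil((1-q) p)`` of them,
    ties broken by coefficient magnitude) form the percentile lists, split by
    the sign of the standardised regression coefficient.
    """
    if not X.index.equals(y.index):
        y = y.reindex(X.index)
        if y.isna().any():
            raise PLSError("response index does not align with predictor rows")
    Xa = X.to_numpy(float)
    ya = y.to_numpy(float)
    p_total = Xa.shape[1]
    if p_total < 20:
        logger.info("only %d predictors; percentile lists may be empty", p_total)

    A_star, press = loo_select_components(Xa, ya, A_max)
    Xz, xs = standardize(Xa)
    yz, ys = standardize(ya)
    model = fit_pls(Xz, yz, A_star)
    model.x_stats, model.y_stats, model.press_by_A = xs, ys, press

    scores = vip(model)
    coefs = model.coefficients()[:, 0]
    genera = np.asarray(X.columns)[xs.kept]
    p = len(genera)

    table = pd.DataFrame(
        {
            "genus": genera,
            "vip": scores,
            "coefficient": coefs,
            "sign": np.where(coefs >= 0, "positive", "negative"),
            "important": scores > vip_threshold,
        }
    )
    cap = math.ceil((1.0 - percentile / 100.0) * p)
    cutoff = np.percentile(scores, percentile)
    candidates = table[table["vip"] >= cutoff].copy()
    candidates = candidates.sort_values(
        ["vip", "coefficient"], key=lambda s: s.abs() if s.name == "coefficient" else s,
        ascending=False,
    ).head(cap)
    table["percentile_list"] = "none"
    table.loc[candidates.index, "percentile_list"] = candidates["sign"]

    return AssociationReport(
        response=str(y.name) if y.name is not None else "response",
        table=table,
        pct_explained=100.0 * model.r2y_cum,
        q2=_q2(press[A_star - 1], ya),
        n_components=A_star,
        press_by_A=press,
    )


def clade_comparison(
    tables: dict[str, pd.DataFrame],
    Y: pd.DataFrame,
    A_max: int = 10,
) -> pd.DataFrame:
    """PLS2 of all responses on each clade level's matrix.

    Returns one row per level with the percentage of response variation
    explained (training R2Y x 100), cross-validated Q2 x 100 and the
    LOO-selected component count, plus a ``best`` flag on the argmax level.
    Levels whose sample keys do not match ``Y`` are skipped with a warning.
    """
    records = []
    for level, data in tables.items():
        if set(data.index) != set(Y.index):
            logger.warning("level %s sample keys do not match responses; skipped",
                           level)
            continue
        Xa = data.reindex(Y.index).to_numpy(float)
        Ya = Y.to_numpy(float)
        A_star, press = loo_select_components(Xa, Ya, A_max)
        Xz, _ = standardize(Xa)
        Yz, _ = standardize(Ya)
        model = fit_pls(Xz, Yz, A_star)
        records.append(
            {
                "level": level,
                "pct_explained": 100.0 * model.r2y_cum,
                "q2_pct": 100.0 * _q2(press[A_star - 1], Ya),
                "n_components": A_star,
                "n_clades": Xa.shape[1],
            }
        )
    if not records:
        raise PLSError("no clade level could be analysed")
    out = pd.DataFrame.from_records(records)
    out["best"] = out["pct_explained"] == out["pct_explained"].max()
    return out
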