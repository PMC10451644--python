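"""Placement comparison statistics for the daily-distance tables.

Fits, per algorithm, a linear mixed model with a fixed placement effect and
random intercepts for tracker, tracker-by-placement unit and date (REML,
variance components constrained non-negative).  Reports least-squares means
with standard errors, the overall placement test, unadjusted pairwise
comparisons with a compact letter display, per-placement tests against zero,
and the static (Indoor+Outdoor) vs. non-static (Animal) contrast.

Denominator degrees of freedom use a Satterthwaite-type approximation
(delta method on the REML variance-parameter information, Fai-Cornelius
combination for multi-df tests), falling back to a containment-style rule
(tracker-by-placement units minus placement levels) when the approximation
is numerically unavailable; exact parity with SAS MIXED's default is not
claimed.  Distances are non-negative but are modelled Gaussian, replicating
the source analysis; singular or degenerate fits fall back to a
fixed-effects ANOVA with a recorded warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PLACEMENTS, STATIC_PLACEMENTS

__all__ = ["PlacementSummary", "fit_placement_model", "letter_grouping"]


@dataclass
class PlacementSummary:
    """Model-based comparison of daily distances across placements."""

    algorithm: str
    placements: list[str]
    ls_means: dict[str, float]
    se: dict[str, float]
    p_vs_zero: dict[str, float]
    letters: dict[str, str]
    pairwise_p: pd.DataFrame
    p_placement: float
    p_static_vs_nonstatic: float
    static_contrast_estimate: float
    alpha: float = 0.05
    method: str = "mixed-reml"
    ddf: float = np.nan
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.placements:
            rows.append(
                {
                    "algorithm": self.algorithm,
                    "state": "non-Static" if p == "Animal" else "Static",
                    "placement": p,
                    "ls_mean_m": self.ls_means[p],
                    "se_m": self.se[p],
                    "letter": self.letters[p],
                    "p_vs_zero": self.p_vs_zero[p],
                    "p_placement": self.p_placement,
                    "p_static_vs_nonstatic": self.p_static_vs_nonstatic,
                    "method": self.method,
                }
            )
        return pd.DataFrame(rows)


def letter_grouping(pairwise_p: pd.DataFrame, alpha: float = 0.05,
                    means: dict[str, float] | None = None) -> dict[str, str]:
    """Compact letter display: groups not different at alpha share a letter.

    Pairs are "different" when p < alpha (NaN counts as not different).
    Implemented with the classic insert-and-absorb algorithm; letters are
    assigned in descending order of group mean when means are given.
    """
    names = list(pairwise_p.index)
    sets: list[set] = [set(names)]
    for i, j in combinations(names, 2):
        p = pairwise_p.loc[i, j]
        if pd.notna(p) and p < alpha:
            new_sets = []
            for s in sets:
                if i in s and j in s:
                    new_sets.extend([s - {i}, s - {j}])
                else:
                    new_sets.append(s)
            # absorb sets contained in another
            sets = [
                s for s in new_sets
                if s and not any(s < t for t in new_sets)
            ]
            # dedupe
            uniq = []
            for s in sets:
                if s not in uniq:
                    uniq.append(s)
            sets = uniq
    if means:
        sets.sort(key=lambda s: -max(means.get(n, 0.0) for n in s))
    letters = {n: "" for n in names}
    for k, s in enumerate(sets):
        lab = chr(ord("a") + k)
        for n in s:
            letters[n] += lab
    return {n: "".join(sorted(letters[n])) for n in names}


class _Satterthwaite:
    """Satterthwaite denominator df for contrasts of a variance-component LMM.

    The marginal covariance is ``Sigma(theta) = theta_0 I + sum_k theta_k
    Z_k Z_k'``; the df of a contrast ``c`` is ``2 (c'Vc)^2 / (g' C g)`` with
    ``V = (X' Sigma^-1 X)^-1``, ``g`` the gradient of ``c'Vc`` in theta and
    ``C`` the inverse observed REML information.  Multi-df tests use the
    Fai-Cornelius eigen-decomposition combination.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Z_list: list[np.ndarray],
                 theta: np.ndarray):
        self.y = y
        self.X = X
        self.ZZ = [Z @ Z.T for Z in Z_list]
        self.theta = np.asarray(theta, dtype=float)
        self.n, self.k = X.shape
        self._I = np.eye(self.n)
        self._C = None

    def _sigma(self, theta: np.ndarray) -> np.ndarray:
        S = theta[0] * self._I
        for t, ZZ in zip(theta[1:], self.ZZ):
            S = S + t * ZZ
        return S

    def _V(self, theta: np.ndarray) -> np.ndarray:
        S = self._sigma(theta)
        SiX = np.linalg.solve(S, self.X)
        return np.linalg.inv(self.X.T @ SiX)

    def _reml_nll(self, theta: np.ndarray) -> float:
        S = self._sigma(theta)
        sign, ld = np.linalg.slogdet(S)
        if sign <= 0:
            return np.inf
        Siy = np.linalg.solve(S, self.y)
        SiX = np.linalg.solve(S, self.X)
        XtSiX = self.X.T @ SiX
        sign2, ldX = np.linalg.slogdet(XtSiX)
        if sign2 <= 0:
            return np.inf
        beta = np.linalg.solve(XtSiX, self.X.T @ Siy)
        r = self.y - self.X @ beta
        quad = float(r @ np.linalg.solve(S, r))
        return 0.5 * (ld + ldX + quad)

    def _steps(self) -> np.ndarray:
        scale = max(self.theta[0], 1e-12)
        return np.maximum(np.abs(self.theta) * 1e-4, scale * 1e-5)

    def info_inverse(self) -> np.ndarray:
        """Inverse observed REML information (central-difference Hessian)."""
        if self._C is not None:
            return self._C
        p = self.theta.size
        h = self._steps()
        H = np.empty((p, p))
        f0 = self._reml_nll(self.theta)
        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p); ei[i] = h[i]
                ej = np.zeros(p); ej[j] = h[j]
                if i == j:
                    fp = self._reml_nll(self.theta + ei)
                    fm = self._reml_nll(self.theta - ei)
                    H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
                else:
                    fpp = self._reml_nll(self.theta + ei + ej)
                    fpm = self._reml_nll(self.theta + ei - ej)
                    fmp = self._reml_nll(self.theta - ei + ej)
                    fmm = self._reml_nll(self.theta - ei - ej)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)):
            raise np.linalg.LinAlgError("non-finite REML Hessian")
        self._C = np.linalg.pinv(H)
        return self._C

    def _grad_cVc(self, c: np.ndarray) -> np.ndarray:
        p = self.theta.size
        h = self._steps()
        g = np.empty(p)
        for i in range(p):
            e = np.zeros(p); e[i] = h[i]
            fp = float(c @ self._V(self.theta + e) @ c)
            fm = float(c @ self._V(self.theta - e) @ c)
            g[i] = (fp - fm) / (2 * h[i])
        return g

    def contrast_ddf(self, c: np.ndarray) -> float:
        C = self.info_inverse()
        f = float(c @ self._V(self.theta) @ c)
        g = self._grad_cVc(c)
        denom = float(g @ C @ g)
        if denom <= 0 or not np.isfinite(denom) or f <= 0:
            raise np.linalg.LinAlgError("degenerate Satterthwaite denominator")
        return np.clip(2.0 * f * f / denom, 1.0, float(self.n))

    def ftest_ddf(self, L: np.ndarray) -> float:
        """Fai-Cornelius denominator df for a q-df Wald F test."""
        V = self._V(self.theta)
        M = L @ V @ L.T
        vals, vecs = np.linalg.eigh(M)
        q = L.shape[0]
        E = 0.0
        for i in range(q):
            if vals[i] <= 0:
                continue
            nu = self.contrast_ddf(L.T @ vecs[:, i])
            if nu > 2.0:
                E += nu / (nu - 2.0)
        if E <= q:
            raise np.linalg.LinAlgError("Fai-Cornelius combination failed")
        return np.clip(2.0 * E / (E - q), 1.0, float(self.n))


def _t_pvalue(est: float, se: float, ddf: float) -> float:
    if not np.isfinite(se) or se == 0.0:
        return 1.0 if est == 0.0 else 0.0
    t = est / se
    return float(2.0 * sps.t.sf(abs(t), ddf))


def _wald_f(beta: np.ndarray, cov: np.ndarray, L: np.ndarray, ddf: float) -> float:
    est = L @ beta
    V = L @ cov @ L.T
    try:
        stat = float(est @ np.linalg.solve(V, est))
    except np.linalg.LinAlgError:
        return np.nan
    q = L.shape[0]
    return float(sps.f.sf(stat / q, q, ddf))


def _fit_mixed(d: pd.DataFrame, present: list[str]):
    import statsmodels.formula.api as smf

    vc = {"tracker": "0 + C(tracker_id)", "date": "0 + C(date)"}
    if d["unit"].nunique() > d["tracker_id"].nunique():
        vc["unit"] = "0 + C(unit)"
    model = smf.mixedlm(
        "distance_m ~ 0 + C(placement)",
        data=d,
        groups=np.ones(len(d)),
        vc_formula=vc,
        re_formula="0",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
    k = len(res.fe_params)
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k, :k]
    names = [n.split("[")[-1].rstrip("]") for n in res.fe_params.index]
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(cov))):
        raise np.linalg.LinAlgError("non-finite mixed-model estimates")
    order = [names.index(p) for p in present]
    beta = beta[order]
    cov = cov[np.ix_(order, order)]

    # Satterthwaite scaffold: vcomp order matches sorted vc_formula keys
    factor = {"tracker": "tracker_id", "date": "date", "unit": "unit"}
    Z_list = [
        pd.get_dummies(d[factor[name]]).to_numpy(dtype=float)
        for name in sorted(vc)
    ]
    X = pd.get_dummies(d["placement"]).reindex(columns=present, fill_value=0)
    sat = _Satterthwaite(
        d["distance_m"].to_numpy(dtype=float),
        X.to_numpy(dtype=float),
        Z_list,
        np.concatenate([[res.scale], np.asarray(res.vcomp, dtype=float)]),
    )
    return beta, cov, sat


def _fit_ols(d: pd.DataFrame):
    import statsmodels.formula.api as smf

    res = smf.ols("distance_m ~ 0 + C(placement)", data=d).fit()
    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    names = [n.split("[")[-1].rstrip("]") for n in res.params.index]
    return beta, cov, names


def fit_placement_model(
    daily: pd.DataFrame,
    algorithm: str | None = None,
    alpha: float = 0.05,
) -> PlacementSummary:
    """Fit the placement-comparison model on one algorithm's daily distances.

    ``daily`` needs columns ``tracker_id, date, placement, algorithm,
    distance_m``; when ``algorithm`` is given the table is filtered to it.
    """
    d = daily if algorithm is None else daily[daily["algorithm"] == algorithm]
    if algorithm is None:
        algos = d["algorithm"].unique()
        if len(algos) != 1:
            raise ValueError("daily table mixes algorithms; pass `algorithm`")
        algorithm = algos[0]
    d = d.copy()
    d = d.dropna(subset=["distance_m"])
    d["unit"] = d["tracker_id"].astype(str) + ":" + d["placement"].astype(str)

    present = [p for p in PLACEMENTS if p in set(d["placement"])]
    if len(present) < 2:
        raise ValueError("need at least 2 placements to compare")
    counts = d.groupby("placement").size()
    if (counts < 2).any():
        raise ValueError("need >= 2 tracker-days per placement")

    n_units = d["unit"].nunique()
    k = len(present)
    containment_ddf = max(n_units - k, 1)

    warn_list: list[str] = []
    sat = None
    endog_var = float(np.var(d["distance_m"].to_numpy(dtype=float)))
    if endog_var == 0.0:
        beta, cov, names = _fit_ols(d)
        order = [names.index(p) for p in present]
        beta, cov = beta[order], np.zeros((k, k))
        method = "degenerate-constant"
        ddf = float(containment_ddf)
        warn_list.append("response is constant; p-values degenerate")
    else:
        try:
            beta, cov, sat = _fit_mixed(d, present)
            method = "mixed-reml"
            ddf = float(containment_ddf)  # refined per contrast below
        except Exception as exc:  # singular/non-converged fit
            beta, cov, names = _fit_ols(d)
            order = [names.index(p) for p in present]
            beta, cov = beta[order], cov[np.ix_(order, order)]
            method = "ols-fallback"
            ddf = float(len(d) - k)
            warn_list.append(f"mixed model fit failed ({exc!r}); fixed-effects ANOVA used")

    def _ddf_for(c: np.ndarray) -> float:
        if sat is not None:
            try:
                return sat.contrast_ddf(c)
            except Exception:
                pass
        return ddf

    ls_means = {p: float(beta[i]) for i, p in enumerate(present)}
    se = {p: float(np.sqrt(max(cov[i, i], 0.0))) for i, p in enumerate(present)}
    p_vs_zero = {}
    for i, p in enumerate(present):
        c = np.zeros(k); c[i] = 1.0
        p_vs_zero[p] = _t_pvalue(ls_means[p], se[p], _ddf_for(c))

    pair = pd.DataFrame(np.nan, index=present, columns=present, dtype=float)
    for i, j in combinations(range(k), 2):
        est = beta[i] - beta[j]
        v = cov[i, i] + cov[j, j] - 2.0 * cov[i, j]
        c = np.zeros(k); c[i] = 1.0; c[j] = -1.0
        p = _t_pvalue(est, np.sqrt(max(v, 0.0)), _ddf_for(c))
        pair.iloc[i, j] = pair.iloc[j, i] = p
    np.fill_diagonal(pair.values, 1.0)

    # overall placement test: all pairwise differences zero
    L = np.zeros((k - 1, k))
    for r in range(k - 1):
        L[r, 0] = 1.0
        L[r, r + 1] = -1.0
    if method == "degenerate-constant":
        p_placement = 1.0
    else:
        f_ddf = ddf
        if sat is not None:
            try:
                f_ddf = sat.ftest_ddf(L)
            except Exception:
                warn_list.append("Satterthwaite df unavailable; containment df used")
        ddf = float(f_ddf)
        p_placement = _wald_f(beta, cov, L, f_ddf)

    # static vs non-static contrast: Animal minus mean of static placements
    statics = [p for p in STATIC_PLACEMENTS if p in present]
    if "Animal" in present and statics:
        c = np.zeros(k)
        c[present.index("Animal")] = 1.0
        for p in statics:
            c[present.index(p)] = -1.0 / len(statics)
        contrast_est = float(c @ beta)
        contrast_se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        p_contrast = _t_pvalue(contrast_est, contrast_se, _ddf_for(c))
    else:
        contrast_est, p_contrast = np.nan, np.nan

    letters = letter_grouping(pair, alpha=alpha, means=ls_means)

    return PlacementSummary(
        algorithm=algorithm,
        placements=present,
        ls_means=ls_means,
        se=se,
        p_vs_zero=p_vs_zero,
        letters=letters,
        pairwise_p=pair,
        p_placement=p_placement,
        p_static_vs_nonstatic=p_contrast,
        static_contrast_estimate=contrast_est,
        alpha=alpha,
        method=method,
        ddf=float(ddf),
        warnings=warn_list,
    )


def summarize_all(daily: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fit the model for every algorithm present; tidy stacked summary."""
    frames = []
    for algo in daily["algorithm"].unique():
        frames.append(fit_placement_model(daily, algorithm=algo, alpha=alpha).to_frame())
    return pd.concat(frames, ignore_index=True)
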