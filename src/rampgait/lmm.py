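"""Velocity-adjusted linear mixed models for joint-angle parameters.

One model per representative joint-angle parameter:

    value ~ velocity + group * condition,  random intercept per participant,

fit by REML, with one observation per participant x condition.  Group and
condition enter with sum-to-zero contrasts so that Wald F tests of the
coefficient blocks are type-III tests; the velocity covariate is centered
at its grand mean, which is also where estimated marginal means (EMMs) are
evaluated.  Denominator degrees of freedom use the Satterthwaite
approximation, computed by numerical differentiation of the contrast
variance with respect to the two variance parameters and the observed REML
information (the same construction the reference mixed-model ANOVA
implementations use).

Between-group simple effects (young - old within each condition) are
evaluated only for parameters whose group x condition interaction is
significant (the gate is configurable); their p-values are pooled across
parameters for Benjamini-Hochberg adjustment, and the standardized effect
size divides the EMM difference by the model's residual SD.

The REML optimum itself comes from statsmodels' MixedLM; everything
downstream of the variance estimates (GLS fixed effects, type-III
F statistics, Satterthwaite df, EMMs, contrasts) is computed here from
closed-form random-intercept algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES
from .stats import fdr_adjust, magnitude_label

CONDITION_ORDER = ("level", "ascent", "descent")
GROUP_ORDER = ("young", "old")

_DEGENERATE_TOL = 1e-9


class LmmError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# design matrix (explicit sum coding)
# ---------------------------------------------------------------------------

def _condition_codes(levels: Sequence[str], cond: str) -> np.ndarray:
    """Sum-to-zero codes for one condition value given the level order."""
    k = len(levels)
    codes = np.zeros(k - 1)
    if cond == levels[-1]:
        codes[:] = -1.0
    else:
        codes[levels.index(cond)] = 1.0
    return codes


def _group_code(group: str) -> float:
    if group not in GROUP_ORDER:
        raise ValueError(f"group must be one of {GROUP_ORDER}, got {group!r}")
    return 1.0 if group == "young" else -1.0


@dataclass(frozen=True)
class LmmDesign:
    """Fixed-effect design bookkeeping for one fitted model."""

    columns: Tuple[str, ...]
    condition_levels: Tuple[str, ...]
    velocity_mean: float
    include_velocity: bool
    term_columns: Mapping[str, Tuple[int, ...]]

    def row(self, group: str, condition: str, velocity: Optional[float] = None) -> np.ndarray:
        """Design row for a (group, condition) cell; velocity defaults to the grand mean."""
        g = _group_code(group)
        c = _condition_codes(list(self.condition_levels), condition)
        parts = [1.0]
        if self.include_velocity:
            v = self.velocity_mean if velocity is None else float(velocity)
            parts.append(v - self.velocity_mean)
        parts.append(g)
        parts.extend(c)
        parts.extend(g * c)
        return np.array(parts)


def _build_design(
    df: pd.DataFrame, include_velocity: bool
) -> Tuple[np.ndarray, LmmDesign]:
    levels = tuple(c for c in CONDITION_ORDER if c in set(df["condition"]))
    if len(levels) < 2:
        raise LmmError("need >= 2 walking conditions for the mixed model")
    vmean = float(df["velocity"].mean()) if include_velocity else 0.0
    columns: List[str] = ["intercept"]
    term_cols: Dict[str, List[int]] = {}
    if include_velocity:
        columns.append("velocity")
        term_cols["velocity"] = [1]
    gi = len(columns)
    columns.append("group")
    term_cols["group"] = [gi]
    ci = len(columns)
    cond_names = [f"condition[{l}]" for l in levels[:-1]]
    columns += cond_names
    term_cols["condition"] = list(range(ci, ci + len(cond_names)))
    ii = len(columns)
    columns += [f"group:{n}" for n in cond_names]
    term_cols["group:condition"] = list(range(ii, ii + len(cond_names)))

    design = LmmDesign(
        columns=tuple(columns),
        condition_levels=levels,
        velocity_mean=vmean,
        include_velocity=include_velocity,
        term_columns={k: tuple(v) for k, v in term_cols.items()},
    )
    rows = [
        design.row(r.group, r.condition, (r.velocity if include_velocity else None))
        for r in df.itertuples()
    ]
    return np.asarray(rows), design


# ---------------------------------------------------------------------------
# closed-form random-intercept algebra
# ---------------------------------------------------------------------------

class _BlockStats:
    """Per-participant cross-products, precomputed once per fit.

    The random-intercept V-weighted sums only need X'X, X'1, X'y, 1'y,
    y'y and n per participant, so every REML / contrast-variance
    evaluation is a handful of vectorized reductions.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, part_idx: np.ndarray):
        order = np.argsort(part_idx, kind="stable")
        Xs, ys, idx = X[order], y[order], part_idx[order]
        bounds = np.flatnonzero(np.r_[True, np.diff(idx) != 0, True])
        self.ns = np.diff(bounds).astype(float)
        self.x1 = np.add.reduceat(Xs, bounds[:-1], axis=0)  # (G, p)
        self.xtx_sum = Xs.T @ Xs
        self.y1 = np.add.reduceat(ys, bounds[:-1])
        self.yty_sum = float(ys @ ys)
        self.xty_sum = Xs.T @ ys
        self.n = len(y)


def _per_group(X: np.ndarray, y: np.ndarray, part_idx: np.ndarray) -> _BlockStats:
    return _BlockStats(X, y, part_idx)


def _gls_pieces(blocks: _BlockStats, sb: float, se: float):
    """Return X'V-1X, X'V-1y, y'V-1y, log|V| for sigma2_b, sigma2_e."""
    w = sb / (se + blocks.ns * sb)  # (G,)
    xtvx = (blocks.xtx_sum - np.einsum("g,gi,gj->ij", w, blocks.x1, blocks.x1)) / se
    xtvy = (blocks.xty_sum - (w * blocks.y1) @ blocks.x1) / se
    ytvy = (blocks.yty_sum - float(w @ (blocks.y1 ** 2))) / se
    logdet = float(np.sum((blocks.ns - 1) * np.log(se) + np.log(se + blocks.ns * sb)))
    return xtvx, xtvy, ytvy, logdet


def _reml_loglik(blocks, n: int, p: int, sb: float, se: float) -> float:
    if se <= 0 or sb < 0:
        return -np.inf
    xtvx, xtvy, ytvy, logdet = _gls_pieces(blocks, sb, se)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    ypy = ytvy - xtvy @ beta
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + logdet_xtvx + ypy)


def _beta_cov(blocks, sb: float, se: float):
    xtvx, xtvy, _, _ = _gls_pieces(blocks, sb, se)
    cov = np.linalg.inv(xtvx)
    return cov @ xtvy, cov


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    """REML fit of one joint-angle parameter's mixed model."""

    response: str
    beta: pd.Series
    cov_beta: np.ndarray
    sigma2_participant: float
    sigma2_resid: float
    loglik_reml: float
    converged: bool
    degenerate: bool
    design: LmmDesign
    n_obs: int
    n_participants: int
    _blocks: object = field(repr=False, default=None)
    #: covariance of (sigma2_participant, sigma2_resid) from the observed
    #: REML information; None for degenerate fits
    varpar_cov: Optional[np.ndarray] = None

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self.sigma2_resid))

    @property
    def rank(self) -> int:
        return len(self.beta)

    # -- Satterthwaite machinery ----------------------------------------
    def _contrast_var(self, l: np.ndarray, sb: float, se: float) -> float:
        _, cov = _beta_cov(self._blocks, sb, se)
        return float(l @ cov @ l)

    def satterthwaite_df(self, l: np.ndarray) -> float:
        """Satterthwaite denominator df for the scalar contrast ``l' beta``."""
        fallback = float(self.n_obs - self.rank)
        if self.degenerate or self.varpar_cov is None:
            return fallback
        sb, se = self.sigma2_participant, self.sigma2_resid
        g0 = self._contrast_var(l, sb, se)
        grad = np.zeros(2)
        for i, (v, h) in enumerate(((sb, _step(sb, se)), (se, _step(se, se)))):
            th = [sb, se]
            th[i] = v + h
            up = self._contrast_var(l, *th)
            th[i] = max(v - h, 0.0 if i == 0 else 1e-12)
            lo = self._contrast_var(l, *th)
            grad[i] = (up - lo) / (v + h - th[i])
        denom = float(grad @ self.varpar_cov @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return fallback
        df = 2.0 * g0 ** 2 / denom
        if not np.isfinite(df) or df <= 0:
            return fallback
        return float(df)


def _step(v: float, scale: float) -> float:
    return max(1e-4 * max(v, 0.05 * scale), 1e-10)


def fit_lmm(
    df: pd.DataFrame,
    response: str = "value",
    include_velocity: bool = True,
) -> LmmFit:
    """Fit the velocity-adjusted random-intercept model by REML.

    Parameters
    ----------
    df:
        One row per participant x condition with columns ``participant``,
        ``group``, ``condition``, ``velocity`` (unless ``include_velocity``
        is False) and the response column.
    response:
        Name of the response column.
    include_velocity:
        Drop the covariate for unadjusted designs (used by reduction
        tests: with balanced data and no covariate, EMMs equal cell
        means).

    Notes
    -----
    A fit whose OLS residual variance is numerically zero (noise-free
    synthetic data) is returned on the *degenerate* path: exact OLS fixed
    effects, zero variance components, zero covariance.  A fit whose
    participant variance collapses to zero is retained and flagged via
    ``converged``/``sigma2_participant`` as statsmodels reports it.
    """
    need = {"participant", "group", "condition", response}
    if include_velocity:
        need.add("velocity")
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["participant", "condition"])
    if dup.any():
        raise ValueError("expect one observation per participant x condition")

    work = df.rename(columns={response: "_y"}).reset_index(drop=True)
    X, design = _build_design(work.rename(columns={"_y": "y"}), include_velocity)
    y = work["_y"].to_numpy(float)
    part_codes, _ = pd.factorize(work["participant"], sort=True)
    n, p = X.shape
    n_participants = int(part_codes.max()) + 1
    counts = np.bincount(part_codes)
    if counts.min() < 2:
        raise LmmError("each participant needs >= 2 conditions for the random intercept")
    blocks = _per_group(X, y, part_codes)

    # degenerate (noise-free) path: exact OLS, zero variances
    beta_ols, res_ss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise LmmError("fixed-effect design is rank deficient (collinear predictors)")
    ss = float(res_ss[0]) if len(res_ss) else float(np.sum((y - X @ beta_ols) ** 2))
    scale = max(float(np.var(y)), 1.0)
    if ss / n < _DEGENERATE_TOL * scale:
        return LmmFit(
            response=response,
            beta=pd.Series(beta_ols, index=design.columns),
            cov_beta=np.zeros((p, p)),
            sigma2_participant=0.0,
            sigma2_resid=0.0,
            loglik_reml=np.inf,
            converged=True,
            degenerate=True,
            design=design,
            n_obs=n,
            n_participants=n_participants,
            _blocks=blocks,
        )

    import statsmodels.regression.mixed_linear_model as sm_mlm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm_mlm.MixedLM(y, X, groups=part_codes)
        res = model.fit(reml=True)
    sb = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
    se = float(res.scale)
    # polish the REML optimum on the closed-form criterion (the generic
    # optimizer stops around 1e-5 relative, which leaks into exact
    # balanced-design identities such as F = t^2)
    from scipy.optimize import minimize

    def _negll(logth):
        return -_reml_loglik(blocks, n, p, float(np.exp(logth[0])), float(np.exp(logth[1])))

    start = np.log([max(sb, 1e-8 * se if se > 0 else 1e-8), max(se, 1e-12)])
    opt = minimize(_negll, start, method="Nelder-Mead",
                   options=dict(xatol=1e-12, fatol=1e-13, maxiter=400))
    if np.isfinite(opt.fun) and -opt.fun >= _reml_loglik(blocks, n, p, sb, se):
        sb, se = float(np.exp(opt.x[0])), float(np.exp(opt.x[1]))
        if sb < 1e-10 * se:
            sb = 0.0
    beta, cov = _beta_cov(blocks, sb, se)
    loglik = _reml_loglik(blocks, n, p, sb, se)

    # observed REML information for the Satterthwaite approximation
    varpar_cov = None
    try:
        H = _numeric_hessian(lambda th: _reml_loglik(blocks, n, p, th[0], th[1]),
                             np.array([sb, se]),
                             np.array([_step(sb, se), _step(se, se)]))
        A = np.linalg.inv(-H)
        if np.all(np.isfinite(A)) and A[0, 0] >= 0 and A[1, 1] >= 0:
            varpar_cov = A
    except np.linalg.LinAlgError:
        pass

    return LmmFit(
        response=response,
        beta=pd.Series(beta, index=design.columns),
        cov_beta=cov,
        sigma2_participant=sb,
        sigma2_resid=se,
        loglik_reml=loglik,
        converged=bool(res.converged),
        degenerate=False,
        design=design,
        n_obs=n,
        n_participants=n_participants,
        _blocks=blocks,
        varpar_cov=varpar_cov,
    )


def _numeric_hessian(f, x0: np.ndarray, h: np.ndarray) -> np.ndarray:
    k = len(x0)
    H = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp = x0.copy(); xp[i] += h[i]
                xm = x0.copy(); xm[i] = max(xm[i] - h[i], 1e-12)
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / ((xp[i] - x0[i]) * (x0[i] - xm[i]))
            else:
                xpp = x0.copy(); xpp[[i, j]] += h[[i, j]]
                xpm = x0.copy(); xpm[i] += h[i]; xpm[j] = max(xpm[j] - h[j], 1e-12)
                xmp = x0.copy(); xmp[j] += h[j]; xmp[i] = max(xmp[i] - h[i], 1e-12)
                xmm = x0.copy()
                xmm[i] = max(xmm[i] - h[i], 1e-12); xmm[j] = max(xmm[j] - h[j], 1e-12)
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    (xpp[i] - xmm[i]) * (xpp[j] - xmm[j])
                )
    return H


# ---------------------------------------------------------------------------
# type-III ANOVA
# ---------------------------------------------------------------------------

def anova_type3(fit: LmmFit) -> pd.DataFrame:
    """Type-III Wald F tests with Satterthwaite denominator df.

    One row per fixed term (velocity, group, condition, group:condition).
    Multi-df terms combine per-eigencontrast Satterthwaite dfs in the
    standard way.  Degenerate (noise-free) fits report exact-zero residual
    structure: F is infinite when the term's effect is nonzero, zero
    otherwise, with p = 0 or 1 accordingly.
    """
    rows = []
    beta = fit.beta.to_numpy()
    for term, cols in fit.design.term_columns.items():
        q = len(cols)
        L = np.zeros((q, fit.rank))
        for r, c in enumerate(cols):
            L[r, c] = 1.0
        est = L @ beta
        if fit.degenerate:
            nonzero = bool(np.any(np.abs(est) > 1e-8))
            rows.append(dict(term=term, F=np.inf if nonzero else 0.0, df_num=q,
                             df_den=np.inf, p=0.0 if nonzero else 1.0))
            continue
        M = L @ fit.cov_beta @ L.T
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            raise LmmError(f"singular contrast covariance for term {term!r}")
        F = float(est @ Minv @ est) / q
        if q == 1:
            df_den = fit.satterthwaite_df(L[0])
        else:
            w, U = np.linalg.eigh(M)
            nus = []
            for i in range(q):
                if w[i] <= 0:
                    continue
                nus.append(fit.satterthwaite_df(L.T @ U[:, i]))
            nus = [nu for nu in nus if nu > 2]
            if len(nus) == q:
                E = sum(nu / (nu - 2) for nu in nus)
                df_den = 2 * E / (E - q) if E > q else float(fit.n_obs - fit.rank)
            else:
                df_den = float(fit.n_obs - fit.rank)
        p = float(sps.f.sf(F, q, df_den))
        rows.append(dict(term=term, F=F, df_num=q, df_den=df_den, p=p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EMMs and simple effects
# ---------------------------------------------------------------------------

def emmeans(fit: LmmFit) -> pd.DataFrame:
    """Estimated marginal means per group x condition at the grand-mean velocity."""
    rows = []
    beta = fit.beta.to_numpy()
    for cond in fit.design.condition_levels:
        for group in GROUP_ORDER:
            l = fit.design.row(group, cond)
            se = 0.0 if fit.degenerate else float(np.sqrt(l @ fit.cov_beta @ l))
            rows.append(dict(group=group, condition=cond, emm=float(l @ beta), se=se))
    return pd.DataFrame(rows)


def simple_effects(
    fit: LmmFit,
    interaction_p: Optional[float] = None,
    gate_on_interaction: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Young - old contrasts within each condition (no FDR; see the battery).

    If ``gate_on_interaction`` and the interaction p-value is >= ``alpha``,
    contrasts are returned with ``evaluated=False`` (reported n.s.; they do
    not enter any FDR family).  The standardized effect size is the EMM
    difference over the residual SD (NaN for degenerate fits, whose
    residual SD is zero).
    """
    gated = bool(gate_on_interaction and interaction_p is not None and interaction_p >= alpha)
    beta = fit.beta.to_numpy()
    rows = []
    for cond in fit.design.condition_levels:
        ly = fit.design.row("young", cond)
        lo = fit.design.row("old", cond)
        l = ly - lo
        est = float(l @ beta)
        if fit.degenerate:
            se_c, df, p = 0.0, np.inf, np.nan
            d = np.nan
        else:
            se_c = float(np.sqrt(l @ fit.cov_beta @ l))
            df = fit.satterthwaite_df(l)
            tval = est / se_c if se_c > 0 else np.inf
            p = float(2 * sps.t.sf(abs(tval), df))
            d = est / fit.residual_sd if fit.residual_sd > 0 else np.nan
        rows.append(
            dict(
                condition=cond,
                emm_young=float(ly @ beta),
                emm_old=float(lo @ beta),
                estimate=est,
                se=se_c,
                df=df,
                p=p,
                d=d,
                magnitude=(magnitude_label(d) if np.isfinite(d) else ""),
                evaluated=not gated,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KinematicStats:
    """Results of the joint-angle tier: per-parameter ANOVA and contrasts."""

    contrasts: pd.DataFrame
    anova: pd.DataFrame
    fits: Mapping[str, LmmFit]


def kinematic_battery(
    feature_table: pd.DataFrame,
    parameters: Optional[Sequence[str]] = None,
    gate_on_interaction: bool = True,
    alpha: float = 0.05,
) -> KinematicStats:
    """Fit one velocity-adjusted LMM per joint-angle parameter.

    ``feature_table`` is tidy (participant, group, condition, parameter,
    value) and must contain ``velocity`` rows alongside the joint-angle
    parameters.  Simple effects are evaluated only where the group x
    condition interaction is significant; all evaluated p-values are
    pooled across parameters and conditions for the BH adjustment.
    """
    vel = feature_table[feature_table["parameter"] == "velocity"][
        ["participant", "condition", "value"]
    ].rename(columns={"value": "velocity"})
    if vel.empty:
        raise ValueError("feature_table must include 'velocity' rows for the covariate")
    if parameters is None:
        present = set(feature_table["parameter"])
        parameters = [p for p in FEATURE_NAMES if p in present]
    contrast_frames = []
    anova_frames = []
    fits: Dict[str, LmmFit] = {}
    for par in parameters:
        sub = feature_table[feature_table["parameter"] == par][
            ["participant", "group", "condition", "value"]
        ].merge(vel, on=["participant", "condition"], how="inner")
        fit = fit_lmm(sub, response="value")
        fits[par] = fit
        an = anova_type3(fit)
        an.insert(0, "parameter", par)
        anova_frames.append(an)
        inter_p = float(an.loc[an["term"] == "group:condition", "p"].iloc[0])
        se_df = simple_effects(fit, interaction_p=inter_p, gate_on_interaction=gate_on_interaction, alpha=alpha)
        se_df.insert(0, "parameter", par)
        se_df["interaction_p"] = inter_p
        contrast_frames.append(se_df)
    contrasts = pd.concat(contrast_frames, ignore_index=True)
    anova = pd.concat(anova_frames, ignore_index=True)
    contrasts["p_fdr"] = np.nan
    mask = contrasts["evaluated"] & contrasts["p"].notna()
    if mask.any():
        contrasts.loc[mask, "p_fdr"] = fdr_adjust(contrasts.loc[mask, "p"].values)
    return KinematicStats(contrasts=contrasts, anova=anova, fits=fits)
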