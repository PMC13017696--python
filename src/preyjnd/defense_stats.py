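"""Behaviour-colour models: does conspicuousness predict defence?

Per-larva defence phenotypes (U-posture display yes/no, defensive-fluid
deployment yes/no, fluid volume) are modelled against the larva's own JND
contrasts (colour and luminance of the ventral or dorsal surface against
the needle background):

* binary traits — logistic regression on a single centred contrast
  predictor, with a Gaussian random intercept for larval family fitted by
  maximum likelihood with adaptive Gauss-Hermite quadrature
  (:func:`fit_logistic`); without a grouping factor a plain IRLS GLM
  (statsmodels) is used;
* fluid volume — gamma GLM with log link and Pearson dispersion
  (:func:`fit_gamma_log`); larval length enters as an allometry covariate
  and zero volumes (no fluid produced) are replaced by a small constant
  (default 0.001) beforehand, since the gamma density excludes zero;
* :func:`behavior_analysis` runs the standard battery of these models over
  a behaviour-record table.

Inference is Wald throughout (estimate, SE from the observed information,
z, two-sided p), matching the usual mixed-model summary presentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "BEHAVIOR_COLUMNS",
    "BehaviorRecord",
    "ModelFit",
    "center",
    "replace_zeros",
    "fit_logistic",
    "fit_gamma_log",
    "behavior_analysis",
    "load_behavior_records",
]

BEHAVIOR_COLUMNS = [
    "individual_id",
    "family_id",
    "length_mm",
    "u_posture",
    "fluid",
    "fluid_volume",
    "ventral_color_jnd",
    "ventral_luminance_jnd",
    "dorsal_color_jnd",
    "dorsal_luminance_jnd",
]


@dataclass
class BehaviorRecord:
    """One larva's defence phenotype joined with its contrast values."""

    individual_id: str
    family_id: str
    length_mm: float
    u_posture: bool
    fluid: bool
    fluid_volume: float
    ventral_color_jnd: float
    ventral_luminance_jnd: float
    dorsal_color_jnd: float = np.nan
    dorsal_luminance_jnd: float = np.nan
    sex: str = "female"


@dataclass
class ModelFit:
    """Wald summary of a fitted GLM/GLMM.

    ``estimates`` etc. are keyed by term name (``intercept`` first).  For
    mixed fits ``random_intercept_sd`` holds the fitted family-level SD.
    ``converged`` is honest: no estimates are reported on failure.
    """

    terms: list
    estimates: dict
    standard_errors: dict
    z_values: dict
    p_values: dict
    family: str
    link: str
    converged: bool
    n: int
    random_intercept_sd: float | None = None
    n_groups: int | None = None
    dispersion: float | None = None
    loglik: float | None = None
    notes: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": [self.estimates[t] for t in self.terms],
            "std_error": [self.standard_errors[t] for t in self.terms],
            "z_value": [self.z_values[t] for t in self.terms],
            "p_value": [self.p_values[t] for t in self.terms],
        }, index=self.terms)


# ---------------------------------------------------------------------------
# predictor preparation


def center(values) -> np.ndarray:
    """Subtract the arithmetic mean; the constant is ``np.mean(values)``.

    Centring makes the intercept of a behaviour-colour model the log-odds
    at the average contrast.  Callers that need the centring constant for
    back-transformation should record ``np.mean(values)`` before calling
    (the battery stores it in ``ModelFit.meta['centering_constant']``).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot center an empty vector")
    return v - v.mean()


def replace_zeros(volumes, epsilon: float = 0.001) -> np.ndarray:
    """Replace zero volumes by ``epsilon`` so a gamma model applies.

    Individuals that produced no fluid have volume exactly 0, which the
    gamma density excludes; they are kept in the model at a nominal small
    volume instead of being dropped.
    """
    v = np.asarray(volumes, dtype=float)
    if np.any(v < 0):
        raise ValueError("fluid volumes must be nonnegative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    out = v.copy()
    out[out == 0] = epsilon
    return out


# ---------------------------------------------------------------------------
# logistic GLM / GLMM


def _as_design(predictor) -> np.ndarray:
    X = np.asarray(predictor, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _glm_logistic(y, X, term_names) -> ModelFit:
    """Plain logistic GLM by IRLS (statsmodels backend)."""
    Xd = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, Xd, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200, tol=1e-10)
        converged = bool(res.converged)
    except Exception as e:  # perfect separation raises in statsmodels
        logger.warning("logistic GLM failed: %s", e)
        return ModelFit(terms=["intercept"] + term_names, estimates={},
                        standard_errors={}, z_values={}, p_values={},
                        family="binomial", link="logit", converged=False,
                        n=len(y), notes=[f"fit failed: {e}"])
    est = res.params
    se = res.bse
    if np.any(np.abs(est) > 15) or not np.all(np.isfinite(se)):
        converged = False
    terms = ["intercept"] + term_names
    with np.errstate(invalid="ignore", divide="ignore"):
        z = est / se
        p = 2.0 * stats.norm.sf(np.abs(z))
    return ModelFit(
        terms=terms,
        estimates=dict(zip(terms, est.tolist())),
        standard_errors=dict(zip(terms, se.tolist())),
        z_values=dict(zip(terms, z.tolist())),
        p_values=dict(zip(terms, p.tolist())),
        family="binomial", link="logit", converged=converged, n=len(y),
        loglik=float(res.llf),
        notes=[] if converged else ["possible separation or non-convergence"],
    )


def _pack_groups(y: np.ndarray, Xd: np.ndarray, groups: np.ndarray):
    """Pad per-group responses/designs into dense (G, n_max[, p]) arrays."""
    uniq = np.unique(groups)
    counts = [int((groups == g).sum()) for g in uniq]
    n_max = max(counts)
    G, p = uniq.size, Xd.shape[1]
    Y = np.zeros((G, n_max))
    Xp = np.zeros((G, n_max, p))
    M = np.zeros((G, n_max), dtype=bool)
    for i, g in enumerate(uniq):
        sel = groups == g
        n = counts[i]
        Y[i, :n] = y[sel]
        Xp[i, :n] = Xd[sel]
        M[i, :n] = True
    return Y, Xp, M


def _glmm_nll(theta, Y, Xp, M, nodes, weights, fix_sigma=None):
    """Negative marginal log likelihood of the random-intercept logistic model.

    theta = (beta..., log sigma) unless ``fix_sigma`` is given, in which
    case theta = beta.  For each group (family) the integrand over the
    standard-normal random effect u is maximised by Newton iteration — the
    integrand is strictly log-concave with curvature <= -1, so the
    undamped step (clipped to +-5) converges — and the integral is taken
    by Gauss-Hermite quadrature recentred and rescaled at the mode
    (adaptive GH; 1 node reproduces the Laplace approximation).  All
    groups are evaluated together on padded arrays.
    """
    if fix_sigma is None:
        beta, sigma = theta[:-1], float(np.exp(theta[-1]))
    else:
        beta, sigma = theta, float(fix_sigma)
    eta0 = Xp @ beta  # (G, n_max)
    G = Y.shape[0]

    u = np.zeros(G)
    for _ in range(60):
        eta = eta0 + sigma * u[:, None]
        p = special.expit(eta)
        h1 = -u + sigma * np.where(M, Y - p, 0.0).sum(axis=1)
        h2 = -1.0 - sigma ** 2 * np.where(M, p * (1 - p), 0.0).sum(axis=1)
        step = np.clip(-h1 / h2, -5.0, 5.0)
        u = u + step
        if np.max(np.abs(h1)) < 1e-12:
            break
    eta = eta0 + sigma * u[:, None]
    p = special.expit(eta)
    h2 = -1.0 - sigma ** 2 * np.where(M, p * (1 - p), 0.0).sum(axis=1)
    tau = 1.0 / np.sqrt(-h2)

    u_k = u[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]  # (G, K)
    eta_k = eta0[:, None, :] + sigma * u_k[:, :, None]  # (G, K, n_max)
    ll_obs = np.where(M[:, None, :],
                      Y[:, None, :] * eta_k - np.logaddexp(0.0, eta_k),
                      0.0).sum(axis=2)
    h_k = -0.5 * u_k ** 2 - 0.5 * np.log(2.0 * np.pi) + ll_obs
    # int e^{h(u)} du ~= sqrt(2) tau sum_k w_k e^{z_k^2} e^{h(u_k)}
    log_lik = (0.5 * np.log(2.0) + np.log(tau)
               + special.logsumexp(np.log(weights)[None, :] + nodes[None, :] ** 2 + h_k,
                                   axis=1))
    return -float(log_lik.sum())


def _numeric_hessian(f, x, h=1e-4):
    x = np.asarray(x, dtype=float)
    k = x.size
    H = np.zeros((k, k))
    hs = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def fit_logistic(response, predictor, family_id=None, quadrature_nodes: int = 15,
                 fix_sigma: float | None = None,
                 term_names: list | None = None) -> ModelFit:
    """Logistic regression with an optional family random intercept.

    Without ``family_id`` this is a plain IRLS GLM.  With it, the marginal
    likelihood of a single Gaussian random intercept is maximised with
    ``quadrature_nodes``-point adaptive Gauss-Hermite quadrature; standard
    errors come from the numerically differentiated observed information.
    ``fix_sigma=0`` constrains the random-intercept SD to zero (the fit
    then coincides with the plain GLM).  One quadrature node reproduces
    the Laplace approximation.
    """
    y = np.asarray(response, dtype=float)
    X = _as_design(predictor)
    if len(np.unique(y)) < 2:
        raise ValueError("binary response has fewer than 2 distinct values")
    if quadrature_nodes < 1:
        raise ValueError("quadrature_nodes must be >= 1")
    if term_names is None:
        term_names = [f"x{j}" for j in range(X.shape[1])] if X.shape[1] > 1 else ["slope"]
    if len(term_names) != X.shape[1]:
        raise ValueError("one term name per predictor column required")

    if family_id is None:
        return _glm_logistic(y, X, term_names)

    groups = np.asarray(family_id)
    uniq = np.unique(groups)
    if uniq.size < 2:
        logger.info("fewer than 2 groups: falling back to a plain GLM")
        fit = _glm_logistic(y, X, term_names)
        fit.notes.append("grouping had < 2 levels; plain GLM used")
        return fit

    Xd = np.column_stack([np.ones(len(y)), X])
    Y, Xp, M = _pack_groups(y, Xd, groups)
    nodes, weights = hermgauss(quadrature_nodes)

    start_glm = _glm_logistic(y, X, term_names)
    if start_glm.estimates:
        beta0 = np.array([start_glm.estimates[t] for t in start_glm.terms])
    else:
        beta0 = np.zeros(Xd.shape[1])

    terms = ["intercept"] + term_names
    if fix_sigma is not None:
        nll = lambda th: _glmm_nll(th, Y, Xp, M, nodes, weights, fix_sigma)
        x0 = beta0
    else:
        nll = lambda th: _glmm_nll(th, Y, Xp, M, nodes, weights)
        x0 = np.append(beta0, np.log(0.5))

    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    # Nelder-Mead polish with restarts: BFGS on finite-difference gradients
    # can stall a few 1e-6 from the optimum, which matters when
    # cross-checking engines against independent optimisers
    for _ in range(3):
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-13,
                                          "maxiter": 4000})
        improved = res2.fun < res.fun - 1e-13
        if res2.fun <= res.fun:
            res = res2
        if not improved:
            break
    theta = res.x
    converged = bool(np.all(np.abs(theta[:Xd.shape[1]]) < 15))

    if fix_sigma is None and np.exp(theta[-1]) < 1e-3:
        # boundary (singular) fit: the random-intercept variance is
        # estimated at zero, so report the plain-GLM estimates with sd 0
        fit = _glm_logistic(y, X, term_names)
        fit.random_intercept_sd = 0.0
        fit.n_groups = int(uniq.size)
        fit.notes.append("random-intercept SD estimated at zero (boundary fit)")
        fit.meta["quadrature_nodes"] = quadrature_nodes
        return fit

    H = _numeric_hessian(nll, theta)
    n_beta = Xd.shape[1]
    try:
        cov = np.linalg.inv(H)
        with np.errstate(invalid="ignore"):
            se_all = np.sqrt(np.diag(cov))
        # the fixed-effect block must be sound; a ragged variance-parameter
        # SE (flat likelihood in log sigma) does not invalidate the betas
        if not np.all(np.isfinite(se_all[:n_beta])):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se_all = np.full(theta.size, np.nan)
        converged = False

    if not converged:
        return ModelFit(terms=terms, estimates={}, standard_errors={},
                        z_values={}, p_values={}, family="binomial",
                        link="logit", converged=False, n=len(y),
                        n_groups=int(uniq.size),
                        notes=["non-convergent mixed fit (possible separation)"])

    beta = theta[:Xd.shape[1]]
    se = se_all[:Xd.shape[1]]
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    sigma = float(fix_sigma) if fix_sigma is not None else float(np.exp(theta[-1]))
    return ModelFit(
        terms=terms,
        estimates=dict(zip(terms, beta.tolist())),
        standard_errors=dict(zip(terms, se.tolist())),
        z_values=dict(zip(terms, z.tolist())),
        p_values=dict(zip(terms, p.tolist())),
        family="binomial", link="logit", converged=True, n=len(y),
        random_intercept_sd=sigma, n_groups=int(uniq.size),
        loglik=-float(res.fun),
        meta={"quadrature_nodes": quadrature_nodes},
    )


# ---------------------------------------------------------------------------
# gamma log-link model


def fit_gamma_log(volume, contrast, length=None, family_id=None,
                  term_names: list | None = None) -> ModelFit:
    """Gamma GLM with log link for defensive-fluid volume.

    The response must be strictly positive (apply :func:`replace_zeros`
    first).  ``length`` is the allometry covariate and is always included
    when given.  Dispersion is the Pearson estimator; Wald z uses the
    normal reference.  A family grouping argument is accepted for interface
    symmetry but the fit is the fixed-effects GLM.
    """
    y = np.asarray(volume, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma response must be strictly positive; run replace_zeros first")
    cols = [np.asarray(contrast, dtype=float)]
    names = term_names or ["contrast"]
    if length is not None:
        cols.append(np.asarray(length, dtype=float))
        if term_names is None:
            names = ["contrast", "length"]
    X = np.column_stack(cols)
    if len(names) != X.shape[1]:
        raise ValueError("one term name per predictor column required")
    notes = []
    if family_id is not None:
        notes.append("family grouping noted but fitted as fixed-effects gamma GLM")
        logger.info(notes[-1])
    terms_all = ["intercept"] + names
    if np.ptp(y) == 0:
        # constant response: the exact ML fit is intercept = log(c), zero
        # slopes, zero dispersion; IRLS cannot start from it
        est = {t: 0.0 for t in terms_all}
        est["intercept"] = float(np.log(y[0]))
        nanv = {t: float("nan") for t in terms_all}
        return ModelFit(terms=terms_all, estimates=est, standard_errors=nanv,
                        z_values=nanv, p_values=nanv, family="gamma", link="log",
                        converged=True, n=len(y), dispersion=0.0,
                        notes=notes + ["degenerate constant response"])
    Xd = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, Xd, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit(maxiter=200, tol=1e-10, scale="X2")
    terms = ["intercept"] + names
    est = res.params
    se = res.bse
    z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return ModelFit(
        terms=terms,
        estimates=dict(zip(terms, est.tolist())),
        standard_errors=dict(zip(terms, se.tolist())),
        z_values=dict(zip(terms, z.tolist())),
        p_values=dict(zip(terms, p.tolist())),
        family="gamma", link="log", converged=bool(res.converged), n=len(y),
        dispersion=float(res.scale), loglik=float(res.llf), notes=notes,
    )


# ---------------------------------------------------------------------------
# the model battery


def _bool01(series) -> np.ndarray:
    v = pd.Series(series)
    if v.dtype == object:
        v = v.map({"yes": 1.0, "no": 0.0, True: 1.0, False: 0.0})
        if v.isna().any():
            raise ValueError("binary columns must be yes/no or boolean")
    return v.to_numpy(dtype=float)


def load_behavior_records(path, females_only: bool = True) -> pd.DataFrame:
    """Read a behaviour CSV; drop males when a ``sex`` column is present."""
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ValueError(f"behavior records missing columns: {missing}")
    if females_only and "sex" in df.columns:
        n0 = len(df)
        df = df[df["sex"] == "female"].reset_index(drop=True)
        if len(df) < n0:
            logger.info("excluded %d non-female record(s)", n0 - len(df))
    return df


def behavior_analysis(records: pd.DataFrame, include_dorsal: bool = False,
                      zero_epsilon: float = 0.001,
                      quadrature_nodes: int = 15) -> dict:
    """Run the standard behaviour-colour model battery.

    Binary models (family random intercept unless noted):

    * ``uposture~ventral_color``, ``uposture~ventral_luminance``
    * ``fluid~ventral_color``, ``fluid~ventral_luminance``
    * with ``include_dorsal=True`` also the dorsal variants;
      ``uposture~dorsal_color`` is fitted as a plain GLM (the mixed variant
      is the one that historically fails to converge on data of this size).

    Volume models (gamma log link, zeros replaced by ``zero_epsilon``,
    length always included): ``volume~ventral_color+length`` and
    ``volume~ventral_luminance+length``.

    All contrast predictors are centred internally; the centring constant
    is stored in each fit's ``meta['centering_constant']``.  With fewer
    than 2 families the mixed models fall back to plain GLMs with a note.
    """
    df = records.copy()
    fam = df["family_id"].to_numpy()
    upost = _bool01(df["u_posture"])
    fluid = _bool01(df["fluid"])
    volume = replace_zeros(df["fluid_volume"].to_numpy(float), zero_epsilon)
    length = df["length_mm"].to_numpy(float)

    predictors = {"ventral_color": "ventral_color_jnd",
                  "ventral_luminance": "ventral_luminance_jnd"}
    if include_dorsal:
        predictors.update({"dorsal_color": "dorsal_color_jnd",
                           "dorsal_luminance": "dorsal_luminance_jnd"})

    fits = {}
    for pname, col in predictors.items():
        raw = df[col].to_numpy(float)
        mu = float(np.mean(raw))
        x = center(raw)
        for resp_name, resp in [("uposture", upost), ("fluid", fluid)]:
            key = f"{resp_name}~{pname}"
            grouping = None if key == "uposture~dorsal_color" else fam
            fit = fit_logistic(resp, x, family_id=grouping,
                               quadrature_nodes=quadrature_nodes,
                               term_names=[f"{pname}_contrast"])
            fit.meta["centering_constant"] = mu
            if grouping is None:
                fit.notes.append("plain GLM by convention for this model")
            fits[key] = fit

    for pname in ("ventral_color", "ventral_luminance"):
        raw = df[predictors[pname]].to_numpy(float)
        mu = float(np.mean(raw))
        fit = fit_gamma_log(volume, center(raw), length=length, family_id=fam,
                            term_names=[f"{pname}_contrast", "length"])
        fit.meta["centering_constant"] = mu
        fits[f"volume~{pname}+length"] = fit
    return fits
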