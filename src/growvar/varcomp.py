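"""Variance components by AI-REML for genomic animal models.

Fits the animal model

    y = X beta + Z a + e,   a ~ N(0, sigma2_A * G),   e ~ N(0, sigma2_E * I)

and its bivariate extensions with additive covariance ``C (x) G`` and
residual covariance ``R (x) I``, where G is a genomic relationship matrix.
For the cross-environment design (each fish recorded in one pond only) the
residual covariance is constrained to zero.

The optimizer is average-information REML: quasi-Newton steps whose Hessian
approximation ``AI_ij = 0.5 y'P V_i P V_j P y`` is cheap and positive
definite near the optimum, with step halving to keep the restricted
log-likelihood monotone and an EM-flavoured gradient fallback when an AI
step cannot improve it.  Standard errors of heritabilities and correlations
come from the delta method on the inverse AI matrix; breeding values are
BLUPs from the converged mixed-model equations.

All dense linear algebra runs through LAPACK Cholesky routines; problem
sizes to a few thousand observations fit comfortably in memory and seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg.lapack import dpotrf, dpotri

from .grm import RelationshipMatrix

log = logging.getLogger(__name__)

MAX_CORR = 0.999  # covariance parameters constrained so |r| stays below this


class RemlError(RuntimeError):
    pass


@dataclass
class VarCompResult:
    """Converged variance components with derived genetic parameters."""

    traits: tuple[str, ...]
    sigma2_a: dict
    sigma2_e: dict
    sigma2_p: dict
    h2: dict
    h2_se: dict
    r_g: float | None = None
    r_g_se: float | None = None
    r_g_raw: float | None = None  # unclipped estimate; may exceed |1|
    r_p: float | None = None
    r_p_se: float | None = None
    cov_a: float | None = None
    cov_e: float | None = None
    loglik: float = np.nan
    converged: bool = False
    boundary: dict = field(default_factory=dict)
    trace: pd.DataFrame | None = field(default=None, repr=False)
    theta: np.ndarray | None = field(default=None, repr=False)
    theta_cov: np.ndarray | None = field(default=None, repr=False)
    beta: np.ndarray | None = field(default=None, repr=False)
    ebv: pd.DataFrame | None = field(default=None, repr=False)

    def component_table(self) -> pd.DataFrame:
        rows = []
        for t in self.traits:
            rows.append(
                {
                    "trait": t,
                    "sigma2_a": self.sigma2_a[t],
                    "sigma2_e": self.sigma2_e[t],
                    "sigma2_p": self.sigma2_p[t],
                    "h2": self.h2[t],
                    "h2_se": self.h2_se[t],
                }
            )
        return pd.DataFrame(rows).set_index("trait")


# ---------------------------------------------------------------------------
# design construction


def build_design(
    table: pd.DataFrame,
    response: str,
    grm: RelationshipMatrix,
    fixed: tuple[str, ...] = ("hapa", "sex"),
    covariate_sw: bool = False,
):
    """Fixed-effect design and response aligned to the GRM.

    Reference-level coding (first observed level dropped) keeps the design
    full rank: an intercept plus 3 hapa and 2 sex contrasts gives 6 columns
    for the standard 4 x 3 factor layout.  Rows with a missing response are
    dropped and logged.  Returns ``(y, X, ids, column_names)``.
    """
    df = table.reset_index() if table.index.name == "fish_id" else table.copy()
    keep = df[response].notna()
    if covariate_sw:
        keep &= df["start_weight"].notna()
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d rows with missing %s", n_drop, response)
    df = df.loc[keep]
    missing = set(df["fish_id"].astype(str)) - set(grm.ids)
    if missing:
        raise KeyError(f"fish absent from GRM: {sorted(missing)[:5]}")

    cols = [np.ones(len(df))]
    names = ["mu"]
    for fac in fixed:
        d = pd.get_dummies(df[fac].astype("category"), prefix=fac, drop_first=True)
        cols.append(d.to_numpy(dtype=float))
        names.extend(d.columns)
    if covariate_sw:
        cols.append(df["start_weight"].to_numpy(dtype=float)[:, None])
        names.append("b_SW")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient fixed design (columns {names}); check aliased levels"
        )
    y = df[response].to_numpy(dtype=float)
    ids = df["fish_id"].astype(str).tolist()
    return y, X, ids, names


# ---------------------------------------------------------------------------
# generic dense AI-REML core


def _chol_inverse(V: np.ndarray):
    """Cholesky factor + full inverse via dpotrf/dpotri; None if not PD."""
    L, info = dpotrf(V, lower=1)
    if info != 0:
        return None, None
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Vi, info = dpotri(L, lower=1)
    if info != 0:
        return None, None
    Vi = np.tril(Vi) + np.tril(Vi, -1).T
    return Vi, logdet


def _evaluate(theta, y, X, V_parts):
    V = np.zeros_like(V_parts[0])
    for th, Vi in zip(theta, V_parts):
        V += th * Vi
    Vinv, logdetV = _chol_inverse(V)
    if Vinv is None:
        return None
    W = Vinv @ X
    M = X.T @ W
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0:
        return None
    beta = np.linalg.solve(M, W.T @ y)
    Py = Vinv @ y - W @ beta
    yPy = float(y @ Py)
    ll = -0.5 * (logdetV + logdetM + yPy)
    return {"ll": ll, "Vinv": Vinv, "W": W, "M": M, "beta": beta, "Py": Py}


class _Reparam:
    """Unconstrained working coordinates for the variance parameters.

    Variances are optimized on the log scale, which keeps them positive
    without corner constraints.  Covariance parameters stay on their linear
    scale and are deliberately *not* constrained to an implied correlation
    inside [-1, 1]: only the overall V must remain positive definite (the
    Cholesky evaluation rejects anything else).  Leaving the covariance
    free is how unstructured-covariance REML implementations behave; it
    avoids piling estimates onto the |r| = 1 boundary, so Monte-Carlo means
    of estimated correlations stay unbiased.  Reported correlations are
    clipped to [-1, 1] with a boundary flag downstream.
    ``cov_links`` maps each covariance index to its (var_i, var_j) indices
    (used only for boundary flagging).
    """

    def __init__(self, k: int, cov_links: dict[int, tuple[int, int]], floor: float):
        self.k = k
        self.cov_links = cov_links
        self.var_idx = [i for i in range(k) if i not in cov_links]
        self.floor = floor

    def phi_from_theta(self, theta):
        phi = np.empty(self.k)
        for i in self.var_idx:
            phi[i] = np.log(max(theta[i], self.floor))
        for c in self.cov_links:
            phi[c] = theta[c]
        return phi

    def theta_from_phi(self, phi):
        theta = np.empty(self.k)
        for i in self.var_idx:
            theta[i] = np.exp(phi[i])
        for c in self.cov_links:
            theta[c] = phi[c]
        return theta

    def jacobian(self, phi, theta):
        """J[a, b] = d theta_a / d phi_b."""
        J = np.zeros((self.k, self.k))
        for i in self.var_idx:
            J[i, i] = theta[i]
        for c in self.cov_links:
            J[c, c] = 1.0
        return J


def _reml_core(
    y,
    X,
    V_parts,
    theta0,
    is_variance,
    cov_links: dict[int, tuple[int, int]] | None = None,
    max_iter: int = 200,
    tol_ll: float = 1e-8,
    tol_par: float = 1e-6,
):
    """Maximize the REML log-likelihood over linear variance parameters.

    ``V = sum_i theta_i V_parts[i]``.  Average-information Newton steps are
    taken in unconstrained working coordinates (:class:`_Reparam`), with
    step halving so the restricted log-likelihood never decreases across
    accepted iterations, and an EM-flavoured gradient fallback when an AI
    step cannot improve it.  Returns a state dict with the converged
    parameters, the inverse AI matrix, the iteration trace and boundary
    flags.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    is_variance = np.asarray(is_variance, dtype=bool)
    k = len(theta)
    cov_links = cov_links or {}
    scale = float(np.var(y)) if np.var(y) > 0 else 1.0
    floor = 1e-8 * scale
    rep = _Reparam(k, cov_links, floor)

    X = np.asarray(X, dtype=float)
    if np.any(np.linalg.norm(X, axis=0) == 0):
        raise RemlError("fixed-effect design has empty columns (aliased factor level?)")
    theta[is_variance] = np.maximum(theta[is_variance], floor)
    phi = rep.phi_from_theta(theta)
    theta = rep.theta_from_phi(phi)
    state = _evaluate(theta, y, X, V_parts)
    if state is None:
        raise RemlError("initial V is not positive definite")

    trace = [{"iter": 0, "loglik": state["ll"], "step": "init",
              **{f"theta{i}": t for i, t in enumerate(theta)}}]
    converged = False
    AI = None
    for it in range(1, max_iter + 1):
        Vinv, Py = state["Vinv"], state["Py"]
        W, M = state["W"], state["M"]
        P = Vinv - W @ np.linalg.solve(M, W.T)
        score = np.empty(k)
        q = []
        for i, Vi in enumerate(V_parts):
            qi = Vi @ Py
            q.append(qi)
            score[i] = -0.5 * (float(np.vdot(P, Vi)) - float(Py @ qi))
        Pq = [P @ qi for qi in q]
        AI = 0.5 * np.array([[float(q[i] @ Pq[j]) for j in range(k)] for i in range(k)])
        AI = (AI + AI.T) / 2.0

        J = rep.jacobian(phi, theta)
        score_phi = J.T @ score
        AI_phi = J.T @ AI @ J
        ridge = 1e-8 * (np.trace(AI_phi) / k + 1.0)
        try:
            delta = np.linalg.solve(AI_phi + ridge * np.eye(k), score_phi)
        except np.linalg.LinAlgError:
            delta = score_phi / (np.trace(AI_phi) / k + 1.0)
        # cap the working-scale step; huge steps arise from tiny curvature.
        # log-variance coordinates are capped absolutely, covariance
        # coordinates relative to the geometric mean of their variances.
        caps = np.full(k, 3.0)
        for c, (ci, cj) in cov_links.items():
            caps[c] = 2.0 * np.sqrt(theta[ci] * theta[cj]) + 1e-300
        shrink = np.min(np.minimum(caps / np.maximum(np.abs(delta), 1e-300), 1.0))
        delta = delta * shrink

        new_state, new_phi, how = None, None, "ai"
        step = 1.0
        for _ in range(30):
            cand_phi = phi + step * delta
            st = _evaluate(rep.theta_from_phi(cand_phi), y, X, V_parts)
            if st is not None and st["ll"] >= state["ll"] - 1e-10:
                new_state, new_phi = st, cand_phi
                break
            step *= 0.5
        if new_state is None or (new_state["ll"] - state["ll"] < 1e-12 and it > 1):
            # EM-flavoured fallback: uphill in the working coordinates
            em_delta = score_phi / max(len(y) / 2.0, 1.0)
            shrink = np.min(np.minimum(0.5 * caps / np.maximum(np.abs(em_delta), 1e-300), 1.0))
            em_delta = em_delta * shrink
            step, how = 1.0, "em"
            for _ in range(30):
                cand_phi = phi + step * em_delta
                st = _evaluate(rep.theta_from_phi(cand_phi), y, X, V_parts)
                if st is not None and st["ll"] >= state["ll"] - 1e-12:
                    if new_state is None or st["ll"] > new_state["ll"]:
                        new_state, new_phi = st, cand_phi
                    break
                step *= 0.5
        if new_state is None:
            converged = True  # no feasible uphill step left
            break

        new_theta = rep.theta_from_phi(new_phi)
        dll = new_state["ll"] - state["ll"]
        dpar = np.max(np.abs(new_theta - theta) / (1.0 + np.abs(theta)))
        phi, theta, state = new_phi, new_theta, new_state
        trace.append({"iter": it, "loglik": state["ll"], "step": how,
                      **{f"theta{i}": t for i, t in enumerate(theta)}})
        if dll < tol_ll * (1.0 + abs(state["ll"])) and dpar < tol_par:
            converged = True
            break

    boundary = {}
    for i in range(k):
        if is_variance[i]:
            boundary[i] = bool(theta[i] <= max(floor * 1.01, 1e-6 * scale))
        else:
            ci, cj = cov_links[i]
            r = theta[i] / np.sqrt(theta[ci] * theta[cj])
            boundary[i] = bool(abs(r) >= MAX_CORR)
    try:
        theta_cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        theta_cov = np.full((k, k), np.nan)
    return {
        "theta": theta,
        "loglik": state["ll"],
        "converged": converged,
        "trace": pd.DataFrame(trace),
        "theta_cov": theta_cov,
        "beta": state["beta"],
        "Py": state["Py"],
        "Vinv": state["Vinv"],
        "boundary": boundary,
        "floor": floor,
    }


def reml_loglik(theta, y, X, V_parts) -> float:
    """Restricted log-likelihood at ``theta`` (for oracles and diagnostics)."""
    st = _evaluate(np.asarray(theta, float), y, X, V_parts)
    return -np.inf if st is None else st["ll"]


# ---------------------------------------------------------------------------
# derived quantities


def heritability(sigma2_a: float, sigma2_p: float, cov: np.ndarray | None = None):
    """h2 = sigma2_A / sigma2_P with optional delta-method SE.

    ``cov`` is the 2x2 covariance of (sigma2_A, sigma2_E).  An estimate
    above 1 (sigma2_A > sigma2_P) is flagged invalid with NaN.
    """
    if sigma2_p <= 0:
        raise ValueError("sigma2_P must be positive")
    h2 = sigma2_a / sigma2_p
    if h2 > 1 + 1e-12:
        log.warning("h2 = %.3f > 1 flagged invalid", h2)
        return np.nan, np.nan
    se = np.nan
    if cov is not None:
        sigma2_e = sigma2_p - sigma2_a
        grad = np.array([sigma2_e, -sigma2_a]) / sigma2_p**2
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return float(h2), se


def _corr_se(c, v1, v2, cov3):
    """Delta-method SE of r = c / sqrt(v1 v2) from cov of (v1, c, v2)."""
    r = c / np.sqrt(v1 * v2)
    grad = np.array(
        [-c / (2 * v1**1.5 * np.sqrt(v2)), 1.0 / np.sqrt(v1 * v2), -c / (2 * v2**1.5 * np.sqrt(v1))]
    )
    return float(r), float(np.sqrt(max(grad @ cov3 @ grad, 0.0)))


# ---------------------------------------------------------------------------
# univariate fit


def reml_univariate(
    y,
    X,
    grm: RelationshipMatrix,
    ids,
    trait: str = "trait",
    **core_kwargs,
) -> VarCompResult:
    """Single-trait animal model: estimates (sigma2_A, sigma2_E), h2 with
    SE, and BLUP breeding values with accuracies for every GRM animal."""
    y = np.asarray(y, dtype=float)
    idx = grm.index_of(ids)
    ZGZ = grm.G[np.ix_(idx, idx)]
    n = len(y)
    V_parts = [ZGZ, np.eye(n)]

    # moment start: split OLS residual variance evenly
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2 = float(np.var(y - X @ beta0, ddof=X.shape[1]))
    fit = _reml_core(y, X, V_parts, [s2 / 2, s2 / 2], [True, True], **core_kwargs)

    sa, se_ = fit["theta"]
    sp = sa + se_
    cov = fit["theta_cov"]
    if fit["boundary"].get(0, False):
        h2, h2_se = sa / sp, np.nan  # SE suppressed at the boundary
        log.warning("sigma2_A at boundary; h2 SE suppressed")
    else:
        h2, h2_se = heritability(sa, sp, cov)

    # BLUP of all GRM animals: a_hat = sigma2_A * G[:, obs] @ Py
    Gobs = grm.G[:, idx]
    ahat = sa * (Gobs @ fit["Py"])
    # PEV diag = sa*G_kk - sa^2 * diag(Gobs P Gobs')
    P = fit["Vinv"] - fit["Vinv"] @ X @ np.linalg.solve(X.T @ fit["Vinv"] @ X, X.T @ fit["Vinv"])
    PG = P @ Gobs.T
    pev = sa * np.diag(grm.G) - sa**2 * np.einsum("ij,ji->i", Gobs, PG)
    denom = sa * np.diag(grm.G)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.sqrt(np.clip(1.0 - pev / np.where(denom > 0, denom, np.nan), 0.0, 1.0))
    ebv = pd.DataFrame({"ebv": ahat, "accuracy": acc}, index=pd.Index(grm.ids, name="fish_id"))

    return VarCompResult(
        traits=(trait,),
        sigma2_a={trait: float(sa)},
        sigma2_e={trait: float(se_)},
        sigma2_p={trait: float(sp)},
        h2={trait: float(h2)},
        h2_se={trait: h2_se},
        loglik=fit["loglik"],
        converged=fit["converged"],
        boundary={"sigma2_a": fit["boundary"].get(0, False)},
        trace=fit["trace"],
        theta=fit["theta"],
        theta_cov=cov,
        beta=fit["beta"],
        ebv=ebv,
    )


# ---------------------------------------------------------------------------
# bivariate fit


def reml_bivariate(
    y1,
    X1,
    ids1,
    y2,
    X2,
    ids2,
    grm: RelationshipMatrix,
    residual_cov_free: bool = True,
    traits: tuple[str, str] = ("trait1", "trait2"),
    **core_kwargs,
) -> VarCompResult:
    """Two-trait animal model with additive covariance ``C (x) G``.

    Same-fish traits (within one pond) require ``residual_cov_free=True``;
    traits recorded on disjoint fish (the cross-environment design) require
    ``residual_cov_free=False``, which fixes the residual covariance at 0.
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    ids1 = [str(i) for i in ids1]
    ids2 = [str(i) for i in ids2]
    shared = set(ids1) & set(ids2)
    if residual_cov_free and set(ids1) != set(ids2):
        raise ValueError("free residual covariance requires both traits on the same fish")
    if not residual_cov_free and shared:
        raise ValueError(
            "traits share fish but the residual covariance is constrained to zero; "
            "use residual_cov_free=True for within-environment pairs"
        )
    if residual_cov_free and ids1 != ids2:
        order = {f: i for i, f in enumerate(ids1)}
        perm = np.argsort([order[f] for f in ids2])
        y2, ids2 = y2[perm], [ids2[i] for i in perm]
        X2 = np.asarray(X2)[perm]

    n1, n2 = len(y1), len(y2)
    idx1, idx2 = grm.index_of(ids1), grm.index_of(ids2)
    G11 = grm.G[np.ix_(idx1, idx1)]
    G12 = grm.G[np.ix_(idx1, idx2)]
    G22 = grm.G[np.ix_(idx2, idx2)]
    N = n1 + n2

    def block(A11=None, A12=None, A22=None):
        M = np.zeros((N, N))
        if A11 is not None:
            M[:n1, :n1] = A11
        if A12 is not None:
            M[:n1, n1:] = A12
            M[n1:, :n1] = A12.T
        if A22 is not None:
            M[n1:, n1:] = A22
        return M

    V_parts = [
        block(A11=G11),                      # sigma2_A1
        block(A12=G12),                      # cov_A
        block(A22=G22),                      # sigma2_A2
        block(A11=np.eye(n1)),               # sigma2_E1
    ]
    names = ["sA1", "cA", "sA2", "sE1"]
    if residual_cov_free:
        V_parts.append(block(A12=np.eye(n1)))
        names.append("cE")
    V_parts.append(block(A22=np.eye(n2)))
    names.append("sE2")
    is_variance = [n[0] == "s" for n in names]
    cov_links = {names.index("cA"): (names.index("sA1"), names.index("sA2"))}
    if "cE" in names:
        cov_links[names.index("cE")] = (names.index("sE1"), names.index("sE2"))

    y = np.concatenate([y1, y2])
    X1 = np.asarray(X1, float)
    X2 = np.asarray(X2, float)
    X = np.zeros((N, X1.shape[1] + X2.shape[1]))
    X[:n1, : X1.shape[1]] = X1
    X[n1:, X1.shape[1]:] = X2

    b1, *_ = np.linalg.lstsq(X1, y1, rcond=None)
    b2, *_ = np.linalg.lstsq(X2, y2, rcond=None)
    r1, r2 = y1 - X1 @ b1, y2 - X2 @ b2
    s1 = float(np.var(r1, ddof=X1.shape[1]))
    s2 = float(np.var(r2, ddof=X2.shape[1]))
    theta0 = {"sA1": s1 / 2, "sA2": s2 / 2, "sE1": s1 / 2, "sE2": s2 / 2, "cA": 0.0, "cE": 0.0}
    if residual_cov_free:
        cp = float(np.cov(r1, r2)[0, 1])
        # cap implied starting correlations at 0.8 so degenerate inputs
        # (e.g. a duplicated trait) still give a PD starting V
        cap = 0.8 * np.sqrt(theta0["sA1"] * theta0["sA2"])
        theta0["cA"] = float(np.clip(cp / 2, -cap, cap))
        cap = 0.8 * np.sqrt(theta0["sE1"] * theta0["sE2"])
        theta0["cE"] = float(np.clip(cp / 2, -cap, cap))
    th0 = [theta0[n] for n in names]

    fit = _reml_core(y, X, V_parts, th0, is_variance, cov_links=cov_links, **core_kwargs)
    th = dict(zip(names, fit["theta"]))
    cov = fit["theta_cov"]

    t1, t2 = traits
    sigma2_a = {t1: th["sA1"], t2: th["sA2"]}
    sigma2_e = {t1: th["sE1"], t2: th["sE2"]}
    sigma2_p = {t: sigma2_a[t] + sigma2_e[t] for t in traits}

    def sub(names_sel):
        ii = [names.index(s) for s in names_sel]
        return cov[np.ix_(ii, ii)]

    h2, h2_se = {}, {}
    for t, (a_n, e_n) in zip(traits, (("sA1", "sE1"), ("sA2", "sE2"))):
        h2[t], h2_se[t] = heritability(sigma2_a[t], sigma2_p[t], sub([a_n, e_n]))

    r_g_raw, r_g_se = _corr_se(th["cA"], th["sA1"], th["sA2"], sub(["sA1", "cA", "sA2"]))
    boundary = {f"sigma2_a_{t}": fit["boundary"].get(names.index(n), False)
                for t, n in zip(traits, ("sA1", "sA2"))}
    r_g = r_g_raw
    if abs(r_g) > MAX_CORR - 1e-6:
        boundary["r_g"] = True
        r_g = float(np.clip(r_g, -1.0, 1.0))

    r_p = r_p_se = None
    cov_e = None
    if residual_cov_free:
        cov_e = th["cE"]
        cP = th["cA"] + th["cE"]
        # delta method on (sA1,cA,sA2,sE1,cE,sE2) for the phenotypic correlation
        v1, v2 = sigma2_p[t1], sigma2_p[t2]
        grad = np.zeros(len(names))
        grad[names.index("sA1")] = grad[names.index("sE1")] = -cP / (2 * v1**1.5 * np.sqrt(v2))
        grad[names.index("sA2")] = grad[names.index("sE2")] = -cP / (2 * v2**1.5 * np.sqrt(v1))
        grad[names.index("cA")] = grad[names.index("cE")] = 1.0 / np.sqrt(v1 * v2)
        r_p = float(cP / np.sqrt(v1 * v2))
        r_p_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    ebv = _bivariate_ebv(fit, grm, idx1, idx2, th, traits)
    return VarCompResult(
        traits=traits,
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        sigma2_p=sigma2_p,
        h2=h2,
        h2_se=h2_se,
        r_g=r_g,
        r_g_se=r_g_se,
        r_g_raw=r_g_raw,
        r_p=r_p,
        r_p_se=r_p_se,
        cov_a=th["cA"],
        cov_e=cov_e,
        loglik=fit["loglik"],
        converged=fit["converged"],
        boundary=boundary,
        trace=fit["trace"],
        theta=fit["theta"],
        theta_cov=cov,
        beta=fit["beta"],
        ebv=ebv,
    )


def _bivariate_ebv(fit, grm, idx1, idx2, th, traits):
    """One EBV per GRM animal per trait: a_hat_t = Cov(a_t, y) V^-1 (y-Xb).

    For the cross-environment design this predicts each animal in the pond
    where it has no record through the genetic covariance.
    """
    Py = fit["Py"]
    n1 = len(idx1)
    G1 = grm.G[:, idx1]
    G2 = grm.G[:, idx2]
    a1 = th["sA1"] * (G1 @ Py[:n1]) + th["cA"] * (G2 @ Py[n1:])
    a2 = th["cA"] * (G1 @ Py[:n1]) + th["sA2"] * (G2 @ Py[n1:])
    return pd.DataFrame(
        {f"ebv_{traits[0]}": a1, f"ebv_{traits[1]}": a2},
        index=pd.Index(grm.ids, name="fish_id"),
    )


def predict_ebv(result: VarCompResult) -> pd.DataFrame:
    """BLUP breeding values of the converged model (computed at fit time)."""
    if not result.converged:
        raise RemlError("cannot predict EBVs from a non-converged model")
    if result.ebv is None:
        raise RemlError("model carries no EBV solutions")
    return result.ebv
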