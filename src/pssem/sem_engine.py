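"""Confirmatory factor / structural equation estimation by discrepancy
minimization.

The model-implied covariance is the standard LISREL-type structure
``Sigma(theta) = Lambda Phi Lambda' + Theta`` for a pure measurement model
with standardized latent variables (factor variances fixed at 1, factor
correlations free), extended with a reduced-form block when factors are
regressed on observed exogenous covariates.

Three discrepancy functions are implemented.  Normal-theory ML minimizes

    F_ML = tr(S Sigma^-1) + log|Sigma| - log|S| - (p + q),

and WLS/ULS minimize the quadratic form ``(s - sigma)' W^-1 (s - sigma)``
in half-vectorized moments, with the ADF fourth-moment weight for WLS and
the identity for ULS.  The normal-theory weight ``W_ML^-1 = 0.5 D'(S^-1 x
S^-1) D`` (D the duplication matrix) is exposed for cross-checks: near the
minimum it reproduces the curvature of F_ML.

Estimates are invariant to whether the input matrix is Pearson- or
PS-based; the input's provenance is carried through to the result.  The
``mlr`` estimator shares ML's point estimates and replaces its standard
errors with the Huber-White sandwich computed from casewise score
contributions.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .ps_core import SampleMatrix

__all__ = [
    "CFAModel",
    "ParameterVector",
    "FitResult",
    "parse_model",
    "implied_sigma",
    "vech",
    "duplication_matrix",
    "duplication_weight_ml",
    "weight_wls",
    "fit",
    "fit_baseline",
    "standard_errors",
    "chi_square",
    "fit_indices",
]

ESTIMATORS = ("ml", "mlr", "wls", "uls", "ps-ml", "ps-mlr", "ps-wls", "ps-uls")

_BIG = 1e10          # objective value returned on a non-PD implied matrix
_THETA_FLOOR = 1e-3  # below this a residual variance flags a Heywood case


# ---------------------------------------------------------------------------
# model specification


@dataclass
class CFAModel:
    """A confirmatory factor model, optionally with structural regressions.

    ``loading_pattern[i, f]`` marks item i as loading on factor f;
    ``structural_pattern[f, k]`` marks factor f as regressed on exogenous
    observed covariate k.  Identification follows the standardized-latent
    convention: factor (residual) variances are fixed at 1 and factor
    correlations are free.
    """

    items: list[str]
    factors: list[str]
    loading_pattern: np.ndarray
    exog: list[str] = field(default_factory=list)
    structural_pattern: np.ndarray | None = None

    def __post_init__(self):
        self.loading_pattern = np.asarray(self.loading_pattern, dtype=bool)
        if self.loading_pattern.shape != (self.p, self.m):
            raise ValueError("loading pattern must be items x factors")
        if not self.loading_pattern.any(axis=0).all():
            raise ValueError("every factor needs at least one indicator")
        if not self.loading_pattern.any(axis=1).all():
            raise ValueError("every item must load on at least one factor")
        if self.q:
            self.structural_pattern = np.asarray(self.structural_pattern,
                                                 dtype=bool)
            if self.structural_pattern.shape != (self.m, self.q):
                raise ValueError("structural pattern must be factors x exog")
        else:
            self.structural_pattern = np.zeros((self.m, 0), dtype=bool)

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def m(self) -> int:
        return len(self.factors)

    @property
    def q(self) -> int:
        return len(self.exog)

    @property
    def observed(self) -> list[str]:
        return self.items + self.exog

    @property
    def n_free(self) -> dict:
        q = self.q
        return {
            "lambda": int(self.loading_pattern.sum()),
            "phi": self.m * (self.m - 1) // 2,
            "gamma": int(self.structural_pattern.sum()),
            "phi_x": q * (q + 1) // 2,
            "theta": self.p,
        }

    @property
    def t(self) -> int:
        return sum(self.n_free.values())

    @property
    def df(self) -> int:
        ptot = self.p + self.q
        return ptot * (ptot + 1) // 2 - self.t

    def to_syntax(self) -> str:
        lines = []
        for f, name in enumerate(self.factors):
            inds = [self.items[i] for i in np.flatnonzero(self.loading_pattern[:, f])]
            lines.append(f"{name} =~ " + " + ".join(inds))
        for f, name in enumerate(self.factors):
            preds = [self.exog[k] for k in np.flatnonzero(self.structural_pattern[f])]
            if preds:
                lines.append(f"{name} ~ " + " + ".join(preds))
        return "\n".join(lines)


_NAME = r"[A-Za-z_][A-Za-z0-9_.]*"


def parse_model(text: str) -> CFAModel:
    """Parse lavaan-style measurement/structural syntax.

    One line per factor, ``F1 =~ y1 + y2 + y3``; optional structural lines
    ``F1 ~ x1 + x2`` regress a factor on observed exogenous covariates.
    ``#`` starts a comment.  Round-trips with :meth:`CFAModel.to_syntax`.
    """
    meas: dict[str, list[str]] = {}
    struct: dict[str, list[str]] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=~" in line:
            lhs, rhs = line.split("=~", 1)
            op = meas
        elif "~" in line:
            lhs, rhs = line.split("~", 1)
            op = struct
        else:
            raise ValueError(f"cannot parse model line: {raw!r}")
        lhs = lhs.strip()
        terms = [t.strip() for t in rhs.split("+")]
        if not re.fullmatch(_NAME, lhs) or not all(
                re.fullmatch(_NAME, t) for t in terms):
            raise ValueError(f"bad variable name in line: {raw!r}")
        op.setdefault(lhs, []).extend(terms)
    if not meas:
        raise ValueError("model declares no factors (no '=~' lines)")
    factors = list(meas)
    items: list[str] = []
    for inds in meas.values():
        items.extend(i for i in inds if i not in items)
    unknown = set(struct) - set(factors)
    if unknown:
        raise ValueError(f"structural line for undeclared factor(s): {sorted(unknown)}")
    exog: list[str] = []
    for preds in struct.values():
        for v in preds:
            if v in items:
                raise ValueError(f"{v!r} is an indicator; only observed "
                                 "exogenous predictors are supported")
            if v not in exog:
                exog.append(v)
    lp = np.zeros((len(items), len(factors)), dtype=bool)
    for f, name in enumerate(factors):
        for ind in meas[name]:
            lp[items.index(ind), f] = True
    sp = np.zeros((len(factors), len(exog)), dtype=bool)
    for name, preds in struct.items():
        for v in preds:
            sp[factors.index(name), exog.index(v)] = True
    return CFAModel(items, factors, lp, exog, sp)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class ParameterVector:
    """Raw (untransformed) model parameters on their natural scales."""

    lambdas: np.ndarray        # p x m, zeros where pattern is fixed
    phi: np.ndarray            # m x m factor (residual) correlation matrix
    thetas: np.ndarray         # p residual variances
    gammas: np.ndarray         # m x q structural slopes
    phi_x: np.ndarray          # q x q exogenous covariance

    def as_dict(self, model: CFAModel) -> dict[str, float]:
        out = {}
        for i, f in zip(*np.nonzero(model.loading_pattern)):
            out[f"{model.factors[f]}=~{model.items[i]}"] = float(self.lambdas[i, f])
        for a in range(model.m):
            for b in range(a + 1, model.m):
                out[f"{model.factors[a]}~~{model.factors[b]}"] = float(self.phi[a, b])
        for f, k in zip(*np.nonzero(model.structural_pattern)):
            out[f"{model.factors[f]}~{model.exog[k]}"] = float(self.gammas[f, k])
        for i, item in enumerate(model.items):
            out[f"{item}~~{item}"] = float(self.thetas[i])
        return out


def _pack_raw(model: CFAModel, pv: ParameterVector) -> np.ndarray:
    parts = [pv.lambdas[model.loading_pattern]]
    iu = np.triu_indices(model.m, 1)
    parts.append(pv.phi[iu])
    if model.q:
        parts.append(pv.gammas[model.structural_pattern])
        il = np.tril_indices(model.q)
        parts.append(np.linalg.cholesky(pv.phi_x)[il])
    parts.append(pv.thetas)
    return np.concatenate(parts)


def _unpack_raw(model: CFAModel, raw: np.ndarray) -> ParameterVector:
    nf = model.n_free
    pos = 0
    lam = np.zeros((model.p, model.m))
    lam[model.loading_pattern] = raw[pos:pos + nf["lambda"]]
    pos += nf["lambda"]
    phi = np.eye(model.m)
    iu = np.triu_indices(model.m, 1)
    phi[iu] = raw[pos:pos + nf["phi"]]
    phi.T[iu] = phi[iu]
    pos += nf["phi"]
    gam = np.zeros((model.m, model.q))
    if model.q:
        gam[model.structural_pattern] = raw[pos:pos + nf["gamma"]]
        pos += nf["gamma"]
        chol = np.zeros((model.q, model.q))
        chol[np.tril_indices(model.q)] = raw[pos:pos + nf["phi_x"]]
        phi_x = chol @ chol.T
        pos += nf["phi_x"]
    else:
        phi_x = np.zeros((0, 0))
    thetas = raw[pos:pos + model.p]
    return ParameterVector(lam, phi, thetas, gam, phi_x)


# unconstrained <-> raw transforms: loadings/slopes/cholesky off-diagonals are
# identity, correlations go through tanh, variances through exp
def _free_layout(model: CFAModel):
    nf = model.n_free
    kinds = (["id"] * nf["lambda"] + ["corr"] * nf["phi"] + ["id"] * nf["gamma"])
    if model.q:
        il = np.tril_indices(model.q)
        kinds += ["var" if i == j else "id" for i, j in zip(*il)]
    kinds += ["var"] * nf["theta"]
    return np.array(kinds)


def _raw_to_free(raw: np.ndarray, kinds: np.ndarray) -> np.ndarray:
    u = raw.copy()
    corr = kinds == "corr"
    var = kinds == "var"
    u[corr] = np.arctanh(np.clip(raw[corr], -0.999999, 0.999999))
    u[var] = np.log(np.maximum(raw[var], 1e-12))
    return u


def _free_to_raw(u: np.ndarray, kinds: np.ndarray) -> np.ndarray:
    raw = u.copy()
    corr = kinds == "corr"
    var = kinds == "var"
    raw[corr] = np.tanh(u[corr])
    raw[var] = np.exp(np.clip(u[var], -40.0, 40.0))
    return raw


def _dr_du(u: np.ndarray, kinds: np.ndarray) -> np.ndarray:
    d = np.ones_like(u)
    corr = kinds == "corr"
    var = kinds == "var"
    d[corr] = 1.0 - np.tanh(u[corr]) ** 2
    d[var] = np.exp(np.clip(u[var], -40.0, 40.0))
    return d


# ---------------------------------------------------------------------------
# implied moments


def implied_sigma(model: CFAModel, pv: ParameterVector) -> np.ndarray:
    """Model-implied covariance among all observed variables (items, then
    exogenous covariates): ``Lambda Phi_eff Lambda' + Theta`` with
    ``Phi_eff = Gamma Phi_x Gamma' + Psi`` in the structural case."""
    lam, phi, thetas = pv.lambdas, pv.phi, pv.thetas
    if lam.shape != (model.p, model.m):
        raise ValueError("lambda dimension mismatch")
    if model.q:
        phi_eff = pv.gammas @ pv.phi_x @ pv.gammas.T + phi
        syy = lam @ phi_eff @ lam.T + np.diag(thetas)
        syx = lam @ pv.gammas @ pv.phi_x
        top = np.hstack([syy, syx])
        bot = np.hstack([syx.T, pv.phi_x])
        return np.vstack([top, bot])
    return lam @ phi @ lam.T + np.diag(thetas)


def vech(mat: np.ndarray) -> np.ndarray:
    """Column-major half-vectorization (s11, s21, ..., sp1, s22, ...)."""
    p = mat.shape[0]
    rows, cols = _vech_indices(p)
    return np.asarray(mat)[rows, cols]


def _vech_indices(p: int):
    cols, rows = np.triu_indices(p)       # upper triangle, row-major ==
    return rows, cols                     # lower triangle, column-major


def duplication_matrix(p: int) -> np.ndarray:
    """D with vec(M) = D vech(M) for symmetric M."""
    rows, cols = _vech_indices(p)
    nh = rows.size
    d = np.zeros((p * p, nh))
    for h, (i, j) in enumerate(zip(rows, cols)):
        d[i + j * p, h] = 1.0
        d[j + i * p, h] = 1.0
    return d


def duplication_weight_ml(S: np.ndarray) -> np.ndarray:
    """Normal-theory weight ``W_ML^-1 = 0.5 D'(S^-1 kron S^-1) D``; the
    quadratic form (s - sigma)' W_ML^-1 (s - sigma) matches F_ML locally."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    try:
        s_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular input matrix") from exc
    d = duplication_matrix(p)
    return 0.5 * d.T @ np.kron(s_inv, s_inv) @ d


def weight_wls(data) -> np.ndarray:
    """ADF (asymptotically distribution-free) weight matrix estimate.

    ``W[ij, kl] = m_ijkl - s_ij s_kl`` built from second and fourth central
    moments of the observed variables, in vech ordering.
    """
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    nh = p * (p + 1) // 2
    if n <= nh:
        warnings.warn(f"n={n} <= p(p+1)/2={nh}: ADF weight will be singular",
                      stacklevel=2)
    y = x - x.mean(axis=0)
    rows, cols = _vech_indices(p)
    z = y[:, rows] * y[:, cols]           # n x nh casewise moment products
    zc = z - z.mean(axis=0)
    return zc.T @ zc / n


# ---------------------------------------------------------------------------
# discrepancy functions and fitting


def _ml_value_grad(sigma, S, logdet_s, model, pv, want_grad):
    try:
        c, low = linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError:
        w = np.linalg.eigvalsh(sigma)
        return _BIG * (1.0 + abs(float(w[0]))), None
    logdet = 2.0 * np.log(np.diag(c)).sum()
    sigma_inv = linalg.cho_solve((c, low), np.eye(sigma.shape[0]))
    f = float(np.sum(sigma_inv * S) + logdet - logdet_s - sigma.shape[0])
    if not want_grad:
        return f, None
    g_mat = sigma_inv - sigma_inv @ S @ sigma_inv
    lam_phi = pv.lambdas @ pv.phi
    g_lam = 2.0 * (g_mat @ lam_phi)[model.loading_pattern]
    lgl = pv.lambdas.T @ g_mat @ pv.lambdas
    g_phi = 2.0 * lgl[np.triu_indices(model.m, 1)]
    g_theta = np.diag(g_mat)
    return f, np.concatenate([g_lam, g_phi, g_theta])


def _quad_value_grad(sigma, s_vec, w_inv, model, pv, want_grad):
    r = s_vec - vech(sigma)
    if w_inv is None:                      # ULS: identity weight
        wr = r
    else:
        wr = w_inv @ r
    f = float(r @ wr)
    if not want_grad:
        return f, None
    lam_phi = pv.lambdas @ pv.phi
    rows, cols = _vech_indices(model.p)
    grad = []
    for i, fac in zip(*np.nonzero(model.loading_pattern)):
        b = lam_phi[:, fac]
        dsig = np.zeros((model.p, model.p))
        dsig[i, :] += b
        dsig[:, i] += b
        grad.append(-2.0 * wr @ dsig[rows, cols])
    for a in range(model.m):
        for bb in range(a + 1, model.m):
            dsig = (np.outer(pv.lambdas[:, a], pv.lambdas[:, bb])
                    + np.outer(pv.lambdas[:, bb], pv.lambdas[:, a]))
            grad.append(-2.0 * wr @ dsig[rows, cols])
    diag_mask = rows == cols
    g_theta = -2.0 * wr * diag_mask
    # vech positions of (i, i) in column order
    for i in range(model.p):
        h = np.flatnonzero((rows == i) & (cols == i))[0]
        grad.append(g_theta[h])
    return f, np.asarray(grad)


def _start_values(model: CFAModel, S: np.ndarray) -> ParameterVector:
    lam = np.where(model.loading_pattern, 0.5, 0.0)
    phi = np.full((model.m, model.m), 0.2)
    np.fill_diagonal(phi, 1.0)
    thetas = 0.5 * np.diag(S)[: model.p]
    gam = np.where(model.structural_pattern, 0.1, 0.0)
    if model.q:
        phi_x = np.asarray(S)[model.p:, model.p:].copy()
    else:
        phi_x = np.zeros((0, 0))
    return ParameterVector(lam, phi, thetas, gam, phi_x)


def _base_estimator(estimator: str) -> str:
    base = estimator[3:] if estimator.startswith("ps-") else estimator
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    return "ml" if base == "mlr" else base


@dataclass
class FitResult:
    """Outcome of one discrepancy minimization."""

    model: CFAModel
    estimates: ParameterVector
    T: float
    df: int
    chi2: float
    chi2_is_chisq: bool
    converged: bool
    heywood: bool
    estimator: str
    input_kind: str
    n: int
    se: dict[str, float] | None = None
    cfi: float | None = None
    rmsea: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "estimator": self.estimator,
            "input_kind": self.input_kind,
            "n": int(self.n),
            "converged": bool(self.converged),
            "heywood": bool(self.heywood),
            "estimates": self.estimates.as_dict(self.model),
            "se": self.se,
            "T": self.T,
            "chi2": self.chi2,
            "chi2_is_chisq": self.chi2_is_chisq,
            "df": int(self.df),
            "cfi": self.cfi,
            "rmsea": self.rmsea,
            "warnings": self.warnings,
        }, indent=2)


def _make_objective(model, estimator_base, S, raw_data):
    """Return f(u) -> (value, grad-or-None) plus metadata."""
    S = np.asarray(S, dtype=float)
    analytic = model.q == 0
    kinds = _free_layout(model)
    if estimator_base == "ml":
        sign, logdet_s = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("input matrix is not positive-definite; "
                             "apply ensure_estimable first")

        def objective(u, want_grad=True):
            pv = _unpack_raw(model, _free_to_raw(u, kinds))
            sigma = implied_sigma(model, pv)
            f, g = _ml_value_grad(sigma, S, logdet_s, model, pv,
                                  want_grad and analytic)
            if g is None:
                return f, None
            return f, g * _dr_du(u, kinds)
        return objective, kinds, analytic

    if estimator_base == "wls":
        if raw_data is None:
            raise ValueError("WLS requires raw_data for the ADF weight matrix")
        w = weight_wls(raw_data)
        try:
            w_inv = np.linalg.inv(w)
        except np.linalg.LinAlgError:
            warnings.warn("singular ADF weight; using pseudo-inverse", stacklevel=3)
            w_inv = np.linalg.pinv(w)
    else:   # uls
        w_inv = None
    s_vec = vech(S)

    def objective(u, want_grad=True):
        pv = _unpack_raw(model, _free_to_raw(u, kinds))
        sigma = implied_sigma(model, pv)
        f, g = _quad_value_grad(sigma, s_vec, w_inv, model, pv,
                                want_grad and analytic)
        if g is None:
            return f, None
        return f, g * _dr_du(u, kinds)
    return objective, kinds, analytic


def fit(model: CFAModel, S: SampleMatrix | np.ndarray, n: int | None = None,
        estimator: str = "ml", raw_data=None, seed: int = 0,
        max_restarts: int = 5) -> FitResult:
    """Estimate the model by minimizing the chosen discrepancy over theta.

    ``S`` may be a :class:`~pssem.ps_core.SampleMatrix` (its ``n`` and
    provenance are used) or a bare array (then ``n`` is required).  The
    ``ps-*`` estimator names denote the same discrepancies applied to a
    PS-based input matrix.  Bounds are enforced through log / atanh
    parameter transforms; on non-convergence up to ``max_restarts``
    jittered restarts are attempted.
    """
    if isinstance(S, SampleMatrix):
        n = S.n if n is None else n
        input_kind = S.kind
        s_arr = S.values
        if estimator.startswith("ps-") != (S.kind == "ps"):
            warnings.warn(f"estimator {estimator!r} applied to a {S.kind} "
                          "input matrix", stacklevel=2)
    else:
        if n is None:
            raise ValueError("n is required when S is a bare array")
        input_kind = "unknown"
        s_arr = np.asarray(S, dtype=float)
    if s_arr.shape[0] != model.p + model.q:
        raise ValueError(f"matrix order {s_arr.shape[0]} does not match "
                         f"model's {model.p + model.q} observed variables")
    base = _base_estimator(estimator)
    objective, kinds, analytic = _make_objective(model, base, s_arr, raw_data)
    u0 = _raw_to_free(_pack_raw(model, _start_values(model, s_arr)), kinds)

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max_restarts + 1):
        u_start = u0 if attempt == 0 else u0 + rng.normal(0, 0.3, size=u0.size)
        if analytic:
            res = optimize.minimize(objective, u_start, jac=True,
                                    method="L-BFGS-B",
                                    options={"maxiter": 500, "ftol": 1e-12,
                                             "gtol": 1e-7})
        else:
            res = optimize.minimize(lambda u: objective(u, False)[0], u_start,
                                    method="L-BFGS-B",
                                    options={"maxiter": 1000, "ftol": 1e-12,
                                             "gtol": 1e-7})
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        ok = bool(res.success) and res.fun < _BIG and (gnorm < 1e-5 or res.fun < 1e-10)
        if best is None or res.fun < best[0].fun:
            best = (res, ok)
        if ok:
            break
    res, converged = best
    pv = _unpack_raw(model, _free_to_raw(res.x, kinds))
    heywood = bool(np.any(pv.thetas < _THETA_FLOOR)
                   or np.any(np.abs(pv.phi[np.triu_indices(model.m, 1)]) > 0.995))
    t_val = max(float(res.fun), 0.0)
    chi2, is_chisq = chi_square(t_val, n, estimator)
    warns = []
    if heywood:
        warns.append("Heywood case: a parameter estimate sits at its boundary")
    if not converged:
        warns.append("optimizer did not converge")
    return FitResult(model=model, estimates=pv, T=t_val, df=model.df,
                     chi2=chi2, chi2_is_chisq=is_chisq, converged=converged,
                     heywood=heywood, estimator=estimator,
                     input_kind=input_kind, n=int(n), warnings=warns)


def chi_square(t_value: float, n: int, estimator: str = "ml"):
    """Scale a discrepancy value to the chi-square metric, ``(n-1) T``.

    ULS produces an unscaled value that does not follow a chi-square
    distribution; it is still scaled for reporting but flagged.
    """
    base = _base_estimator(estimator) if estimator in ESTIMATORS else estimator
    return (n - 1) * t_value, base != "uls"


# ---------------------------------------------------------------------------
# standard errors


def _num_hessian(fun, x0, h=1e-5):
    t = x0.size
    hess = np.zeros((t, t))
    f0 = fun(x0)
    for a in range(t):
        for b in range(a, t):
            xpp = x0.copy(); xpp[[a, b]] += h
            xpm = x0.copy(); xpm[a] += h; xpm[b] -= h
            xmp = x0.copy(); xmp[a] -= h; xmp[b] += h
            xmm = x0.copy(); xmm[[a, b]] -= h
            if a == b:
                xp = x0.copy(); xp[a] += h
                xm = x0.copy(); xm[a] -= h
                hess[a, a] = (fun(xp) - 2 * f0 + fun(xm)) / h**2
            else:
                hess[a, b] = hess[b, a] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * h**2)
    return hess


def standard_errors(fitres: FitResult, S: SampleMatrix | np.ndarray,
                    raw_data=None) -> dict[str, float]:
    """Per-parameter standard errors, stored on the fit and returned.

    ML/WLS/ULS use the inverse curvature of the (n-1)-scaled discrepancy at
    the optimum, ``SE = sqrt(diag((0.5 (n-1) H)^-1))``.  MLR uses the
    Huber-White sandwich ``A^-1 B A^-1`` from casewise score contributions,
    which requires ``raw_data``.
    """
    model = fitres.model
    n = fitres.n
    s_arr = S.values if isinstance(S, SampleMatrix) else np.asarray(S, float)
    base = _base_estimator(fitres.estimator)
    raw_hat = _pack_raw(model, fitres.estimates)

    if base == "ml":
        _, logdet_s = np.linalg.slogdet(s_arr)

        def f_raw(raw):
            pv = _unpack_raw(model, raw)
            f, _ = _ml_value_grad(implied_sigma(model, pv), s_arr, logdet_s,
                                  model, pv, False)
            return f
    else:
        if base == "wls":
            if raw_data is None:
                raise ValueError("WLS standard errors require raw_data")
            w_inv = np.linalg.pinv(weight_wls(raw_data))
        else:
            w_inv = None
        s_vec = vech(s_arr)

        def f_raw(raw):
            pv = _unpack_raw(model, raw)
            f, _ = _quad_value_grad(implied_sigma(model, pv), s_vec, w_inv,
                                    model, pv, False)
            return f

    hess = _num_hessian(f_raw, raw_hat)
    is_mlr = fitres.estimator.replace("ps-", "") == "mlr"
    if is_mlr:
        if raw_data is None:
            raise ValueError("MLR standard errors require raw_data")
        cov = _sandwich_cov(model, raw_hat, np.asarray(raw_data, float), hess, n)
    else:
        try:
            cov = np.linalg.inv(0.5 * (n - 1) * hess)
        except np.linalg.LinAlgError:
            fitres.warnings.append("singular information: SEs unavailable")
            fitres.se = None
            return None
    diag = np.diag(cov)
    if np.any(diag <= 0):
        fitres.warnings.append("non-positive information curvature: SEs unreliable")
        diag = np.abs(diag)
    ses = np.sqrt(diag)
    names = list(fitres.estimates.as_dict(model))
    fitres.se = dict(zip(names, map(float, ses)))
    return fitres.se


def _casewise_loglik(model, raw, y):
    pv = _unpack_raw(model, raw)
    sigma = implied_sigma(model, pv)
    c, low = linalg.cho_factor(sigma, lower=True)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    sol = linalg.cho_solve((c, low), y.T)
    quad = np.sum(y.T * sol, axis=0)
    return -0.5 * (logdet + quad)


def _sandwich_cov(model, raw_hat, data, hess_f, n):
    y = data - data.mean(axis=0)
    h = 1e-5
    t = raw_hat.size
    scores = np.zeros((n, t))
    for j in range(t):
        rp = raw_hat.copy(); rp[j] += h
        rm = raw_hat.copy(); rm[j] -= h
        scores[:, j] = (_casewise_loglik(model, rp, y)
                        - _casewise_loglik(model, rm, y)) / (2 * h)
    a_mat = 0.5 * n * hess_f          # observed information of the total loglik
    b_mat = scores.T @ scores
    a_inv = np.linalg.inv(a_mat)
    return a_inv @ b_mat @ a_inv


# ---------------------------------------------------------------------------
# baseline model and fit indices


def fit_baseline(S: SampleMatrix | np.ndarray, n: int | None = None,
                 estimator: str = "ml", raw_data=None):
    """Fit the independence baseline (free variances, zero covariances).

    Returns ``(chi2_baseline, df_baseline)``.  ML has the closed form
    ``F = -log|R|``; WLS/ULS solve the diagonal-restricted quadratic form
    in closed form.
    """
    if isinstance(S, SampleMatrix):
        n = S.n if n is None else n
        s_arr = S.values
    else:
        s_arr = np.asarray(S, dtype=float)
        if n is None:
            raise ValueError("n is required when S is a bare array")
    p = s_arr.shape[0]
    df_b = p * (p + 1) // 2 - p
    base = _base_estimator(estimator)
    if base == "ml":
        d = np.sqrt(np.diag(s_arr))
        r = s_arr / np.outer(d, d)
        sign, logdet_r = np.linalg.slogdet(r)
        if sign <= 0:
            raise ValueError("singular input matrix")
        f_b = -logdet_r
    else:
        rows, cols = _vech_indices(p)
        s_vec = vech(s_arr)
        sel = np.zeros((s_vec.size, p))
        for i in range(p):
            sel[np.flatnonzero((rows == i) & (cols == i))[0], i] = 1.0
        if base == "wls":
            if raw_data is None:
                raise ValueError("WLS baseline requires raw_data")
            w_inv = np.linalg.pinv(weight_wls(raw_data))
        else:
            w_inv = np.eye(s_vec.size)
        a = sel.T @ w_inv @ sel
        d_hat = np.linalg.solve(a, sel.T @ w_inv @ s_vec)
        r_vec = s_vec - sel @ d_hat
        f_b = float(r_vec @ w_inv @ r_vec)
    return (n - 1) * max(f_b, 0.0), df_b


def fit_indices(chi2: float, df: int, chi2_baseline: float, df_baseline: int,
                n: int):
    """Comparative fit index and RMSEA from model and baseline chi-squares.

    ``CFI = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0)``
    (clipped to [0, 1]); ``RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1)))``.
    """
    if df <= 0 or df_baseline <= 0:
        raise ValueError("degrees of freedom must be positive")
    ncp = max(chi2 - df, 0.0)
    ncp_b = max(chi2_baseline - df_baseline, 0.0)
    denom = max(ncp_b, ncp)
    cfi = 1.0 if denom == 0.0 else 1.0 - ncp / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    rmsea = float(np.sqrt(ncp / (df * (n - 1))))
    return cfi, rmsea
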