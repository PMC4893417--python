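"""Covariance-structure (SEM) estimation with latent variables.

The model is held in RAM form: for the stacked variable vector v
(latents first, then observed variables),

    v = A v + u,      Cov(u) = S,      observed = F v,

so the implied covariance of the observed variables is
``Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T``.  Free parameters are
directed coefficients (structural paths and loadings), covariances of
exogenous terms / residuals, and residual variances.  Estimation is
maximum likelihood: the discrepancy

    F_ML = ln|Sigma| + tr(S_obs Sigma^-1) - ln|S_obs| - p

is minimised by quasi-Newton iteration with an analytic gradient.
Standard errors come from the inverse expected information,
modification indices are score (Lagrange-multiplier) tests for fixed
parameters, and ``respecify`` runs the greedy BIC-guided search used to
add residual covariance arcs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "PathEdge",
    "CovEdge",
    "SemModelSpec",
    "RamMatrices",
    "SemFit",
    "build_ram",
    "implied_covariance",
    "fit_ml",
    "fit_indices",
    "independence_chi2",
    "modification_indices",
    "respecify",
    "saturated_spec",
]

_PENALTY = 1e12  # objective value returned outside the PD region


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathEdge:
    """Directed edge ``src -> dst`` (structural path or loading)."""

    src: str
    dst: str
    free: bool = True
    value: float | None = None  # start value if free, fixed value otherwise

    @property
    def name(self) -> str:
        return f"{self.src}->{self.dst}"


@dataclass(frozen=True)
class CovEdge:
    """Two-headed arc ``a <-> b`` between exogenous terms / residuals."""

    a: str
    b: str
    free: bool = True
    value: float | None = None

    @property
    def name(self) -> str:
        return f"{self.a}<->{self.b}"


@dataclass(frozen=True)
class SemModelSpec:
    """Graph specification of a latent-variable covariance model.

    Parameters
    ----------
    latents, observed
        Variable names; the two sets must be disjoint.
    paths
        Directed edges.  Latent-to-observed edges are loadings,
        latent-to-latent edges structural paths.
    covariances
        Residual covariance arcs (between observed residuals) or
        covariances between exogenous latents.
    latent_scaling
        ``"unit_variance"`` fixes every exogenous latent variance to 1
        and frees endogenous latent residual variances (the reported
        solution is re-standardized afterwards); ``"marker"`` instead
        fixes the first loading of each latent to 1 and frees all latent
        (residual) variances.
    """

    latents: tuple[str, ...]
    observed: tuple[str, ...]
    paths: tuple[PathEdge, ...]
    covariances: tuple[CovEdge, ...] = ()
    latent_scaling: str = "unit_variance"

    def __post_init__(self):
        object.__setattr__(self, "latents", tuple(self.latents))
        object.__setattr__(self, "observed", tuple(self.observed))
        object.__setattr__(self, "paths", tuple(self.paths))
        object.__setattr__(self, "covariances", tuple(self.covariances))
        self.validate()

    # -- bookkeeping -------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return self.latents + self.observed

    def validate(self) -> None:
        if set(self.latents) & set(self.observed):
            raise ValueError("latent and observed names overlap")
        known = set(self.names)
        seen = set()
        for e in self.paths:
            if e.src not in known or e.dst not in known:
                raise ValueError(f"unknown variable in path {e.name}")
            if (e.src, e.dst) in seen:
                raise ValueError(f"duplicate path {e.name}")
            seen.add((e.src, e.dst))
        seenc = set()
        for c in self.covariances:
            if c.a not in known or c.b not in known:
                raise ValueError(f"unknown variable in covariance {c.name}")
            key = frozenset((c.a, c.b))
            if key in seenc:
                raise ValueError(f"duplicate covariance {c.name}")
            seenc.add(key)
        if self.latent_scaling not in ("unit_variance", "marker"):
            raise ValueError(f"unknown latent_scaling {self.latent_scaling!r}")
        g = nx.DiGraph()
        g.add_nodes_from(self.latents)
        g.add_edges_from(
            (e.src, e.dst)
            for e in self.paths
            if e.src in self.latents and e.dst in self.latents
        )
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("directed cycles among latent variables")
        reached = {e.dst for e in self.paths}
        for v in self.observed:
            if v not in reached:
                # allowed: the variable then only carries a free variance
                continue

    def endogenous_latents(self) -> tuple[str, ...]:
        dsts = {e.dst for e in self.paths}
        return tuple(l for l in self.latents if l in dsts)

    def exogenous_latents(self) -> tuple[str, ...]:
        dsts = {e.dst for e in self.paths}
        return tuple(l for l in self.latents if l not in dsts)

    # -- serialisation -----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "latents": list(self.latents),
            "observed": list(self.observed),
            "paths": [
                {"src": e.src, "dst": e.dst, "free": e.free, "value": e.value}
                for e in self.paths
            ],
            "covariances": [
                {"a": c.a, "b": c.b, "free": c.free, "value": c.value}
                for c in self.covariances
            ],
            "latent_scaling": self.latent_scaling,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SemModelSpec":
        try:
            doc = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                doc = json.load(fh)
        return cls(
            latents=tuple(doc["latents"]),
            observed=tuple(doc["observed"]),
            paths=tuple(PathEdge(**e) for e in doc["paths"]),
            covariances=tuple(CovEdge(**c) for c in doc["covariances"]),
            latent_scaling=doc.get("latent_scaling", "unit_variance"),
        )

    def to_dot(self) -> str:
        lines = ["digraph sem {", "  rankdir=LR;"]
        for l in self.latents:
            lines.append(f'  "{l}" [shape=ellipse];')
        for o in self.observed:
            lines.append(f'  "{o}" [shape=box];')
        for e in self.paths:
            lab = "" if e.value is None else f' [label="{e.value:g}"]'
            lines.append(f'  "{e.src}" -> "{e.dst}"{lab};')
        for c in self.covariances:
            lab = 'dir=both, style=dashed'
            if c.value is not None:
                lab += f', label="{c.value:g}"'
            lines.append(f'  "{c.a}" -> "{c.b}" [{lab}];')
        lines.append("}")
        return "\n".join(lines)


def saturated_spec(observed) -> SemModelSpec:
    """Model with every covariance among the observed variables free."""
    observed = tuple(observed)
    covs = tuple(
        CovEdge(observed[i], observed[j])
        for i in range(len(observed))
        for j in range(i + 1, len(observed))
    )
    return SemModelSpec(latents=(), observed=observed, paths=(), covariances=covs)


# ---------------------------------------------------------------------------
# RAM assembly
# ---------------------------------------------------------------------------

@dataclass
class RamMatrices:
    """RAM matrices with slot maps from the free-parameter vector theta."""

    names: tuple[str, ...]
    n_latent: int
    a_base: np.ndarray          # fixed part of A
    s_base: np.ndarray          # fixed part of S
    param_names: tuple[str, ...]
    a_slots: list               # (theta_index, row, col)
    s_slots: list               # (theta_index, row, col)  (symmetrised)
    start: np.ndarray

    @property
    def m(self) -> int:
        return len(self.names)

    @property
    def obs_idx(self) -> np.ndarray:
        return np.arange(self.n_latent, self.m)

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = self.a_base.copy()
        S = self.s_base.copy()
        for k, i, j in self.a_slots:
            A[i, j] = theta[k]
        for k, i, j in self.s_slots:
            S[i, j] = theta[k]
            S[j, i] = theta[k]
        return A, S


def build_ram(spec: SemModelSpec) -> RamMatrices:
    names = spec.names
    idx = {v: i for i, v in enumerate(names)}
    m = len(names)
    a_base = np.zeros((m, m))
    s_base = np.zeros((m, m))
    a_slots, s_slots, pnames, start = [], [], [], []

    marker_fixed: set[str] = set()
    if spec.latent_scaling == "marker":
        for l in spec.latents:
            for e in spec.paths:
                if e.src == l and e.dst in spec.observed:
                    marker_fixed.add(e.name)
                    break

    k = 0
    for e in spec.paths:
        i, j = idx[e.dst], idx[e.src]  # A[i, j]: coefficient of src on dst
        if e.name in marker_fixed:
            a_base[i, j] = 1.0 if e.value is None else e.value
        elif e.free:
            a_slots.append((k, i, j))
            pnames.append(e.name)
            start.append(0.5 if e.value is None else e.value)
            k += 1
        else:
            a_base[i, j] = 0.0 if e.value is None else e.value

    for c in spec.covariances:
        i, j = idx[c.a], idx[c.b]
        if c.free:
            s_slots.append((k, i, j))
            pnames.append(c.name)
            start.append(0.0 if c.value is None else c.value)
            k += 1
        else:
            s_base[i, j] = s_base[j, i] = 0.0 if c.value is None else c.value

    exo = set(spec.exogenous_latents())
    for v in names:
        i = idx[v]
        if v in exo and spec.latent_scaling == "unit_variance":
            s_base[i, i] = 1.0
        else:
            s_slots.append((k, i, i))
            pnames.append(f"var({v})")
            start.append(0.5)
            k += 1

    return RamMatrices(
        names=names,
        n_latent=len(spec.latents),
        a_base=a_base,
        s_base=s_base,
        param_names=tuple(pnames),
        a_slots=a_slots,
        s_slots=s_slots,
        start=np.asarray(start, dtype=float),
    )


def implied_covariance(ram: RamMatrices, theta) -> np.ndarray:
    """``F (I-A)^-1 S (I-A)^-T F^T`` at the given parameter point."""
    theta = np.asarray(theta, dtype=float)
    A, S = ram.matrices(theta)
    ima = np.eye(ram.m) - A
    try:
        B = linalg.inv(ima)
    except linalg.LinAlgError as err:
        raise ValueError("(I - A) is singular") from err
    V = B @ S @ B.T
    o = ram.obs_idx
    return V[np.ix_(o, o)]


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _prepare_cov(spec, s_obs, var_order):
    if isinstance(s_obs, pd.DataFrame):
        s = s_obs.loc[list(spec.observed), list(spec.observed)].to_numpy(float)
        return s
    s = np.asarray(s_obs, dtype=float)
    if var_order is not None and tuple(var_order) != spec.observed:
        order = [list(var_order).index(v) for v in spec.observed]
        s = s[np.ix_(order, order)]
    return s


def _fml_and_grad(theta, ram, s_obs, logdet_s):
    m, p = ram.m, len(ram.obs_idx)
    A, S = ram.matrices(theta)
    ima = np.eye(m) - A
    try:
        B = linalg.inv(ima)
    except linalg.LinAlgError:
        return _PENALTY, np.zeros_like(theta)
    V = B @ S @ B.T
    o = ram.obs_idx
    Sigma = V[np.ix_(o, o)]
    try:
        c, low = linalg.cho_factor(Sigma, check_finite=False)
    except linalg.LinAlgError:
        return _PENALTY, np.zeros_like(theta)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Sig_inv = linalg.cho_solve((c, low), np.eye(p), check_finite=False)
    f = logdet + float(np.sum(Sig_inv * s_obs)) - logdet_s - p
    # gradient: dF/dtheta_k = tr(M dSigma_k), M = Sig^-1 - Sig^-1 S_obs Sig^-1
    M = Sig_inv - Sig_inv @ s_obs @ Sig_inv
    W = np.zeros((m, m))
    W[np.ix_(o, o)] = M
    WB = W @ B
    GA = 2.0 * (B.T @ W @ V)          # dF/dA[i,j]
    GS = B.T @ WB                     # building block for S slots
    grad = np.zeros_like(theta)
    for k, i, j in ram.a_slots:
        grad[k] = GA[i, j]
    for k, i, j in ram.s_slots:
        grad[k] = GS[i, j] if i == j else 2.0 * GS[i, j]
    return f, grad


def _dsigma_matrices(ram, theta):
    """dSigma/dtheta_k for every free parameter, at theta."""
    A, S = ram.matrices(theta)
    m = ram.m
    B = linalg.inv(np.eye(m) - A)
    V = B @ S @ B.T
    o = ram.obs_idx
    out = [None] * (len(ram.a_slots) + len(ram.s_slots))
    for k, i, j in ram.a_slots:
        T = np.outer(B[:, i], V[j, :])
        D = T + T.T
        out[k] = D[np.ix_(o, o)]
    for k, i, j in ram.s_slots:
        T = np.outer(B[:, i], B[:, j])
        D = T if i == j else T + T.T
        out[k] = D[np.ix_(o, o)]
    return out, V


def _expected_information(sigma_inv, dsigmas):
    """0.5 tr(Sig^-1 dSig_i Sig^-1 dSig_j) for all pairs."""
    K = np.array([sigma_inv @ D for D in dsigmas])
    q = len(dsigmas)
    info = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            info[i, j] = info[j, i] = 0.5 * np.sum(K[i] * K[j].T)
    return info


@dataclass
class SemFit:
    """Result of a maximum-likelihood covariance-structure fit."""

    spec: SemModelSpec
    ram: RamMatrices
    theta: np.ndarray
    s_obs: np.ndarray
    n: int
    f_min: float
    converged: bool
    n_iter: int
    grad_norm: float
    heywood: tuple[str, ...] = ()

    # filled in by fit_ml
    se: np.ndarray | None = None
    chi2: float = np.nan
    df: int = 0
    indices: dict = field(default_factory=dict)

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.ram.param_names

    @property
    def estimates(self) -> dict:
        return dict(zip(self.param_names, self.theta))

    @property
    def sigma_hat(self) -> np.ndarray:
        return implied_covariance(self.ram, self.theta)

    # -- standardized solution --------------------------------------------
    def standardized(self) -> dict:
        """Standardized estimates for every path and covariance parameter.

        Directed coefficients are rescaled to unit-variance variables;
        covariance arcs are reported as correlations of the residuals
        they connect (matching the scale on which two-headed arcs are
        printed in standardized path diagrams).
        """
        A, S = self.ram.matrices(self.theta)
        m = self.ram.m
        B = linalg.inv(np.eye(m) - A)
        V = B @ S @ B.T
        sd = np.sqrt(np.clip(np.diag(V), 1e-12, None))
        idx = {v: i for i, v in enumerate(self.ram.names)}
        out = {}
        for e in self.spec.paths:
            i, j = idx[e.dst], idx[e.src]
            out[e.name] = A[i, j] * sd[j] / sd[i]
        for c in self.spec.covariances:
            i, j = idx[c.a], idx[c.b]
            # residual correlation; under a Heywood case (negative
            # variance estimate) the correlation is undefined, so the
            # magnitude is computed on |variances| and clipped to +-1
            denom = np.sqrt(max(abs(S[i, i]) * abs(S[j, j]), 1e-12))
            out[c.name] = float(np.clip(S[i, j] / denom, -1.0, 1.0))
        return out

    def parameter_table(self) -> pd.DataFrame:
        std = self.standardized()
        se = self.se if self.se is not None else np.full_like(self.theta, np.nan)
        z = np.where(se > 0, self.theta / se, np.nan)
        pv = 2.0 * stats.norm.sf(np.abs(z))
        rows = []
        for k, name in enumerate(self.param_names):
            rows.append(
                {
                    "parameter": name,
                    "estimate": self.theta[k],
                    "se": se[k],
                    "z": z[k],
                    "p_value": pv[k],
                    "standardized": std.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def fit_summary(self) -> dict:
        return {
            "f_min": float(self.f_min),
            "chi2": float(self.chi2),
            "df": self.df,
            "n": self.n,
            "converged": bool(self.converged),
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "heywood": list(self.heywood),
            **self.indices,
        }


def fit_ml(
    spec: SemModelSpec,
    s_obs,
    n: int,
    var_order=None,
    start=None,
    heywood: str = "warn",
    max_iter: int = 1000,
    f_tol: float = 1e-8,
    compute_se: bool = True,
) -> SemFit:
    """Fit the model to a sample covariance (or correlation) matrix.

    Parameters
    ----------
    s_obs
        Sample covariance matrix (DataFrame, or array with ``var_order``
        giving the column names).  Must be positive-definite.
    n
        Number of cases behind ``s_obs``; ``chi2 = (n - 1) * F_min``.
    heywood
        ``"warn"`` (default) flags negative residual variances in the
        solution; ``"bound"`` constrains variance parameters to be
        non-negative during optimisation.
    """
    ram = build_ram(spec)
    s = _prepare_cov(spec, s_obs, var_order)
    p = len(spec.observed)
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive-definite")
    q = len(ram.param_names)
    if n <= q:
        raise ValueError(f"n = {n} does not exceed the {q} free parameters")

    theta0 = ram.start.copy() if start is None else np.asarray(start, float)
    bounds = None
    if heywood == "bound":
        bounds = [(None, None)] * q
        for k, i, j in ram.s_slots:
            if i == j:
                bounds[k] = (0.0, None)

    res = optimize.minimize(
        _fml_and_grad,
        theta0,
        args=(ram, s, logdet_s),
        method="L-BFGS-B",
        jac=True,
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": f_tol * 1e-2, "gtol": 1e-9},
    )
    theta = res.x
    f_min, grad = _fml_and_grad(theta, ram, s, logdet_s)
    gnorm = float(np.max(np.abs(grad)))
    # Newton polish with the expected information (Hessian of F is 2I):
    # L-BFGS-B stops on function decrease; a few scoring steps push the
    # gradient to the reporting tolerance
    for _ in range(20):
        if gnorm < 1e-7 or f_min >= _PENALTY / 2:
            break
        dsig, _ = _dsigma_matrices(ram, theta)
        try:
            sigma_inv = linalg.inv(implied_covariance(ram, theta))
        except (linalg.LinAlgError, ValueError):
            break
        info = _expected_information(sigma_inv, dsig)
        # pinvh handles the near-singular information of near-unit loadings
        step = linalg.pinvh(2.0 * info) @ grad
        scale = 1.0
        improved = False
        for _half in range(8):
            cand = theta - scale * step
            if bounds is not None:
                cand = np.clip(cand, [b[0] if b[0] is not None else -np.inf
                                      for b in bounds], np.inf)
            f_c, g_c = _fml_and_grad(cand, ram, s, logdet_s)
            if (f_c <= f_min + 1e-14
                    and float(np.max(np.abs(g_c))) < gnorm):
                theta, f_min, grad = cand, f_c, g_c
                gnorm = float(np.max(np.abs(grad)))
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
    converged = bool(res.success and f_min < _PENALTY / 2)
    if not converged:
        err = RuntimeError(
            f"SEM fit did not converge: {res.message}; |grad|_inf = {gnorm:.3g}"
        )
        err.best_theta = theta  # carried for diagnosis
        err.grad_norm = gnorm
        raise err

    hey = []
    _, S = ram.matrices(theta)
    for k, i, j in ram.s_slots:
        if i == j and theta[k] < 0:
            hey.append(ram.param_names[k])
    if hey and heywood == "warn":
        warnings.warn(f"Heywood case: negative variance for {hey}", stacklevel=2)

    df = p * (p + 1) // 2 - q
    chi2 = (n - 1) * f_min
    fit = SemFit(
        spec=spec,
        ram=ram,
        theta=theta,
        s_obs=s,
        n=n,
        f_min=f_min,
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=gnorm,
        heywood=tuple(hey),
        chi2=chi2,
        df=df,
    )

    if compute_se:
        dsig, _ = _dsigma_matrices(ram, theta)
        sigma = implied_covariance(ram, theta)
        sigma_inv = linalg.inv(sigma)
        info = _expected_information(sigma_inv, dsig)
        # pinvh tolerates the near-singular information of near-unit
        # loadings (residual variance ~ 1e-3) without spurious warnings
        acov = linalg.pinvh(info) / (n - 1)
        fit.se = np.sqrt(np.clip(np.diag(acov), 0, None))

    chi2_null, df_null = independence_chi2(s, n)
    fit.indices = fit_indices(
        chi2, df, n, chi2_null, df_null, s, implied_covariance(ram, theta)
    )
    return fit


def independence_chi2(s_obs, n: int) -> tuple[float, int]:
    """Chi-square of the independence (free-variances-only) null model."""
    s = np.asarray(s_obs, float)
    p = s.shape[0]
    _, logdet_s = np.linalg.slogdet(s)
    f_null = float(np.sum(np.log(np.diag(s))) - logdet_s)
    return (n - 1) * f_null, p * (p - 1) // 2


def fit_indices(chi2, df, n, chi2_null, df_null, s_obs, sigma_hat) -> dict:
    """RMSEA, NFI, GFI and BIC for a fitted covariance structure.

    ``RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1)))`` (0 with a flag
    when df = 0), ``NFI = (chi2_null - chi2)/chi2_null``,
    ``GFI = 1 - tr[(Sig^-1 S - I)^2] / tr[(Sig^-1 S)^2]`` and
    ``BIC = chi2 - df ln(n)`` (the form that yields negative values for
    well-fitting over-identified models).
    """
    out = {}
    if df > 0:
        out["rmsea"] = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
        out["rmsea_undefined"] = False
    else:
        out["rmsea"] = 0.0
        out["rmsea_undefined"] = True
    out["nfi"] = float((chi2_null - chi2) / chi2_null) if chi2_null > 0 else 1.0
    s = np.asarray(s_obs, float)
    sig = np.asarray(sigma_hat, float)
    ratio = linalg.solve(sig, s)
    ident = np.eye(s.shape[0])
    out["gfi"] = float(1.0 - np.trace((ratio - ident) @ (ratio - ident))
                       / np.trace(ratio @ ratio))
    out["bic"] = float(chi2 - df * np.log(n))
    out["chi2_null"] = float(chi2_null)
    out["df_null"] = int(df_null)
    return out


# ---------------------------------------------------------------------------
# modification indices and respecification
# ---------------------------------------------------------------------------

def _candidate_dsigma(fit: SemFit, cand) -> np.ndarray:
    """dSigma/dtheta for an omitted parameter at the fitted point."""
    kind, a, b = cand
    ram = fit.ram
    idx = {v: i for i, v in enumerate(ram.names)}
    A, S = ram.matrices(fit.theta)
    m = ram.m
    B = linalg.inv(np.eye(m) - A)
    V = B @ S @ B.T
    o = ram.obs_idx
    if kind == "path":
        i, j = idx[b], idx[a]  # a -> b
        T = np.outer(B[:, i], V[j, :])
        D = T + T.T
    elif kind == "cov":
        i, j = idx[a], idx[b]
        T = np.outer(B[:, i], B[:, j])
        D = T if i == j else T + T.T
    else:
        raise ValueError(f"unknown candidate kind {kind!r}")
    return D[np.ix_(o, o)]


def modification_indices(fit: SemFit, candidates) -> dict:
    """Score-test statistic (expected chi-square drop) per omitted edge.

    Candidates are ``("path", src, dst)`` or ``("cov", a, b)`` tuples
    naming parameters currently fixed at zero.
    """
    existing = {e.name for e in fit.spec.paths}
    existing |= {c.name for c in fit.spec.covariances}
    existing |= {f"{c.b}<->{c.a}" for c in fit.spec.covariances}
    sigma = fit.sigma_hat
    sigma_inv = linalg.inv(sigma)
    M = sigma_inv - sigma_inv @ fit.s_obs @ sigma_inv
    dsig_free, _ = _dsigma_matrices(fit.ram, fit.theta)
    out = {}
    for cand in candidates:
        kind, a, b = cand
        name = f"{a}->{b}" if kind == "path" else f"{a}<->{b}"
        if name in existing:
            raise ValueError(f"candidate {name} is already in the model")
        D = _candidate_dsigma(fit, cand)
        g = float(np.sum(M * D))
        info = _expected_information(sigma_inv, dsig_free + [D])
        q = len(dsig_free)
        i_ff, i_cf, i_cc = info[:q, :q], info[q, :q], info[q, q]
        # pinvh: the free-parameter information is near-singular when a
        # loading sits at the unit boundary
        schur = i_cc - i_cf @ linalg.pinvh(i_ff) @ i_cf
        # expected chi2 drop: chi2 = (n-1) F, the profiled Hessian of F
        # is 2*schur, so the quadratic drop is (n-1) g^2 / (4*schur)
        out[name] = float((fit.n - 1) * g * g / (4.0 * max(schur, 1e-12)))
    return out


def respecify(
    spec: SemModelSpec,
    s_obs,
    n: int,
    candidates,
    var_order=None,
    max_additions: int | None = None,
) -> tuple[SemModelSpec, list]:
    """Greedy BIC-guided respecification.

    Repeatedly frees the highest-modification-index candidate, refits,
    and keeps the addition iff BIC decreases; stops at the first
    rejected candidate.  Returns the final spec and a decision log.
    """
    log = []
    pool = list(candidates)
    current = spec
    fit = fit_ml(current, s_obs, n, var_order=var_order, compute_se=False)
    while pool:
        if max_additions is not None and len([e for e in log if e["kept"]]) >= max_additions:
            break
        mis = modification_indices(fit, pool)
        best = max(pool, key=lambda c: mis[_cand_name(c)])
        best_name = _cand_name(best)
        trial = _free_candidate(current, best)
        try:
            trial_fit = fit_ml(trial, s_obs, n, var_order=var_order, compute_se=False)
        except RuntimeError:
            log.append({"candidate": best_name, "mi": mis[best_name],
                        "kept": False, "reason": "refit failed"})
            break
        kept = trial_fit.indices["bic"] < fit.indices["bic"]
        log.append(
            {
                "candidate": best_name,
                "mi": mis[best_name],
                "bic_before": fit.indices["bic"],
                "bic_after": trial_fit.indices["bic"],
                "kept": bool(kept),
            }
        )
        if not kept:
            break
        current, fit = trial, trial_fit
        pool.remove(best)
    return current, log


def _cand_name(cand) -> str:
    kind, a, b = cand
    return f"{a}->{b}" if kind == "path" else f"{a}<->{b}"


def _free_candidate(spec: SemModelSpec, cand) -> SemModelSpec:
    kind, a, b = cand
    if kind == "path":
        return replace(spec, paths=spec.paths + (PathEdge(a, b),))
    return replace(spec, covariances=spec.covariances + (CovEdge(a, b),))
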