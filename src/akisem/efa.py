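"""Exploratory factor analysis with varimax rotation and refinement.

Implements the variable-reduction stage of the analysis: adequacy
diagnostics (Bartlett sphericity, Kaiser-Meyer-Olkin), principal-axis
factoring with iterated communalities, varimax rotation, and the
iterative refinement loop that discards weak / ambiguous variables and
collapses families of interchangeable metrics to a single surrogate.

Exclusion rules applied by :func:`refine` (one worst offender per
iteration):

* low loading — no rotated loading reaches the significance threshold.
  The default threshold follows the usual sample-size calibration for
  practically significant loadings (0.40 at n = 200, down to 0.30 for
  n >= 350); pass ``min_loading`` to fix it.
* low communality — common variance below ``min_communality``
  (default 0.10, i.e. essentially no shared variance; factor solutions
  of clinical datasets routinely retain variables with communalities
  near 0.2, so a stricter default would discard variables that belong
  in the published solution).
* cross-loading — loadings at or above the significance threshold on
  two or more factors.

Each declared family of interchangeable metrics is first reduced to a
single surrogate: the member that correlates most strongly, on average,
with the variables outside the family.  (Loadings cannot rank family
members: inside a factor solution their mutual collinearity dominates
whatever factor they touch.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "AdequacyReport",
    "FactorSolution",
    "RefinementTrace",
    "DEFAULT_FAMILIES",
    "loading_threshold",
    "bartlett_test",
    "kmo",
    "extract_factors",
    "varimax",
    "refine",
    "variance_explained",
]

#: families of interchangeable derived metrics (surrogate selection)
DEFAULT_FAMILIES = (
    ("ungal_norm_auc", "ungal_abs_auc", "ungal_excretion_auc"),
    ("oliguria_05_auc", "oliguria_1_auc", "oliguria_2_auc"),
    ("dscr_rel_auc", "dscr50_auc", "akin_stage"),
    ("sap_auc", "map_auc"),
)

# practical-significance calibration for factor loadings by sample size
_LOADING_TABLE = (
    (350, 0.30), (250, 0.35), (200, 0.40), (150, 0.45), (120, 0.50),
    (100, 0.55), (85, 0.60), (70, 0.65), (60, 0.70), (50, 0.75),
)


def loading_threshold(n: int) -> float:
    """Smallest practically significant loading for a sample of size n."""
    for n_min, thr in _LOADING_TABLE:
        if n >= n_min:
            return thr
    return _LOADING_TABLE[-1][1]


@dataclass(frozen=True)
class AdequacyReport:
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    kmo: float


@dataclass
class FactorSolution:
    """Loadings, eigenvalues, communalities and variance shares."""

    loadings: pd.DataFrame          # p x k
    eigenvalues: np.ndarray         # k, from the reduced correlation matrix
    communalities: pd.Series
    proportion_explained: np.ndarray
    rotation: str = "none"
    retained: tuple = ()

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def assignment(self) -> pd.Series:
        """Factor with the largest absolute loading per variable."""
        return self.loadings.abs().idxmax(axis=1)

    def to_csv(self, path) -> None:
        df = self.loadings.copy()
        df["communality"] = self.communalities
        df.loc["eigenvalue"] = list(self.eigenvalues) + [np.nan]
        df.loc["proportion_explained"] = list(self.proportion_explained) + [np.nan]
        df.to_csv(path)


@dataclass
class RefinementTrace:
    """Ordered audit log of refinement actions."""

    actions: list = field(default_factory=list)

    def add(self, variable, action, **values):
        self.actions.append({"variable": variable, "action": action, **values})

    def to_json(self, path=None) -> str:
        text = json.dumps(self.actions, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# adequacy diagnostics
# ---------------------------------------------------------------------------

def bartlett_test(corr, n: int) -> AdequacyReport:
    """Bartlett test of sphericity: H0 is a diagonal correlation matrix.

    ``chi2 = -(n - 1 - (2p + 5)/6) ln|R|`` on ``p(p-1)/2`` degrees of
    freedom.  The KMO field is filled by :func:`kmo`; use
    :func:`adequacy` for both at once.
    """
    r = np.asarray(corr, float)
    p = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive-definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return AdequacyReport(bartlett_chi2=float(chi2), bartlett_df=df,
                          bartlett_p=pval, kmo=kmo(r))


def kmo(corr) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    Ratio of summed squared correlations to summed squared correlations
    plus squared partial correlations (anti-image), over off-diagonal
    entries.
    """
    r = np.asarray(corr, float)
    inv = linalg.inv(r)
    d = 1.0 / np.sqrt(np.diag(inv))
    partial = -inv * np.outer(d, d)
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = np.sum(r[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    if r2 + q2 == 0:  # exactly diagonal input
        return 0.0
    return float(r2 / (r2 + q2))


# ---------------------------------------------------------------------------
# extraction and rotation
# ---------------------------------------------------------------------------

def extract_factors(corr, k: int, max_iter: int = 3000, tol: float = 1e-4,
                    max_communality: float = 0.999):
    """Principal-axis factoring with iterated communality estimates.

    Starts from squared multiple correlations, substitutes communality
    estimates into the diagonal of the reduced correlation matrix, and
    iterates eigendecomposition until the communalities stabilise.
    Communalities are capped just below 1 (``max_communality``) so that
    near-collinear variable clusters, whose communality estimates creep
    towards 1 without limit, converge onto the cap instead of stalling.

    Returns ``(loadings, eigenvalues, communalities)`` where the
    eigenvalues are the top-k of the final reduced matrix.
    """
    r = np.asarray(corr, float)
    p = r.shape[0]
    if not 1 <= k < p:
        raise ValueError(f"cannot extract {k} factors from {p} variables")
    h = np.clip(1.0 - 1.0 / np.diag(linalg.inv(r)), 0.0, max_communality)
    lam = None
    hist = []
    for it in range(max_iter):
        reduced = r.copy()
        np.fill_diagonal(reduced, h)
        w, v = linalg.eigh(reduced)
        order = np.argsort(w)[::-1][:k]
        ev = w[order]
        lam = v[:, order] * np.sqrt(np.clip(ev, 0.0, None))
        h_new = np.clip(np.sum(lam**2, axis=1), 0.0, max_communality)
        delta = float(np.max(np.abs(h_new - h)))
        # damped update: same fixed point, but immune to the two-cycle
        # oscillations that near-degenerate trailing eigenvalues induce
        h = 0.5 * (h + h_new)
        if delta < tol:
            break
        # Aitken delta-squared acceleration: Heywood-adjacent variables
        # approach their limit (the communality cap) geometrically with
        # ratio near 1; extrapolating the per-variable sequence jumps
        # over thousands of creeping iterations without changing the
        # fixed point
        hist.append(h.copy())
        if len(hist) == 3:
            h0, h1, h2 = hist
            d1, d2 = h1 - h0, h2 - h1
            denom = d2 - d1
            # extrapolate only monotone, decelerating components; the
            # rest keep their plain iterate
            safe = (np.abs(denom) > 1e-12) & (d1 * d2 > 0) & (np.abs(d2) < np.abs(d1))
            accel = np.where(safe, h2 - np.divide(d2**2, denom,
                                                  out=np.zeros_like(d2),
                                                  where=safe), h2)
            h = np.clip(accel, 0.0, max_communality)
            hist = []
    else:
        raise RuntimeError(
            f"communality iteration did not converge in {max_iter} steps "
            f"(last change {delta:.2e})"
        )
    # deterministic orientation: largest-|loading| entry positive
    for j in range(k):
        if lam[np.argmax(np.abs(lam[:, j])), j] < 0:
            lam[:, j] = -lam[:, j]
    return lam, ev, h


def varimax(loadings, gamma: float = 1.0, max_iter: int = 1000,
            tol: float = 1e-12) -> np.ndarray:
    """Kaiser-normalized varimax rotation (orthogonal).

    Maximises the variance of squared loadings per factor; each rotated
    factor is sign-fixed so its largest absolute loading is positive.
    Row communalities are invariant.
    """
    lam = np.asarray(loadings, float)
    p, k = lam.shape
    if k == 1:
        return lam.copy()
    h = np.sqrt(np.sum(lam**2, axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    x = lam / h_safe[:, None]
    rot = np.eye(k)
    crit = 0.0
    for _ in range(max_iter):
        y = x @ rot
        u, s, vt = linalg.svd(
            x.T @ (y**3 - (gamma / p) * y @ np.diag(np.sum(y**2, axis=0)))
        )
        rot = u @ vt
        new = np.sum(s)
        if crit != 0 and new <= crit * (1.0 + tol):
            break
        crit = new
    out = (x @ rot) * h_safe[:, None]
    for j in range(k):
        if out[np.argmax(np.abs(out[:, j])), j] < 0:
            out[:, j] = -out[:, j]
    return out


def _solution(r_df, k, rotate=True) -> FactorSolution:
    lam, ev, h = extract_factors(r_df.to_numpy(), k)
    if rotate and k > 1:
        lam = varimax(lam)
    cols = [f"F{j + 1}" for j in range(k)]
    # order factors by explained variance, descending, for stable output
    ss = np.sum(lam**2, axis=0)
    order = np.argsort(ss)[::-1]
    lam = lam[:, order]
    loadings = pd.DataFrame(lam, index=r_df.index, columns=cols)
    p = len(r_df)
    return FactorSolution(
        loadings=loadings,
        eigenvalues=np.sort(ev)[::-1],
        communalities=pd.Series(h, index=r_df.index, name="communality"),
        proportion_explained=np.sum(lam**2, axis=0) / p,
        rotation="varimax" if rotate and k > 1 else "none",
        retained=tuple(r_df.index),
    )


def variance_explained(solution_or_proportions, p_total: int | None = None):
    """Per-factor and total proportion of variance explained.

    For a :class:`FactorSolution`, proportions are sums of squared
    loadings divided by ``p_total`` (default: the number of variables
    in the displayed solution).  A plain sequence of per-factor
    proportions is summed as-is.
    """
    if isinstance(solution_or_proportions, FactorSolution):
        sol = solution_or_proportions
        p = p_total if p_total is not None else len(sol.loadings)
        props = np.sum(sol.loadings.to_numpy() ** 2, axis=0) / p
        return props, float(np.sum(props))
    props = np.asarray(solution_or_proportions, float)
    return props, float(np.sum(props))


# ---------------------------------------------------------------------------
# refinement loop
# ---------------------------------------------------------------------------

def _select_k(r, k_override=None):
    """Number of factors: latent-root criterion (eigenvalues of R > 1)
    unless explicitly overridden.  The scree-style reduction of factors
    with too few significant loadings happens in :func:`refine`.
    """
    if k_override is not None:
        return max(1, int(k_override))
    ev = np.sort(linalg.eigvalsh(np.asarray(r, float)))[::-1]
    return max(1, int(np.sum(ev > 1.0)))


def refine(
    indicator_matrix,
    families=DEFAULT_FAMILIES,
    n: int | None = None,
    min_loading: float | None = None,
    min_communality: float = 0.10,
    k_override: int | None = None,
    min_significant_per_factor: int = 2,
    max_iter: int = 100,
):
    """Iterative EFA refinement producing the final factor solution.

    Each round: choose k (eigenvalue > 1, reducible when a trailing
    factor has fewer than ``min_significant_per_factor`` significant
    loadings), extract, rotate, then (a) drop the single worst variable
    violating the loading / communality / cross-loading rules, else
    (b) within each family keep only the strongest member; stops when a
    full round changes nothing.  Returns ``(FactorSolution,
    RefinementTrace)``.
    """
    from .synthetic_cohort import IndicatorMatrix

    if isinstance(indicator_matrix, IndicatorMatrix):
        data = indicator_matrix.to_frame()
    else:
        data = pd.DataFrame(indicator_matrix)
    n = int(n if n is not None else len(data))
    thr = loading_threshold(n) if min_loading is None else float(min_loading)

    trace = RefinementTrace()
    cols = list(data.columns)

    # Family surrogate pre-selection.  Interchangeable metrics are near
    # collinear; inside a factor solution their mutual correlation
    # dominates any loading they show, so loadings cannot rank them as
    # representatives.  Each family is instead reduced up front to the
    # member that correlates most strongly, on average, with the
    # variables outside the family -- the member carrying the most of
    # the family's shared signal as seen by the rest of the dataset.
    active_families = [
        [v for v in family if v in cols] for family in families
    ]
    if any(len(f) > 1 for f in active_families):
        corr_abs = data[cols].corr().abs()
        for present in active_families:
            if len(present) < 2:
                continue
            outside = [c for c in cols if c not in present]
            score = {m: float(corr_abs.loc[m, outside].mean()) for m in present}
            best = max(present, key=lambda m: (score[m], -present.index(m)))
            for v in present:
                if v != best:
                    trace.add(v, "dropped-family-duplicate", surrogate=best,
                              mean_outside_corr=score[v])
                    cols.remove(v)
            trace.add(best, "surrogate-selected",
                      mean_outside_corr=score[best])

    sol = None
    for _ in range(max_iter):
        if len(cols) < 3:
            raise ValueError("fewer than 3 variables left; refinement failed")
        sub = data[cols]
        r = pd.DataFrame(np.corrcoef(sub.to_numpy(), rowvar=False),
                         index=cols, columns=cols)
        k = _select_k(r.to_numpy(), k_override=k_override)
        k = min(k, len(cols) - 1)
        sol = _solution(r, k)
        # scree-style reduction: shed trailing factors carried by fewer
        # than min_significant_per_factor significant loadings
        while sol.n_factors > 1 and k_override is None:
            n_sig = (sol.loadings.abs() >= thr).sum(axis=0)
            if (n_sig < min_significant_per_factor).any():
                k = sol.n_factors - 1
                sol = _solution(r, k)
            else:
                break

        lam = sol.loadings
        offenders = []  # (severity, variable, action, values)
        for v in cols:
            row = lam.loc[v].abs()
            if row.max() < thr:
                offenders.append((thr - row.max(), v, "dropped-low-loading",
                                  {"max_loading": float(row.max()), "threshold": thr}))
            elif float(sol.communalities[v]) < min_communality:
                offenders.append(
                    (min_communality - float(sol.communalities[v]), v,
                     "dropped-low-communality",
                     {"communality": float(sol.communalities[v]),
                      "threshold": min_communality})
                )
            elif int((row >= thr).sum()) >= 2:
                second = float(np.sort(row.to_numpy())[-2])
                offenders.append((second - thr, v, "dropped-cross-loading",
                                  {"secondary_loading": second, "threshold": thr}))
        if offenders:
            _, v, action, values = max(offenders, key=lambda o: o[0])
            trace.add(v, action, **values)
            cols.remove(v)
            continue

        break

    else:
        raise RuntimeError("refinement did not stabilise")

    sol.retained = tuple(cols)
    return sol, trace
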