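"""Synthetic infant cardiac-surgery cohorts with a known latent structure.

The generative model is the four-construct structural model of
perioperative acute kidney injury: a cardiopulmonary-bypass construct
(CPB) drives both AKI and low cardiac output syndrome (LCOS), LCOS
contributes to AKI, and AKI drives the post-operative outcome.  Each
construct is expressed through observed indicators via standardized
loadings; two residual correlations couple bypass duration with
creatinine-normalized uNGAL, and in-hospital mortality with the
ΔsCr>50% metric.

Data can be generated at three levels:

* ``simulate_latents`` — standardized construct scores per patient;
* ``simulate_indicators`` — the n x 13 indicator matrix fed to factor
  analysis / SEM, standardized or on the clinical scale;
* ``simulate_timeseries`` — raw longitudinal channels (serum
  creatinine, urine output, arterial pressures, lactate, uNGAL) plus a
  static per-patient record, from which :mod:`akisem.derived_metrics`
  reconstructs the indicators end to end.

Defaults reproduce the reported cohort conditions: n = 200 patients,
the published standardized coefficients, marginal scales from the
cohort summary table (e.g. bypass duration 118.2 +/- 63.0 min), and a
4 % in-hospital mortality produced by thresholding a continuous
propensity at its 96th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .sem_engine import CovEdge, PathEdge, SemModelSpec

__all__ = [
    "CohortConfig",
    "LatentRecord",
    "IndicatorMatrix",
    "STRUCTURAL_PATHS",
    "LOADINGS",
    "RESIDUAL_CORRELATIONS",
    "MARGINAL_SCALES",
    "INDICATOR_NAMES",
    "REFERENCE_FACTOR_PATTERN",
    "infant_aki_spec",
    "reference_efa_config",
    "simulate_latents",
    "simulate_indicators",
    "simulate_timeseries",
    "latent_covariance",
]

LATENTS = ("CPB", "LCOS", "AKI", "Outcome")

#: structural paths among constructs (standardized coefficients)
STRUCTURAL_PATHS = {
    ("CPB", "AKI"): 0.596,
    ("CPB", "LCOS"): 0.451,
    ("LCOS", "AKI"): 0.347,
    ("AKI", "Outcome"): 0.684,
}

#: measurement loadings (construct -> indicator), standardized
LOADINGS = {
    ("CPB", "cpb_duration"): 0.997,
    ("CPB", "crossclamp_duration"): 0.838,
    ("CPB", "ultrafiltration"): 0.708,
    ("LCOS", "age"): -0.661,
    ("LCOS", "sap_auc"): 0.684,
    ("LCOS", "lactate_auc"): 0.749,
    ("LCOS", "transfusions"): 0.709,
    ("AKI", "ungal_auc"): 0.508,
    ("AKI", "dscr50_auc"): 0.443,
    ("AKI", "oliguria_auc"): 0.494,
    ("Outcome", "ventilation_days"): 0.998,
    ("Outcome", "icu_days"): 0.934,
    ("Outcome", "mortality"): 0.652,
}

#: correlations between the residuals of two indicator pairs
RESIDUAL_CORRELATIONS = {
    ("cpb_duration", "ungal_auc"): 0.137,
    ("mortality", "dscr50_auc"): 0.197,
}

#: clinical-scale (mean, sd) per indicator.  Values without a published
#: summary statistic (the AUC-type metrics) are plausible scales chosen
#: once; only the correlation structure is contractual.
MARGINAL_SCALES = {
    "cpb_duration": (118.2, 63.0),        # min
    "crossclamp_duration": (62.9, 33.9),  # min
    "ultrafiltration": (1.4, 0.6),        # ml/kg/min of bypass
    "age": (95.8, 91.1),                  # days
    "sap_auc": (2.0, 2.0),                # mmHg below age-group quintile
    "lactate_auc": (3.7, 1.9),            # mmol/L, duration-normalized
    "transfusions": (752.8, 195.0),       # ml of blood products, day 0
    "ungal_auc": (250.0, 300.0),          # ng/mg creatinine, 12 h
    "dscr50_auc": (0.5, 1.5),             # fractional excess x h
    "oliguria_auc": (0.3, 0.8),           # ml/kg/h deficit x h
    "ventilation_days": (2.5, 3.0),
    "icu_days": (5.5, 4.0),
    "mortality": (0.0, 1.0),              # kept 0/1; scale unused
}

INDICATOR_NAMES = tuple(ind for _, ind in LOADINGS)

#: published four-factor varimax pattern (significant loadings only),
#: used by the orthogonal reference generator for factor-recovery tests.
#: factor order: Outcome, CPB, LCOS, AKI.
REFERENCE_FACTOR_PATTERN = {
    ("Outcome", "ventilation_days"): 0.946,
    ("Outcome", "icu_days"): 0.910,
    ("Outcome", "mortality"): 0.613,
    ("CPB", "cpb_duration"): 0.907,
    ("CPB", "crossclamp_duration"): 0.817,
    ("CPB", "ultrafiltration"): 0.695,
    ("LCOS", "age"): -0.773,
    ("LCOS", "sap_auc"): 0.610,
    ("LCOS", "lactate_auc"): 0.680,
    ("LCOS", "transfusions"): 0.627,
    ("AKI", "ungal_auc"): 0.494,
    ("AKI", "dscr50_auc"): 0.538,
    ("AKI", "oliguria_auc"): 0.420,
}

#: default sampling grids, hours after surgery
DEFAULT_TIME_GRID = {
    "scr": tuple(float(t) for t in range(0, 54, 6)),
    "urine_output": tuple(float(t) for t in range(0, 25)),
    "sap": tuple(float(t) for t in range(0, 25)),
    "map": tuple(float(t) for t in range(0, 25)),
    "lactate": tuple(float(t) for t in range(0, 54, 6)),
    "ungal": (0.0, 2.0, 4.0, 8.0, 12.0),
}


def infant_aki_spec(
    observed=None,
    residual_covariances=True,
    start_values: bool = False,
) -> SemModelSpec:
    """The canonical four-construct structural model (measurement +
    structural paths, optionally with the two residual covariance arcs).

    Parameters
    ----------
    observed
        Restrict the measurement model to these indicators (e.g. the
        survivors of EFA refinement).  Constructs left without any
        indicator are dropped together with their paths.
    residual_covariances
        Include the bypass-duration<->uNGAL and mortality<->ΔsCr>50%
        residual arcs (both endpoints must be retained).
    start_values
        Seed free parameters at the canonical coefficients instead of
        the default 0.5 starts (useful for warm-started refits).
    """
    observed = tuple(observed) if observed is not None else INDICATOR_NAMES
    lat_used = tuple(
        l for l in LATENTS if any((l, ind) in LOADINGS for ind in observed)
    )
    paths = []
    for (l, ind), lam in LOADINGS.items():
        if l in lat_used and ind in observed:
            paths.append(PathEdge(l, ind, value=lam if start_values else None))
    for (a, b), v in STRUCTURAL_PATHS.items():
        if a in lat_used and b in lat_used:
            paths.append(PathEdge(a, b, value=v if start_values else None))
    covs = []
    if residual_covariances:
        for (a, b), r in RESIDUAL_CORRELATIONS.items():
            if a in observed and b in observed:
                covs.append(CovEdge(a, b, value=0.0 if not start_values else None))
    return SemModelSpec(
        latents=lat_used, observed=observed, paths=tuple(paths),
        covariances=tuple(covs),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth generative model for a synthetic cohort."""

    n_patients: int = 200
    seed: int = 0
    structural_paths: dict = field(default_factory=lambda: dict(STRUCTURAL_PATHS))
    loadings: dict = field(default_factory=lambda: dict(LOADINGS))
    residual_correlations: dict = field(
        default_factory=lambda: dict(RESIDUAL_CORRELATIONS)
    )
    marginal_scales: dict = field(default_factory=lambda: dict(MARGINAL_SCALES))
    mortality_rate: float = 0.04
    mortality_mode: str = "binary"  # "binary" | "propensity"
    time_grid: dict = field(default_factory=lambda: dict(DEFAULT_TIME_GRID))

    def __post_init__(self):
        for (a, b), v in self.structural_paths.items():
            if abs(v) > 1:
                raise ValueError(f"structural path {a}->{b} magnitude > 1")
        for (l, ind), v in self.loadings.items():
            if abs(v) >= 1:
                raise ValueError(f"loading {l}->{ind} magnitude >= 1")
        for pair, r in self.residual_correlations.items():
            if abs(r) >= 1:
                raise ValueError(
                    f"residual correlation {pair} makes the residual block "
                    "non-positive-definite"
                )
        if not 0 < self.mortality_rate < 1:
            raise ValueError("mortality_rate must be in (0, 1)")
        if self.mortality_mode not in ("binary", "propensity"):
            raise ValueError(f"unknown mortality_mode {self.mortality_mode!r}")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")

    def latent_names(self) -> tuple[str, ...]:
        order = [l for l in LATENTS if self._mentions(l)]
        extra = sorted(
            {l for pair in self.structural_paths for l in pair if l not in order}
            | {l for (l, _) in self.loadings if l not in order}
        )
        return tuple(order + extra)

    def _mentions(self, l) -> bool:
        return any(l in pair for pair in self.structural_paths) or any(
            l == lat for (lat, _) in self.loadings
        )

    def indicator_names(self) -> tuple[str, ...]:
        return tuple(ind for (_, ind) in self.loadings)

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        doc = {
            "n_patients": self.n_patients,
            "seed": self.seed,
            "structural_paths": {f"{a}->{b}": v for (a, b), v in self.structural_paths.items()},
            "loadings": {f"{l}->{i}": v for (l, i), v in self.loadings.items()},
            "residual_correlations": {
                f"{a}<->{b}": v for (a, b), v in self.residual_correlations.items()
            },
            "marginal_scales": {k: list(v) for k, v in self.marginal_scales.items()},
            "mortality_rate": self.mortality_rate,
            "mortality_mode": self.mortality_mode,
            "time_grid": {k: list(v) for k, v in self.time_grid.items()},
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path) -> "CohortConfig":
        try:
            with open(text_or_path) as fh:
                doc = yaml.safe_load(fh)
        except (OSError, TypeError):
            doc = yaml.safe_load(text_or_path)
        split = lambda k, sep: tuple(k.split(sep))
        return cls(
            n_patients=doc["n_patients"],
            seed=doc["seed"],
            structural_paths={split(k, "->"): v for k, v in doc["structural_paths"].items()},
            loadings={split(k, "->"): v for k, v in doc["loadings"].items()},
            residual_correlations={
                split(k, "<->"): v for k, v in doc["residual_correlations"].items()
            },
            marginal_scales={k: tuple(v) for k, v in doc["marginal_scales"].items()},
            mortality_rate=doc["mortality_rate"],
            mortality_mode=doc.get("mortality_mode", "binary"),
            time_grid={k: tuple(v) for k, v in doc.get("time_grid", DEFAULT_TIME_GRID).items()},
        )


def reference_efa_config(n_patients: int = 2000, seed: int = 0) -> CohortConfig:
    """Config generating from the published orthogonal four-factor pattern.

    Constructs are independent (no structural paths) and each indicator
    carries its published significant varimax loading.  This is the
    generator for factor-recovery tests: under the full structural
    model the constructs correlate too strongly for an orthogonal
    four-factor solution to be recoverable even in population.
    Mortality is kept as its continuous propensity because the
    published pattern describes the observed correlation structure;
    dichotomizing would attenuate its loading to ~0.27 and the pattern
    could not be reproduced.
    """
    return CohortConfig(
        n_patients=n_patients,
        seed=seed,
        structural_paths={},
        loadings=dict(REFERENCE_FACTOR_PATTERN),
        residual_correlations={},
        mortality_mode="propensity",
    )


@dataclass(frozen=True)
class LatentRecord:
    """Standardized construct scores for one patient."""

    patient_id: int
    scores: dict


@dataclass
class IndicatorMatrix:
    """n x p matrix of derived observed variables entering EFA / SEM."""

    patient_ids: np.ndarray
    variables: tuple[str, ...]
    values: np.ndarray
    scale: str = "standardized"  # "standardized" | "clinical"
    binary_mortality: bool = True  # False when mortality kept as propensity

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.variables)):
            raise ValueError("value matrix shape does not match ids/variables")
        if np.isnan(self.values).any():
            raise ValueError("indicator matrix contains missing values")
        if self.binary_mortality and "mortality" in self.variables:
            col = self.values[:, self.variables.index("mortality")]
            if not np.isin(col, (0.0, 1.0)).all():
                raise ValueError("mortality column must be 0/1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.variables),
                            index=pd.Index(self.patient_ids, name="patient_id"))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, scale="clinical") -> "IndicatorMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.to_numpy(), tuple(df.columns), df.to_numpy(float), scale)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale="clinical") -> "IndicatorMatrix":
        return cls(np.asarray(df.index), tuple(df.columns), df.to_numpy(float), scale)


# ---------------------------------------------------------------------------
# latent layer
# ---------------------------------------------------------------------------

def _structural_order(config: CohortConfig):
    g = nx.DiGraph()
    g.add_nodes_from(config.latent_names())
    g.add_edges_from(config.structural_paths)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("structural paths contain a cycle")
    return list(nx.topological_sort(g)), g


def _residual_variances(config: CohortConfig, order, g):
    """Residual variance per latent so that every latent has unit variance."""
    phi = latent_covariance(config)
    res = {}
    for l in order:
        parents = list(g.predecessors(l))
        if not parents:
            res[l] = 1.0
            continue
        b = np.array([config.structural_paths[(p, l)] for p in parents])
        sub = phi.loc[parents, parents].to_numpy()
        explained = float(b @ sub @ b)
        r = 1.0 - explained
        if r <= 0:
            raise ValueError(
                f"implied residual variance of latent {l!r} is not positive "
                f"({r:.4f}); structural paths are too strong"
            )
        res[l] = r
    return res


def latent_covariance(config: CohortConfig) -> pd.DataFrame:
    """Model-implied covariance of the latent constructs (unit variances)."""
    order, g = _structural_order(config)
    m = len(order)
    idx = {l: i for i, l in enumerate(order)}
    B = np.zeros((m, m))
    for (a, b), v in config.structural_paths.items():
        B[idx[b], idx[a]] = v
    # solve for residual variances giving unit total variances, in
    # topological order: var(l) = b' Phi_parents b + psi_l = 1
    phi = np.zeros((m, m))
    psi = np.zeros(m)
    for l in order:
        i = idx[l]
        parents = list(g.predecessors(l))
        pi = [idx[p] for p in parents]
        b = np.array([config.structural_paths[(p, l)] for p in parents])
        explained = float(b @ phi[np.ix_(pi, pi)] @ b) if parents else 0.0
        psi[i] = 1.0 - explained
        # cov(l, earlier j) = sum_p b_p cov(p, j)
        for j in range(m):
            if j == i:
                phi[i, i] = 1.0
            else:
                phi[i, j] = phi[j, i] = float(b @ phi[np.ix_(pi, [j])][:, 0]) if parents else 0.0
    return pd.DataFrame(phi, index=order, columns=order)


def simulate_latents(config: CohortConfig, rng=None) -> list[LatentRecord]:
    """Draw standardized construct scores patient by patient.

    Each latent is its parents' weighted sum plus a normal residual
    whose variance tops the total up to 1; exogenous constructs are
    standard normal.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    order, g = _structural_order(config)
    res = _residual_variances(config, order, g)
    n = config.n_patients
    scores = {}
    for l in order:
        parents = list(g.predecessors(l))
        e = rng.standard_normal(n) * np.sqrt(res[l])
        total = e
        for p in parents:
            total = total + config.structural_paths[(p, l)] * scores[p]
        scores[l] = total
    return [
        LatentRecord(patient_id=i, scores={l: float(scores[l][i]) for l in order})
        for i in range(n)
    ]


def _latent_frame(latents) -> pd.DataFrame:
    rows = {r.patient_id: r.scores for r in latents}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# indicator layer
# ---------------------------------------------------------------------------

def _indicator_residuals(config: CohortConfig, n, rng):
    """Residual draws per indicator, with the configured pairs correlated."""
    names = config.indicator_names()
    res = {}
    paired = set()
    for (a, b), r in config.residual_correlations.items():
        if a not in names or b not in names:
            raise ValueError(f"residual correlation names unknown indicator: {(a, b)}")
        cov = np.array([[1.0, r], [r, 1.0]])
        draw = rng.multivariate_normal([0.0, 0.0], cov, size=n,
                                       method="cholesky")
        res[a], res[b] = draw[:, 0], draw[:, 1]
        paired |= {a, b}
    for nm in names:
        if nm not in paired:
            res[nm] = rng.standard_normal(n)
    return res


def simulate_indicators(
    latents, config: CohortConfig, scale: str = "standardized", rng=None
) -> IndicatorMatrix:
    """Generate the observed indicator matrix from latent scores.

    Standardized indicator = loading x latent + residual with variance
    ``1 - loading**2`` (floored at 1e-6 for near-unit loadings);
    correlated residual pairs are drawn bivariate-normal.  Mortality is
    dichotomized at the ``1 - mortality_rate`` population quantile of
    its continuous propensity unless ``mortality_mode="propensity"``.
    Clinical scale applies ``mean + sd * z`` per indicator.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    lf = _latent_frame(latents)
    n = len(lf)
    if n < len(config.indicator_names()) + 1:
        raise ValueError("need more patients than indicators for a "
                         "full-rank indicator matrix")
    unit = _indicator_residuals(config, n, rng)
    cols = {}
    for (lat, ind), lam in config.loadings.items():
        resvar = max(1.0 - lam * lam, 1e-6)
        cols[ind] = lam * lf[lat].to_numpy() + np.sqrt(resvar) * unit[ind]
    names = config.indicator_names()
    z = np.column_stack([cols[nm] for nm in names])
    values = z
    if scale == "clinical":
        values = z.copy()
        for j, nm in enumerate(names):
            mu, sd = config.marginal_scales.get(nm, (0.0, 1.0))
            if nm != "mortality":
                values[:, j] = mu + sd * z[:, j]
    elif scale != "standardized":
        raise ValueError(f"unknown scale {scale!r}")
    if "mortality" in names and config.mortality_mode == "binary":
        j = names.index("mortality")
        cut = float(np.sqrt(1.0) * _norm_ppf(1.0 - config.mortality_rate))
        values[:, j] = (z[:, j] > cut).astype(float)
    return IndicatorMatrix(
        patient_ids=lf.index.to_numpy(), variables=names, values=values, scale=scale,
        binary_mortality=(config.mortality_mode == "binary"),
    )


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


# ---------------------------------------------------------------------------
# raw time-series layer
# ---------------------------------------------------------------------------

def _propensity(lf, config, lat, lam, rng):
    """Standardized channel propensity: loading x latent + residual."""
    n = len(lf)
    resvar = max(1.0 - lam * lam, 1e-6)
    return lam * lf[lat].to_numpy() + np.sqrt(resvar) * rng.standard_normal(n)


def _unit_shape(rng, t, kind, n):
    """Per-patient positive shapes with trapezoid mean 1 over the grid."""
    t = np.asarray(t, dtype=float)
    span = t[-1] - t[0]
    if kind == "peak":  # rise to a patient-specific peak time, then decay
        tp = rng.uniform(0.25, 0.75, size=n)[:, None] * span + t[0]
        width = rng.uniform(0.25, 0.6, size=n)[:, None] * span
        s = np.exp(-0.5 * ((t[None, :] - tp) / width) ** 2)
    elif kind == "decay":
        tau = rng.uniform(0.3, 1.2, size=n)[:, None] * span
        s = np.exp(-(t[None, :] - t[0]) / tau)
    else:  # flat with noise
        s = np.ones((n, len(t)))
    s = s * np.exp(rng.normal(0.0, 0.15, size=s.shape))
    mean = np.trapezoid(s, t, axis=1) / span
    return s / mean[:, None]


def simulate_timeseries(latents, config: CohortConfig, rng=None):
    """Generate raw longitudinal channels and static records.

    Returns ``(timeseries, statics)``: a long-format DataFrame
    ``(patient_id, variable, time_h, value)`` and a per-patient static
    DataFrame.  Shapes (piecewise trends with noise) are invented; only
    the induced correlation between derived metrics and the generating
    latents is contractual — each channel's patient-level magnitude is
    driven by a propensity sharing the indicator's loading.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    grid = config.time_grid
    for k, t in grid.items():
        if len(t) == 0:
            raise ValueError(f"empty time grid for {k!r}")
    lf = _latent_frame(latents)
    n = len(lf)
    ids = lf.index.to_numpy()
    load = config.loadings
    scales = config.marginal_scales

    def loading_of(ind, default_lat, default_lam):
        for (lat, name), lam in load.items():
            if name == ind:
                return lat, lam
        return default_lat, default_lam

    frames = []

    def emit(var, tgrid, matrix):
        t = np.asarray(tgrid, float)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(ids, len(t)),
                    "variable": var,
                    "time_h": np.tile(t, n),
                    "value": matrix.ravel(),
                }
            )
        )

    # --- age & weight (statics; age is also an indicator) ---------------
    lat_age, lam_age = loading_of("age", "LCOS", -0.661)
    p_age = _propensity(lf, config, lat_age, lam_age, rng)
    mu_a, sd_a = scales.get("age", (95.8, 91.1))
    age = np.clip(mu_a + sd_a * p_age, 1.0, 365.0)
    weight = np.clip(4.4 + 1.5 * (0.15 * (age - mu_a) / sd_a
                                  + np.sqrt(0.9775) * rng.standard_normal(n)), 1.5, None)

    # --- uNGAL (12 h), three family metrics via urine creatinine/flow ---
    lat_u, lam_u = loading_of("ungal_auc", "AKI", 0.508)
    p_u = _propensity(lf, config, lat_u, lam_u, rng)
    mu_u, sd_u = scales.get("ungal_auc", (250.0, 300.0))
    level_u = np.clip(mu_u + sd_u * p_u, 5.0, None)
    shape_u = _unit_shape(rng, grid["ungal"], "peak", n)
    emit("ungal", grid["ungal"], level_u[:, None] * shape_u)
    urine_creatinine = np.clip(
        0.6 * np.exp(rng.normal(0.0, 0.3, size=n)), 0.1, None
    )  # mg/ml, per-patient

    # --- serum creatinine -----------------------------------------------
    lat_d, lam_d = loading_of("dscr50_auc", "AKI", 0.443)
    p_d = _propensity(lf, config, lat_d, lam_d, rng)
    baseline = np.clip(32.0 + 8.0 * rng.standard_normal(n), 12.0, None)  # umol/L
    peak_rel = np.clip(0.264 + 0.471 * p_d, -0.35, None)
    t_scr = np.asarray(grid["scr"], float)
    tp = rng.uniform(18.0, 36.0, size=n)[:, None]
    width = rng.uniform(10.0, 20.0, size=n)[:, None]
    rise = np.exp(-0.5 * ((t_scr[None, :] - tp) / width) ** 2)
    rise = rise / rise.max(axis=1, keepdims=True)
    rise[:, t_scr == 0.0] = 0.0
    scr = baseline[:, None] * (1.0 + peak_rel[:, None] * rise)
    scr = scr * np.exp(rng.normal(0.0, 0.02, size=scr.shape))
    emit("scr", t_scr, scr)

    # --- urine output ----------------------------------------------------
    lat_o, lam_o = loading_of("oliguria_auc", "AKI", 0.494)
    p_o = _propensity(lf, config, lat_o, lam_o, rng)
    # log-linear level in the propensity: keeps urine output positive
    # with mean ~4.1 ml/kg/h while the oliguria deficit AUCs stay
    # close to monotone-linear in the propensity
    level_uo = 4.1 * np.exp(-1.1 * p_o - 1.1**2 / 2)
    t_uo = np.asarray(grid["urine_output"], float)
    uo = level_uo[:, None] * np.exp(rng.normal(0.0, 0.45, size=(n, len(t_uo))))
    emit("urine_output", t_uo, uo)

    # --- arterial pressures ---------------------------------------------
    lat_s, lam_s = loading_of("sap_auc", "LCOS", 0.684)
    p_s = _propensity(lf, config, lat_s, lam_s, rng)
    base_sap = 60.0 + 4.0 * np.log1p(age) / np.log(365.0)
    t_sap = np.asarray(grid["sap"], float)
    sap = (base_sap - 14.0 * p_s)[:, None] + rng.normal(0.0, 6.0, size=(n, len(t_sap)))
    emit("sap", t_sap, sap)
    t_map = np.asarray(grid["map"], float)
    mam = 0.72 * ((base_sap - 14.0 * p_s)[:, None]
                  + rng.normal(0.0, 6.0, size=(n, len(t_map)))) + 2.0
    emit("map", t_map, mam)

    # --- lactate ---------------------------------------------------------
    lat_l, lam_l = loading_of("lactate_auc", "LCOS", 0.749)
    p_l = _propensity(lf, config, lat_l, lam_l, rng)
    mu_l, sd_l = scales.get("lactate_auc", (3.7, 1.9))
    level_l = np.clip(mu_l + sd_l * p_l, 0.4, None)
    shape_l = _unit_shape(rng, grid["lactate"], "decay", n)
    emit("lactate", grid["lactate"], level_l[:, None] * shape_l)

    ts = pd.concat(frames, ignore_index=True)

    # --- statics ---------------------------------------------------------
    def clinical(ind, lat, lam, floor=None):
        p = _propensity(lf, config, lat, lam, rng)
        mu, sd = scales.get(ind, (0.0, 1.0))
        x = mu + sd * p
        return np.clip(x, floor, None) if floor is not None else x

    lat_m, lam_m = loading_of("mortality", "Outcome", 0.652)
    p_m = _propensity(lf, config, lat_m, lam_m, rng)
    if config.mortality_mode == "binary":
        mortality = (p_m > _norm_ppf(1.0 - config.mortality_rate)).astype(float)
    else:
        mortality = p_m
    lat_k = "AKI" if "AKI" in lf.columns else lat_m  # dialysis tied to AKI
    p_dial = _propensity(lf, config, lat_k, 0.7, rng)
    dialysis = (p_dial > _norm_ppf(0.92)).astype(float)

    p_vis = _propensity(lf, config, lat_s, 0.20, rng)  # weak LCOS coupling
    p_fb = _propensity(lf, config, lat_d, 0.20, rng)   # weak AKI coupling
    fluid_balance = -28.06 + 26.8 * p_fb
    fluid_in = 150.0 * weight
    fluid_out = fluid_in - fluid_balance * weight

    statics = pd.DataFrame(
        {
            "patient_id": ids,
            "age_days": age,
            "weight_kg": weight,
            "baseline_scr": baseline,
            "urine_creatinine": urine_creatinine,
            "cpb_duration": clinical("cpb_duration", *loading_of("cpb_duration", "CPB", 0.997), floor=15.0),
            "crossclamp_duration": clinical("crossclamp_duration", *loading_of("crossclamp_duration", "CPB", 0.838), floor=0.0),
            "ultrafiltration": clinical("ultrafiltration", *loading_of("ultrafiltration", "CPB", 0.708), floor=0.1),
            "transfusions": clinical("transfusions", *loading_of("transfusions", "LCOS", 0.709), floor=0.0),
            "ventilation_days": clinical("ventilation_days", *loading_of("ventilation_days", "Outcome", 0.998), floor=0.0),
            "icu_days": clinical("icu_days", *loading_of("icu_days", "Outcome", 0.934), floor=0.5),
            "mortality": mortality,
            "dialysis": dialysis,
            "dopamine": np.clip(7.0 + 2.5 * p_vis, 0.0, None),
            "epinephrine": np.clip(0.03 + 0.02 * p_vis, 0.0, None),
            "milrinone": np.clip(0.5 + 0.25 * p_vis, 0.0, None),
            "dobutamine": 0.0,
            "norepinephrine": 0.0,
            "vasopressin": 0.0,
            "fluid_in_ml": fluid_in,
            "fluid_out_ml": fluid_out,
            "preop_resuscitation": rng.random(n) < 0.01,
            "preop_mechanical_ventilation": rng.random(n) < 0.055,
            "preop_inotropic_support": rng.random(n) < 0.015,
            "preop_infection": rng.random(n) < 0.095,
            "preop_enterocolitis": rng.random(n) < 0.02,
            "preop_pulmonary_hypertension": rng.random(n) < 0.05,
            "preop_nephrotoxic_exposure": rng.random(n) < 0.30,
            "preop_genetic_syndrome": rng.random(n) < 0.04,
        }
    ).set_index("patient_id")
    return ts, statics
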