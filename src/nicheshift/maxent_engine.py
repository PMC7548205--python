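"""Presence-background maximum-entropy niche model.

The model estimates a probability distribution q over the landscape's
background cells that has maximum entropy subject to (soft) constraints
that feature expectations under q match their empirical means over the
presence records.  Equivalently it is an L1-penalized exponential-family
density: q(x) = exp(lambda . f(x)) / Z, fitted by maximizing

    mean_presence log q(x)  -  sum_j beta_j |lambda_j|

with per-feature penalties beta_j = beta * base(class, m) * s_j / sqrt(m),
where m is the presence count, s_j the feature's standard deviation over
presences, and base(class, m) the conventional per-class default schedule
(linear/quadratic/product interpolated on sample size, hinge 0.5,
threshold 1.0).  beta is the user-facing global regularization
multiplier: larger values give smoother, sparser models.

At an optimum the KKT conditions bound the moment gaps:
|E_q[f_j] - mean_pres f_j| <= beta_j, with equality where lambda_j != 0.
The optimizer is L-BFGS-B on the split lambda = u - v (u, v >= 0), which
makes the penalized problem smooth and box-constrained.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grid_io import Grid, LayerStack

DEFAULT_CLASSES = ("linear", "quadratic", "product", "hinge")
ALL_CLASSES = (
    "linear", "quadratic", "product", "hinge_forward", "hinge_reverse", "threshold",
)

# default per-class regularization schedule: (sample sizes, base values),
# interpolated linearly in sample size and clamped at the ends
_BASE_SCHEDULE = {
    "lqp": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "hinge": ([0], [0.5]),
    "threshold": ([0], [1.0]),
}

_MIN_FEATURE_SD = 1e-4
MAX_ITER = 5000

#: optimizer presets: "high" polishes to the KKT tolerance (slower);
#: "search" is for scoring many candidates where ranking, not the last
#: digit of the optimum, matters
PRECISION_OPTIONS = {
    "high": {"maxiter": MAX_ITER, "ftol": 1e-12, "gtol": 1e-8},
    "search": {"maxiter": 150, "ftol": 1e-7, "gtol": 1e-5},
}


def base_regularization(feature_class: str, n_presence: int) -> float:
    """Per-class base penalty as a function of presence sample size."""
    key = (
        "lqp" if feature_class in ("linear", "quadratic", "product")
        else "hinge" if feature_class.startswith("hinge")
        else "threshold"
    )
    xs, ys = _BASE_SCHEDULE[key]
    return float(np.interp(n_presence, xs, ys))


@dataclass(frozen=True)
class FeatureDefinition:
    feature_class: str               # one of ALL_CLASSES
    variables: tuple[str, ...]       # 1 variable (2 for product)
    knot: float | None = None        # hinge/threshold knot, inside training range

    def label(self) -> str:
        v = "*".join(self.variables)
        return f"{self.feature_class}({v})" + (
            f"@{self.knot:.6g}" if self.knot is not None else ""
        )


@dataclass
class FeatureSet:
    """Feature expansion with its scaling, mapping raw variables to [0,1]."""

    definitions: list[FeatureDefinition]
    variables: list[str]                       # variable order for input tables
    var_range: dict[str, tuple[float, float]]  # training min/max per variable
    var_mean: dict[str, float]                 # background mean per variable
    feature_range: np.ndarray = field(default=None)  # (J, 2) raw min/max

    @property
    def n_features(self) -> int:
        return len(self.definitions)

    def _raw(self, X: np.ndarray) -> np.ndarray:
        col = {v: i for i, v in enumerate(self.variables)}
        out = np.empty((X.shape[0], len(self.definitions)))
        for j, d in enumerate(self.definitions):
            x = X[:, col[d.variables[0]]]
            if d.feature_class == "linear":
                out[:, j] = x
            elif d.feature_class == "quadratic":
                out[:, j] = x * x
            elif d.feature_class == "product":
                out[:, j] = x * X[:, col[d.variables[1]]]
            elif d.feature_class == "hinge_forward":
                out[:, j] = np.maximum(0.0, x - d.knot)
            elif d.feature_class == "hinge_reverse":
                out[:, j] = np.maximum(0.0, d.knot - x)
            elif d.feature_class == "threshold":
                out[:, j] = (x > d.knot).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature class {d.feature_class!r}")
        return out

    def evaluate(self, X, clamp: bool = False) -> np.ndarray:
        """(n, J) feature matrix in [0,1]; optionally clamp inputs to range."""
        X = self._coerce(X)
        if clamp:
            X = X.copy()
            for i, v in enumerate(self.variables):
                lo, hi = self.var_range[v]
                X[:, i] = np.clip(X[:, i], lo, hi)
        raw = self._raw(X)
        lo = self.feature_range[:, 0]
        span = self.feature_range[:, 1] - lo
        return np.clip((raw - lo) / span, 0.0, 1.0)

    def _coerce(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[self.variables].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.variables):
            raise ValueError(
                f"expected {len(self.variables)} variable columns, got {X.shape[1]}"
            )
        return X

    def classes(self) -> np.ndarray:
        return np.array([d.feature_class for d in self.definitions])


def build_features(
    stack: LayerStack | None,
    variables: list[str],
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    hinge_knots: int = 50,
    background: pd.DataFrame | None = None,
) -> FeatureSet:
    """Expand variables into scaled features.

    Knots and scaling come from the background value table: either
    ``background`` (a DataFrame of variable columns, e.g. a background
    sample) or, when omitted, every non-nodata cell of ``stack``.
    Constant variables are dropped with a warning.  ``hinge`` expands to
    forward + reverse hinges at ``hinge_knots`` background quantiles.
    """
    if background is None:
        if stack is None:
            raise ValueError("need a stack or a background value table")
        mask = stack.common_mask()
        rows, cols = np.nonzero(~mask)
        background = pd.DataFrame(
            stack.value_table(rows, cols, list(variables)), columns=list(variables)
        )
    missing = [v for v in variables if v not in background.columns]
    if missing:
        raise KeyError(f"variables not present: {missing}")
    if "hinge" in classes or "threshold" in classes:
        if hinge_knots < 2:
            raise ValueError("hinge_knots must be >= 2 when hinge features are on")

    usable = []
    var_range, var_mean = {}, {}
    for v in variables:
        x = background[v].to_numpy(dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            warnings.warn(f"variable {v!r} is constant; dropped", stacklevel=2)
            continue
        usable.append(v)
        var_range[v] = (lo, hi)
        var_mean[v] = float(np.mean(x))

    expanded = set(classes)
    if "hinge" in expanded:
        expanded.discard("hinge")
        expanded.update(("hinge_forward", "hinge_reverse"))

    defs: list[FeatureDefinition] = []
    for v in usable:
        if "linear" in expanded:
            defs.append(FeatureDefinition("linear", (v,)))
        if "quadratic" in expanded:
            defs.append(FeatureDefinition("quadratic", (v,)))
    if "product" in expanded:
        for a, b in itertools.combinations(usable, 2):
            defs.append(FeatureDefinition("product", (a, b)))
    knotted = [c for c in ("hinge_forward", "hinge_reverse", "threshold")
               if c in expanded]
    if knotted:
        qs = (np.arange(hinge_knots) + 1.0) / (hinge_knots + 1.0)
        for v in usable:
            knots = np.unique(np.quantile(background[v].to_numpy(dtype=float), qs))
            lo, hi = var_range[v]
            knots = knots[(knots > lo) & (knots < hi)]
            for c in knotted:
                defs.extend(FeatureDefinition(c, (v,), knot=float(k)) for k in knots)

    fs = FeatureSet(defs, usable, var_range, var_mean)
    raw = fs._raw(background[usable].to_numpy(dtype=float))
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    keep = hi > lo
    if not np.all(keep):
        dropped = [fs.definitions[j].label() for j in np.nonzero(~keep)[0]]
        warnings.warn(f"dropped {len(dropped)} constant features", stacklevel=2)
    fs.definitions = [d for d, k in zip(fs.definitions, keep) if k]
    fs.feature_range = np.column_stack([lo[keep], hi[keep]])
    return fs


@dataclass
class BackgroundSample:
    """Uniform sample (without replacement) of non-nodata cells."""

    rows: np.ndarray
    cols: np.ndarray
    values: pd.DataFrame   # one column per stack layer

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> np.ndarray:
        """Flat cell ids (row-major) identifying the sample."""
        return self.rows, self.cols


def sample_background(stack: LayerStack, n: int, seed: int) -> BackgroundSample:
    """Draw ``n`` background cells uniformly without replacement."""
    mask = stack.common_mask()
    rows, cols = np.nonzero(~mask)
    if n > len(rows):
        raise ValueError(
            f"requested {n} background points but only {len(rows)} usable cells"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n, replace=False)
    pick.sort()
    r, c = rows[pick], cols[pick]
    values = pd.DataFrame(stack.value_table(r, c), columns=stack.names)
    return BackgroundSample(rows=r, cols=c, values=values)


@dataclass
class MaxentModel:
    lambdas: np.ndarray
    feature_set: FeatureSet
    log_z: float                 # log of the density normalizer over background
    entropy: float               # H of the fitted distribution, nats
    beta: float
    n_presence: int
    background_ids: tuple = None

    @property
    def density_normalizer(self) -> float:
        return float(np.exp(self.log_z))

    def _active(self) -> tuple[FeatureSet, np.ndarray]:
        """Feature subset with nonzero weight (L1 fits are sparse)."""
        cached = getattr(self, "_active_cache", None)
        if cached is None:
            idx = np.nonzero(self.lambdas)[0]
            fs = self.feature_set
            sub = FeatureSet(
                [fs.definitions[j] for j in idx],
                fs.variables,
                fs.var_range,
                fs.var_mean,
                feature_range=fs.feature_range[idx].reshape(-1, 2),
            )
            cached = (sub, self.lambdas[idx])
            self._active_cache = cached
        return cached

    def raw(self, X, clamp: bool = False) -> np.ndarray:
        """Raw score q(x) = exp(lambda . f(x)) / Z_train."""
        sub, lam = self._active()
        if len(lam) == 0:
            n = sub._coerce(X).shape[0]
            return np.full(n, np.exp(-self.log_z))
        F = sub.evaluate(X, clamp=clamp)
        return np.exp(F @ lam - self.log_z)

    def k_nonzero(self, tol: float = 1e-8) -> int:
        return int(np.sum(np.abs(self.lambdas) > tol))

    # --- serialization -----------------------------------------------------
    def to_json(self) -> str:
        fs = self.feature_set
        return json.dumps(
            {
                "beta": self.beta,
                "log_z": self.log_z,
                "entropy": self.entropy,
                "n_presence": self.n_presence,
                "variables": fs.variables,
                "var_range": fs.var_range,
                "var_mean": fs.var_mean,
                "features": [
                    {
                        "class": d.feature_class,
                        "variables": list(d.variables),
                        "knot": d.knot,
                        "lambda": float(l),
                        "raw_min": float(lo),
                        "raw_max": float(hi),
                    }
                    for d, l, (lo, hi) in zip(
                        fs.definitions, self.lambdas, fs.feature_range
                    )
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        obj = json.loads(text)
        defs, lams, ranges = [], [], []
        for f in obj["features"]:
            defs.append(
                FeatureDefinition(f["class"], tuple(f["variables"]), f["knot"])
            )
            lams.append(f["lambda"])
            ranges.append((f["raw_min"], f["raw_max"]))
        fs = FeatureSet(
            defs,
            list(obj["variables"]),
            {k: tuple(v) for k, v in obj["var_range"].items()},
            dict(obj["var_mean"]),
            feature_range=np.array(ranges, dtype=float).reshape(-1, 2),
        )
        return cls(
            lambdas=np.array(lams, dtype=float),
            feature_set=fs,
            log_z=obj["log_z"],
            entropy=obj["entropy"],
            beta=obj["beta"],
            n_presence=obj["n_presence"],
        )


@dataclass
class FitReport:
    log_likelihood: float   # sum over presences of log raw score, nats
    gain: float             # mean presence log q + ln(N_background), nats
    iterations: int
    converged: bool
    tolerance: float        # achieved worst-case KKT violation
    objective_path: list = field(default_factory=list, repr=False)


def feature_penalties(
    F_presence: np.ndarray, classes: np.ndarray, beta: float, n_presence: int
) -> np.ndarray:
    """Per-feature L1 penalties beta_j = beta * base(class, m) * s_j / sqrt(m)."""
    s = np.maximum(F_presence.std(axis=0), _MIN_FEATURE_SD)
    base = np.array([base_regularization(c, n_presence) for c in classes])
    return beta * base * s / np.sqrt(n_presence)


def fit_maxent(
    presences,
    background: BackgroundSample | pd.DataFrame | np.ndarray,
    features: FeatureSet,
    beta: float = 1.0,
    x0: np.ndarray | None = None,
    precision: str = "high",
    track_objective: bool = False,
) -> tuple[MaxentModel, FitReport]:
    """Fit the penalized maximum-entropy model.

    ``presences`` and the background are variable-value tables (DataFrame
    with named columns, or arrays in ``features.variables`` order).  The
    normalizer Z is computed over the background sample only.  Returns
    the fitted model plus a report carrying gain, iteration count, and
    the achieved KKT tolerance; non-convergence is reported, never
    silent.
    """
    bg_values = background.values if isinstance(background, BackgroundSample) else background
    F_pres = features.evaluate(presences)
    F_bg = features.evaluate(bg_values)
    m, J = F_pres.shape
    if m < 2:
        raise ValueError("need at least 2 presences")
    if J == 0:
        raise ValueError("empty feature set")
    n_bg = F_bg.shape[0]

    pres_mean = F_pres.mean(axis=0)
    pen = feature_penalties(F_pres, features.classes(), beta, m)

    # single precision is ample for candidate screening and makes the
    # dominant mat-vecs ~2x faster; the polished default stays double
    F_opt = F_bg.astype(np.float32) if precision == "search" else F_bg

    path: list[float] = []

    def objective(z):
        lam = z[:J] - z[J:]
        eta = (F_opt @ lam.astype(F_opt.dtype)).astype(np.float64)
        log_z = logsumexp(eta)
        obj = log_z - pres_mean @ lam + pen @ (z[:J] + z[J:])
        w = np.exp(eta - log_z)
        grad_lam = (F_opt.T @ w.astype(F_opt.dtype)).astype(np.float64) - pres_mean
        grad = np.concatenate([grad_lam + pen, -grad_lam + pen])
        return obj, grad

    z0 = np.zeros(2 * J)
    if x0 is not None:
        z0[:J] = np.maximum(x0, 0)
        z0[J:] = np.maximum(-x0, 0)
    res = minimize(
        objective,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * J),
        callback=(
            (lambda z: path.append(float(objective(z)[0])))
            if track_objective else None
        ),
        options=PRECISION_OPTIONS[precision],
    )
    lam = res.x[:J] - res.x[J:]
    # zero out split-variable cancellation noise
    lam[np.abs(lam) < 1e-8] = 0.0

    eta = F_bg @ lam
    log_z = float(logsumexp(eta))
    w = np.exp(eta - log_z)
    entropy = float(-np.sum(w * (eta - log_z)))
    grad = F_bg.T @ w - pres_mean      # = E_q[f] - mean_pres f
    # KKT: |grad_j| <= pen_j everywhere; equality where lambda_j != 0
    slack = np.abs(grad) - pen
    viol = np.maximum(slack, 0.0)
    active = np.abs(lam) > 1e-6
    if np.any(active):
        viol[active] = np.maximum(viol[active], np.abs(np.abs(grad[active]) - pen[active]))
    tol = float(viol.max(initial=0.0))
    converged = bool(res.success) and tol <= 1e-4

    ll = float(np.sum(F_pres @ lam - log_z))
    gain = ll / m + np.log(n_bg)
    model = MaxentModel(
        lambdas=lam,
        feature_set=features,
        log_z=log_z,
        entropy=entropy,
        beta=beta,
        n_presence=m,
        background_ids=(
            background.ids if isinstance(background, BackgroundSample) else None
        ),
    )
    report = FitReport(
        log_likelihood=ll,
        gain=float(gain),
        iterations=int(res.nit),
        converged=converged,
        tolerance=tol,
        objective_path=path,
    )
    return model, report


TRANSFORMS = ("raw", "cumulative", "logistic", "cloglog")
_LOGISTIC_TAU = 0.5


def apply_transform(
    raw: np.ndarray,
    transform: str,
    entropy: float,
    background_raw: np.ndarray | None = None,
) -> np.ndarray:
    """Map raw scores onto the requested output scale.

    logistic: tau*e^H*q / (1 + tau*e^H*q), tau = 0.5; cloglog:
    1 - exp(-e^H * q); cumulative: percentile (0-100) of q among the
    training background raw scores.
    """
    if transform == "raw":
        return raw
    if transform == "logistic":
        t = _LOGISTIC_TAU * np.exp(entropy) * raw
        return t / (1.0 + t)
    if transform == "cloglog":
        return 1.0 - np.exp(-np.exp(entropy) * raw)
    if transform == "cumulative":
        if background_raw is None:
            raise ValueError("cumulative transform needs background raw scores")
        ref = np.sort(background_raw)
        return 100.0 * np.searchsorted(ref, raw, side="right") / len(ref)
    raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")


def predict(
    model: MaxentModel,
    stack: LayerStack,
    transform: str = "cloglog",
    clamp: bool = True,
) -> Grid:
    """Evaluate the fitted model across a layer stack.

    With ``clamp`` on, projection-time inputs are truncated to the
    training range of each variable before feature evaluation.
    """
    missing = [v for v in model.feature_set.variables if v not in stack]
    if missing:
        raise KeyError(f"stack {stack.scenario_tag!r} missing variables {missing}")
    template = stack.template
    mask = stack.common_mask()
    rows, cols = np.nonzero(~mask)
    X = stack.value_table(rows, cols, model.feature_set.variables)
    raw = model.raw(X, clamp=clamp)
    if transform == "cumulative":
        # percentile reference: the model's own training background is not
        # stored cell-by-cell; use this stack's raw scores as reference
        out_vals = apply_transform(raw, transform, model.entropy, background_raw=raw)
    else:
        out_vals = apply_transform(raw, transform, model.entropy)
    out = np.full(template.values.shape, template.nodata, dtype=float)
    out[rows, cols] = out_vals
    return Grid(
        values=out,
        x_min=template.x_min,
        y_max=template.y_max,
        cell_size=template.cell_size,
        nodata=template.nodata,
        name=f"suitability_{transform}",
    )


def isolated_gain(
    stack: LayerStack,
    presences,
    background: BackgroundSample,
    variable: str,
    beta: float = 1.0,
    classes: tuple[str, ...] = ("linear", "quadratic", "hinge"),
    hinge_knots: int = 10,
    precision: str = "high",
) -> float:
    """Training gain of a model fitted with a single variable's features.

    Used for the "highest gain when used in isolation" variable ranking.
    """
    if variable not in stack:
        raise KeyError(f"variable {variable!r} not in stack")
    fs = build_features(
        None, [variable], classes=classes, hinge_knots=hinge_knots,
        background=background.values,
    )
    pres = presences[[variable]] if isinstance(presences, pd.DataFrame) else presences
    _, report = fit_maxent(pres, background.values[[variable]], fs, beta=beta,
                           precision=precision)
    return report.gain


def response_curve(
    model: MaxentModel, variable: str, n_points: int = 100, transform: str = "cloglog"
) -> pd.DataFrame:
    """Suitability along one variable, others fixed at background means."""
    fs = model.feature_set
    if variable not in fs.variables:
        raise KeyError(f"variable {variable!r} not in model")
    lo, hi = fs.var_range[variable]
    grid = np.linspace(lo, hi, n_points)
    X = np.tile([fs.var_mean[v] for v in fs.variables], (n_points, 1))
    X[:, fs.variables.index(variable)] = grid
    raw = model.raw(X)
    suit = apply_transform(raw, transform, model.entropy)
    return pd.DataFrame({"value": grid, "suitability": suit})
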