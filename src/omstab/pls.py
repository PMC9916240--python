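"""Multi-response partial least squares (PLS2) with chemometric diagnostics.

A deterministic NIPALS implementation producing the diagnostics chemometrics
software conventionally reports:

* ``R²X(cum)`` / ``R²Y(cum)`` — cumulative fractions of X / Y variance
  explained by the fitted components (measures of fit);
* ``Q²(cum)`` — cumulative predicted Y variance under grouped
  cross-validation, combined multiplicatively over components,
  ``Q²(cum) = 1 − Π_a PRESS_a / SS_{a−1}`` (measure of predictivity;
  values above 0.5 are conventionally read as good);
* per-response ``R²VY(cum)`` / ``Q²VY(cum)``;
* ``RMSEE`` (root-mean-square error of estimation, training fit, with
  ``n − A − 1`` denominator) and ``RMSEcv`` (its cross-validated analogue,
  ``sqrt(PRESS/n)``), both on the original response scale.

Both X and Y are mean-centred and unit-variance scaled by default.
Cross-validation uses 7 groups with deterministic interleaved assignment
by row order, so identical inputs give bit-identical results.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScalingSpec", "PLSModel", "CVResult", "fit_pls", "predict", "cross_validate"]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class ScalingSpec:
    """Column centring / unit-variance scaling learned from training data.

    Zero-variance columns get scale factor 1 (with a warning) so that
    constant responses survive the transform unchanged.
    """

    center: bool = True
    unit_variance: bool = True
    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ScalingSpec":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        if self.unit_variance:
            std = X.std(axis=0, ddof=1)
            zero = std <= 0
            if np.any(zero):
                warnings.warn(
                    f"{int(zero.sum())} zero-variance column(s); scale factor set to 1",
                    stacklevel=2,
                )
                std = np.where(zero, 1.0, std)
            self.std_ = std
        else:
            self.std_ = np.ones(X.shape[1])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.std_

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.std_ + self.mean_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def clone_unfitted(self) -> "ScalingSpec":
        return ScalingSpec(center=self.center, unit_variance=self.unit_variance)


def _as_2d(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y.reshape(-1, 1) if Y.ndim == 1 else Y


def _nipals_component(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract one latent component from (residual) X, Y.

    Returns (w, t, c, p). Initialization: the Y column of largest variance;
    the weight sign is fixed so its largest-magnitude entry is positive.
    """
    start = int(np.argmax(Y.var(axis=0)))
    u = Y[:, start].copy()
    if not np.any(u):
        u = np.ones(X.shape[0])
    w = np.zeros(X.shape[1])
    for _ in range(_NIPALS_MAX_ITER):
        w_new = X.T @ u / (u @ u)
        norm = np.linalg.norm(w_new)
        if norm == 0:
            raise np.linalg.LinAlgError("X residual collapsed to zero during NIPALS")
        w_new /= norm
        if w_new[np.argmax(np.abs(w_new))] < 0:
            w_new = -w_new
        t = X @ w_new
        c = Y.T @ t / (t @ t)
        denom = c @ c
        u = Y @ c / denom if denom > 0 else t
        if np.linalg.norm(w_new - w) < _NIPALS_TOL:
            w = w_new
            break
        w = w_new
    t = X @ w
    c = Y.T @ t / (t @ t)
    p = X.T @ t / (t @ t)
    return w, t, c, p


@dataclass
class PLSModel:
    """A fitted multi-response PLS model plus its diagnostics."""

    n_components: int
    weights: np.ndarray  # W, p x A
    x_loadings: np.ndarray  # P, p x A
    y_loadings: np.ndarray  # C, q x A
    scores: np.ndarray  # T, n x A
    coef: np.ndarray  # B, p x q, scaled space
    x_scaler: ScalingSpec
    y_scaler: ScalingSpec
    r2x: np.ndarray = field(default=None)  # type: ignore[assignment]
    r2y: np.ndarray = field(default=None)  # type: ignore[assignment]
    r2x_cum: float = 0.0
    r2y_cum: float = 0.0
    r2vy_cum: np.ndarray = field(default=None)  # type: ignore[assignment]
    rmsee: np.ndarray = field(default=None)  # type: ignore[assignment]
    q2: np.ndarray | None = None
    q2_cum: float | None = None
    q2vy_cum: np.ndarray | None = None
    rmsecv: np.ndarray | None = None
    ss_y_sequence: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_samples: int = 0
    x_names: list[str] | None = None
    y_names: list[str] | None = None

    # -- prediction ---------------------------------------------------------

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        p = self.weights.shape[0]
        if X_new.shape[1] != p:
            raise ValueError(f"expected {p} predictor columns, got {X_new.shape[1]}")
        Xs = self.x_scaler.transform(X_new)
        Ys = Xs @ self.coef
        return self.y_scaler.inverse_transform(Ys)

    def fitted_values(self, X_train: np.ndarray) -> np.ndarray:
        return self.predict(X_train)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "n_components": self.n_components,
            "n_samples": self.n_samples,
            "weights": arr(self.weights),
            "x_loadings": arr(self.x_loadings),
            "y_loadings": arr(self.y_loadings),
            "coef": arr(self.coef),
            "x_scaler": {
                "center": self.x_scaler.center,
                "unit_variance": self.x_scaler.unit_variance,
                "mean": arr(self.x_scaler.mean_),
                "std": arr(self.x_scaler.std_),
            },
            "y_scaler": {
                "center": self.y_scaler.center,
                "unit_variance": self.y_scaler.unit_variance,
                "mean": arr(self.y_scaler.mean_),
                "std": arr(self.y_scaler.std_),
            },
            "diagnostics": {
                "r2x": arr(self.r2x),
                "r2y": arr(self.r2y),
                "r2x_cum": self.r2x_cum,
                "r2y_cum": self.r2y_cum,
                "r2vy_cum": arr(self.r2vy_cum),
                "rmsee": arr(self.rmsee),
                "q2": arr(self.q2),
                "q2_cum": self.q2_cum,
                "q2vy_cum": arr(self.q2vy_cum),
                "rmsecv": arr(self.rmsecv),
            },
            "x_names": self.x_names,
            "y_names": self.y_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        def scaler(s):
            sc = ScalingSpec(center=s["center"], unit_variance=s["unit_variance"])
            sc.mean_ = arr(s["mean"])
            sc.std_ = arr(s["std"])
            return sc

        diag = d["diagnostics"]
        model = cls(
            n_components=d["n_components"],
            weights=arr(d["weights"]),
            x_loadings=arr(d["x_loadings"]),
            y_loadings=arr(d["y_loadings"]),
            scores=np.zeros((0, d["n_components"])),
            coef=arr(d["coef"]),
            x_scaler=scaler(d["x_scaler"]),
            y_scaler=scaler(d["y_scaler"]),
        )
        model.n_samples = d.get("n_samples", 0)
        model.r2x = arr(diag["r2x"])
        model.r2y = arr(diag["r2y"])
        model.r2x_cum = diag["r2x_cum"]
        model.r2y_cum = diag["r2y_cum"]
        model.r2vy_cum = arr(diag["r2vy_cum"])
        model.rmsee = arr(diag["rmsee"])
        model.q2 = arr(diag["q2"])
        model.q2_cum = diag["q2_cum"]
        model.q2vy_cum = arr(diag["q2vy_cum"])
        model.rmsecv = arr(diag["rmsecv"])
        model.x_names = d.get("x_names")
        model.y_names = d.get("y_names")
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PLSModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def diagnostics_frame(self):
        """Per-response diagnostics as a DataFrame (one row per Y variable)."""
        import pandas as pd

        names = self.y_names or [f"y{j}" for j in range(self.coef.shape[1])]
        return pd.DataFrame(
            {
                "response": names,
                "R2VY_cum": self.r2vy_cum,
                "Q2VY_cum": self.q2vy_cum,
                "RMSEE": self.rmsee,
                "RMSEcv": self.rmsecv,
            }
        )


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    x_scaling: ScalingSpec | None = None,
    y_scaling: ScalingSpec | None = None,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> PLSModel:
    """Fit a PLS2 model by sequential NIPALS extraction with X and Y deflation.

    Requires ``n >= n_components + 2`` (so RMSEE's ``n − A − 1`` denominator
    stays positive) and ``n_components`` no larger than the rank of the
    scaled, centred X. Refitting identical input is bit-identical.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n < n_components + 2:
        raise ValueError(f"need n >= A + 2 rows (n={n}, A={n_components})")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values are not supported")

    x_scaler = (x_scaling or ScalingSpec()).clone_unfitted()
    y_scaler = (y_scaling or ScalingSpec()).clone_unfitted()
    Xs = x_scaler.fit_transform(X)
    Ys = y_scaler.fit_transform(Y)

    rank = np.linalg.matrix_rank(Xs)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")

    ssx_total = float(np.sum(Xs**2))
    ssy_total = float(np.sum(Ys**2))
    ssy0_per_col = np.sum(Ys**2, axis=0)

    Xr, Yr = Xs.copy(), Ys.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((Y.shape[1], n_components))
    T = np.zeros((n, n_components))
    r2x = np.zeros(n_components)
    r2y = np.zeros(n_components)
    ss_y_sequence = np.zeros(n_components + 1)
    ss_y_sequence[0] = ssy_total

    for a in range(n_components):
        w, t, c, pl = _nipals_component(Xr, Yr)
        W[:, a], T[:, a], C[:, a], P[:, a] = w, t, c, pl
        Xr = Xr - np.outer(t, pl)
        Yr = Yr - np.outer(t, c)
        tt = t @ t
        r2x[a] = tt * (pl @ pl) / ssx_total if ssx_total > 0 else 0.0
        r2y[a] = tt * (c @ c) / ssy_total if ssy_total > 0 else 0.0
        ss_y_sequence[a + 1] = float(np.sum(Yr**2))

    B = W @ np.linalg.solve(P.T @ W, C.T)

    model = PLSModel(
        n_components=n_components,
        weights=W,
        x_loadings=P,
        y_loadings=C,
        scores=T,
        coef=B,
        x_scaler=x_scaler,
        y_scaler=y_scaler,
        x_names=x_names,
        y_names=y_names,
    )
    model.n_samples = n
    model.r2x = r2x
    model.r2y = r2y
    model.r2x_cum = float(r2x.sum())
    model.r2y_cum = float(r2y.sum())
    ssres_per_col = np.sum(Yr**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        model.r2vy_cum = np.where(
            ssy0_per_col > 0, 1.0 - ssres_per_col / ssy0_per_col, 0.0
        )
    model.ss_y_sequence = ss_y_sequence

    # RMSEE on the original response scale
    resid = Y - model.predict(X)
    dof = n - n_components - 1
    if dof <= 0:  # unreachable given the n >= A + 2 precondition
        raise ValueError("RMSEE undefined: n <= A + 1")
    model.rmsee = np.sqrt(np.sum(resid**2, axis=0) / dof)
    return model


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`PLSModel.predict`."""
    return model.predict(X_new)


def _cv_groups(n: int, n_groups: int, assignment: str, seed: int | None) -> np.ndarray:
    if not (2 <= n_groups <= n):
        raise ValueError(f"n_groups must be in [2, n] (n={n}, n_groups={n_groups})")
    if assignment == "interleave":
        return np.arange(n) % n_groups
    if assignment == "random":
        rng = np.random.default_rng(seed)
        return rng.permutation(np.arange(n) % n_groups)
    raise ValueError(f"unknown assignment {assignment!r}")


@dataclass
class CVResult:
    """Grouped cross-validation summary for a PLS model."""

    q2: np.ndarray  # per component
    q2_cum: float
    q2vy_cum: np.ndarray  # per response
    rmsecv: np.ndarray  # per response, original scale
    press: np.ndarray  # per component, scaled space
    groups: np.ndarray


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_groups: int = 7,
    assignment: str = "interleave",
    seed: int | None = None,
    x_scaling: ScalingSpec | None = None,
    y_scaling: ScalingSpec | None = None,
) -> CVResult:
    """Grouped cross-validation of a PLS fit.

    Column scaling is treated as fixed preprocessing: the centring and
    unit-variance factors are computed once from the full data, and each
    fold refits only the centring and the latent components on its training
    rows before predicting the left-out responses component by component.
    ``PRESS_a`` accumulates the left-out residual sum of squares after *a*
    components (in the common scaled Y space); ``SS_{a−1}``, the
    denominator, is the full-model residual before component *a*. Q² per
    component is ``1 − PRESS_a/SS_{a−1}`` and cumulative Q² combines the
    ratios multiplicatively. RMSEcv is computed on the original response
    scale as ``sqrt(PRESS(A)/n)`` per response.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, q = Y.shape

    full = fit_pls(X, Y, n_components, x_scaling, y_scaling)
    ss_seq = full.ss_y_sequence  # SS_0 .. SS_A (scaled space)
    Xs = full.x_scaler.transform(X)
    Ys = full.y_scaler.transform(Y)
    ssy0_per_col = np.sum(Ys**2, axis=0)
    # per-column residual SS sequence from the full model
    ss_col_seq = np.zeros((n_components + 1, q))
    ss_col_seq[0] = ssy0_per_col
    Yr = Ys.copy()
    for a in range(n_components):
        Yr = Yr - np.outer(full.scores[:, a], full.y_loadings[:, a])
        ss_col_seq[a + 1] = np.sum(Yr**2, axis=0)

    groups = _cv_groups(n, n_groups, assignment, seed)
    press = np.zeros(n_components)
    press_col = np.zeros((n_components, q))
    press_orig = np.zeros(q)  # final-A PRESS on the original scale

    center_only = ScalingSpec(center=True, unit_variance=False)
    for g in np.unique(groups):
        out = groups == g
        sub = fit_pls(
            Xs[~out], Ys[~out], n_components, center_only, center_only
        )
        Xr = sub.x_scaler.transform(Xs[out])
        Yr_te = sub.y_scaler.transform(Ys[out])
        y_hat_scaled = np.tile(sub.y_scaler.mean_, (int(out.sum()), 1))
        for a in range(n_components):
            t = Xr @ sub.weights[:, a]
            Yr_te = Yr_te - np.outer(t, sub.y_loadings[:, a])
            Xr = Xr - np.outer(t, sub.x_loadings[:, a])
            y_hat_scaled += np.outer(t, sub.y_loadings[:, a])
            press[a] += float(np.sum(Yr_te**2))
            press_col[a] += np.sum(Yr_te**2, axis=0)
        y_hat = full.y_scaler.inverse_transform(y_hat_scaled)
        press_orig += np.sum((Y[out] - y_hat) ** 2, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = press / ss_seq[:-1]
        q2 = 1.0 - ratios
        q2_cum = float(1.0 - np.prod(ratios))
        ratios_col = np.where(ss_col_seq[:-1] > 0, press_col / ss_col_seq[:-1], 1.0)
        q2vy_cum = 1.0 - np.prod(ratios_col, axis=0)
    rmsecv = np.sqrt(press_orig / n)
    return CVResult(
        q2=q2,
        q2_cum=q2_cum,
        q2vy_cum=q2vy_cum,
        rmsecv=rmsecv,
        press=press,
        groups=groups,
    )


def fit_pls_cv(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_groups: int = 7,
    assignment: str = "interleave",
    seed: int | None = None,
    x_scaling: ScalingSpec | None = None,
    y_scaling: ScalingSpec | None = None,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> PLSModel:
    """Fit a PLS model and attach cross-validation diagnostics to it."""
    model = fit_pls(X, Y, n_components, x_scaling, y_scaling, x_names, y_names)
    cv = cross_validate(
        X, Y, n_components, n_groups, assignment, seed, x_scaling, y_scaling
    )
    model.q2 = cv.q2
    model.q2_cum = cv.q2_cum
    model.q2vy_cum = cv.q2vy_cum
    model.rmsecv = cv.rmsecv
    return model


def auto_components(
    X: np.ndarray,
    Y: np.ndarray,
    max_components: int,
    q2_threshold: float = 0.05,
    **cv_kwargs,
) -> int:
    """Smallest informative component count: stop when a component's Q² < threshold.

    Off by default in the pipeline (component counts are fixed by config);
    provided for exploratory use.
    """
    for a in range(1, max_components + 1):
        cv = cross_validate(X, Y, a, **cv_kwargs)
        if cv.q2[a - 1] < q2_threshold:
            return max(a - 1, 1)
    return max_components
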