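"""PLS and PCR regression on autoscaled data with leave-one-out validation.

Both model families regress the autoscaled activity on the autoscaled
descriptor matrix, so the fitted equations have no intercept and their
coefficients are directly comparable across descriptors:

* **PLS1 (NIPALS)** extracts latent variables maximizing the covariance
  between X-scores and y, deflating X and y after each component.  The
  nonlinear iterative scheme is run to convergence (tolerance 1e-12 on the
  score vector, at most 500 iterations per component); for a single response
  it converges in one pass, and the iterative path must agree with that
  closed form.
* **PCR** regresses y on the leading principal-component scores of X and
  back-projects the coefficients to descriptor space.

Validation follows the classical chemometrics protocol: leave-one-out
cross-validation with the autoscalers re-fit on every fold (no information
leaks from the held-out compound), accumulating the squared prediction errors
into PRESS.  Reported statistics:

    PRESS_cal = sum (y_i - yhat_cal,i)^2        (calibration residual SS)
    PRESS_val = sum (y_i - yhat_loo,i)^2        (validation PRESS)
    R^2   = 1 - PRESS_cal / TSS
    Q^2   = 1 - PRESS_val / TSS                 (TSS about the training mean)
    SEV   = sqrt(PRESS_val / n)
    R^2adj = 1 - (1 - R^2)(n - 1)/(n - k)
    s     = sqrt(PRESS_cal / (n - k))
    F     = (R^2 / k) / ((1 - R^2)/(n - k - 1)),  df = (k, n - k - 1)
    s_PRESS = sqrt(PRESS_val / (n - k - 1))

The number of components can be chosen by minimum LOO PRESS
(:func:`select_n_components`), the selection rule classical chemometrics
packages apply before reporting a final model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import QSARDataError, QSARDataset
from .pca import fit_pca
from .preprocess import AutoscaleModel, fit_autoscale

__all__ = [
    "LatentModel",
    "FitStatistics",
    "PredictionResult",
    "fit_pls",
    "fit_pcr",
    "fit_latent_model",
    "predict",
    "loo_cross_validate",
    "select_n_components",
    "compute_fit_statistics",
    "evaluate_model",
    "compare_models",
    "save_model",
    "load_model",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500
_RANK_TOL = 1e-10


@dataclass
class LatentModel:
    """A fitted PLS or PCR model in autoscaled X / autoscaled y space."""

    method: str  # "PLS" or "PCR"
    n_components: int
    coefficients: np.ndarray  # standardized-space coefficient vector, length m
    x_scaler: AutoscaleModel
    y_scaler: AutoscaleModel  # single column
    descriptor_names: list[str]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise QSARDataError("non-finite model coefficients")
        if len(self.coefficients) != len(self.descriptor_names):
            raise QSARDataError("coefficient length does not match descriptor count")


@dataclass
class FitStatistics:
    """Calibration and leave-one-out validation statistics of a latent model."""

    r2: float
    r2_adj: float
    s: float
    f_value: float
    df: tuple[int, int]
    q2: float
    sev: float
    press_cal: float
    press_val: float
    s_press: float
    n: int
    k: int

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in (
            "r2", "r2_adj", "s", "f_value", "q2", "sev",
            "press_cal", "press_val", "s_press", "n", "k",
        )}
        d["df1"], d["df2"] = self.df
        return d


@dataclass
class PredictionResult:
    compound_ids: list[str]
    predicted: np.ndarray
    observed: np.ndarray | None = None
    validation_error: np.ndarray | None = None  # predicted - observed

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=float)
            if self.validation_error is None:
                self.validation_error = self.predicted - self.observed

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"compound_id": self.compound_ids, "predicted": self.predicted})
        if self.observed is not None:
            df["observed"] = self.observed
            df["validation_error"] = self.validation_error
        return df


# -- fitting ---------------------------------------------------------------


def _autoscaled_xy(dataset: QSARDataset) -> tuple[np.ndarray, np.ndarray, AutoscaleModel, AutoscaleModel]:
    if not dataset.has_activity:
        raise QSARDataError("fitting requires a complete activity column")
    x_scaler = fit_autoscale(dataset)
    xs = x_scaler.transform(dataset)
    y = dataset.activity()
    sy = y.std(ddof=1)
    if sy == 0.0:
        raise QSARDataError(f"constant activity column {dataset.activity_name!r}")
    y_scaler = AutoscaleModel([dataset.activity_name], np.array([y.mean()]), np.array([sy]))
    ys = (y - y.mean()) / sy
    return xs, ys, x_scaler, y_scaler


def _nipals_pls1(xs: np.ndarray, ys: np.ndarray, n_components: int) -> np.ndarray:
    """NIPALS PLS1: returns the standardized-space coefficient vector.

    X and y are deflated in place on copies; weights are collected to build
    B = W (P'W)^-1 q.  Requesting more components than the effective rank of
    the X/y covariance raises a rank-deficiency error.
    """
    x_res = xs.copy()
    y_res = ys.copy()
    n, m = x_res.shape
    weights, x_loadings, y_loadings = [], [], []
    for a in range(n_components):
        w = x_res.T @ y_res
        norm_w = np.linalg.norm(w)
        if norm_w < _RANK_TOL:
            raise QSARDataError(
                f"rank deficiency: no covariance left for component {a + 1}"
            )
        w /= norm_w
        t = x_res @ w
        # The iterative NIPALS loop; with a single response u = y_res is fixed,
        # so this converges immediately, but the loop is kept as the canonical
        # algorithm and as a guard.
        for _ in range(_NIPALS_MAX_ITER):
            w_new = x_res.T @ y_res
            w_new /= np.linalg.norm(w_new)
            t_new = x_res @ w_new
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * max(1.0, np.linalg.norm(t)):
                w, t = w_new, t_new
                break
            w, t = w_new, t_new
        tt = t @ t
        if tt < _RANK_TOL:
            raise QSARDataError(
                f"rank deficiency: degenerate score vector at component {a + 1}"
            )
        p = x_res.T @ t / tt
        q = (y_res @ t) / tt
        x_res = x_res - np.outer(t, p)
        y_res = y_res - q * t
        weights.append(w)
        x_loadings.append(p)
        y_loadings.append(q)
    w_mat = np.array(weights).T  # m x a
    p_mat = np.array(x_loadings).T
    q_vec = np.array(y_loadings)
    return w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_vec)


def _pcr_coefficients(xs: np.ndarray, ys: np.ndarray, n_components: int) -> np.ndarray:
    model = fit_pca(xs)
    if model.eigenvalues[n_components - 1] < _RANK_TOL:
        raise QSARDataError(
            f"rank deficiency: eigenvalue {n_components} is numerically zero"
        )
    scores = model.scores[:, :n_components]
    gamma, *_ = np.linalg.lstsq(scores, ys, rcond=None)
    return model.loadings[:, :n_components] @ gamma


def fit_pls(dataset: QSARDataset, n_components: int = 3) -> LatentModel:
    """NIPALS PLS1 on autoscaled X and y; coefficients in standardized space."""
    return fit_latent_model("PLS", dataset, n_components)


def fit_pcr(dataset: QSARDataset, n_components: int = 3) -> LatentModel:
    """Regression of autoscaled y on the first principal-component scores."""
    return fit_latent_model("PCR", dataset, n_components)


def fit_latent_model(method: str, dataset: QSARDataset, n_components: int = 3) -> LatentModel:
    method = method.upper()
    if method not in ("PLS", "PCR"):
        raise QSARDataError(f"unknown method {method!r}; choose PLS or PCR")
    m = dataset.n_descriptors
    if not 1 <= n_components <= m:
        raise QSARDataError(f"n_components must lie in [1, {m}], got {n_components}")
    xs, ys, x_scaler, y_scaler = _autoscaled_xy(dataset)
    fit = _nipals_pls1 if method == "PLS" else _pcr_coefficients
    coefficients = fit(xs, ys, n_components)
    return LatentModel(
        method=method,
        n_components=n_components,
        coefficients=coefficients,
        x_scaler=x_scaler,
        y_scaler=y_scaler,
        descriptor_names=list(dataset.descriptor_names),
    )


# -- prediction and validation ---------------------------------------------


def predict(model: LatentModel, dataset: QSARDataset) -> PredictionResult:
    """Scale with the model's training scalers, apply the coefficient vector
    and back-transform to activity units.  Observed values and validation
    errors (predicted - observed) are attached when activity is present."""
    xs = model.x_scaler.transform(dataset)  # raises on missing descriptor
    ys_hat = xs @ model.coefficients
    predicted = model.y_scaler.inverse_transform(ys_hat.reshape(-1, 1)).ravel()
    observed = dataset.activity() if dataset.has_activity else None
    return PredictionResult(dataset.compound_ids, predicted, observed)


def loo_cross_validate(
    method: str,
    dataset: QSARDataset,
    n_components: int = 3,
    refit_scalers: bool = True,
) -> tuple[PredictionResult, float]:
    """Leave-one-out cross-validation: refit on n-1 compounds, predict the one
    held out; returns the LOO predictions and PRESS_val.

    By default the autoscalers are re-fit on every fold along with the model;
    ``refit_scalers=False`` keeps the full-training scalers fixed instead.
    A fold whose training subset has a constant column aborts with an error
    naming the fold.
    """
    n = dataset.n_compounds
    if n < 3:
        raise QSARDataError("leave-one-out validation requires at least 3 compounds")
    y = dataset.activity()
    full_scalers: tuple[AutoscaleModel, AutoscaleModel] | None = None
    if not refit_scalers:
        _, _, xsc, ysc = _autoscaled_xy(dataset)
        full_scalers = (xsc, ysc)

    predictions = np.empty(n)
    x_all = dataset.matrix()
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        fold = dataset.select_rows(keep)
        try:
            if refit_scalers:
                model = fit_latent_model(method, fold, n_components)
            else:
                xsc, ysc = full_scalers
                xs = xsc.transform(fold)
                ys = (fold.activity() - ysc.means[0]) / ysc.stdevs[0]
                fit = _nipals_pls1 if method.upper() == "PLS" else _pcr_coefficients
                coef = fit(xs, ys, n_components)
                model = LatentModel(
                    method.upper(), n_components, coef, xsc, ysc,
                    list(dataset.descriptor_names),
                )
        except QSARDataError as exc:
            raise QSARDataError(
                f"degenerate fold leaving out compound "
                f"{dataset.compound_ids[i]!r}: {exc}"
            ) from exc
        xs_i = model.x_scaler.transform(x_all[i])
        predictions[i] = model.y_scaler.inverse_transform(
            (xs_i @ model.coefficients).reshape(-1, 1)
        ).ravel()[0]
    result = PredictionResult(dataset.compound_ids, predictions, y)
    press_val = float(np.sum((y - predictions) ** 2))
    return result, press_val


def select_n_components(
    method: str, dataset: QSARDataset, max_components: int | None = None
) -> tuple[int, dict[int, float]]:
    """Pick the component count minimizing LOO PRESS (ties go to the fewest).

    Returns ``(best, press_by_count)``.  This is the factor-selection rule of
    classical chemometrics software: the final reported model uses the
    cross-validation-optimal number of latent variables, which may be fewer
    than the number of components examined.
    """
    m = dataset.n_descriptors
    a_max = m if max_components is None else max_components
    if not 1 <= a_max <= m:
        raise QSARDataError(f"max_components must lie in [1, {m}], got {a_max}")
    press: dict[int, float] = {}
    for a in range(1, a_max + 1):
        _, press[a] = loo_cross_validate(method, dataset, a)
    best = min(press, key=lambda a: (press[a], a))
    return best, press


# -- statistics ------------------------------------------------------------


def compute_fit_statistics(
    observed: np.ndarray,
    predicted_cal: np.ndarray,
    predicted_val: np.ndarray,
    k: int,
) -> FitStatistics:
    """Assemble the full statistics suite from calibration and LOO predictions.

    ``k`` is the number of descriptors in the model (not the component count);
    it sets the degrees of freedom: R^2adj and s divide by n - k, F uses
    (k, n - k - 1).
    """
    y = np.asarray(observed, dtype=float)
    cal = np.asarray(predicted_cal, dtype=float)
    val = np.asarray(predicted_val, dtype=float)
    n = len(y)
    if not (len(cal) == len(val) == n):
        raise QSARDataError("observed/predicted vectors differ in length")
    if k < 1:
        raise QSARDataError(f"k must be >= 1, got {k}")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise QSARDataError("degenerate activity: zero total sum of squares")
    press_cal = float(np.sum((y - cal) ** 2))
    press_val = float(np.sum((y - val) ** 2))
    r2 = 1.0 - press_cal / tss
    q2 = 1.0 - press_val / tss
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k)
    s = float(np.sqrt(press_cal / (n - k)))
    df = (k, n - k - 1)
    f_value = (
        float(np.inf) if r2 >= 1.0 else (r2 / k) / ((1.0 - r2) / (n - k - 1))
    )
    sev = float(np.sqrt(press_val / n))
    s_press = float(np.sqrt(press_val / (n - k - 1)))
    return FitStatistics(
        r2=r2, r2_adj=r2_adj, s=s, f_value=f_value, df=df, q2=q2, sev=sev,
        press_cal=press_cal, press_val=press_val, s_press=s_press, n=n, k=k,
    )


def evaluate_model(
    method: str,
    dataset: QSARDataset,
    n_components: int = 3,
    validation_components: int | None = None,
) -> tuple[LatentModel, FitStatistics, PredictionResult]:
    """Fit, cross-validate and score a model in one call.

    ``validation_components`` lets the LOO statistics be computed at a
    different (e.g. PRESS-optimal) component count than the calibration fit;
    by default both use ``n_components``.
    """
    model = fit_latent_model(method, dataset, n_components)
    cal = predict(model, dataset)
    a_val = n_components if validation_components is None else validation_components
    loo, _ = loo_cross_validate(method, dataset, a_val)
    stats = compute_fit_statistics(
        dataset.activity(), cal.predicted, loo.predicted, k=dataset.n_descriptors
    )
    return model, stats, loo


def compare_models(
    result_a: PredictionResult, result_b: PredictionResult
) -> pd.DataFrame:
    """Per-compound prediction residues a - b (e.g. PLS minus PCR)."""
    if result_a.compound_ids != result_b.compound_ids:
        raise QSARDataError("prediction results cover different compounds")
    return pd.DataFrame(
        {
            "compound_id": result_a.compound_ids,
            "pred_a": result_a.predicted,
            "pred_b": result_b.predicted,
            "residue": result_a.predicted - result_b.predicted,
        }
    )


# -- plain-text model serialization ----------------------------------------


def save_model(model: LatentModel, path: str | Path) -> None:
    """Human-diffable key-value model file (full float precision)."""
    lines = [
        f"method: {model.method}",
        f"n_components: {model.n_components}",
        f"descriptors: {','.join(model.descriptor_names)}",
        f"coefficients: {','.join(repr(float(c)) for c in model.coefficients)}",
        f"x_means: {','.join(repr(float(v)) for v in model.x_scaler.means)}",
        f"x_stdevs: {','.join(repr(float(v)) for v in model.x_scaler.stdevs)}",
        f"y_name: {model.y_scaler.column_names[0]}",
        f"y_mean: {float(model.y_scaler.means[0])!r}",
        f"y_stdev: {float(model.y_scaler.stdevs[0])!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> LatentModel:
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            key, _, value = line.partition(":")
            fields[key.strip()] = value.strip()
    names = fields["descriptors"].split(",")
    floats = lambda key: np.array([float(v) for v in fields[key].split(",")])
    return LatentModel(
        method=fields["method"],
        n_components=int(fields["n_components"]),
        coefficients=floats("coefficients"),
        x_scaler=AutoscaleModel(names, floats("x_means"), floats("x_stdevs")),
        y_scaler=AutoscaleModel(
            [fields["y_name"]],
            np.array([float(fields["y_mean"])]),
            np.array([float(fields["y_stdev"])]),
        ),
        descriptor_names=names,
    )
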