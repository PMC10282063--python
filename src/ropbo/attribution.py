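"""Feature attribution for the stereoselectivity surrogate.

Shapley values explain one surrogate prediction as a sum of per-feature
contributions referenced to the average prediction over a background
sample. The value function is interventional: v(S) is the mean model
output when the features in S are taken from the explained record and the
rest from a background row. Exact enumeration (all 2^d subsets) is used
for small feature counts; permutation sampling scales beyond that.

The module also provides mean-|phi| feature ranking with correlation-sign
summaries, ordinary-least-squares multivariate selectivity models, and the
buried-volume range summary comparing highly isoselective (P_m > 0.8) and
highly heteroselective (P_r > 0.8) catalyst classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import CollinearityError, ValidationError
from .surrogate import GPModel, predict_arrays

EXACT_LIMIT = 15

ModelFn = Callable[[np.ndarray], np.ndarray]


def _as_model_fn(model) -> ModelFn:
    if isinstance(model, GPModel):
        return lambda X: predict_arrays(model, X)[0]
    if callable(model):
        return lambda X: np.asarray(model(X), dtype=float).ravel()
    raise ValidationError("model must be a GPModel or a callable")


def shapley_attribution(
    model,
    record: np.ndarray | pd.Series,
    background: np.ndarray | pd.DataFrame,
    mode: str = "exact",
    n_permutations: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Shapley contributions (phi per feature) and base value for one record.

    In exact mode all 2^d feature subsets are enumerated, so the
    efficiency, symmetry, and null-player axioms hold to numerical
    precision; the mode refuses d > 15. Sampled mode averages marginal
    contributions over random feature orderings and satisfies efficiency
    in expectation.

    Returns ``(phi, base)`` with ``base + phi.sum()`` equal to the model
    prediction at the record (exactly for exact mode).
    """
    f = _as_model_fn(model)
    x = (
        record.to_numpy(dtype=float)
        if isinstance(record, pd.Series)
        else np.asarray(record, dtype=float)
    ).ravel()
    bg = (
        background.to_numpy(dtype=float)
        if isinstance(background, pd.DataFrame)
        else np.asarray(background, dtype=float)
    )
    if bg.ndim == 1:
        bg = bg[None, :]
    if bg.shape[0] == 0:
        raise ValidationError("background must be nonempty")
    d = x.size
    if bg.shape[1] != d:
        raise ValidationError("record and background dimension mismatch")

    if mode == "exact":
        if d > EXACT_LIMIT:
            raise ValidationError(
                f"exact enumeration limited to {EXACT_LIMIT} features "
                f"(got {d}); use mode='sampled'"
            )
        return _shapley_exact(f, x, bg)
    if mode == "sampled":
        return _shapley_sampled(f, x, bg, n_permutations, seed)
    raise ValidationError(f"unknown mode {mode!r}")


def _subset_values(f: ModelFn, x: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """v(S) for every subset bitmask: mean model output with features in S
    taken from x and the rest from each background row."""
    d = x.size
    n_bg = bg.shape[0]
    n_sub = 1 << d
    composites = np.tile(bg, (n_sub, 1))
    for mask in range(n_sub):
        block = slice(mask * n_bg, (mask + 1) * n_bg)
        for i in range(d):
            if mask >> i & 1:
                composites[block, i] = x[i]
    preds = f(composites)
    return preds.reshape(n_sub, n_bg).mean(axis=1)


def _shapley_exact(
    f: ModelFn, x: np.ndarray, bg: np.ndarray
) -> tuple[np.ndarray, float]:
    d = x.size
    v = _subset_values(f, x, bg)
    weights = np.array(
        [factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)]
    )
    phi = np.zeros(d)
    for mask in range(1 << d):
        s = bin(mask).count("1")
        for i in range(d):
            if not mask >> i & 1:
                phi[i] += weights[s] * (v[mask | (1 << i)] - v[mask])
    return phi, float(v[0])


def _shapley_sampled(
    f: ModelFn,
    x: np.ndarray,
    bg: np.ndarray,
    n_permutations: int,
    seed: int,
) -> tuple[np.ndarray, float]:
    d = x.size
    rng = np.random.default_rng(seed)
    base = float(f(bg).mean())
    contribs = np.zeros((n_permutations, d))
    for p in range(n_permutations):
        order = rng.permutation(d)
        composite = bg.copy()
        prev = base
        for i in order:
            composite[:, i] = x[i]
            cur = float(f(composite).mean())
            contribs[p, i] = cur - prev
            prev = cur
    return contribs.mean(axis=0), base


def linear_shapley(
    coef: np.ndarray, record: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """Closed-form Shapley values for a linear model with the
    background-replacement value function: phi_i = beta_i (x_i - mean x_i)."""
    return np.asarray(coef, dtype=float) * (
        np.asarray(record, dtype=float)
        - np.asarray(background, dtype=float).mean(axis=0)
    )


@dataclass
class AttributionResult:
    """Shapley attributions for a set of records under one surrogate."""

    phi: pd.DataFrame  # rows: record ids, columns: feature names
    base: float
    predictions: np.ndarray
    feature_values: pd.DataFrame

    def efficiency_gap(self) -> np.ndarray:
        """Per-record |base + sum(phi) - prediction| (0 in exact mode)."""
        return np.abs(
            self.base + self.phi.sum(axis=1).to_numpy() - self.predictions
        )


def attribute_dataset(
    model,
    X: pd.DataFrame,
    background: pd.DataFrame | None = None,
    mode: str = "exact",
    n_permutations: int = 200,
    seed: int = 0,
) -> AttributionResult:
    """Shapley-attribute every row of X (background defaults to X itself)."""
    if background is None:
        background = X
    f = _as_model_fn(model)
    phis = []
    base = None
    for _, row in X.iterrows():
        phi, base = shapley_attribution(
            model, row, background, mode=mode,
            n_permutations=n_permutations, seed=seed,
        )
        phis.append(phi)
    return AttributionResult(
        phi=pd.DataFrame(phis, index=X.index, columns=X.columns),
        base=float(base),
        predictions=f(X.to_numpy(dtype=float)),
        feature_values=X.copy(),
    )


def rank_features(result: AttributionResult) -> pd.DataFrame:
    """Rank features by mean |phi| with a correlation-sign summary.

    The sign is the sign of the Pearson correlation between the feature's
    values and its Shapley contributions across records: positive means
    larger feature values push the predicted selectivity up. Ties in mean
    |phi| break alphabetically for stability.
    """
    if len(result.phi) == 0:
        raise ValidationError("no attributed records to rank")
    mean_abs = result.phi.abs().mean(axis=0)
    signs = {}
    for col in result.phi.columns:
        x = result.feature_values[col].to_numpy(dtype=float)
        p = result.phi[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(p) == 0:
            signs[col] = 0
        else:
            signs[col] = int(np.sign(pearsonr(x, p).statistic))
    table = pd.DataFrame(
        {"feature": mean_abs.index, "mean_abs_phi": mean_abs.values}
    )
    table["sign"] = [signs[c] for c in table["feature"]]
    table = table.sort_values(
        ["mean_abs_phi", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return table


@dataclass
class LinearModel:
    """An OLS selectivity model on standardized descriptors."""

    features: list[str]
    coef: np.ndarray  # on standardized scale
    intercept: float
    r2: float
    mae: float
    means: np.ndarray
    scales: np.ndarray

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xa = (
            X[self.features].to_numpy(dtype=float)
            if isinstance(X, pd.DataFrame)
            else np.asarray(X, dtype=float)
        )
        Z = (Xa - self.means) / self.scales
        return self.intercept + Z @ self.coef


def fit_linear(
    X: pd.DataFrame, y: Sequence[float], selected: Sequence[str] | None = None
) -> LinearModel:
    """Ordinary least squares of an outcome on standardized descriptors.

    Reports coefficients, R^2 = 1 - SS_res/SS_tot, and the mean absolute
    error on the fitting data. A rank-deficient design raises a
    collinearity error naming the offending columns.
    """
    cols = list(selected) if selected is not None else list(X.columns)
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValidationError(f"unknown feature columns: {missing}")
    ya = np.asarray(y, dtype=float)
    n, p = len(ya), len(cols)
    if n <= p + 1:
        raise ValidationError(
            f"need more than {p + 1} records to fit {p} coefficients, got {n}"
        )
    Xa = X[cols].to_numpy(dtype=float)
    means = Xa.mean(axis=0)
    scales = Xa.std(axis=0, ddof=0)
    if np.any(scales == 0):
        bad = [cols[i] for i in np.flatnonzero(scales == 0)]
        raise CollinearityError(f"constant columns in design: {bad}")
    Z = (Xa - means) / scales
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < p + 1:
        corr = np.corrcoef(Z, rowvar=False)
        bad_pairs = [
            (cols[i], cols[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise CollinearityError(
            f"rank-deficient design; exactly collinear columns: {bad_pairs}"
        )
    beta, *_ = np.linalg.lstsq(design, ya, rcond=None)
    fitted = design @ beta
    ss_res = float(np.sum((ya - fitted) ** 2))
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearModel(
        features=cols,
        coef=beta[1:],
        intercept=float(beta[0]),
        r2=r2,
        mae=float(np.mean(np.abs(ya - fitted))),
        means=means,
        scales=scales,
    )


def selectivity_vbur_summary(
    p_m: Sequence[float],
    vbur: Sequence[float],
    threshold: float = 0.8,
) -> dict[str, dict[str, float] | None]:
    """Buried-volume ranges of the highly iso- and heteroselective classes.

    For records with P_m above the threshold (isoselective) and records
    with P_r = 1 - P_m above it (heteroselective), report the min, max,
    and span of whole-complex %V_bur. An empty class is reported as None.
    """
    pm = np.asarray(p_m, dtype=float)
    vb = np.asarray(vbur, dtype=float)
    if pm.shape != vb.shape:
        raise ValidationError("p_m and vbur length mismatch")
    out: dict[str, dict[str, float] | None] = {}
    for label, mask in (
        ("isoselective", pm > threshold),
        ("heteroselective", (1.0 - pm) > threshold),
    ):
        if not np.any(mask):
            out[label] = None
        else:
            sel = vb[mask]
            out[label] = {
                "n": int(mask.sum()),
                "min": float(sel.min()),
                "max": float(sel.max()),
                "span": float(sel.max() - sel.min()),
            }
    return out
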