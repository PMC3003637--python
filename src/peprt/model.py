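"""The two-descriptor QSRR retention model.

The model is an ordinary least-squares multiple linear regression

    t_R = k1 + k2 * log Sum(k+1)_AA + k3 * clogP

predicting the gradient RP-LC retention time (minutes) of a tryptic
peptide from its composite hydrophobicity descriptor and its calculated
octanol/water partition coefficient.  Fit statistics follow the usual MLR
conventions: R is the positive multiple correlation coefficient, s the
standard error of estimate with n - 3 degrees of freedom, and F the
overall significance test with (2, n - 3) degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .descriptors import DescriptorPair

__all__ = [
    "QsrrModel",
    "FitStatistics",
    "Prediction",
    "REFERENCE_MODEL",
    "fit_mlr",
    "predict_rt",
    "delta_rt",
    "evaluate_test_set",
    "save_model",
    "load_model",
]

_COEF_NAMES = ("k1", "k2", "k3")


@dataclass(frozen=True)
class QsrrModel:
    """Regression coefficients of the retention-time equation."""

    k1: float  # intercept, min
    k2: float  # min per log-unit of log Sum(k+1)_AA
    k3: float  # min per log-unit of clogP

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.k1, self.k2, self.k3))):
            raise ValueError("model coefficients must be finite")

    def predict(self, log_sum_k1: float, clogp: float) -> float:
        return self.k1 + self.k2 * log_sum_k1 + self.k3 * clogp


#: Coefficient set distributed alongside the original calibration data.
#: Shipped for reference only: these coefficients do NOT reproduce the
#: ``t_r_pred`` column bundled with that data (they are low by ~6 min for
#: typical peptides), whereas the statistics of a fresh OLS fit on the
#: calibration table do match the reported ones.  The package's canonical
#: model is therefore the refit (see :func:`peprt.tables.calibration_model`).
REFERENCE_MODEL = QsrrModel(k1=-25.07, k2=33.16, k3=0.60)


@dataclass(frozen=True)
class FitStatistics:
    """Calibration-set fit statistics of a :class:`QsrrModel`."""

    n: int
    R: float  # multiple correlation coefficient, in [0, 1]
    s: float  # standard error of estimate, min
    F: float
    p_overall: float
    p_coef: dict[str, float]
    se_coef: dict[str, float]


@dataclass(frozen=True)
class Prediction:
    """Predicted retention time and (when t_r_exp is known) its residual."""

    t_r_pred: float
    delta_t_r: float | None = None
    abs_delta_t_r: float | None = None


class FittingError(ValueError):
    """Raised for degenerate calibration sets."""


def _design(pairs: Sequence[DescriptorPair]) -> np.ndarray:
    return np.column_stack(
        [
            np.ones(len(pairs)),
            [d.log_sum_k1 for d in pairs],
            [d.clogp for d in pairs],
        ]
    )


def fit_mlr(
    calibration: Iterable[tuple[DescriptorPair, float]],
) -> tuple[QsrrModel, FitStatistics]:
    """OLS fit of retention time on the two descriptors plus intercept.

    ``calibration`` yields (descriptors, experimental retention time) pairs.
    Raises :class:`FittingError` when n <= 3 or a descriptor column is
    degenerate (constant or collinear) — no silent pseudo-inverse.
    """
    rows = list(calibration)
    if len(rows) <= 3:
        raise FittingError(f"need more than 3 calibration peptides, got {len(rows)}")
    X = _design([d for d, _ in rows])
    y = np.array([t for _, t in rows], dtype=float)
    if np.linalg.matrix_rank(X) < 3:
        raise FittingError(
            "degenerate calibration set: descriptor columns are constant "
            "or collinear"
        )
    res = sm.OLS(y, X).fit()
    n = len(rows)
    r2 = res.rsquared
    model = QsrrModel(*map(float, res.params))
    stats = FitStatistics(
        n=n,
        R=float(np.sqrt(r2)),
        s=float(np.sqrt(res.ssr / (n - 3))),
        F=math.inf if r2 >= 1.0 else float((r2 / 2) / ((1 - r2) / (n - 3))),
        p_overall=float(res.f_pvalue),
        p_coef=dict(zip(_COEF_NAMES, map(float, res.pvalues))),
        se_coef=dict(zip(_COEF_NAMES, map(float, res.bse))),
    )
    return model, stats


def predict_rt(model: QsrrModel, d: DescriptorPair) -> Prediction:
    """Predicted gradient retention time for one descriptor pair."""
    return Prediction(t_r_pred=model.predict(d.log_sum_k1, d.clogp))


def delta_rt(t_r_exp: float, t_r_pred: float) -> tuple[float, float]:
    """Signed (experimental - predicted) retention difference and |.|, min."""
    if not (math.isfinite(t_r_exp) and math.isfinite(t_r_pred)):
        raise ValueError("retention times must be finite")
    signed = t_r_exp - t_r_pred
    return signed, abs(signed)


def evaluate_test_set(
    model: QsrrModel,
    rows: Iterable[tuple[DescriptorPair, float]],
) -> tuple[list[Prediction], dict[str, float]]:
    """Apply a fitted model to held-out rows; no refitting.

    Returns per-row predictions with residuals, plus a summary with the
    mean and maximum absolute retention-time error (empty dict for empty
    input).
    """
    predictions: list[Prediction] = []
    for d, t_exp in rows:
        t_pred = model.predict(d.log_sum_k1, d.clogp)
        signed, mag = delta_rt(t_exp, t_pred)
        predictions.append(
            Prediction(t_r_pred=t_pred, delta_t_r=signed, abs_delta_t_r=mag)
        )
    if not predictions:
        return [], {}
    abs_err = np.array([p.abs_delta_t_r for p in predictions])
    signed_err = np.array([p.delta_t_r for p in predictions])
    summary = {
        "n": float(len(predictions)),
        "mean_abs_delta_t_r": float(abs_err.mean()),
        "max_abs_delta_t_r": float(abs_err.max()),
        "mean_delta_t_r": float(signed_err.mean()),
    }
    return predictions, summary


def save_model(
    model: QsrrModel,
    path: str | Path,
    stats: FitStatistics | None = None,
    provenance: str | None = None,
) -> None:
    """Serialize a model (and optional fit statistics) as key=value text."""
    lines = [f"{name}={getattr(model, name)!r}" for name in _COEF_NAMES]
    if stats is not None:
        lines += [
            f"n={stats.n}",
            f"R={stats.R!r}",
            f"s={stats.s!r}",
            f"F={stats.F!r}",
            f"p_overall={stats.p_overall!r}",
        ]
        for name in _COEF_NAMES:
            lines.append(f"p_{name}={stats.p_coef[name]!r}")
            lines.append(f"se_{name}={stats.se_coef[name]!r}")
    if provenance:
        lines.append(f"calibration={provenance}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> QsrrModel:
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            key, val = line.split("=", 1)
            values[key.strip()] = val.strip()
    try:
        return QsrrModel(*(float(values[name]) for name in _COEF_NAMES))
    except KeyError as exc:
        raise ValueError(f"{path}: missing coefficient {exc}") from exc


def predictions_frame(predictions: Sequence[Prediction]) -> pd.DataFrame:
    """Tabulate predictions as a DataFrame (helper for reports and I/O)."""
    return pd.DataFrame(
        {
            "t_r_pred": [p.t_r_pred for p in predictions],
            "delta_t_r": [p.delta_t_r for p in predictions],
            "abs_delta_t_r": [p.abs_delta_t_r for p in predictions],
        }
    )
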