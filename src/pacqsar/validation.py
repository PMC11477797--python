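"""Model validation statistics: fit, simulated external validation, and
leave-one-out cross-validation.

Conventions (stated wherever outputs appear):

* residual e_i = observed - predicted;
* R² is the squared Pearson correlation of observed vs predicted, while
  Q² = 1 - SSE/SST — identical for an in-sample OLS fit, but they diverge on
  external data, which is why a test set can print e.g. R² 0.93 next to
  Q² 0.92;
* MPE / MNE are the extreme positive / negative residuals (signed extremes,
  not means); a config switch gives the mean-of-signs variant instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .modelbuild import QsarDataset, DatasetError, design_matrix


@dataclass
class ValidationReport:
    """Fit statistics in the layout of the published summary tables."""

    n: int
    r2: float
    q2: float
    rmse: float
    bias: float
    mae: float
    mpe: float
    mne: float
    extras: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k.upper() if k in ("n",) else k: v for k, v in asdict(self).items()}
        extras = d.pop("extras")
        d.update(extras)
        return d

    def table_row(self) -> dict:
        """Fixed-column row mirroring the published table layout."""
        return {
            "N": self.n, "R2": round(self.r2, 4), "Q2": round(self.q2, 4),
            "RMSE": round(self.rmse, 4), "BIAS": round(self.bias, 4),
            "MAE": round(self.mae, 4), "MPE": round(self.mpe, 4),
            "MNE": round(self.mne, 4),
        }


def fit_stats(
    y_obs: np.ndarray, y_pred: np.ndarray, error_convention: str = "extremes"
) -> ValidationReport:
    """R², Q², RMSE, BIAS, MAE, MPE, MNE for an (observed, predicted) pair."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1 or len(y_obs) < 2:
        raise ValueError("y_obs and y_pred must be equal-length vectors (n >= 2)")
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero variance in y_obs: R² and Q² are undefined")
    e = y_obs - y_pred
    sse = float(e @ e)
    if np.allclose(y_pred, y_pred[0]):
        r2 = 0.0  # constant predictions carry no correlation
    else:
        r2 = float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)
    if error_convention == "extremes":
        mpe, mne = float(e.max()), float(e.min())
    elif error_convention == "signed_means":
        pos, neg = e[e > 0], e[e < 0]
        mpe = float(pos.mean()) if pos.size else 0.0
        mne = float(neg.mean()) if neg.size else 0.0
    else:
        raise ValueError(f"unknown error convention {error_convention!r}")
    return ValidationReport(
        n=len(y_obs),
        r2=r2,
        q2=1.0 - sse / sst,
        rmse=float(np.sqrt(sse / len(e))),
        bias=float(e.mean()),
        mae=float(np.abs(e).mean()),
        mpe=mpe,
        mne=mne,
    )


@dataclass(frozen=True)
class ExternalStats:
    q2_f1: float
    q2_f2: float
    q2_f3: float
    ccc: float

    def to_dict(self) -> dict:
        return {"Q2_F1": self.q2_f1, "Q2_F2": self.q2_f2,
                "Q2_F3": self.q2_f3, "CCC": self.ccc}


def external_stats(
    y_train: np.ndarray, y_test_obs: np.ndarray, y_test_pred: np.ndarray
) -> ExternalStats:
    """External predictivity metrics Q²F1, Q²F2, Q²F3 and Lin's CCC.

    The three Q²F variants differ only in the reference variance: F1 centres
    the test responses on the *training* mean, F2 on the test mean, and F3
    compares per-compound mean squared errors against the training variance.
    CCC uses 1/n moments throughout.
    """
    y_train = np.asarray(y_train, dtype=float)
    o = np.asarray(y_test_obs, dtype=float)
    p = np.asarray(y_test_pred, dtype=float)
    if len(o) < 2 or len(y_train) < 2:
        raise ValueError("need at least 2 training and 2 test compounds")
    e = o - p
    sse = float(e @ e)
    den_f1 = float(np.sum((o - y_train.mean()) ** 2))
    den_f2 = float(np.sum((o - o.mean()) ** 2))
    den_f3 = float(np.sum((y_train - y_train.mean()) ** 2)) / len(y_train)
    for label, den in (("Q2_F1", den_f1), ("Q2_F2", den_f2), ("Q2_F3", den_f3)):
        if den == 0:
            raise ValueError(f"zero denominator for {label}")
    s_o = float(np.mean((o - o.mean()) ** 2))
    s_p = float(np.mean((p - p.mean()) ** 2))
    s_op = float(np.mean((o - o.mean()) * (p - p.mean())))
    ccc_den = s_o + s_p + (o.mean() - p.mean()) ** 2
    if ccc_den == 0:
        raise ValueError("zero denominator for CCC")
    return ExternalStats(
        q2_f1=1.0 - sse / den_f1,
        q2_f2=1.0 - sse / den_f2,
        q2_f3=1.0 - (sse / len(o)) / den_f3,
        ccc=float(2.0 * s_op / ccc_den),
    )


def loo_cv(
    data: QsarDataset, descriptors: list[str] | None = None
) -> tuple[float, float, np.ndarray]:
    """Leave-one-out cross-validation of the OLS fit.

    Uses the hat-matrix shortcut e_loo,i = e_i / (1 - h_i), algebraically
    identical to n explicit refits (and verified against them in the test
    suite).  Returns (Q²CV, RMSECV, per-compound LOO predictions) with
    Q²CV = 1 - PRESS/SST and RMSECV = sqrt(PRESS/n).
    """
    X = data.X if descriptors is None else data.X[list(descriptors)]
    n, p = len(X), X.shape[1]
    if n <= p + 2:
        raise DatasetError(f"need n > p + 2 for leave-one-out (n={n}, p={p})")
    Xd = design_matrix(X)
    y = data.y
    XtX = Xd.T @ Xd
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise DatasetError("rank-deficient design in leave-one-out")
    beta = np.linalg.solve(XtX, Xd.T @ y)
    h = np.einsum("ij,jk,ik->i", Xd, np.linalg.inv(XtX), Xd)
    if np.any(h >= 1.0 - 1e-12):
        raise DatasetError("a leave-one-out design is rank-deficient (leverage 1)")
    e = y - Xd @ beta
    e_loo = e / (1.0 - h)
    press = float(e_loo @ e_loo)
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sst, float(np.sqrt(press / n)), y - e_loo
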