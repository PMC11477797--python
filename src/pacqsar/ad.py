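"""Applicability-domain analysis: leverages, the h* warning threshold,
standardized residuals and the Williams-plot classification.

A prediction is trusted only inside the training data's descriptor-space
region.  Leverage h = x'(X'X)^{-1}x (intercept included) measures distance
from the training centroid in descriptor space; compounds with h above
h* = 3(p+1)/n are structural outliers (extrapolation), while training
compounds with |standardized residual| > 3 are response outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modelbuild import QsarDataset, DatasetError, design_matrix
from .models import LinearModel

SR_CUTOFF = 3.0


def leverage_threshold(n: int, p: int) -> float:
    """Warning leverage h* = 3(p + 1)/n."""
    if n <= p + 1:
        raise DatasetError(f"need n > p + 1 for a meaningful threshold (n={n}, p={p})")
    return 3.0 * (p + 1) / n


def leverage(X_train: np.ndarray | pd.DataFrame, x_query: np.ndarray) -> float:
    """Leverage of a query point against a training descriptor matrix.

    Both are in raw descriptor space; an intercept column is prepended
    internally, so the centroid of a one-descriptor design has h = 1/n.
    """
    Xd = design_matrix(pd.DataFrame(np.asarray(X_train, dtype=float)))
    XtX = Xd.T @ Xd
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise DatasetError("singular training design in leverage computation")
    xq = np.concatenate([[1.0], np.asarray(x_query, dtype=float)])
    return float(xq @ np.linalg.solve(XtX, xq))


def self_leverages(X_train: pd.DataFrame) -> np.ndarray:
    """Diagonal of the hat matrix for the training design (sums to p + 1)."""
    Xd = design_matrix(X_train)
    XtX = Xd.T @ Xd
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise DatasetError("singular training design")
    return np.einsum("ij,jk,ik->i", Xd, np.linalg.inv(XtX), Xd)


@dataclass
class AdReport:
    """Williams-plot table: leverage, standardized residual and class per compound.

    ``sr`` is NaN for query compounds (standardized residuals are defined for
    training compounds only) and for exact-interpolation points (h = 1).
    Classes are ``in_domain``, ``structural_outlier`` (h > h*),
    ``response_outlier`` (|SR| > 3) and ``both``.
    """

    table: pd.DataFrame  # columns: id, set, h, sr, ad_class
    h_star: float
    s: float             # residual standard error of the training fit

    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["ad_class"] != "in_domain"]


def _classify(h: float, sr: float, h_star: float) -> str:
    structural = h > h_star
    response = np.isfinite(sr) and abs(sr) > SR_CUTOFF
    if structural and response:
        return "both"
    if structural:
        return "structural_outlier"
    if response:
        return "response_outlier"
    return "in_domain"


def williams(
    model: LinearModel,
    train: QsarDataset,
    query: QsarDataset | None = None,
    studentize: bool = True,
) -> AdReport:
    """Williams-plot analysis of a model over its training set (plus queries).

    Residuals use the given model's predictions (e = observed - predicted);
    s² = SSE/(n - p - 1).  With ``studentize`` (default) SR_i is internally
    studentized, e_i / (s * sqrt(1 - h_i)); otherwise the raw e_i / s variant
    is used.
    """
    cols = model.descriptor_names
    missing = [c for c in cols if c not in train.X.columns]
    if missing:
        raise DatasetError(f"training data lacks model descriptors: {missing}")
    Xt = train.X[cols]
    n, p = len(Xt), len(cols)
    h_star = leverage_threshold(n, p)
    h_train = self_leverages(Xt)
    preds = np.array([model.predict(row) for row in Xt.to_dict("records")])
    e = train.y - preds
    dof = n - p - 1
    if dof < 1:
        raise DatasetError("no residual degrees of freedom for standardization")
    s = float(np.sqrt(e @ e / dof))
    # an (essentially) exact fit has no residual scale: all SR are 0, not 0/0
    s_negligible = s <= 1e-10 * (np.abs(train.y).max() + 1.0)
    rows = []
    for i, cid in enumerate(train.ids):
        h_i = float(h_train[i])
        if 1.0 - h_i < 1e-12:
            sr = np.nan  # exact interpolation point: SR undefined
        elif s_negligible:
            sr = 0.0
        elif studentize:
            sr = float(e[i] / (s * np.sqrt(1.0 - h_i)))
        else:
            sr = float(e[i] / s)
        rows.append(
            {"id": cid, "set": "train", "h": h_i, "sr": sr,
             "ad_class": _classify(h_i, sr, h_star)}
        )
    if query is not None:
        missing = [c for c in cols if c not in query.X.columns]
        if missing:
            raise DatasetError(f"query data lacks model descriptors: {missing}")
        for i, cid in enumerate(query.ids):
            h_i = leverage(Xt.to_numpy(), query.X[cols].iloc[i].to_numpy())
            rows.append(
                {"id": cid, "set": "query", "h": h_i, "sr": np.nan,
                 "ad_class": _classify(h_i, np.nan, h_star)}
            )
    return AdReport(table=pd.DataFrame(rows), h_star=h_star, s=s)


def williams_plot(report: AdReport, path: str, title: str = "Williams plot") -> None:
    """Leverage vs standardized residual with h* and ±3 guide lines (vector output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for subset, marker, color in (("train", "o", "tab:blue"), ("query", "s", "tab:red")):
        sub = report.table[report.table["set"] == subset]
        if sub.empty:
            continue
        sr = sub["sr"].fillna(0.0)
        ax.scatter(sub["h"], sr, marker=marker, label=subset,
                   color=color, alpha=0.75, edgecolor="k", linewidth=0.3)
    ax.axvline(report.h_star, linestyle="--", color="gray",
               label=f"h* = {report.h_star:.2f}")
    for yline in (SR_CUTOFF, -SR_CUTOFF):
        ax.axhline(yline, linestyle=":", color="gray")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
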