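"""Multiple-linear-regression model building: OLS fits, forward stepwise
descriptor selection, and train/test splitting.

The regression machinery is written against the normal equations directly
(via a QR solve) rather than wrapping a statistics package: the module's
contract includes exact agreement with a brute-force (X'X)^{-1}X'y oracle
and hat-matrix identities that downstream validation and applicability-domain
code relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .models import LinearModel, ModelError


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class QsarDataset:
    """Compound ids, descriptor matrix, response vector, optional split labels."""

    ids: tuple[str, ...]
    X: pd.DataFrame          # n x p, column names = descriptor names
    y: np.ndarray            # length n
    split: tuple[str, ...] | None = None  # per-row "train" / "test"

    def __post_init__(self):
        n = len(self.ids)
        if len(self.X) != n or len(self.y) != n:
            raise DatasetError("ids, X and y must have equal length")
        if self.X.isna().any().any() or np.isnan(self.y).any():
            raise DatasetError("missing values in X or y are not allowed")
        if self.split is not None and len(self.split) != n:
            raise DatasetError("split labels must cover every row")
        if self.split is not None:
            bad = set(self.split) - {"train", "test"}
            if bad:
                raise DatasetError(f"unknown split labels: {sorted(bad)}")
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, mask: np.ndarray) -> "QsarDataset":
        idx = np.nonzero(mask)[0]
        return QsarDataset(
            ids=tuple(self.ids[i] for i in idx),
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            split=None,
        )

    def train_test(self) -> tuple["QsarDataset", "QsarDataset"]:
        if self.split is None:
            raise DatasetError("dataset has no split labels")
        labels = np.array(self.split)
        return self.subset(labels == "train"), self.subset(labels == "test")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, response: str, id_col: str = "id",
        split_col: str | None = None,
    ) -> "QsarDataset":
        """Build from a flat table (id column, descriptor columns, response)."""
        drop = [id_col, response] + ([split_col] if split_col else [])
        X = df.drop(columns=[c for c in drop if c in df.columns])
        return cls(
            ids=tuple(df[id_col].astype(str)),
            X=X.reset_index(drop=True),
            y=df[response].to_numpy(dtype=float),
            split=tuple(df[split_col]) if split_col and split_col in df else None,
        )


def design_matrix(X: pd.DataFrame) -> np.ndarray:
    """Descriptor matrix with a prepended intercept column."""
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def fit_mlr(data: QsarDataset, response_name: str = "y") -> LinearModel:
    """Ordinary least squares with intercept.

    Raises on a rank-deficient design, naming the collinear columns (found
    by pivoted QR on the centred descriptor matrix).
    """
    if data.n <= data.p + 1:
        raise DatasetError(
            f"need n > p + 1 to fit (n={data.n}, p={data.p})"
        )
    Xd = design_matrix(data.X)
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        from scipy.linalg import qr

        _, R, piv = qr(Xd, pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xd.shape) * np.finfo(float).eps
        dropped = [piv[k] for k in range(len(diag)) if diag[k] <= tol] + list(
            piv[len(diag):]
        )
        names = ["<intercept>"] + list(data.X.columns)
        bad = sorted(names[j] for j in dropped)
        raise ModelError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xd, data.y, rcond=None)
    return LinearModel(
        name="mlr_fit",
        intercept=float(beta[0]),
        terms=tuple(zip(data.X.columns, map(float, beta[1:]))),
        response=response_name,
        n_train=data.n,
    )


def _rss(Xd: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    r = y - Xd @ beta
    return float(r @ r)


def select_descriptors(
    data: QsarDataset,
    max_terms: int,
    seed: int = 0,
    alpha: float = 0.05,
) -> LinearModel:
    """Forward stepwise selection by partial F-test, capped at ``max_terms``.

    At each step every remaining descriptor is scored by its F-to-enter; the
    candidate with the largest F (equivalently, the largest adjusted-R² gain)
    enters if its p-value is below ``alpha``.  Ties break lexicographically
    on the descriptor name, making the procedure deterministic.  ``seed`` is
    accepted for interface symmetry with the other builders; the algorithm
    itself is deterministic.
    """
    if max_terms < 1:
        raise DatasetError("max_terms must be >= 1")
    if data.p < max_terms:
        raise DatasetError(f"only {data.p} descriptors available for max_terms={max_terms}")
    n = data.n
    y = data.y
    selected: list[str] = []
    remaining = list(data.X.columns)
    rss_cur = float(np.sum((y - y.mean()) ** 2))
    while len(selected) < max_terms and remaining:
        best = None  # (F, name, rss_new)
        df_resid = n - (len(selected) + 2)  # intercept + selected + candidate
        if df_resid < 1:
            break
        for name in sorted(remaining):
            Xd = design_matrix(data.X[selected + [name]])
            rss_new = _rss(Xd, y)
            if rss_new >= rss_cur:
                f_stat = 0.0
            else:
                f_stat = (rss_cur - rss_new) / (rss_new / df_resid)
            if best is None or f_stat > best[0] + 1e-12:
                best = (f_stat, name, rss_new)
        f_stat, name, rss_new = best
        p_val = stats.f.sf(f_stat, 1, df_resid) if f_stat > 0 else 1.0
        if p_val > alpha:
            break
        selected.append(name)
        remaining.remove(name)
        rss_cur = rss_new
    if not selected:
        raise DatasetError(
            f"no descriptor passed the F-to-enter threshold (alpha={alpha})"
        )
    sub = QsarDataset(data.ids, data.X[selected], data.y)
    model = fit_mlr(sub)
    return replace(model, name="stepwise_mlr")


def split_dataset(
    data: QsarDataset,
    fraction_train: float,
    seed: int = 0,
    strategy: str = "random",
) -> QsarDataset:
    """Assign train/test labels; |train| = round(fraction_train * n).

    ``random`` shuffles with the seed; ``sorted_response_stride`` ranks
    compounds by response and sends every k-th one to the test set — a common
    QSAR practice that keeps the test set spread across the response range.
    """
    if not 0 < fraction_train < 1:
        raise DatasetError("fraction_train must be in (0, 1)")
    n = data.n
    n_train = int(round(fraction_train * n))
    n_test = n - n_train
    if n_train < 1 or n_test < 1:
        raise DatasetError(
            f"fraction {fraction_train} yields an empty train or test set (n={n})"
        )
    labels = np.array(["train"] * n, dtype=object)
    if strategy == "random":
        rng = np.random.default_rng(seed)
        labels[rng.permutation(n)[:n_test]] = "test"
    elif strategy == "sorted_response_stride":
        order = np.argsort(data.y, kind="stable")
        # evenly spaced picks over the ranked responses
        picks = (
            np.unique(np.linspace(0, n - 1, num=n_test).round().astype(int))
            if n_test > 1
            else np.array([n // 2])
        )
        labels[order[picks]] = "test"
    else:
        raise DatasetError(f"unknown split strategy {strategy!r}")
    return QsarDataset(data.ids, data.X, data.y, split=tuple(labels))
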