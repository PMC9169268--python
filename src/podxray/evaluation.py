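"""Dataset splitting, regression metrics, predictor comparison, derived traits.

The dataset is split 90:10 into calibration and test sets (identical for both
predictors), and calibration is further split 80:20 into CNN training and
validation.  Prediction quality per predictor and trait is summarized by six
statistics of the prediction-vs-truth relation: Pearson r, R^2 (= r^2), MSE,
MAE, and the OLS slope and intercept of prediction regressed on ground truth.
A PCA over observed and predicted columns compares the predictors globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "split_dataset",
    "compute_metrics",
    "pca_compare",
    "shelling_percentage",
]


@dataclass(frozen=True)
class SplitPlan:
    """Deterministic partition of pod ids into calibration/test and train/validation."""

    test: tuple[str, ...]
    train: tuple[str, ...]
    validation: tuple[str, ...]
    seed: int
    fractions: tuple[float, float]  # (test fraction, validation-within-calibration)

    @property
    def calibration(self) -> tuple[str, ...]:
        return self.train + self.validation

    def assignment(self, pod_id: str) -> tuple[str, str | None]:
        if pod_id in set(self.test):
            return "test", None
        if pod_id in set(self.train):
            return "calibration", "train"
        if pod_id in set(self.validation):
            return "calibration", "validation"
        raise KeyError(pod_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pod_id": p, "split": "test", "subsplit": "", "seed": self.seed}
            for p in self.test
        ]
        rows += [
            {"pod_id": p, "split": "calibration", "subsplit": "train", "seed": self.seed}
            for p in self.train
        ]
        rows += [
            {"pod_id": p, "split": "calibration", "subsplit": "validation", "seed": self.seed}
            for p in self.validation
        ]
        return pd.DataFrame(rows)


def split_dataset(
    pod_ids: list[str],
    test_fraction: float = 0.10,
    validation_fraction: float = 0.20,
    seed: int = 0,
) -> SplitPlan:
    """Seeded uniform shuffle then slice: |test| = round(test_fraction * N),
    and within calibration |validation| = round(validation_fraction * n_cal).
    """
    for f in (test_fraction, validation_fraction):
        if not 0.0 < f < 1.0:
            raise ValueError(f"fraction {f} outside (0, 1)")
    if len(pod_ids) < 10:
        raise ValueError("need at least 10 pods to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pod_ids))
    shuffled = [pod_ids[i] for i in order]
    n_test = int(round(test_fraction * len(pod_ids)))
    test = shuffled[:n_test]
    calibration = shuffled[n_test:]
    n_val = int(round(validation_fraction * len(calibration)))
    validation = calibration[:n_val]
    train = calibration[n_val:]
    return SplitPlan(
        test=tuple(test),
        train=tuple(train),
        validation=tuple(validation),
        seed=seed,
        fractions=(test_fraction, validation_fraction),
    )


@dataclass
class MetricsReport:
    """Six regression statistics for one predictor x trait x split."""

    predictor: str
    trait: str
    split: str
    r: float
    r2: float
    mse: float
    mae: float
    slope: float
    intercept: float
    n: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "trait": self.trait,
            "split": self.split,
            "r": self.r,
            "r2": self.r2,
            "mse": self.mse,
            "mae": self.mae,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
        }


def compute_metrics(
    predictions: np.ndarray,
    ground_truth: np.ndarray,
    predictor: str = "",
    trait: str = "",
    split: str = "",
) -> MetricsReport:
    """Prediction-vs-truth statistics.

    The slope and intercept come from the OLS regression of prediction on
    ground truth; R^2 is reported as the square of the Pearson correlation (the
    goodness of that simple linear fit).  The coefficient of determination of
    the 1:1 line, 1 - SSE/SST, is kept in ``extras`` for reference.  MSE and MAE
    are computed on the raw residuals prediction - truth.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(ground_truth, dtype=float)
    if p.size != y.size or p.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in predictions or ground truth")
    if np.ptp(p) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(y, p).statistic)
    res = stats.linregress(y, p)
    err = p - y
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_identity = float(1.0 - np.sum(err**2) / sst)
    return MetricsReport(
        predictor=predictor,
        trait=trait,
        split=split,
        r=r,
        r2=r * r,
        mse=float(np.mean(err**2)),
        mae=float(np.mean(np.abs(err))),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(p.size),
        extras={"r2_one_to_one": r2_identity},
    )


def pca_compare(
    table: pd.DataFrame, standardize: bool = True
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """PCA over observed and predicted trait columns.

    Columns are centered (and by default scaled to unit variance); returns
    (explained_variance_ratio, loadings as a components x columns frame, scores).
    A well-calibrated pair of predictors concentrates nearly all variance on
    the first component, with the predictor disagreements on the second.
    """
    x = table.to_numpy(dtype=float)
    if x.shape[1] < 3 or x.shape[0] < 3:
        raise ValueError("PCA comparison needs >= 3 columns and >= 3 rows")
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(table.columns, sd) if s == 0]
        raise ValueError(f"constant column(s): {bad}")
    z = x - x.mean(axis=0)
    if standardize:
        z = z / sd
    pca = PCA(n_components=min(z.shape))
    scores = pca.fit_transform(z)
    loadings = pd.DataFrame(
        pca.components_,
        columns=list(table.columns),
        index=[f"PC{i + 1}" for i in range(pca.components_.shape[0])],
    )
    return pca.explained_variance_ratio_, loadings, scores


def plot_pca_biplot(table: pd.DataFrame, path, standardize: bool = True) -> None:
    """Save a PC1/PC2 biplot of observed vs predicted traits (SVG/PNG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    evr, loadings, scores = pca_compare(table, standardize=standardize)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(scores[:, 0], scores[:, 1], s=8, alpha=0.4, color="gray")
    scale = np.abs(scores[:, :2]).max() * 0.9
    for col in loadings.columns:
        vx, vy = loadings.loc["PC1", col], loadings.loc["PC2", col]
        ax.annotate(
            col,
            xy=(vx * scale, vy * scale),
            xytext=(0, 0),
            textcoords="data",
            arrowprops=dict(arrowstyle="<-", color="tab:red"),
            color="tab:red",
            fontsize=8,
        )
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def shelling_percentage(kernel_g: float, total_pod_g: float) -> float:
    """Shelling percentage s = 100 * Wk / Wp, the kernel share of total pod mass."""
    if total_pod_g <= 0:
        raise ValueError("total pod weight must be positive")
    if kernel_g < 0 or kernel_g > total_pod_g:
        raise ValueError("kernel weight must lie in [0, total pod weight]")
    return 100.0 * kernel_g / total_pod_g


def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    """Tabulate metric reports (metric x predictor x trait x split layout)."""
    return pd.DataFrame([r.to_dict() for r in reports])
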