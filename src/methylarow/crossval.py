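"""4-fold cross-validation series, regularization sweep, and model selection.

Cell lines are partitioned into four fixed groups A-D. The four learning
series are: Series-1 trains on B,C,D and tests on A; Series-2 on C,D,A / B;
Series-3 on D,A,B / C; Series-4 on A,B,C / D. For each series and each
regularization weight in the grid, the model is trained for a fixed number
of epochs (per-epoch random sample order) and assessed on the training and
test folds at every checkpoint epoch.

The optimal ``(epoch, r)`` is the cell whose *test* macro F-score, averaged
over the four series, is highest (ties: higher average train macro F, then
smaller epoch, then smaller r). Pooled ("mixed") evaluation concatenates
the four series' test-fold predictions at the selected cell, so every
cohort sample contributes exactly once to one confusion matrix.

Reproducibility: each (series, r) cell derives its own random stream from
the master seed via ``np.random.SeedSequence([master_seed, series_id,
r_index])``, so cells are independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .arow import MulticlassArowModel
from .io import CLASSES, FOLD_GROUPS, BetaMatrix
from .metrics import ConfusionMatrix, MacroMetrics, confusion, macro_metrics

logger = logging.getLogger(__name__)

#: The six regularization weight values of the default sweep.
DEFAULT_REG_WEIGHTS: tuple[float, ...] = (0.10, 0.25, 0.50, 0.90, 1.00, 1.10)


@dataclass(frozen=True)
class FoldSeries:
    series_id: int
    train_groups: tuple[str, ...]
    test_group: str


def make_fold_series() -> list[FoldSeries]:
    """The four fixed train/test series over groups A-D."""
    groups = list(FOLD_GROUPS)
    out = []
    for i in range(4):
        test = groups[i]
        train = tuple(groups[(i + k) % 4] for k in (1, 2, 3))
        out.append(FoldSeries(series_id=i + 1, train_groups=train, test_group=test))
    return out


def assign_fold_groups(sheet: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Assign fold groups A-D, stratified by cell type.

    Samples of each cell type are shuffled and dealt round-robin over the
    four groups, so per-class group sizes differ by at most one.
    """
    sheet = sheet.copy()
    sheet["fold_group"] = ""
    for cell_type in sheet["cell_type"].unique():
        idx = sheet.index[sheet["cell_type"] == cell_type].to_numpy()
        idx = idx[rng.permutation(len(idx))]
        for k, i in enumerate(idx):
            sheet.loc[i, "fold_group"] = FOLD_GROUPS[k % 4]
    return sheet


@dataclass(frozen=True)
class SweepConfig:
    reg_weights: tuple[float, ...] = DEFAULT_REG_WEIGHTS
    epochs: int = 300
    checkpoint_every: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.reg_weights or any(r <= 0 for r in self.reg_weights):
            raise ValueError("reg_weights must be non-empty and positive")
        if self.epochs % self.checkpoint_every != 0:
            raise ValueError("epochs must be divisible by checkpoint_every")

    @property
    def n_checkpoints(self) -> int:
        return self.epochs // self.checkpoint_every

    @property
    def n_records(self) -> int:
        return 4 * len(self.reg_weights) * self.n_checkpoints

    @property
    def total_epochs(self) -> int:
        return 4 * len(self.reg_weights) * self.epochs


@dataclass
class CheckpointRecord:
    series_id: int
    r: float
    epoch: int
    train_metrics: MacroMetrics
    test_metrics: MacroMetrics
    test_sample_ids: list[str]
    test_true: list[str]
    test_pred: list[str]
    model: MulticlassArowModel | None = None


def _labels_of(sheet: pd.DataFrame) -> dict[str, str]:
    return dict(zip(sheet["sample_id"], sheet["cell_type"]))


def run_sweep(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    config: SweepConfig,
    keep_models: bool = True,
    classes: Sequence[str] = CLASSES,
) -> list[CheckpointRecord]:
    """Train the full (series x r) grid and record metrics at checkpoints.

    Returns ``4 * len(reg_weights) * (epochs / checkpoint_every)`` records.
    With ``keep_models`` each record carries a frozen copy of the model at
    that checkpoint (needed later for weight mining of the selected epoch).
    """
    labels = _labels_of(sheet)
    groups = dict(zip(sheet["sample_id"], sheet["fold_group"]))
    missing = [s for s in beta.sample_ids if s not in labels]
    if missing:
        raise KeyError(f"samples without sheet rows: {missing[:5]}")
    X = np.nan_to_num(beta.data.to_numpy())
    sample_ids = beta.sample_ids
    records: list[CheckpointRecord] = []
    for series in make_fold_series():
        train_cols = [j for j, s in enumerate(sample_ids) if groups[s] in series.train_groups]
        test_cols = [j for j, s in enumerate(sample_ids) if groups[s] == series.test_group]
        if not test_cols:
            raise ValueError(f"fold group {series.test_group!r} has no test samples")
        X_train, X_test = X[:, train_cols], X[:, test_cols]
        y_train = [labels[sample_ids[j]] for j in train_cols]
        y_test = [labels[sample_ids[j]] for j in test_cols]
        test_ids = [sample_ids[j] for j in test_cols]
        for r_index, r in enumerate(config.reg_weights):
            ss = np.random.SeedSequence([config.master_seed, series.series_id, r_index])
            rng = np.random.default_rng(ss)
            model = MulticlassArowModel(
                beta.probe_ids, classes=classes, r=r,
                rng_seed=int(ss.generate_state(1)[0] % (2**31)),
            )
            for epoch in range(1, config.epochs + 1):
                model.train_epoch(X_train, y_train, rng)
                if epoch % config.checkpoint_every == 0:
                    pred_train = model.predict_matrix(X_train)
                    pred_test = model.predict_matrix(X_test)
                    records.append(
                        CheckpointRecord(
                            series_id=series.series_id,
                            r=r,
                            epoch=epoch,
                            train_metrics=macro_metrics(
                                confusion(y_train, pred_train, classes)
                            ),
                            test_metrics=macro_metrics(
                                confusion(y_test, pred_test, classes)
                            ),
                            test_sample_ids=test_ids,
                            test_true=y_test,
                            test_pred=pred_test,
                            model=model.copy() if keep_models else None,
                        )
                    )
            logger.info("series %d, r=%.2f: %d epochs done", series.series_id, r, config.epochs)
    return records


def records_table(records: Sequence[CheckpointRecord]) -> pd.DataFrame:
    """Flatten checkpoint records into the sweep-results table."""
    rows = []
    for rec in records:
        for split, mm in (("train", rec.train_metrics), ("test", rec.test_metrics)):
            rows.append(
                {
                    "series": rec.series_id,
                    "r": rec.r,
                    "epoch": rec.epoch,
                    "split": split,
                    "precision_macro": mm.precision_macro,
                    "recall_macro": mm.recall_macro,
                    "f_macro": mm.f_macro,
                    "accuracy": mm.accuracy,
                }
            )
    return pd.DataFrame(rows)


def select_optimal(records: Sequence[CheckpointRecord]) -> tuple[int, float]:
    """The (epoch, r) with the highest series-averaged test macro F-score.

    Ties break by higher average train macro F, then smaller epoch, then
    smaller r. The result is invariant to record order.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        {
            "epoch": [rec.epoch for rec in records],
            "r": [rec.r for rec in records],
            "test_f": [rec.test_metrics.f_macro for rec in records],
            "train_f": [rec.train_metrics.f_macro for rec in records],
        }
    )
    agg = df.groupby(["epoch", "r"], as_index=False).mean()
    agg = agg.sort_values(
        by=["test_f", "train_f", "epoch", "r"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    best = agg.iloc[0]
    return int(best["epoch"]), float(best["r"])


def records_at(
    records: Sequence[CheckpointRecord], epoch: int, r: float
) -> list[CheckpointRecord]:
    sel = [rec for rec in records if rec.epoch == epoch and np.isclose(rec.r, r)]
    sel.sort(key=lambda rec: rec.series_id)
    if len(sel) != 4:
        raise ValueError(f"expected 4 series records at epoch={epoch}, r={r}, got {len(sel)}")
    return sel


def pooled_confusion(
    records: Sequence[CheckpointRecord],
    epoch: int,
    r: float,
    classes: Sequence[str] = CLASSES,
) -> ConfusionMatrix:
    """Confusion matrix pooling the four series' test folds at (epoch, r)."""
    sel = records_at(records, epoch, r)
    true: list[str] = []
    pred: list[str] = []
    for rec in sel:
        true.extend(rec.test_true)
        pred.extend(rec.test_pred)
    return confusion(true, pred, classes)
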