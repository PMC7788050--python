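"""Model/Results facade over the cross-validated AROW analysis.

``CellTypeArow`` bundles a filtered beta matrix with its sample sheet;
``fit()`` runs the 4-fold regularization sweep and returns a
``CellTypeArowResults`` carrying the checkpoint records, the selected
(epoch, r) cell, the four selected fold models, the pooled test confusion
matrix and its macro metrics. Weight mining and a text ``summary()`` hang
off the results object, in the style of statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import crossval, weights as weights_mod
from .arow import MulticlassArowModel
from .crossval import CheckpointRecord, SweepConfig
from .io import CLASSES, BetaMatrix, validate_sample_sheet
from .metrics import ConfusionMatrix, MacroMetrics, macro_metrics


class CellTypeArow:
    """Cell-type classification model over a methylation beta matrix.

    Parameters
    ----------
    beta : BetaMatrix
        Filtered, aligned probes x samples methylation rates.
    sample_sheet : DataFrame
        One row per sample with ``sample_id``, ``cell_type`` and
        ``fold_group`` columns.
    """

    def __init__(self, beta: BetaMatrix, sample_sheet: pd.DataFrame,
                 classes: Sequence[str] = CLASSES) -> None:
        validate_sample_sheet(sample_sheet)
        missing = set(beta.sample_ids) - set(sample_sheet["sample_id"])
        if missing:
            raise ValueError(f"samples without sheet rows: {sorted(missing)[:5]}")
        self.beta = beta
        self.sample_sheet = sample_sheet.reset_index(drop=True)
        self.classes = tuple(classes)

    @classmethod
    def from_files(cls, beta_path, sheet_path) -> "CellTypeArow":
        from .io import read_beta_matrix, read_sample_sheet

        return cls(read_beta_matrix(beta_path), read_sample_sheet(sheet_path))

    def fit(
        self,
        reg_weights: Sequence[float] = crossval.DEFAULT_REG_WEIGHTS,
        epochs: int = 300,
        checkpoint_every: int = 10,
        seed: int = 0,
    ) -> "CellTypeArowResults":
        """Run the full (series x r) sweep and select the optimal cell."""
        config = SweepConfig(
            reg_weights=tuple(reg_weights),
            epochs=epochs,
            checkpoint_every=checkpoint_every,
            master_seed=seed,
        )
        records = crossval.run_sweep(
            self.beta, self.sample_sheet, config, keep_models=True, classes=self.classes
        )
        return CellTypeArowResults(self, config, records)


class CellTypeArowResults:
    """Fit results: checkpoint records, selected models, pooled evaluation."""

    def __init__(self, model: CellTypeArow, config: SweepConfig,
                 records: list[CheckpointRecord]) -> None:
        self.model = model
        self.config = config
        self.records = records
        self.optimal_epoch, self.optimal_r = crossval.select_optimal(records)
        selected = crossval.records_at(records, self.optimal_epoch, self.optimal_r)
        self.selected_records = selected
        self.fold_models: dict[int, MulticlassArowModel] = {
            rec.series_id: rec.model for rec in selected if rec.model is not None
        }
        self.pooled_confusion: ConfusionMatrix = crossval.pooled_confusion(
            records, self.optimal_epoch, self.optimal_r, self.model.classes
        )
        self.pooled_metrics: MacroMetrics = macro_metrics(self.pooled_confusion)
        test_f = [rec.test_metrics.f_macro for rec in selected]
        self.best_mean_test_f_macro = float(np.mean(test_f))

    # -- reporting ----------------------------------------------------------

    def sweep_table(self) -> pd.DataFrame:
        return crossval.records_table(self.records)

    def summary(self) -> str:
        pct = self.pooled_metrics.as_percent()
        classes = self.model.classes
        lines = [
            "Cell-type AROW classification results",
            "=" * 53,
            f"samples: {len(self.model.beta.sample_ids)}   "
            f"probes: {len(self.model.beta.probe_ids)}",
            f"sweep: r in {tuple(self.config.reg_weights)}, "
            f"{self.config.epochs} epochs, checkpoint every {self.config.checkpoint_every}",
            f"total epochs trained: {self.config.total_epochs}   "
            f"checkpoint records: {len(self.records)}",
            f"selected model: epoch {self.optimal_epoch}, r = {self.optimal_r:.2f} "
            f"(mean test F-macro {100 * self.best_mean_test_f_macro:.2f}%)",
            "",
            "Pooled test confusion (rows true, columns predicted)",
            "-" * 53,
            "true\\pred  " + "".join(f"{c:>9}" for c in classes),
        ]
        for i, c in enumerate(classes):
            row = "".join(f"{int(v):>9}" for v in self.pooled_confusion.counts[i])
            lines.append(f"{c:<10}" + row)
        lines += [
            "-" * 53,
            "per-class precision: "
            + "  ".join(f"{c} {pct[f'precision_{c}']:.2f}%" for c in classes),
            "per-class recall:    "
            + "  ".join(f"{c} {pct[f'recall_{c}']:.2f}%" for c in classes),
            f"macro precision {pct['precision_macro']:.2f}%   "
            f"macro recall {pct['recall_macro']:.2f}%",
            f"macro F-score {pct['f_macro']:.2f}%   accuracy {pct['accuracy']:.2f}%",
        ]
        return "\n".join(lines)

    # -- weight mining ------------------------------------------------------

    def weight_tables(self, classes: Sequence[str] = ("ESC", "iPSC")) -> list[pd.DataFrame]:
        return [
            weights_mod.extract_weight_table(self.fold_models[sid], classes)
            for sid in sorted(self.fold_models)
        ]

    def high_weight_selections(
        self, k: int = 2000, classes: Sequence[str] = ("ESC", "iPSC")
    ) -> list[weights_mod.HighWeightSelection]:
        return [
            weights_mod.select_high_weight(
                weights_mod.extract_weight_table(self.fold_models[sid], classes),
                k=k, series_id=sid, class_order=classes,
            )
            for sid in sorted(self.fold_models)
        ]

    def signature(self, k: int = 2000) -> weights_mod.CommonSignature:
        """Cross-fold, cross-class high-weight signature at selection size k."""
        return weights_mod.common_sites(self.high_weight_selections(k=k))

    # -- plotting -----------------------------------------------------------

    def plot_sweep(self, ax=None):
        """Mean test macro F-score per epoch, one line per r value."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tbl = self.sweep_table()
        test = tbl[tbl["split"] == "test"]
        for r, grp in test.groupby("r"):
            curve = grp.groupby("epoch")["f_macro"].mean()
            ax.plot(curve.index, 100 * curve.values, label=f"r = {r:.2f}")
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean test F-macro (%)")
        ax.legend(fontsize="small")
        return ax
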