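"""Evaluation protocol: R^2 and NRMSE per trait, per cultivar, per model.

R^2 is the coefficient of determination against the 1:1 line,
``1 - SSE / SST`` (not a squared correlation).  NRMSE is the root mean square
error normalized by the mean of the observed values, in percent.  Reports are
laid out as the model x trait grid used to compare the CNN against the
shallow baselines (SVR, RF) and the depth linear models (LR-V, LR-PA, LR-H),
with an optional per-cultivar breakdown and a cross-season generalization
evaluation that never refits the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError

TRAITS = ("lfw", "ldw", "la")
MODEL_ORDER = ("CNN", "SVR", "RF", "LR-V", "LR-PA", "LR-H")

__all__ = ["r_squared", "nrmse", "EvalReport", "build_report",
           "generalization_eval", "TRAITS", "MODEL_ORDER"]


def _check_pair(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise DomainError("actual and predicted must be equal-length vectors")
    if len(a) < 2:
        raise DomainError("need at least 2 samples")
    return a, p


def r_squared(actual, predicted) -> float:
    """Coefficient of determination 1 - sum (a-p)^2 / sum (a-abar)^2."""
    a, p = _check_pair(actual, predicted)
    sst = float(np.sum((a - a.mean()) ** 2))
    if sst < 1e-15:
        raise DomainError("actual values are constant; R^2 undefined")
    return 1.0 - float(np.sum((a - p) ** 2)) / sst


def nrmse(actual, predicted) -> float:
    """Normalized RMSE in percent: 100 * RMSE / mean(actual).

    The normalization mode can matter when comparing across traits; mean
    normalization is used throughout this package.
    """
    a, p = _check_pair(actual, predicted)
    mean_a = float(a.mean())
    if mean_a <= 0:
        raise DomainError("mean of actual values must be positive")
    return 100.0 * float(np.sqrt(np.mean((a - p) ** 2))) / mean_a


@dataclass
class EvalReport:
    """Metric grid plus the predicted-vs-actual pairs behind it.

    ``rows``: one record per (model, trait, stratum) with r2, nrmse_pct, n.
    ``pairs``: long-format (model, trait, stratum-labels, actual, predicted).
    """

    rows: pd.DataFrame
    pairs: pd.DataFrame
    label: str = "test"

    def grid(self, metric: str = "r2") -> pd.DataFrame:
        """Model x trait pivot of one metric over the pooled stratum."""
        pooled = self.rows[self.rows["stratum"] == "all"]
        g = pooled.pivot(index="model", columns="trait", values=metric)
        order = [m for m in MODEL_ORDER if m in g.index]
        extra = [m for m in g.index if m not in MODEL_ORDER]
        return g.loc[order + extra, [t for t in TRAITS if t in g.columns]]

    def summary(self) -> str:
        r2g = self.grid("r2")
        ng = self.grid("nrmse_pct")
        lines = [f"Evaluation report ({self.label})", "=" * 54,
                 "R^2 (1:1 line)", r2g.round(4).to_string(), "",
                 "NRMSE (% of mean observed)", ng.round(2).to_string()]
        return "\n".join(lines)


def build_report(predictions: Mapping[str, pd.DataFrame],
                 truth: pd.DataFrame,
                 strata: Sequence[str] = ("all", "cultivar"),
                 label: str = "test") -> EvalReport:
    """Assemble the model x trait (x cultivar) metric grid.

    ``predictions`` maps model name to a frame indexed by sample id with one
    column per trait; ``truth`` is indexed by id with trait columns and a
    ``cultivar`` column.  Every model must predict every id in ``truth``.
    """
    if truth is None or len(truth) == 0:
        raise DomainError("empty truth table")
    traits = [t for t in TRAITS if t in truth.columns]
    if not traits:
        raise DomainError(f"truth table must contain trait columns {TRAITS}")
    rows = []
    pair_frames = []
    for model_name, pred in predictions.items():
        missing = truth.index.difference(pred.index)
        if len(missing):
            raise DomainError(
                f"model {model_name!r} lacks predictions for ids "
                f"{list(missing)[:5]}...")
        pred = pred.loc[truth.index]
        for trait in traits:
            a_all = truth[trait].to_numpy(dtype=float)
            p_all = pred[trait].to_numpy(dtype=float)
            groups: list[tuple[str, np.ndarray]] = []
            if "all" in strata:
                groups.append(("all", np.ones(len(truth), dtype=bool)))
            if "cultivar" in strata and "cultivar" in truth.columns:
                for cv in sorted(truth["cultivar"].unique()):
                    groups.append((str(cv),
                                   (truth["cultivar"] == cv).to_numpy()))
            for stratum, sel in groups:
                if sel.sum() < 2:
                    continue
                rows.append({
                    "model": model_name, "trait": trait, "stratum": stratum,
                    "r2": r_squared(a_all[sel], p_all[sel]),
                    "nrmse_pct": nrmse(a_all[sel], p_all[sel]),
                    "n": int(sel.sum()),
                })
            frame = pd.DataFrame({
                "id": truth.index, "model": model_name, "trait": trait,
                "actual": a_all, "predicted": p_all,
            })
            if "cultivar" in truth.columns:
                frame["cultivar"] = truth["cultivar"].to_numpy()
            pair_frames.append(frame)
    report = EvalReport(rows=pd.DataFrame(rows),
                        pairs=pd.concat(pair_frames, ignore_index=True),
                        label=label)
    _check_internal_consistency(report)
    return report


def _check_internal_consistency(report: EvalReport) -> None:
    """R^2 and NRMSE of each row must satisfy the identity
    R^2 = 1 - (NRMSE/100)^2 * mean(a)^2 / var(a), and pooled SSE must equal
    the sum of per-cultivar SSEs."""
    for _, row in report.rows.iterrows():
        sel = report.pairs[(report.pairs["model"] == row["model"])
                           & (report.pairs["trait"] == row["trait"])]
        if row["stratum"] != "all":
            sel = sel[sel["cultivar"] == row["stratum"]]
        a = sel["actual"].to_numpy()
        mean2 = a.mean() ** 2
        var = a.var()
        implied = 1.0 - (row["nrmse_pct"] / 100.0) ** 2 * mean2 / var
        if abs(implied - row["r2"]) > 1e-8 * max(1.0, abs(row["r2"])):
            raise DomainError("internal metric inconsistency in report")


def generalization_eval(results, new_images: np.ndarray,
                        new_truth: pd.DataFrame,
                        train_ids: Sequence[str] = (),
                        strata: Sequence[str] = ("all",)) -> EvalReport:
    """Evaluate a fitted CNN on a disjoint new-season sample set, no refitting.

    ``results`` is a fitted :class:`~canopytraits.cnn.CNNTraitResults`;
    ``new_truth`` is indexed by id with trait columns (row order matching
    ``new_images``).  Ids overlapping the training set are a domain error.
    """
    if new_truth is None or len(new_truth) == 0:
        raise DomainError("new-season sample set is empty")
    overlap = set(map(str, new_truth.index)) & set(map(str, train_ids))
    if overlap:
        raise DomainError(f"new-season ids overlap training set: "
                          f"{sorted(overlap)[:5]}")
    pred = results.predict(new_images)
    pred_df = pd.DataFrame(pred, index=new_truth.index, columns=list(TRAITS))
    return build_report({"CNN": pred_df}, new_truth, strata=strata,
                        label="cross-season")
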