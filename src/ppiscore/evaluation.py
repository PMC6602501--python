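"""Decoy-ranking evaluation and rate-based classification metrics.

Given per-target score tables of one native complex against its docking
decoys, this module computes the native's rank and percentile, top-k
counts across targets, and the rate-based classifier metrics (TPR/TNR/
FPR/FNR, accuracy at a given prevalence, balanced accuracy, and the
Matthews correlation coefficient computed directly from rates — the
appropriate variant when classes are heavily imbalanced, e.g. one native
per hundred decoys).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ParameterError

#: Score orderings: which direction means "more stable".
HIGHER_IS_BETTER = "higher"  # e.g. Z score
LOWER_IS_BETTER = "lower"  # e.g. energy-convention raw score


@dataclass
class DecoySetResult:
    """Rank of one native complex among its decoys."""

    target_id: str
    native_score: float
    decoy_scores: list[float]
    rank: int  # 1 = native beats every decoy
    percentile: float  # 100 = every decoy is strictly worse


@dataclass
class RateMetrics:
    tpr: float
    tnr: float
    fpr: float
    fnr: float
    accuracy: float
    balanced_accuracy: float
    mcc: float

    def to_dict(self) -> dict[str, float]:
        return {
            "tpr": self.tpr, "tnr": self.tnr, "fpr": self.fpr, "fnr": self.fnr,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
        }


def percentile_rank(
    native: float,
    decoys: list[float],
    better: str = HIGHER_IS_BETTER,
    target_id: str = "",
) -> DecoySetResult:
    """Rank a native score within its decoy set.

    rank = 1 + number of decoys scoring strictly better than the native;
    percentile = 100 * (decoys strictly worse) / (number of decoys).
    Ties never outrank the native.
    """
    if not decoys:
        raise ParameterError("decoy list is empty")
    if better not in (HIGHER_IS_BETTER, LOWER_IS_BETTER):
        raise ParameterError(f"unknown ordering {better!r}")
    sign = 1.0 if better == HIGHER_IS_BETTER else -1.0
    n_better = sum(1 for dscore in decoys if sign * dscore > sign * native)
    n_worse = sum(1 for dscore in decoys if sign * dscore < sign * native)
    return DecoySetResult(
        target_id=target_id,
        native_score=native,
        decoy_scores=list(decoys),
        rank=1 + n_better,
        percentile=100.0 * n_worse / len(decoys),
    )


def topk_counts(
    results: list[DecoySetResult], ks: tuple[int, ...] = (1, 3, 5, 10)
) -> dict[int, int]:
    """How many targets have their native ranked within the top k."""
    if not results:
        raise ParameterError("no ranking results supplied")
    return {k: sum(1 for r in results if r.rank <= k) for k in ks}


def rate_metrics(tpr: float, tnr: float, prevalence: float = 1 / 101) -> RateMetrics:
    """Classifier metrics computed from rates.

    ``prevalence`` is the positive-class fraction; the default 1/101
    corresponds to one native per hundred decoys.  MCC uses the
    rate-based form (tpr*tnr - fpr*fnr) / sqrt((tpr+fpr)(tpr+fnr)(tnr+fpr)(tnr+fnr)).
    """
    for name, v in (("tpr", tpr), ("tnr", tnr)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {v}")
    if not 0.0 < prevalence < 1.0:
        raise ParameterError(f"prevalence must lie in (0, 1), got {prevalence}")
    fpr = 1.0 - tnr
    fnr = 1.0 - tpr
    denom_factors = (tpr + fpr, tpr + fnr, tnr + fpr, tnr + fnr)
    if any(f == 0 for f in denom_factors):
        warnings.warn("degenerate classifier: MCC denominator is zero; reporting 0",
                      stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tpr * tnr - fpr * fnr) / math.sqrt(math.prod(denom_factors))
    return RateMetrics(
        tpr=tpr,
        tnr=tnr,
        fpr=fpr,
        fnr=fnr,
        accuracy=prevalence * tpr + (1.0 - prevalence) * tnr,
        balanced_accuracy=(tpr + tnr) / 2.0,
        mcc=mcc,
    )


def rank_score_table(
    table: pd.DataFrame, better: str = HIGHER_IS_BETTER
) -> list[DecoySetResult]:
    """Rank every target of a (target_id, structure_role, score) table.

    ``structure_role`` is ``native`` or ``decoy``; each target must have
    exactly one native row and at least one decoy row.
    """
    required = {"target_id", "structure_role", "score"}
    if not required.issubset(table.columns):
        raise ParameterError(f"score table must have columns {sorted(required)}")
    results = []
    for target_id, grp in table.groupby("target_id", sort=True):
        natives = grp.loc[grp.structure_role == "native", "score"]
        decoys = grp.loc[grp.structure_role == "decoy", "score"]
        if len(natives) != 1:
            raise ParameterError(
                f"target {target_id}: expected exactly 1 native, got {len(natives)}"
            )
        if decoys.empty:
            raise ParameterError(f"target {target_id}: no decoys")
        results.append(
            percentile_rank(
                float(natives.iloc[0]), decoys.tolist(), better=better,
                target_id=str(target_id),
            )
        )
    return results


def results_frame(results: list[DecoySetResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_id": r.target_id,
                "native_score": r.native_score,
                "n_decoys": len(r.decoy_scores),
                "rank": r.rank,
                "percentile": round(r.percentile, 2),
            }
            for r in results
        ]
    )


def write_benchmark(
    results: list[DecoySetResult],
    out_dir: str | Path,
    ks: tuple[int, ...] = (1, 3, 5, 10),
) -> None:
    """Write ranks TSV and a top-k summary JSON for a benchmark run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results_frame(results).to_csv(out_dir / "ranks.tsv", sep="\t", index=False)
    summary = {
        "n_targets": len(results),
        "top_k_counts": {str(k): v for k, v in topk_counts(results, ks).items()},
    }
    (out_dir / "rank_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
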