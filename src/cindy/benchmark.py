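"""Precision/recall evaluation of called (modulator, TF) pairs.

The gold standard is intersected with the tested pair universe before either
ratio is computed: pairs outside the universe were never candidates, so
counting them against recall would measure coverage of the expression matrix
rather than inference quality.  Precision over an empty called set is
undefined and reported as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GoldStandard

__all__ = ["BenchmarkCurve", "precision_recall", "threshold_sweep"]


Pair = tuple[str, str]


def precision_recall(
    called: set[Pair], gold: GoldStandard, universe: set[Pair]
) -> tuple[float | None, float]:
    """Precision and recall of ``called`` against ``gold`` within ``universe``.

    ``precision = |called ∩ gold| / |called|`` and
    ``recall = |called ∩ gold| / |gold ∩ universe|``, with the gold standard
    restricted to the tested universe first.  An empty called set yields
    ``(None, 0.0)``; a gold standard disjoint from the universe is an error.
    """
    called = set(called)
    universe = set(universe)
    if not called <= universe:
        extra = sorted(called - universe)[:5]
        raise ValueError(f"called pairs outside the tested universe, e.g. {extra}")
    gold_in = {p for p in universe if p in gold.pairs}
    if not gold_in:
        raise ValueError("gold standard and tested universe are disjoint")
    hits = len(called & gold_in)
    recall = hits / len(gold_in)
    if not called:
        return None, 0.0
    return hits / len(called), recall


@dataclass(frozen=True)
class BenchmarkCurve:
    """Precision/recall at every N_sig >= k threshold, k = 1..k_max."""

    thresholds: np.ndarray
    precision: tuple[float | None, ...]
    recall: np.ndarray
    universe: frozenset[Pair]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.thresholds,
                "precision": [np.nan if p is None else p for p in self.precision],
                "recall": self.recall,
            }
        )


def threshold_sweep(
    pair_results: pd.DataFrame,
    gold: GoldStandard,
    universe: set[Pair] | None = None,
    k_max: int = 300,
) -> BenchmarkCurve:
    """Precision/recall curve over the robustness thresholds ``N_sig >= k``.

    ``pair_results`` must carry ``m_id``, ``tf_id`` and ``n_sig`` columns (the
    pairs table of either pipeline).  The universe defaults to all pairs in
    the table.
    """
    for col in ("m_id", "tf_id", "n_sig"):
        if col not in pair_results.columns:
            raise ValueError(f"pair results lack required column {col!r}")
    table_pairs = list(zip(pair_results["m_id"], pair_results["tf_id"]))
    if universe is None:
        universe = set(table_pairs)
    nsig = pair_results["n_sig"].to_numpy()
    ks = np.arange(1, k_max + 1)
    precisions: list[float | None] = []
    recalls = np.empty(k_max)
    for i, k in enumerate(ks):
        called = {p for p, v in zip(table_pairs, nsig) if v >= k}
        prec, rec = precision_recall(called, gold, universe)
        precisions.append(prec)
        recalls[i] = rec
    return BenchmarkCurve(
        thresholds=ks,
        precision=tuple(precisions),
        recall=recalls,
        universe=frozenset(universe),
    )
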