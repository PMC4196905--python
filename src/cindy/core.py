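"""The CINDy pipeline: triplet scoring, N_sig counting, and FDR calling.

For every admissible (modulator, TF, target) triplet the full conditional
mutual information I(TF;Tg|M) is estimated and converted to a p-value with
the MI-stratified permutation null.  Per (M, TF) pair, the number of targets
with a significant conditional interaction after multiple-testing correction
(N_sig) is the pair statistic; its significance is assessed against an
empirical null obtained by re-running the scoring with every modulator
profile replaced by a permuted copy, followed by Benjamini-Hochberg control
across pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.multitest import multipletests

from .ap import DEFAULT_ALPHA, FastInfo
from .io import ExpressionMatrix, GeneSet
from .null import CmiNullModel

__all__ = [
    "score_triplets",
    "count_significant",
    "build_nsig_null",
    "call_modulations",
    "run_cindy",
]

# Randomized-modulator rounds for the N_sig null.  With per-TF pooling over
# m modulators the smallest achievable empirical p is 1/(1 + m*n_rounds), so
# n_rounds must be large enough that that floor, BH-adjusted across the pair
# universe, can fall below the FDR threshold.
DEFAULT_N_ROUNDS = 40


def _resolve(ids, ranks, degenerate, what):
    present = sorted(set(ids) & set(ranks))
    missing = sorted(set(ids) - set(ranks))
    if missing:
        raise KeyError(f"unknown {what} gene ids: {', '.join(missing[:10])}"
                       + ("..." if len(missing) > 10 else ""))
    usable = [g for g in present if g not in degenerate]
    dropped = set(present) - set(usable)
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} constant-expression {what} gene(s): "
            + ", ".join(sorted(dropped)[:10]),
            UserWarning,
            stacklevel=3,
        )
    return usable


def _corrected_significance(pvals: np.ndarray, alpha: float, method: str) -> np.ndarray:
    """Per-pair multiple-testing correction across a pair's tested targets."""
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if method == "bonferroni":
        return pvals <= alpha / pvals.size
    if method == "bh":
        return multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    raise ValueError(f"unknown correction method {method!r}")


def _pair_score(m_id, tf_id, tg_list, ranks, m_ranks, mi_cache, cmi_fn, null,
                alpha_corrected, correction):
    tf_r = ranks[tf_id]
    tgs = [tg for tg in tg_list if tg != m_id and tg != tf_id]
    mis = np.array([mi_cache[(tf_id, tg)] for tg in tgs])
    cmis = np.empty(len(tgs))
    for i, tg in enumerate(tgs):
        cmis[i] = cmi_fn(tf_r, ranks[tg], m_ranks)
    pvals = np.array([null.pvalue(mis[i], cmis[i]) for i in range(len(tgs))])
    sig = _corrected_significance(pvals, alpha_corrected, correction)
    return tgs, mis, cmis, pvals, sig


def score_triplets(
    matrix: ExpressionMatrix,
    modulators: GeneSet,
    tfs: GeneSet,
    targets: GeneSet | None = None,
    null: CmiNullModel = None,
    alpha_corrected: float = 0.05,
    correction: str = "bonferroni",
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    n_jobs: int = 1,
    ranks: dict[str, np.ndarray] | None = None,
    degenerate: set[str] | None = None,
    modulator_ranks: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Score every admissible (M, TF, Tg) triplet.

    When ``targets`` is omitted the target universe is all matrix genes; the
    triplet's own members are always excluded, as are constant-expression
    genes.  ``significant`` marks triplets whose p-value survives the per-pair
    correction (Bonferroni by default) at ``alpha_corrected``.
    ``modulator_ranks`` substitutes modulator profiles (used by the
    randomized-modulator null).  Results are sorted, and all randomness is
    keyed, so output does not depend on ``n_jobs``.
    """
    if null is None:
        raise ValueError("a CmiNullModel is required")
    if ranks is None:
        ranks, degenerate = matrix.rank_matrix(seed=seed)
    degenerate = degenerate or set()
    mod_ids = _resolve(modulators.ids, ranks, degenerate, "modulator")
    tf_ids = _resolve(tfs.ids, ranks, degenerate, "transcription factor")
    if targets is None:
        tg_list = sorted(set(ranks) - degenerate)
    else:
        tg_list = _resolve(targets.ids, ranks, degenerate, "target")

    info = FastInfo(alpha=alpha)
    mi_cache: dict[tuple[str, str], float] = {}
    for tf in tf_ids:
        tf_r = ranks[tf]
        for tg in tg_list:
            if tg != tf and (tf, tg) not in mi_cache:
                mi_cache[(tf, tg)] = info.mi(tf_r, ranks[tg])

    mod_ranks = modulator_ranks or {}
    jobs = [(m, tf) for m in mod_ids for tf in tf_ids if m != tf]
    results = Parallel(n_jobs=n_jobs, backend="threading")(
        delayed(_pair_score)(
            m, tf, tg_list, ranks, mod_ranks.get(m, ranks[m]), mi_cache,
            info.cmi, null, alpha_corrected, correction,
        )
        for m, tf in jobs
    )
    rows_m, rows_tf, rows_tg, rows_mi, rows_cmi, rows_p, rows_sig = [], [], [], [], [], [], []
    for (m, tf), (tgs, mis, cmis, pvals, sig) in zip(jobs, results):
        rows_m.extend([m] * len(tgs))
        rows_tf.extend([tf] * len(tgs))
        rows_tg.extend(tgs)
        rows_mi.append(mis)
        rows_cmi.append(cmis)
        rows_p.append(pvals)
        rows_sig.append(sig)
    if not rows_m:
        return pd.DataFrame(columns=["m_id", "tf_id", "tg_id", "mi", "cmi", "p", "significant"])
    return pd.DataFrame(
        {
            "m_id": rows_m,
            "tf_id": rows_tf,
            "tg_id": rows_tg,
            "mi": np.concatenate(rows_mi),
            "cmi": np.concatenate(rows_cmi),
            "p": np.concatenate(rows_p),
            "significant": np.concatenate(rows_sig),
        }
    )


def count_significant(triplets: pd.DataFrame) -> pd.DataFrame:
    """N_sig per (M, TF): the count of significant conditional target interactions."""
    if triplets.empty:
        return pd.DataFrame(columns=["m_id", "tf_id", "n_sig"])
    out = (
        triplets.groupby(["m_id", "tf_id"], sort=True)["significant"]
        .sum()
        .astype(int)
        .reset_index()
        .rename(columns={"significant": "n_sig"})
    )
    return out


def _round_nsig(matrix, modulators, tfs, targets, null, alpha_corrected, correction,
                seed, alpha, ranks, degenerate, round_index, mod_ids):
    perm_ranks = {}
    for i, m in enumerate(mod_ids):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF00D, round_index, i)))
        perm_ranks[m] = rng.permutation(ranks[m])
    trip = score_triplets(
        matrix, modulators, tfs, targets, null,
        alpha_corrected=alpha_corrected, correction=correction, seed=seed,
        alpha=alpha, ranks=ranks, degenerate=degenerate, modulator_ranks=perm_ranks,
    )
    return count_significant(trip)


def build_nsig_null(
    matrix: ExpressionMatrix,
    modulators: GeneSet,
    tfs: GeneSet,
    targets: GeneSet | None,
    null: CmiNullModel,
    n_rounds: int = DEFAULT_N_ROUNDS,
    seed: int = 0,
    alpha_corrected: float = 0.05,
    correction: str = "bonferroni",
    alpha: float = DEFAULT_ALPHA,
    pool: str = "per_tf",
    n_jobs: int = 1,
    ranks: dict[str, np.ndarray] | None = None,
    degenerate: set[str] | None = None,
) -> dict[str, np.ndarray]:
    """Null N_sig distribution from randomized modulator expression.

    Every round replaces each modulator profile with a seeded permutation of
    itself, re-scores all triplets and records the per-pair N_sig.  Values are
    pooled per TF (``pool="per_tf"``) or across all pairs (``pool="global"``,
    key ``"*"``).
    """
    if n_rounds < 2:
        raise ValueError("n_rounds must be at least 2")
    if ranks is None:
        ranks, degenerate = matrix.rank_matrix(seed=seed)
    degenerate = degenerate or set()
    mod_ids = _resolve(modulators.ids, ranks, degenerate, "modulator")
    per_round = Parallel(n_jobs=n_jobs, backend="threading")(
        delayed(_round_nsig)(
            matrix, modulators, tfs, targets, null, alpha_corrected, correction,
            seed, alpha, ranks, degenerate, r, mod_ids,
        )
        for r in range(n_rounds)
    )
    pooled: dict[str, list[int]] = {}
    for nsig in per_round:
        for tf, value in zip(nsig["tf_id"], nsig["n_sig"]):
            key = tf if pool == "per_tf" else "*"
            pooled.setdefault(key, []).append(int(value))
    return {k: np.sort(np.asarray(v)) for k, v in sorted(pooled.items())}


def call_modulations(
    nsig: pd.DataFrame,
    nsig_null: dict[str, np.ndarray],
    fdr: float = 0.05,
    k_max: int = 300,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call modulated (M, TF) pairs against the randomized-modulator null.

    Per pair the empirical p-value is ``(1 + #null >= N_sig) / (1 + #null)``
    with the null pooled for that TF; Benjamini-Hochberg q-values are computed
    across all pairs and a pair is called iff ``q <= fdr``.  Also returns the
    robustness sweep: the size of the called set at thresholds
    ``N_sig >= k`` for ``k = 1..k_max``.
    """
    if nsig.empty:
        pairs = pd.DataFrame(columns=["m_id", "tf_id", "n_sig", "p", "q", "called"])
        sweep = pd.DataFrame({"k": np.arange(1, k_max + 1), "n_called": 0})
        return pairs, sweep
    pvals = np.empty(len(nsig))
    for i, (tf, value) in enumerate(zip(nsig["tf_id"], nsig["n_sig"])):
        sample = nsig_null.get(tf, nsig_null.get("*"))
        if sample is None or sample.size == 0:
            raise ValueError(f"no null N_sig distribution for TF {tf!r}")
        n_ge = sample.size - int(np.searchsorted(sample, value, side="left"))
        pvals[i] = (1.0 + n_ge) / (1.0 + sample.size)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    pairs = nsig.copy()
    pairs["p"] = pvals
    pairs["q"] = qvals
    pairs["called"] = pairs["q"] <= fdr
    pairs = pairs.sort_values(
        ["q", "n_sig", "m_id", "tf_id"], ascending=[True, False, True, True]
    ).reset_index(drop=True)
    ks = np.arange(1, k_max + 1)
    counts = np.array([(pairs["n_sig"].to_numpy() >= k).sum() for k in ks])
    sweep = pd.DataFrame({"k": ks, "n_called": counts})
    return pairs, sweep


@dataclass
class CindyResult:
    triplets: pd.DataFrame
    nsig: pd.DataFrame
    pairs: pd.DataFrame
    sweep: pd.DataFrame
    null: CmiNullModel
    nsig_null: dict[str, np.ndarray]


def run_cindy(
    matrix: ExpressionMatrix,
    modulators: GeneSet,
    tfs: GeneSet,
    targets: GeneSet | None = None,
    null: CmiNullModel | None = None,
    alpha_corrected: float = 0.05,
    fdr: float = 0.05,
    correction: str = "bonferroni",
    n_rounds: int = DEFAULT_N_ROUNDS,
    null_pairs: int = 1000,
    null_perm: int = 100,
    null_bins: int = 20,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    pool: str = "per_tf",
    n_jobs: int = 1,
    k_max: int = 300,
) -> CindyResult:
    """End-to-end CINDy run: null model, triplet scoring, N_sig FDR calling.

    The only thresholds the method needs are the corrected per-triplet
    significance level (default 0.05) and the pair-level FDR (default 0.05).
    The ``null_*`` sizes default to a desk-scale configuration; the full-scale
    construction is ``null_pairs=10^4, null_perm=1000, null_bins=100``.
    """
    from .null import build_null

    ranks, degenerate = matrix.rank_matrix(seed=seed)
    if null is None:
        null = build_null(
            matrix,
            tfs,
            targets if targets is not None else GeneSet("target", frozenset(matrix.gene_ids)),
            n_pairs=null_pairs,
            n_perm=null_perm,
            n_bins=null_bins,
            seed=seed,
            modulators=modulators,
            alpha=alpha,
            ranks=ranks,
            degenerate=degenerate,
        )
    triplets = score_triplets(
        matrix, modulators, tfs, targets, null,
        alpha_corrected=alpha_corrected, correction=correction, seed=seed,
        alpha=alpha, n_jobs=n_jobs, ranks=ranks, degenerate=degenerate,
    )
    nsig = count_significant(triplets)
    nsig_null = build_nsig_null(
        matrix, modulators, tfs, targets, null,
        n_rounds=n_rounds, seed=seed, alpha_corrected=alpha_corrected,
        correction=correction, alpha=alpha, pool=pool, n_jobs=n_jobs,
        ranks=ranks, degenerate=degenerate,
    )
    pairs, sweep = call_modulations(nsig, nsig_null, fdr=fdr, k_max=k_max)
    return CindyResult(
        triplets=triplets, nsig=nsig, pairs=pairs, sweep=sweep,
        null=null, nsig_null=nsig_null,
    )
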