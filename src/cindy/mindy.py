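"""The MINDy delta-I baseline: tail-conditional MI difference with prefilters.

MINDy approximates conditional dependence by comparing the TF-target mutual
information in the samples where the modulator is highest (L+) against the
samples where it is lowest (L-): delta_i = I(high tail) - I(low tail).  Two
prefilters restrict the tested triplets: (M, TF) pairs must be statistically
independent (the tails are only meaningful when the modulator does not simply
track the TF), and targets must depend on the TF strongly enough for tail MI
to carry signal, but not be near-duplicates of it.

Per-triplet significance uses a tail-label permutation null; the batch
pipeline pools these null delta-I values across a pair's targets so that
p-values below 1/(n_perm + 1) are resolvable.  Pair calling then reuses the
same randomized-modulator N_sig machinery as the main pipeline: a permuted
modulator profile induces random tail membership, which is exactly a draw
from the label-permutation null, so null rounds are scored against the same
pooled per-pair null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .ap import DEFAULT_ALPHA, FastInfo, rank_transform
from .core import DEFAULT_N_ROUNDS, _resolve, call_modulations
from .io import ExpressionMatrix, GeneSet
from .null import fit_tail

__all__ = [
    "MindyParams",
    "DeltaIResult",
    "MiNull",
    "select_tails",
    "prefilter_pairs",
    "prefilter_targets",
    "delta_i",
    "run_mindy",
]


@dataclass(frozen=True)
class MindyParams:
    """MINDy thresholds; defaults follow the method's published parameter table."""

    tail_fraction: float = 0.35      # fraction of samples in each modulator tail
    p_indep_m_tf: float = 1e-5       # MI p-value above which (M, TF) counts as independent
    alpha_corrected: float = 0.05    # corrected per-triplet delta-I significance
    p_dep_tf_tg: float = 1e-6        # MI p-value below which (TF, Tg) counts as dependent
    fdr: float = 0.05                # pair-level FDR
    n_perm: int = 100                # tail-label permutations per triplet
    corr_ceiling: float = 0.9        # drop targets with |rank correlation| at/above this

    def validate(self) -> None:
        if not 0.0 < self.tail_fraction <= 0.5:
            raise ValueError("tail_fraction must be in (0, 0.5]")
        for name in ("p_indep_m_tf", "p_dep_tf_tg", "alpha_corrected", "fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.corr_ceiling <= 1.0:
            raise ValueError("corr_ceiling must be in (0, 1]")


@dataclass(frozen=True)
class DeltaIResult:
    """Signed tail MI difference of one triplet with its permutation p-value."""

    m_id: str
    tf_id: str
    tg_id: str
    i_high: float
    i_low: float
    delta_i: float
    p: float


class MiNull:
    """Permutation null of the MI estimate between independent rank profiles.

    Under rank permutation the null MI distribution depends only on the sample
    count n (and the estimator settings), so one shared null serves every pair
    of profiles of that length.  The empirical survival is extended below its
    1/n_perm resolution with the extended-exponential tail fit, which is what
    makes thresholds like 1e-5 and 1e-6 decidable.
    """

    def __init__(self, n: int, n_perm: int = 2_000_000, seed: int = 0,
                 alpha: float = DEFAULT_ALPHA):
        from scipy.stats import chi2

        from ._kernels import mi_null_2d
        from .ap import _capacity

        crit = float(chi2.isf(alpha, 3))
        kernel_seed = int(np.random.SeedSequence((seed, 0x316E)).generate_state(1)[0] >> 1)
        values = mi_null_2d(n, crit, 4, n_perm, kernel_seed, _capacity(n, 2))
        self.n = n
        self.sample = np.sort(values)
        positive = self.sample[self.sample > 0]
        self.tail = None
        if positive.shape[0] >= 10:
            # fit on all positive null values: with a large atom at MI = 0
            # they ARE the extreme tail of the distribution
            frac = positive.shape[0] / self.sample.shape[0]
            try:
                self.tail = fit_tail(self.sample, tail_fraction=frac)
            except ValueError:
                self.tail = None

    def pvalue(self, mi: float) -> float:
        if mi <= 0:
            return 1.0
        n = self.sample.shape[0]
        n_ge = n - int(np.searchsorted(self.sample, mi, side="left"))
        if n_ge > 0:
            return n_ge / n
        if self.tail is None:
            return 1.0 / (n + 1.0)
        return float(min(self.tail.survival(mi), 1.0 / n))


def select_tails(m_profile, tail_fraction: float = 0.35, seed=0) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the highest and lowest ``tail_fraction`` of a modulator profile.

    Returns ``(high, low)`` index arrays of ``floor(tail_fraction * n)`` samples
    each.  Ties at the boundary are resolved by the seeded rank transform, so
    membership is deterministic for a given seed.
    """
    if not 0.0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5] so the tails cannot overlap")
    ranks = rank_transform(m_profile, seed=seed).values
    n = ranks.shape[0]
    k = int(tail_fraction * n)
    if k < 1:
        raise ValueError(f"tail of {k} samples from n={n} at fraction {tail_fraction}")
    order = np.argsort(ranks)
    low = np.sort(order[:k])
    high = np.sort(order[n - k:])
    return high, low


def _tail_mi(info: FastInfo, tf: np.ndarray, tg: np.ndarray, idx: np.ndarray, key: tuple) -> float:
    """MI of tail-restricted profiles, re-ranked so marginals stay uniform.

    ``key`` is a flat tuple of integers seeding the tie-break streams.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rt = rank_transform(tf[idx], seed=np.random.SeedSequence(key + (1,))).values
        rg = rank_transform(tg[idx], seed=np.random.SeedSequence(key + (2,))).values
    return info.mi(rt, rg)


MIN_TAIL = 10  # below this the tail MI estimate is meaningless


def delta_i(tf, tg, high, low, n_perm: int = 100, seed: int = 0,
            alpha: float = DEFAULT_ALPHA,
            m_id: str = "", tf_id: str = "", tg_id: str = "") -> DeltaIResult:
    """Tail MI difference I(high) - I(low) with a two-sided label-permutation p.

    ``tf``/``tg`` are full-length profiles (raw values or ranks); ``high`` and
    ``low`` are the modulator-tail sample indices.  The null re-assigns the
    pooled tail samples to two pseudo-tails ``n_perm`` times; the p-value is
    ``(1 + #{|null delta| >= |observed|}) / (1 + n_perm)``.
    """
    tf = np.asarray(tf, dtype=float)
    tg = np.asarray(tg, dtype=float)
    high = np.asarray(high, dtype=np.int64)
    low = np.asarray(low, dtype=np.int64)
    if np.intersect1d(high, low).size:
        raise ValueError("tail index sets overlap")
    if high.size < MIN_TAIL or low.size < MIN_TAIL:
        raise ValueError(
            f"each tail needs at least {MIN_TAIL} samples, got {high.size}/{low.size}"
        )
    info = FastInfo(alpha=alpha)
    i_high = _tail_mi(info, tf, tg, high, (seed, 10))
    i_low = _tail_mi(info, tf, tg, low, (seed, 20))
    observed = i_high - i_low

    pooled = np.concatenate([high, low])
    k = high.size
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD17A)))
    n_ge = 0
    for j in range(n_perm):
        perm = rng.permutation(pooled)
        d = _tail_mi(info, tf, tg, perm[:k], (seed, 30, j)) - _tail_mi(
            info, tf, tg, perm[k:], (seed, 40, j)
        )
        if abs(d) >= abs(observed):
            n_ge += 1
    p = (1.0 + n_ge) / (1.0 + n_perm)
    return DeltaIResult(m_id=m_id, tf_id=tf_id, tg_id=tg_id,
                        i_high=i_high, i_low=i_low, delta_i=observed, p=p)


def prefilter_pairs(matrix: ExpressionMatrix, modulators: GeneSet, tfs: GeneSet,
                    params: MindyParams = MindyParams(), seed: int = 0,
                    mi_null: MiNull | None = None,
                    ranks: dict[str, np.ndarray] | None = None,
                    degenerate: set[str] | None = None) -> list[tuple[str, str]]:
    """(M, TF) pairs whose expression is statistically independent.

    A pair is admissible iff the permutation p-value of MI(M, TF) exceeds
    ``p_indep_m_tf`` — modulators that track their TF's expression are
    excluded, because tail-conditioning on them conditions on the TF itself.
    """
    params.validate()
    if ranks is None:
        ranks, degenerate = matrix.rank_matrix(seed=seed)
    degenerate = degenerate or set()
    mod_ids = _resolve(modulators.ids, ranks, degenerate, "modulator")
    tf_ids = _resolve(tfs.ids, ranks, degenerate, "transcription factor")
    if mi_null is None:
        mi_null = MiNull(matrix.n_samples, seed=seed)
    info = FastInfo()
    kept = []
    for m in mod_ids:
        for t in tf_ids:
            if m == t:
                continue
            p = mi_null.pvalue(info.mi(ranks[m], ranks[t]))
            if p > params.p_indep_m_tf:
                kept.append((m, t))
    return kept


def prefilter_targets(matrix: ExpressionMatrix, tf: str, targets: GeneSet,
                      params: MindyParams = MindyParams(), seed: int = 0,
                      mi_null: MiNull | None = None,
                      ranks: dict[str, np.ndarray] | None = None,
                      degenerate: set[str] | None = None) -> list[str]:
    """Targets that depend on the TF but are not near-duplicates of it.

    A target is admissible iff the permutation p-value of MI(TF, Tg) is at
    most ``p_dep_tf_tg`` and the rank correlation satisfies
    ``|rho| < corr_ceiling`` (tail MI is meaningless for near-duplicates).
    """
    params.validate()
    if ranks is None:
        ranks, degenerate = matrix.rank_matrix(seed=seed)
    degenerate = degenerate or set()
    tg_ids = _resolve(targets.ids, ranks, degenerate, "target")
    if mi_null is None:
        mi_null = MiNull(matrix.n_samples, seed=seed)
    info = FastInfo()
    tf_r = ranks[tf].astype(float)
    tf_c = tf_r - tf_r.mean()
    tf_norm = float(np.sqrt(tf_c @ tf_c))
    kept = []
    for tg in tg_ids:
        if tg == tf:
            continue
        tg_r = ranks[tg].astype(float)
        tg_c = tg_r - tg_r.mean()
        rho = float(tf_c @ tg_c) / (tf_norm * float(np.sqrt(tg_c @ tg_c)))
        if abs(rho) >= params.corr_ceiling:
            continue
        if mi_null.pvalue(info.mi(ranks[tf], ranks[tg])) <= params.p_dep_tf_tg:
            kept.append(tg)
    return kept


@dataclass
class MindyResult:
    triplets: pd.DataFrame   # m_id, tf_id, tg_id, i_high, i_low, delta_i, p, significant
    nsig: pd.DataFrame
    pairs: pd.DataFrame      # same schema as the main pipeline's pairs table
    sweep: pd.DataFrame
    admissible_pairs: list[tuple[str, str]]


def _pair_delta(info, ranks, raw, m, t, tgs, high, low, seed, n_perm, pair_index):
    """Observed delta-I per target plus the pooled label-permutation null."""
    pooled_idx = np.concatenate([high, low])
    k = high.size
    obs = np.empty((len(tgs), 2))
    nulls = np.empty(len(tgs) * n_perm)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD17A, pair_index)))
    for i, tg in enumerate(tgs):
        tf_p, tg_p = raw[t], raw[tg]
        ih = _tail_mi(info, tf_p, tg_p, high, (seed, 10, i))
        il = _tail_mi(info, tf_p, tg_p, low, (seed, 20, i))
        obs[i] = (ih, il)
        for j in range(n_perm):
            perm = rng.permutation(pooled_idx)
            nulls[i * n_perm + j] = _tail_mi(info, tf_p, tg_p, perm[:k], (seed, 30, i, j)) - _tail_mi(
                info, tf_p, tg_p, perm[k:], (seed, 40, i, j)
            )
    return obs, np.sort(np.abs(nulls))


def _pvals_against_pool(deltas: np.ndarray, pool_abs: np.ndarray) -> np.ndarray:
    n = pool_abs.shape[0]
    idx = np.searchsorted(pool_abs, np.abs(deltas), side="left")
    return (1.0 + (n - idx)) / (1.0 + n)


def run_mindy(
    matrix: ExpressionMatrix,
    modulators: GeneSet,
    tfs: GeneSet,
    targets: GeneSet | None = None,
    params: MindyParams = MindyParams(),
    seed: int = 0,
    n_rounds: int = DEFAULT_N_ROUNDS,
    n_jobs: int = 1,
    k_max: int = 300,
    mi_null: MiNull | None = None,
) -> MindyResult:
    """Full MINDy run: prefilters, delta-I scoring, N_sig FDR calling.

    Per-triplet p-values come from the pooled per-pair label-permutation null
    (pooling across a pair's targets resolves p-values below 1/(n_perm+1),
    which the per-pair Bonferroni correction requires).  The pair-level null
    re-scores every pair ``n_rounds`` times with permuted modulator profiles
    — equivalent to fresh draws from the label null — and calling proceeds
    exactly as in the main pipeline.
    """
    params.validate()
    ranks, degenerate = matrix.rank_matrix(seed=seed)
    raw = {g: matrix.row(g) for g in matrix.gene_ids}
    if mi_null is None:
        mi_null = MiNull(matrix.n_samples, seed=seed)
    elif mi_null.n != matrix.n_samples:
        raise ValueError(
            f"mi_null was built for n={mi_null.n}, matrix has {matrix.n_samples} samples"
        )
    admissible = prefilter_pairs(matrix, modulators, tfs, params, seed=seed,
                                 mi_null=mi_null, ranks=ranks, degenerate=degenerate)
    target_set = targets if targets is not None else GeneSet("target", frozenset(matrix.gene_ids))
    tg_by_tf: dict[str, list[str]] = {}
    for _, t in admissible:
        if t not in tg_by_tf:
            tg_by_tf[t] = prefilter_targets(matrix, t, target_set, params, seed=seed,
                                            mi_null=mi_null, ranks=ranks, degenerate=degenerate)

    info = FastInfo()
    tails = {m: select_tails(raw[m], params.tail_fraction,
                             seed=np.random.SeedSequence((seed, 0x7A11, i)))
             for i, m in enumerate(sorted({m for m, _ in admissible}))}

    jobs = [(m, t, [tg for tg in tg_by_tf[t] if tg != m and tg != t])
            for m, t in admissible]
    results = Parallel(n_jobs=n_jobs, backend="threading")(
        delayed(_pair_delta)(info, ranks, raw, m, t, tgs, tails[m][0], tails[m][1],
                             seed, params.n_perm, pi)
        for pi, (m, t, tgs) in enumerate(jobs)
    )

    rows = []
    pair_pool: dict[tuple[str, str], np.ndarray] = {}
    nsig_rows = []
    for (m, t, tgs), (obs, pool_abs) in zip(jobs, results):
        pair_pool[(m, t)] = pool_abs
        deltas = obs[:, 0] - obs[:, 1]
        if len(tgs):
            pvals = _pvals_against_pool(deltas, pool_abs)
            sig = pvals <= params.alpha_corrected / len(tgs)
        else:
            pvals = np.zeros(0)
            sig = np.zeros(0, dtype=bool)
        for i, tg in enumerate(tgs):
            rows.append((m, t, tg, obs[i, 0], obs[i, 1], deltas[i], pvals[i], bool(sig[i])))
        nsig_rows.append((m, t, int(sig.sum())))

    triplets = pd.DataFrame(
        rows, columns=["m_id", "tf_id", "tg_id", "i_high", "i_low", "delta_i", "p", "significant"]
    )
    nsig = pd.DataFrame(nsig_rows, columns=["m_id", "tf_id", "n_sig"])
    if nsig.empty:
        pairs = pd.DataFrame(columns=["m_id", "tf_id", "n_sig", "p", "q", "called"])
        sweep = pd.DataFrame({"k": np.arange(1, k_max + 1), "n_called": 0})
        return MindyResult(triplets=triplets, nsig=nsig, pairs=pairs, sweep=sweep,
                           admissible_pairs=admissible)

    # N_sig null: permuted modulator profiles induce random tails, i.e. fresh
    # draws from the label-permutation null, scored against the same pool.
    nsig_null: dict[str, list[int]] = {}
    for r in range(n_rounds):
        for pi, (m, t, tgs) in enumerate(jobs):
            rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF00D, r, pi)))
            perm = rng.permutation(matrix.n_samples)
            k = tails[m][0].size
            high, low = np.sort(perm[:k]), np.sort(perm[k:2 * k])
            if len(tgs):
                deltas = np.array([
                    _tail_mi(info, raw[t], raw[tg], high, (seed, 50, r, i)) -
                    _tail_mi(info, raw[t], raw[tg], low, (seed, 60, r, i))
                    for i, tg in enumerate(tgs)
                ])
                pvals = _pvals_against_pool(deltas, pair_pool[(m, t)])
                count = int((pvals <= params.alpha_corrected / len(tgs)).sum())
            else:
                count = 0
            nsig_null.setdefault(t, []).append(count)
    null_arrays = {k: np.sort(np.asarray(v)) for k, v in sorted(nsig_null.items())}
    pairs, sweep = call_modulations(nsig, null_arrays, fdr=params.fdr, k_max=k_max)
    return MindyResult(triplets=triplets, nsig=nsig, pairs=pairs, sweep=sweep,
                       admissible_pairs=admissible)
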