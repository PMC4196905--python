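"""MI-stratified permutation null model for conditional mutual information.

The significance of a CMI value depends strongly on how coupled the TF-target
pair already is: strongly dependent pairs have stochastically larger null CMI
because the 3-D partition resolves more structure.  The null model therefore
stratifies: it samples (TF, Tg) pairs, estimates their MI, computes CMI
against permuted modulator profiles (permutation destroys any three-way
coupling while preserving the modulator's marginal), splits the MI range into
equi-probable bins, and pools the null CMI values within each bin.  P-values
are the empirical upper-tail survival inside the observed null range and an
extended-exponential extrapolation ``ln S(x) = a + b*x^c`` beyond it, which
is what allows p-values far below the 1/n_perm permutation resolution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .ap import DEFAULT_ALPHA, FastInfo

P_FLOOR = 1e-30  # avoid log-domain underflow in downstream corrections

__all__ = ["TailFit", "CmiNullModel", "build_null", "fit_tail", "cmi_pvalue"]


@dataclass(frozen=True)
class TailFit:
    """Parameters of the extended-exponential survival tail ln S = a + b*x^c."""

    a: float
    b: float
    c: float

    def survival(self, x) -> np.ndarray:
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        return np.exp(self.a + self.b * x**self.c)


def fit_tail(null_cmis, tail_fraction: float = 0.25, stretch_gain: float = 0.5) -> TailFit:
    """Fit ``ln S(x) = a + b*x^c`` to the upper tail of the empirical survival.

    Fits the top ``tail_fraction`` of the values; ``c`` stays at 1 unless the
    stretch reduces the tail sum of squared errors by the factor
    ``stretch_gain`` (default: halved).  ``b < 0`` is enforced.
    """
    values = np.sort(np.asarray(null_cmis, dtype=float))
    n = values.shape[0]
    if n < 100:
        raise ValueError(f"tail fit needs at least 100 values, got {n}")
    if values[0] == values[-1]:
        raise ValueError("degenerate null: all values identical")
    surv = (n - np.arange(n)) / n
    start = int(np.ceil((1.0 - tail_fraction) * n))
    x = values[start:]
    ln_s = np.log(surv[start:])
    keep = x > 0
    x, ln_s = x[keep], ln_s[keep]
    if x.shape[0] < 10 or x[0] == x[-1]:
        raise ValueError("degenerate null tail")

    def sse_for(c: float) -> tuple[float, float, float]:
        xc = x**c
        bb, aa = np.polyfit(xc, ln_s, 1)
        resid = ln_s - (aa + bb * xc)
        return float(resid @ resid), float(aa), float(bb)

    sse1, a1, b1 = sse_for(1.0)
    res = minimize_scalar(lambda c: sse_for(c)[0], bounds=(0.25, 4.0), method="bounded")
    a, b, c = a1, b1, 1.0
    if res.success and res.fun <= stretch_gain * sse1:
        c = float(res.x)
        _, a, b = sse_for(c)
    if b >= 0:
        warnings.warn("non-decreasing null tail; clamping slope", UserWarning, stacklevel=2)
        b = -1e-12
    return TailFit(a=a, b=b, c=c)


@dataclass
class CmiNullModel:
    """MI-stratified null CMI distributions with fitted extrapolation tails.

    ``bin_edges`` has ``n_bins + 1`` entries spanning the observed MI range;
    ``bin_samples[k]`` is the sorted null CMI sample of bin ``k`` and
    ``tails[k]`` its extended-exponential fit (None when the bin was too
    small to fit).  MI values outside the range clamp to the end bins.
    """

    bin_edges: np.ndarray
    bin_samples: list[np.ndarray]
    tails: list[TailFit | None]
    n_pairs: int
    n_perm: int
    seed: int | None = None
    n_samples: int | None = None
    two_sided: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.bin_samples)

    def bin_index(self, mi: float) -> int:
        idx = int(np.searchsorted(self.bin_edges[1:-1], mi, side="right"))
        return min(max(idx, 0), self.n_bins - 1)

    def pvalue(self, mi: float, cmi: float) -> float:
        """Upper-tail p-value of ``cmi`` given the MI stratum of its pair."""
        k = self.bin_index(mi)
        sample = self.bin_samples[k]
        n = sample.shape[0]
        if cmi <= 0:
            return 1.0
        n_ge = n - int(np.searchsorted(sample, cmi, side="left"))
        if n_ge > 0:
            p = n_ge / n
        else:
            tail = self.tails[k]
            if tail is None:
                p = 1.0 / (n + 1.0)
            else:
                p = min(float(tail.survival(cmi)), 1.0 / n)
        p = min(max(p, P_FLOOR), 1.0)
        if self.two_sided:
            p = min(2.0 * p, 1.0)
        return p

    # -- serialization ----------------------------------------------------
    #: per-bin sample size kept when serializing (quantile grid)
    SERIAL_SAMPLE = 2001

    def to_dict(self) -> dict:
        bins = []
        for sample, tail in zip(self.bin_samples, self.tails):
            if sample.shape[0] > self.SERIAL_SAMPLE:
                q = np.linspace(0.0, 1.0, self.SERIAL_SAMPLE)
                stored = np.quantile(sample, q)
            else:
                stored = sample
            bins.append(
                {
                    "sample": [float(v) for v in stored],
                    "tail": None if tail is None else {"a": tail.a, "b": tail.b, "c": tail.c},
                }
            )
        return {
            "bin_edges": [float(v) for v in self.bin_edges],
            "bins": bins,
            "n_pairs": self.n_pairs,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_samples": self.n_samples,
            "two_sided": self.two_sided,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CmiNullModel":
        return cls(
            bin_edges=np.asarray(d["bin_edges"], dtype=float),
            bin_samples=[np.asarray(b["sample"], dtype=float) for b in d["bins"]],
            tails=[None if b["tail"] is None else TailFit(**b["tail"]) for b in d["bins"]],
            n_pairs=int(d["n_pairs"]),
            n_perm=int(d["n_perm"]),
            seed=d.get("seed"),
            n_samples=d.get("n_samples"),
            two_sided=bool(d.get("two_sided", False)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "CmiNullModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def cmi_pvalue(model: CmiNullModel, mi: float, cmi: float) -> float:
    """P-value of a CMI given the MI of its (TF, Tg) pair."""
    return model.pvalue(mi, cmi)


def _sample_distinct_pairs(rng, tf_ids, tg_ids, n_pairs):
    n_tf, n_tg = len(tf_ids), len(tg_ids)
    total = sum(1 for t in tf_ids for g in tg_ids if t != g)
    if total <= n_pairs:
        warnings.warn(
            f"only {total} distinct (TF, Tg) combinations available; using all",
            UserWarning,
            stacklevel=3,
        )
        return [(t, g) for t in tf_ids for g in tg_ids if t != g]
    chosen: list[tuple[str, str]] = []
    seen: set[int] = set()
    while len(chosen) < n_pairs:
        draw = rng.integers(0, n_tf * n_tg, size=2 * (n_pairs - len(chosen)))
        for k in draw:
            k = int(k)
            if k in seen:
                continue
            t, g = tf_ids[k // n_tg], tg_ids[k % n_tg]
            if t == g:
                continue
            seen.add(k)
            chosen.append((t, g))
            if len(chosen) == n_pairs:
                break
    return chosen


def build_null(
    matrix,
    tfs,
    targets,
    n_pairs: int = 10_000,
    n_perm: int = 1000,
    n_bins: int = 100,
    seed: int = 0,
    modulators=None,
    alpha: float = DEFAULT_ALPHA,
    mi_fn=None,
    cmi_fn=None,
    ranks: dict[str, np.ndarray] | None = None,
    degenerate: set[str] | None = None,
) -> CmiNullModel:
    """Build the MI-stratified CMI null model from an expression matrix.

    Samples ``n_pairs`` distinct (TF, Tg) pairs, estimates their MI, and for
    each pair computes ``n_perm`` CMI scores against modulator profiles whose
    sample order has been randomly permuted.  The MI range is split into
    ``n_bins`` equi-probable bins and an extended-exponential tail is fitted
    per bin.  ``mi_fn``/``cmi_fn`` may replace the adaptive-partitioning
    estimators (used to exercise the machinery cheaply); ``ranks`` may carry
    precomputed per-gene rank vectors.

    Fully reproducible given ``seed``: permutation streams are keyed by
    (seed, pair index) so the result does not depend on evaluation order.
    """
    if ranks is None:
        ranks, degenerate = matrix.rank_matrix(seed=seed)
    degenerate = degenerate or set()
    info = FastInfo(alpha=alpha)
    if mi_fn is None:
        mi_fn = info.mi
    if cmi_fn is None:
        cmi_fn = info.cmi

    tf_ids = sorted(set(tfs.ids) & set(ranks) - degenerate)
    tg_ids = sorted(set(targets.ids) & set(ranks) - degenerate)
    if modulators is None:
        mod_ids = sorted(set(ranks) - degenerate)
    else:
        mod_ids = sorted(set(modulators.ids) & set(ranks) - degenerate)
    if not tf_ids or not tg_ids or not mod_ids:
        raise ValueError("empty TF, target or modulator universe after filtering")

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB1)))
    pairs = _sample_distinct_pairs(rng, tf_ids, tg_ids, n_pairs)
    n_pairs_used = len(pairs)
    if n_pairs_used < n_bins:
        raise ValueError(
            f"{n_pairs_used} pairs cannot fill {n_bins} MI bins; reduce n_bins"
        )

    mi_values = np.empty(n_pairs_used)
    null_cmis = np.empty((n_pairs_used, n_perm))
    for i, (t, g) in enumerate(pairs):
        rt, rg = ranks[t], ranks[g]
        mi_values[i] = mi_fn(rt, rg)
        prng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED, i)))
        for j in range(n_perm):
            mod = ranks[mod_ids[int(prng.integers(0, len(mod_ids)))]]
            null_cmis[i, j] = cmi_fn(rt, rg, prng.permutation(mod))

    if np.unique(mi_values).shape[0] < n_bins:
        raise ValueError(
            f"only {np.unique(mi_values).shape[0]} distinct MI values for "
            f"{n_bins} bins; reduce n_bins"
        )

    order = np.argsort(mi_values, kind="stable")
    sorted_mi = mi_values[order]
    edges = np.empty(n_bins + 1)
    edges[0] = sorted_mi[0]
    edges[-1] = sorted_mi[-1]
    for k in range(1, n_bins):
        edges[k] = sorted_mi[(k * n_pairs_used) // n_bins]

    bin_samples: list[np.ndarray] = []
    tails: list[TailFit | None] = []
    for k in range(n_bins):
        lo = (k * n_pairs_used) // n_bins
        hi = ((k + 1) * n_pairs_used) // n_bins
        sample = np.sort(null_cmis[order[lo:hi]].ravel())
        bin_samples.append(sample)
        if sample.shape[0] >= 100 and sample[0] != sample[-1]:
            try:
                tails.append(fit_tail(sample))
            except ValueError:
                # tail dominated by exact zeros (partition never split):
                # fall back to the empirical 1/(n+1) bound for this bin
                tails.append(None)
        else:
            tails.append(None)
    return CmiNullModel(
        bin_edges=edges,
        bin_samples=bin_samples,
        tails=tails,
        n_pairs=n_pairs_used,
        n_perm=n_perm,
        seed=seed,
        n_samples=matrix.n_samples if matrix is not None else None,
    )
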