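import numpy as np
import pandas as pd
import pytest

from cindy.core import (
    build_nsig_null,
    call_modulations,
    count_significant,
    run_cindy,
    score_triplets,
)
from cindy.io import GeneSet
from cindy.null import CmiNullModel, TailFit, build_null
from cindy.synth import SyntheticSpec, TripletConfig, generate


def _flat_null():
    """Single-bin null: uniform CMI on [0, 0.2] regardless of MI."""
    return CmiNullModel(
        bin_edges=np.array([0.0, 10.0]),
        bin_samples=[np.sort(np.linspace(1e-4, 0.2, 2000))],
        tails=[TailFit(a=0.0, b=-30.0, c=1.0)],
        n_pairs=1,
        n_perm=2000,
    )


def _planted(n_samples=300, n_targets=6, n_decoys=30, seed=11):
    spec = SyntheticSpec(
        n_samples=n_samples,
        n_decoy_genes=n_decoys,
        triplets=(TripletConfig(n_targets=n_targets),),
        seed=seed,
    )
    matrix, truth = generate(spec)
    decoys = sorted(g for g in matrix.gene_ids if g.startswith("D"))
    mods = GeneSet("modulator", frozenset({"M0000"} | set(decoys[:2])))
    tfs = GeneSet("transcription_factor", frozenset({"TF0000"}))
    targets = GeneSet("target", frozenset(g for g in matrix.gene_ids if g.startswith("TG")))
    return matrix, truth, mods, tfs, targets


@pytest.fixture(scope="module")
def planted_with_null():
    """Planted fixture plus a real MI-stratified null over a broad pair universe."""
    matrix, truth, mods, tfs, targets = _planted()
    null = build_null(
        matrix,
        GeneSet("transcription_factor", frozenset(matrix.gene_ids)),
        GeneSet("target", frozenset(matrix.gene_ids)),
        n_pairs=200, n_perm=25, n_bins=2, seed=4,
    )
    return matrix, truth, mods, tfs, targets, null


class TestScoreTriplets:
    def test_planted_triplets_score_high(self, planted_with_null):
        matrix, truth, mods, tfs, targets, null = planted_with_null
        trip = score_triplets(matrix, mods, tfs, targets, null=null, seed=0)
        assert len(trip) == 3 * 6  # 3 modulators x 1 TF x 6 targets
        planted = trip[trip.m_id == "M0000"]
        decoy = trip[trip.m_id != "M0000"]
        assert planted.cmi.mean() > decoy.cmi.mean()
        # the null's upper MI stratum is built from the planted coupled pairs
        # themselves here, so per-triplet calls are conservative: expect a
        # clear majority of planted triplets and no decoys
        assert planted.significant.sum() >= 3
        assert not decoy.significant.any()

    def test_self_triplets_excluded(self):
        matrix, truth, mods, tfs, _ = _planted()
        universe = GeneSet("target", frozenset({"TG0000_000", "M0000", "TF0000"}))
        trip = score_triplets(matrix, mods, tfs, universe, null=_flat_null(), seed=0)
        sub = trip[trip.m_id == "M0000"]
        assert set(sub.tg_id) == {"TG0000_000"}  # own M and TF rows removed

    def test_independent_of_n_jobs(self):
        matrix, truth, mods, tfs, targets = _planted()
        a = score_triplets(matrix, mods, tfs, targets, null=_flat_null(), seed=0, n_jobs=1)
        b = score_triplets(matrix, mods, tfs, targets, null=_flat_null(), seed=0, n_jobs=4)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_gene_rejected(self):
        matrix, truth, mods, tfs, targets = _planted()
        bad = GeneSet("modulator", frozenset({"NOT_A_GENE"}))
        with pytest.raises(KeyError):
            score_triplets(matrix, bad, tfs, targets, null=_flat_null())

    def test_null_model_required(self):
        matrix, truth, mods, tfs, targets = _planted()
        with pytest.raises(ValueError):
            score_triplets(matrix, mods, tfs, targets, null=None)

    def test_bonferroni_vs_bh_ordering(self):
        matrix, truth, mods, tfs, targets = _planted()
        bon = score_triplets(matrix, mods, tfs, targets, null=_flat_null(),
                             correction="bonferroni")
        bh = score_triplets(matrix, mods, tfs, targets, null=_flat_null(),
                            correction="bh")
        # BH is uniformly no stricter than Bonferroni
        assert (bh.significant.to_numpy() >= bon.significant.to_numpy()).all()


class TestCountSignificant:
    def test_counts(self):
        trip = pd.DataFrame(
            {
                "m_id": ["a", "a", "a", "b"],
                "tf_id": ["t", "t", "t", "t"],
                "tg_id": ["g1", "g2", "g3", "g1"],
                "significant": [True, False, True, False],
            }
        )
        out = count_significant(trip)
        assert dict(zip(zip(out.m_id, out.tf_id), out.n_sig)) == {("a", "t"): 2, ("b", "t"): 0}

    def test_empty(self):
        out = count_significant(pd.DataFrame(columns=["m_id", "tf_id", "significant"]))
        assert out.empty and list(out.columns) == ["m_id", "tf_id", "n_sig"]


class TestNsigNull:
    def test_shapes_and_determinism(self):
        matrix, truth, mods, tfs, targets = _planted()
        kw = dict(n_rounds=3, seed=5)
        a = build_nsig_null(matrix, mods, tfs, targets, _flat_null(), **kw)
        b = build_nsig_null(matrix, mods, tfs, targets, _flat_null(), **kw)
        assert set(a) == {"TF0000"}
        assert a["TF0000"].shape == (3 * 3,)  # rounds x modulators, pooled per TF
        assert np.array_equal(a["TF0000"], b["TF0000"])

    def test_randomization_destroys_signal(self, planted_with_null):
        matrix, truth, mods, tfs, targets, null = planted_with_null
        nsig_null = build_nsig_null(matrix, mods, tfs, targets, null, n_rounds=3, seed=5)
        trip = score_triplets(matrix, mods, tfs, targets, null=null, seed=5)
        observed = count_significant(trip)
        planted = int(observed.loc[observed.m_id == "M0000", "n_sig"].iloc[0])
        assert planted >= 3
        assert nsig_null["TF0000"].max() < planted

    def test_min_rounds(self):
        matrix, truth, mods, tfs, targets = _planted()
        with pytest.raises(ValueError):
            build_nsig_null(matrix, mods, tfs, targets, _flat_null(), n_rounds=1)


class TestCallModulations:
    def test_clear_pair_called(self):
        nsig = pd.DataFrame({"m_id": ["m1", "m2"], "tf_id": ["t", "t"], "n_sig": [40, 1]})
        null = {"t": np.sort(np.array([0, 0, 1, 1, 2, 3] * 20))}
        pairs, sweep = call_modulations(nsig, null, fdr=0.05)
        row = pairs[pairs.m_id == "m1"].iloc[0]
        assert bool(row.called)
        assert row.p == pytest.approx(1.0 / 121.0)
        assert not bool(pairs[pairs.m_id == "m2"].iloc[0].called)

    def test_sweep_counts(self):
        nsig = pd.DataFrame({"m_id": ["a", "b", "c"], "tf_id": ["t"] * 3, "n_sig": [10, 4, 0]})
        null = {"t": np.arange(50)}
        _, sweep = call_modulations(nsig, null, k_max=12)
        counts = dict(zip(sweep.k, sweep.n_called))
        assert counts[1] == 2 and counts[4] == 2 and counts[5] == 1 and counts[11] == 0

    def test_missing_tf_null_error(self):
        nsig = pd.DataFrame({"m_id": ["a"], "tf_id": ["t"], "n_sig": [3]})
        with pytest.raises(ValueError):
            call_modulations(nsig, {"other": np.arange(5)})

    def test_global_pool_fallback(self):
        nsig = pd.DataFrame({"m_id": ["a"], "tf_id": ["t"], "n_sig": [3]})
        pairs, _ = call_modulations(nsig, {"*": np.zeros(99, dtype=int)})
        assert pairs.iloc[0].p == pytest.approx(0.01)

    def test_empty_input(self):
        pairs, sweep = call_modulations(
            pd.DataFrame(columns=["m_id", "tf_id", "n_sig"]), {"*": np.arange(3)}
        )
        assert pairs.empty and (sweep.n_called == 0).all()


class TestRunCindy:
    def test_end_to_end_planted_pair_called(self, planted_with_null):
        matrix, truth, mods, tfs, targets, null = planted_with_null
        # null model supplied up front: 1 TF x 6 targets is far too small a
        # pair universe to build one from (construction is tested separately)
        res = run_cindy(
            matrix, mods, tfs, targets, null=null,
            seed=3, n_jobs=2,
        )
        called = set(zip(res.pairs[res.pairs.called].m_id, res.pairs[res.pairs.called].tf_id))
        assert ("M0000", "TF0000") in called
        decoy_called = {p for p in called if p[0] != "M0000"}
        assert not decoy_called
        assert res.null.n_samples == 300
        assert len(res.sweep) == 300
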