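"""Synthetic expression matrices with planted modulation triplets.

Two triplet topologies are generated.  Under *independent* regulation the
modulator and the TF act additively on the target, so the TF-target coupling
does not change with the modulator and the conditional mutual information
I(TF;Tg|M) carries no three-way term.  Under *modulated* regulation the
modulator multiplicatively gates the TF's effect through a logistic squash
g(M) in [0, 1], the canonical three-way interaction:

    independent:  Tg = alpha*TF + gamma*M        + sigma*eps
    modulated:    Tg = alpha*TF + beta*g(M)*TF   + sigma*eps

with M ~ N(0,1), TF = rho_MT*M + sqrt(1-rho_MT^2)*Z, decoys i.i.d. normal.
The default modulated target has no baseline coupling (alpha = 0): the TF
acts on the target only through the modulator gate, the canonical strong
three-way interaction.
Downstream estimation is rank-based, so plain Gaussian noise suffices: any
monotone marginal transform would leave the estimates unchanged.  Per-gene
RNG streams are keyed by (seed, gene index) so adding triplets does not
perturb existing genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .io import ExpressionMatrix, GeneSet

__all__ = ["TripletConfig", "SyntheticSpec", "TruthTable", "generate", "make_benchmark_fixture"]

TOPOLOGIES = ("independent", "modulated")

#: steepness of the logistic gate g(M) = expit(GATE_STEEPNESS * M).  The
#: modulated topology models switch-like control: the TF regulates its
#: targets only when the modulator is expressed, so the gate should be near
#: 0 for low M and near 1 for high M.  At steepness 4 the gate is 0.02 at
#: M = -1 and 0.98 at M = +1 while staying smooth.
GATE_STEEPNESS = 4.0


@dataclass(frozen=True)
class TripletConfig:
    """One planted (M, TF) pair with its block of targets."""

    topology: str = "modulated"
    beta: float = 2.0          # modulation strength (multiplicative gate)
    alpha: float = 0.0         # baseline TF->target coupling
    gamma: float = 1.0         # direct M->target coupling (independent topology)
    rho_mt: float = 0.0        # modulator-TF expression correlation
    sigma: float = 0.5         # target noise sd
    n_targets: int = 50

    def validate(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be in {TOPOLOGIES}, got {self.topology!r}")
        if self.topology == "independent" and self.beta != 0.0:
            raise ValueError("independent topology forces beta = 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not -1.0 < self.rho_mt < 1.0:
            raise ValueError("|rho_mt| must be < 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 300
    n_decoy_genes: int = 100
    triplets: tuple[TripletConfig, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.n_decoy_genes < 0:
            raise ValueError("n_decoy_genes must be >= 0")
        for t in self.triplets:
            t.validate()


@dataclass(frozen=True)
class TruthTable:
    """Planted triplets and the derived positive (M, TF) pair set."""

    records: tuple[tuple[str, str, str, str, float], ...]  # m, tf, tg, topology, beta

    @property
    def positive_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((m, tf) for m, tf, _, topo, _ in self.records if topo == "modulated")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["m_id", "tf_id", "tg_id", "topology", "beta"]
        )


def _stream(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, gene_index)))


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, TruthTable]:
    """Expression matrix with planted triplets plus decoys, and its ground truth."""
    spec.validate()
    n = spec.n_samples
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    records: list[tuple[str, str, str, str, float]] = []
    gidx = 0

    for t_i, cfg in enumerate(spec.triplets):
        m = _stream(spec.seed, gidx).standard_normal(n)
        gidx += 1
        z = _stream(spec.seed, gidx).standard_normal(n)
        gidx += 1
        tf = cfg.rho_mt * m + np.sqrt(1.0 - cfg.rho_mt**2) * z
        m_id, tf_id = f"M{t_i:04d}", f"TF{t_i:04d}"
        gene_ids += [m_id, tf_id]
        rows += [m, tf]
        gate = expit(GATE_STEEPNESS * m)  # logistic squash of M to [0, 1]
        for j in range(cfg.n_targets):
            eps = _stream(spec.seed, gidx).standard_normal(n)
            gidx += 1
            if cfg.topology == "modulated":
                tg = cfg.alpha * tf + cfg.beta * gate * tf + cfg.sigma * eps
            else:
                tg = cfg.alpha * tf + cfg.gamma * m + cfg.sigma * eps
            tg_id = f"TG{t_i:04d}_{j:03d}"
            gene_ids.append(tg_id)
            rows.append(tg)
            records.append((m_id, tf_id, tg_id, cfg.topology, cfg.beta))

    for j in range(spec.n_decoy_genes):
        rows.append(_stream(spec.seed, gidx).standard_normal(n))
        gidx += 1
        gene_ids.append(f"D{j:04d}")

    values = np.vstack(rows) if rows else np.empty((0, n))
    shuffle = np.random.default_rng(np.random.SeedSequence((spec.seed, 1 << 20)))
    order = shuffle.permutation(len(gene_ids))
    matrix = ExpressionMatrix(
        gene_ids=[gene_ids[i] for i in order],
        sample_ids=[f"S{k:04d}" for k in range(n)],
        values=values[order],
    )
    return matrix, TruthTable(records=tuple(records))


#: fixture presets: (n_samples, planted pairs, targets per pair, decoy-only
#: modulators, decoy genes).  `small` completes a full CINDy run in well under
#: two minutes on one CPU; `medium` matches the benchmark scale of 10 planted
#: pairs among 200 decoy (M, TF) combinations.
PRESETS = {
    "small": dict(n_samples=200, n_planted=3, n_targets=10, n_decoy_mods=4, n_decoys=50),
    "medium": dict(n_samples=300, n_planted=10, n_targets=50, n_decoy_mods=11, n_decoys=100),
}


def preset_spec(preset: str, seed: int = 0, rho_mt: float = 0.0) -> SyntheticSpec:
    try:
        p = PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}") from None
    triplets = tuple(
        TripletConfig(topology="modulated", rho_mt=rho_mt, n_targets=p["n_targets"])
        for _ in range(p["n_planted"])
    )
    return SyntheticSpec(
        n_samples=p["n_samples"],
        n_decoy_genes=p["n_decoys"],
        triplets=triplets,
        seed=seed,
    )


def fixture_gene_sets(matrix: ExpressionMatrix, truth: TruthTable, preset: str):
    """Modulator/TF/target sets for a generated fixture.

    Modulators are the planted ones plus decoy genes promoted to candidate
    modulators, so the tested pair universe contains planted and decoy pairs.
    """
    p = PRESETS[preset]
    planted_mods = sorted({m for m, *_ in truth.records})
    planted_tfs = sorted({tf for _, tf, *_ in truth.records})
    decoys = sorted(g for g in matrix.gene_ids if g.startswith("D"))[: p["n_decoy_mods"]]
    mods = GeneSet("modulator", frozenset(planted_mods + decoys))
    tfs = GeneSet("transcription_factor", frozenset(planted_tfs))
    targets = GeneSet(
        "target", frozenset(g for g in matrix.gene_ids if g.startswith("TG"))
    )
    return mods, tfs, targets


def make_benchmark_fixture(preset: str, seed: int = 0, outdir=".") -> dict[str, Path]:
    """Write a self-contained benchmark fixture to ``outdir``.

    Emits the expression matrix (TSV), modulator/TF/target lists, the gold
    standard (exactly the planted positive pairs), the full truth table and a
    config YAML; all parse back through the standard readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = preset_spec(preset, seed=seed)
    matrix, truth = generate(spec)
    mods, tfs, targets = fixture_gene_sets(matrix, truth, preset)

    paths = {
        "matrix": outdir / "matrix.tsv",
        "modulators": outdir / "modulators.txt",
        "tfs": outdir / "tfs.txt",
        "targets": outdir / "targets.txt",
        "gold": outdir / "gold.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    matrix.to_frame().to_csv(paths["matrix"], sep="\t")
    for key, gs in (("modulators", mods), ("tfs", tfs), ("targets", targets)):
        paths[key].write_text("".join(f"{g}\n" for g in gs))
    pos = sorted(truth.positive_pairs)
    paths["gold"].write_text("".join(f"{m}\t{tf}\n" for m, tf in pos))
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    cfg = {
        "preset": preset,
        "seed": seed,
        "n_samples": spec.n_samples,
        "n_decoy_genes": spec.n_decoy_genes,
        "triplets": [asdict(t) for t in spec.triplets],
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=False))
    return paths
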