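"""Readers and writers for expression matrices, gene lists, gold standards and result tables.

Expression matrices are tab-delimited text with gene identifiers in the first
column and sample identifiers in the header row (genes x samples), or the
two-header-line GCT dialect with a Description column.  Gene lists are one
symbol per line with ``#`` comments; gold standards are two-column TSV pair
files.  Identifier namespaces are the caller's responsibility: no symbol /
Entrez mapping is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ap import rank_transform

#: below this sample count rank-based CMI inference is unreliable
RECOMMENDED_MIN_SAMPLES = 150

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GoldStandard",
    "read_expression",
    "read_gene_list",
    "read_gold_standard",
    "write_pairs_table",
    "read_pairs_table",
    "write_triplets_table",
    "read_triplets_table",
]


class SmallSampleWarning(UserWarning):
    """Fewer samples than the recommended minimum for reliable inference."""


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with unique gene and sample identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    zero_variance_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain missing or non-finite entries")
        if self.n_samples < 3:
            raise ValueError(f"at least 3 samples required, got {self.n_samples}")
        if self.n_samples < RECOMMENDED_MIN_SAMPLES:
            warnings.warn(
                f"{self.n_samples} samples is below the recommended minimum of "
                f"{RECOMMENDED_MIN_SAMPLES} for reliable modulator inference",
                SmallSampleWarning,
                stacklevel=2,
            )
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def rank_matrix(self, seed: int = 0) -> tuple[dict[str, np.ndarray], set[str]]:
        """Per-gene strict ranks (tie-break streams keyed by seed and row index).

        Returns the ranks by gene id and the set of degenerate (constant) genes.
        """
        ranks: dict[str, np.ndarray] = {}
        degenerate: set[str] = set()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, g in enumerate(self.gene_ids):
                rv = rank_transform(self.values[i], seed=np.random.SeedSequence((seed, i)))
                ranks[g] = rv.values
                if rv.degenerate:
                    degenerate.add(g)
        return ranks, degenerate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneSet:
    """A deduplicated identifier set with its role in the analysis."""

    role: str  # modulator | transcription_factor | target
    ids: frozenset[str]

    ROLES = ("modulator", "transcription_factor", "target")

    def __post_init__(self):
        if self.role not in self.ROLES:
            raise ValueError(f"role must be one of {self.ROLES}, got {self.role!r}")
        if not self.ids:
            raise ValueError("gene set is empty")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(sorted(self.ids))


@dataclass(frozen=True)
class GoldStandard:
    """Known modulator/TF interactions; self-pairs excluded, duplicates collapsed."""

    pairs: frozenset[tuple[str, str]]
    source_labels: dict[tuple[str, str], str] | None = None

    def __post_init__(self):
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a!r}, {b!r}) in gold standard")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs


def _dedupe_gene_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene rows, keeping the highest-variance one."""
    if df.index.is_unique:
        return df
    variances = df.var(axis=1).to_numpy()
    keep = np.ones(len(df), dtype=bool)
    by_gene: dict[str, int] = {}
    for i, g in enumerate(df.index):
        j = by_gene.get(g)
        if j is None:
            by_gene[g] = i
        elif variances[i] > variances[j]:
            keep[j] = False
            by_gene[g] = i
        else:
            keep[i] = False
    return df.loc[keep]


def _check_header(path, header: list[str]) -> None:
    # validated on the raw line: the parser would silently rename duplicates
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate sample identifiers in header")


def read_expression(path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from TSV or GCT text.

    ``format`` is ``"tsv"``, ``"gct"`` or None (inferred from the suffix,
    defaulting to TSV).  Duplicate gene rows are collapsed by keeping the
    highest-variance row; zero-variance genes are retained but flagged
    (they carry no information for rank-based estimators).
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {format!r}")
    try:
        if format == "gct":
            with open(path) as fh:
                version = fh.readline()
                if not version.startswith("#1.2"):
                    raise ValueError(f"{path}: not a #1.2 GCT file")
                fh.readline()  # dimensions line
                header = fh.readline().rstrip("\n").split("\t")[2:]
                _check_header(path, header)
                df = pd.read_csv(fh, sep="\t", index_col=0, header=None)
                df.columns = ["Description", *header]
            df = df.drop(columns=df.columns[0])  # Description column
        else:
            with open(path) as fh:
                header = fh.readline().rstrip("\n").split("\t")[1:]
                _check_header(path, header)
                df = pd.read_csv(fh, sep="\t", index_col=0, header=None)
                df.columns = header
    except FileNotFoundError:
        raise
    df.index = df.index.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise ValueError(f"{path}: malformed numeric cell at row {row!r}, column {col!r}")
    if df.isna().any().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {df.index[loc[0]]!r}, column {df.columns[loc[1]]!r}"
        )
    df = _dedupe_gene_rows(df)
    values = df.to_numpy(dtype=float)
    zero_var = frozenset(df.index[values.var(axis=1) == 0.0])
    return ExpressionMatrix(
        gene_ids=list(df.index),
        sample_ids=[str(c) for c in df.columns],
        values=values,
        zero_variance_genes=zero_var,
    )


def read_gene_list(path, role: str) -> GeneSet:
    """Read a one-identifier-per-line gene list; ``#`` comments and blanks ignored."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                ids.add(token)
    if not ids:
        raise ValueError(f"{path}: no gene identifiers found")
    return GeneSet(role=role, ids=frozenset(ids))


def read_gold_standard(paths, symmetric: bool = True) -> GoldStandard:
    """Union of two-column (modulator, TF) pair files; self-pairs dropped.

    With ``symmetric`` (default) the reverse of every pair is inserted as
    well, matching undirected protein-protein interaction databases.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    pairs: set[tuple[str, str]] = set()
    labels: dict[tuple[str, str], str] = {}
    for path in paths:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.rstrip("\n")
                if not stripped.strip() or stripped.lstrip().startswith("#"):
                    continue
                cols = stripped.split("\t")
                if len(cols) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}"
                    )
                a, b = cols[0].strip(), cols[1].strip()
                if a == b:
                    continue  # homodimerization interactions are excluded
                new = [(a, b), (b, a)] if symmetric else [(a, b)]
                for p in new:
                    if p not in pairs:
                        pairs.add(p)
                        labels[p] = str(path)
    if not pairs:
        raise ValueError("gold standard is empty after filtering")
    return GoldStandard(pairs=frozenset(pairs), source_labels=labels)


PAIR_COLUMNS = ["m_id", "tf_id", "n_sig", "p", "q", "called"]
TRIPLET_COLUMNS = ["m_id", "tf_id", "tg_id", "mi", "cmi", "p", "significant"]


def write_pairs_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=[c for c in PAIR_COLUMNS if c in df.columns])


def read_pairs_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"m_id": str, "tf_id": str})


def write_triplets_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=[c for c in TRIPLET_COLUMNS if c in df.columns])


def read_triplets_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"m_id": str, "tf_id": str, "tg_id": str})
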