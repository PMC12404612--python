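"""Count-matrix containers, CPM normalization, gene filtering, and IO.

The central container is :class:`ExpressionMatrix`: genes x worms raw
counts with per-worm library sizes (column sums) and a lazily computed
counts-per-million layer.  CPM is plain counts-per-million —
``counts * 1e6 / library_size`` — without TMM effective-library-size
adjustment; a ``tmm`` flag is accepted for forward compatibility but
only the plain variant is implemented (the downstream models consume
plain CPM).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix", "GeneSetFilter", "cpm_normalize", "filter_genes",
    "log_transform_for_pca", "read_counts_tsv", "write_counts_tsv",
    "read_counts_mtx", "write_counts_mtx", "read_phenotypes", "write_phenotypes",
]

PHENOTYPE_COLUMNS = ["worm_id", "replicate", "parental_age", "early_temp",
                     "elo_hours", "early_brood"]


@dataclass
class ExpressionMatrix:
    """Genes x worms raw counts plus derived layers."""

    counts: pd.DataFrame  # genes x worms, nonnegative
    _cpm: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if not self.counts.columns.is_unique or not self.counts.index.is_unique:
            raise ValueError("duplicate gene or worm identifiers")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def worms(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def cpm(self) -> pd.DataFrame:
        if self._cpm is None:
            self._cpm = cpm_layer(self.counts)
        return self._cpm

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[list(genes)])


def cpm_layer(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for worm(s): {list(zero.index)}")
    return counts * 1e6 / lib


def cpm_normalize(expr: ExpressionMatrix | pd.DataFrame, tmm: bool = False) -> ExpressionMatrix:
    """Attach the counts-per-million layer (cpm = counts * 1e6 / libsize)."""
    if tmm:
        raise NotImplementedError("TMM effective library sizes are not implemented")
    if isinstance(expr, pd.DataFrame):
        expr = ExpressionMatrix(expr)
    expr._cpm = cpm_layer(expr.counts)
    return expr


@dataclass
class GeneSetFilter:
    rule: str
    threshold: float
    genes: list

    def __post_init__(self):
        if self.rule not in ("any_gt", "all_gt"):
            raise ValueError(f"unknown filter rule {self.rule!r}")


def filter_worms(expr: ExpressionMatrix, min_library_size: float = 0.0) -> ExpressionMatrix:
    """Drop worms below a minimum library size (default 0: gate off).

    Upstream read-level QC happens before the count matrix; this is only
    a coarse guard against near-empty libraries slipping through.
    """
    keep = expr.library_sizes >= min_library_size
    if keep.all():
        return expr
    return cpm_normalize(ExpressionMatrix(expr.counts.loc[:, keep]))


def filter_genes(expr: ExpressionMatrix, rule: str, threshold: float) -> GeneSetFilter:
    """Expression filters with strict inequalities.

    ``any_gt``: keep genes whose CPM exceeds the threshold in at least
    one worm (used for the trait-association scan, CPM > 10).
    ``all_gt``: keep genes whose CPM exceeds the threshold in every worm
    (used where zeros break model fitting, CPM > 1).
    """
    cpm = expr.cpm
    if rule == "any_gt":
        keep = cpm.max(axis=1) > threshold
    elif rule == "all_gt":
        keep = cpm.min(axis=1) > threshold
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    return GeneSetFilter(rule=rule, threshold=threshold,
                         genes=list(cpm.index[keep]))


def log_transform_for_pca(expr: ExpressionMatrix, gene_set=None,
                          pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene mean-normalized log2 CPM: log2((cpm + eps) / mean(cpm + eps)).

    The pseudocount guards all-zero observations; the order (divide by
    gene mean, then log2) makes the transform invariant to per-gene
    rescaling.  Rows are genes, columns worms.
    """
    cpm = expr.cpm if gene_set is None else expr.cpm.loc[list(gene_set)]
    if cpm.shape[0] == 0:
        raise ValueError("empty gene set")
    shifted = cpm + pseudocount
    means = shifted.mean(axis=1)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"non-positive mean CPM for genes: {bad[:5]}")
    return np.log2(shifted.div(means, axis=0))


# ----------------------------------------------------------------------
# IO
# ----------------------------------------------------------------------

def read_counts_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_counts_tsv(expr: ExpressionMatrix, path) -> None:
    expr.counts.to_csv(path, sep="\t", index_label="gene")


def write_counts_mtx(expr: ExpressionMatrix, prefix) -> None:
    """MatrixMarket triplet with `<prefix>.mtx`, `<prefix>.genes.txt`, `<prefix>.worms.txt`."""
    from scipy import io as spio
    from scipy import sparse
    spio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(expr.counts.values))
    with open(f"{prefix}.genes.txt", "w") as fh:
        fh.write("\n".join(map(str, expr.genes)) + "\n")
    with open(f"{prefix}.worms.txt", "w") as fh:
        fh.write("\n".join(map(str, expr.worms)) + "\n")


def read_counts_mtx(prefix) -> ExpressionMatrix:
    from scipy import io as spio
    mat = spio.mmread(f"{prefix}.mtx").toarray()
    genes = open(f"{prefix}.genes.txt").read().split()
    worms = open(f"{prefix}.worms.txt").read().split()
    return ExpressionMatrix(pd.DataFrame(mat, index=genes, columns=worms))


def validate_phenotypes(pheno: pd.DataFrame, elo_window=(60, 80)) -> pd.DataFrame:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if pheno["worm_id"].duplicated().any():
        raise ValueError("duplicate worm_id")
    for col in ("parental_age", "early_temp"):
        vals = set(pheno[col].dropna().unique())
        if not vals <= {0, 1}:
            raise ValueError(f"{col} must be binary 0/1, got {sorted(vals)}")
    elo = pheno["elo_hours"].dropna()
    if len(elo) and ((elo < elo_window[0]) | (elo > elo_window[1])).any():
        raise ValueError(f"elo_hours outside window {elo_window}")
    if (pheno["early_brood"].dropna() < 0).any():
        raise ValueError("negative early_brood")
    return pheno


def read_phenotypes(path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_phenotypes(df) if validate else df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)
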