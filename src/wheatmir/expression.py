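"""miRNA expression profiling across tissue libraries.

Raw per-library counts are normalised to RP10M (reads per ten million
mapped reads), the unit used for cross-tissue comparisons of sRNA
abundance.  On top of the normalised matrix the module provides Welch
t-tests on log-transformed abundances (e.g. 21 vs 22 nt size-class
comparisons between seed and non-seed tissues), threshold-based calls of
tissue-preferential / tissue-specific / silenced miRNAs, 5'-terminal
nucleotide composition by length (21 nt miRNAs are expected U-biased,
24 nt A-biased), and average-linkage hierarchical clustering on
1 - Pearson correlation of log2(RP10M + 1) profiles for heatmap layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def normalize_rp10m(counts: pd.DataFrame,
                    mapped_totals: Mapping[str, int] | pd.Series | None = None
                    ) -> pd.DataFrame:
    """Scale each library column to reads per 10 million mapped reads.

    ``mapped_totals`` gives the per-library mapped-read totals; when
    omitted, column sums of ``counts`` are used (i.e. the matrix is the
    full tag set).  Zero or missing totals raise ``ValueError``.
    """
    if mapped_totals is None:
        totals = counts.sum(axis=0)
    else:
        totals = pd.Series(mapped_totals)
    missing = [c for c in counts.columns if c not in totals.index]
    if missing:
        raise ValueError(f"missing mapped totals for libraries: {missing}")
    totals = totals.loc[counts.columns].astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"non-positive mapped totals for: {bad}")
    return counts / totals * 1e7


def group_abundance_test(group_a: Sequence[float],
                         group_b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t-test on log10(x+1)-transformed abundances.

    Returns (t statistic, two-sided p).  Degenerate input with zero
    variance in both groups and equal means yields (0, 1).
    """
    a = np.log10(np.asarray(group_a, dtype=float) + 1.0)
    b = np.log10(np.asarray(group_b, dtype=float) + 1.0)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def call_tissue_preferential(
    matrix: pd.DataFrame,
    target_libraries: Sequence[str],
    on_threshold: float = 10.0,
    off_threshold: float = 1.0,
    fold: float = 10.0,
) -> dict[str, str]:
    """Label miRNAs as preferential/specific/silenced for a tissue set.

    * preferential: mean RP10M over the target libraries >= on_threshold
      and >= ``fold`` times the maximum outside;
    * specific: preferential and the maximum outside <= off_threshold;
    * silenced: <= off_threshold in every target library while reaching
      >= on_threshold in some other library.

    Rows matching no rule are omitted from the result.
    """
    targets = list(target_libraries)
    if not targets:
        raise ValueError("target library set is empty")
    others = [c for c in matrix.columns if c not in targets]
    if not others:
        raise ValueError("target set must not cover every library")
    missing = [t for t in targets if t not in matrix.columns]
    if missing:
        raise ValueError(f"unknown libraries: {missing}")
    labels: dict[str, str] = {}
    inside = matrix[targets]
    outside = matrix[others]
    for mirna in matrix.index:
        mean_in = float(inside.loc[mirna].mean())
        max_in = float(inside.loc[mirna].max())
        max_out = float(outside.loc[mirna].max())
        if mean_in >= on_threshold and mean_in >= fold * max_out:
            labels[mirna] = ("specific" if max_out <= off_threshold
                             else "preferential")
        elif max_in <= off_threshold and max_out >= on_threshold:
            labels[mirna] = "silenced"
    return labels


def first_nucleotide_bias(
    sequences: Mapping[str, str] | Sequence[str],
    abundances: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-length fractions of the 5'-terminal nucleotide (RNA alphabet).

    Computed on unique sequences by default, or abundance-weighted when
    per-sequence ``abundances`` are given (keyed like ``sequences``).
    Rows are lengths, columns A/C/G/U, each row summing to 1.
    """
    if isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = [(s, s) for s in sequences]
    if not items:
        raise ValueError("no sequences")
    table: dict[int, dict[str, float]] = {}
    for key, seq in items:
        seq = seq.upper().replace("U", "T")
        first = seq[0].replace("T", "U")
        weight = 1.0 if abundances is None else float(abundances[key])
        row = table.setdefault(len(seq), {b: 0.0 for b in "ACGU"})
        row[first] += weight
    df = pd.DataFrame.from_dict(table, orient="index").sort_index()
    df = df[["A", "C", "G", "U"]]
    return df.div(df.sum(axis=1), axis=0)


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    n_constant_rows: int = 0
    n_constant_cols: int = 0


def _corr_distance(data: np.ndarray) -> tuple[np.ndarray, int]:
    """Pairwise 1 - Pearson distances between rows; constant rows get
    maximal distance (2.0) to everything else."""
    n = data.shape[0]
    sd = data.std(axis=1)
    constant = sd == 0
    dist = np.full((n, n), 2.0)
    np.fill_diagonal(dist, 0.0)
    ok = ~constant
    if ok.sum() >= 2:
        sub = data[ok]
        corr = np.corrcoef(sub)
        d = 1.0 - corr
        idx = np.where(ok)[0]
        dist[np.ix_(idx, idx)] = np.clip(d, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
    return dist, int(constant.sum())


def cluster_expression(matrix: pd.DataFrame,
                       row_zscore: bool = False) -> ClusterResult:
    """Average-linkage hierarchical clustering of rows and columns.

    Distance is 1 - Pearson correlation on log2(RP10M + 1); constant
    profiles (undefined correlation) are assigned the maximal distance
    and counted in the result.  Leaf order is deterministic (scipy's
    ordering with input-order tie-breaking).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix to cluster")
    data = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    if row_zscore:
        mu = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data = (data - mu) / sd
    rd, n_const_rows = _corr_distance(data)
    cd, n_const_cols = _corr_distance(data.T)
    row_link = hierarchy.linkage(squareform(rd, checks=False), method="average")
    col_link = hierarchy.linkage(squareform(cd, checks=False), method="average")
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterResult(row_linkage=row_link, col_linkage=col_link,
                         row_order=row_order, col_order=col_order,
                         n_constant_rows=n_const_rows,
                         n_constant_cols=n_const_cols)


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = walk(node.get_left())
        right = walk(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return walk(tree) + ";"
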