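"""Differential-expression integration by cross-dataset vote counting.

Each dataset contributes a DE result table (gene, log2 fold change, raw and
BH-adjusted p).  A gene is called significant in a dataset when
``|logFC| > 1`` and ``p_adj < 0.05`` (both strict).  The frequency score
``s_g`` of a gene is the number of datasets in which it is significant —
a gene differentially expressed in four studies scores 4, a never-significant
gene scores 0.  The dual-evidence filter then defines the regulon-enrichment
query set: genes significant in at least two datasets, plus genes significant
in exactly one dataset that carry independent literature evidence of an
IMiD-induced alteration.

Upstream normalization and model fitting (RMA/VSN/TMM, batch correction,
limma/edgeR) are deliberately out of scope: real studies supply precomputed
DE tables.  :func:`call_de_simple` is a plain Welch two-group test on log2
values, provided so fully synthetic expression matrices can be pushed
through the same interface end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tfdegrome._util import canon, pct_one_decimal

DE_COLUMNS = ("gene", "lfc", "p_raw", "p_adj")

LFC_THRESHOLD = 1.0
ALPHA_DE = 0.05


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de_simple(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    dataset_id: str = "",
) -> pd.DataFrame:
    """Two-group DE on a genes x samples matrix of log2 expression values.

    Per gene: ``lfc`` = mean(case) - mean(control); ``p_raw`` from a
    two-sided Welch (unequal-variance) t-test; ``p_adj`` by BH over all
    genes in the dataset.  Genes with zero variance in both groups get
    ``p_raw = 1`` and ``zero_variance = True``.

    ``groups`` labels the columns with ``"case"`` / ``"control"``; each group
    needs at least two samples.
    """
    groups = [g.strip().lower() for g in groups]
    if len(groups) != matrix.shape[1]:
        raise ValueError("group labels do not match the number of sample columns")
    bad = set(groups) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene rows in expression matrix")
    case = matrix.loc[:, [g == "case" for g in groups]].to_numpy(dtype=float)
    ctrl = matrix.loc[:, [g == "control" for g in groups]].to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("each group needs at least two samples")

    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant genes trigger a precision warning; they are handled
        # below via the zero-variance flag
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p_raw = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    zero_var = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    p_raw = np.where(zero_var, 1.0, p_raw)
    out = pd.DataFrame(
        {
            "gene": [canon(g) for g in matrix.index],
            "lfc": lfc,
            "p_raw": p_raw,
            "p_adj": benjamini_hochberg(p_raw),
            "zero_variance": zero_var,
        }
    )
    if dataset_id:
        out["dataset_id"] = dataset_id
    return out


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a per-dataset DE table (``gene  lfc  p_raw  p_adj``)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    df["gene"] = df["gene"].map(canon)
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(DE_COLUMNS)].to_csv(path, sep="\t", index=False)


def filter_significant(
    records: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA_DE,
) -> set[str]:
    """Genes with ``|lfc| > lfc_threshold`` and ``p_adj < alpha``.

    Both inequalities are strict, so boundary cases (|lfc| exactly 1,
    p_adj exactly 0.05) are excluded.
    """
    keep = (records["lfc"].abs() > lfc_threshold) & (records["p_adj"] < alpha)
    return {canon(g) for g in records.loc[keep, "gene"]}


def frequency_scores(
    significant: Mapping[str, Iterable[str]] | Iterable[tuple[str, Iterable[str]]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Vote-count across datasets: per gene, the number of datasets in which
    it was significant and the sorted list of those dataset ids.

    With a ``universe``, genes never significant anywhere are materialized
    with score 0 (needed for genome-wide summaries and for GSEA ranking);
    without one, only scored genes appear.
    """
    pairs = (
        list(significant.items())
        if isinstance(significant, Mapping)
        else list(significant)
    )
    ids = [ds for ds, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset ids")
    hits: dict[str, set[str]] = {}
    for ds, genes in pairs:
        for g in genes:
            hits.setdefault(canon(g), set()).add(ds)
    if universe is not None:
        for g in universe:
            hits.setdefault(canon(g), set())
    rows = [
        (g, len(ds_ids), ",".join(sorted(ds_ids)))
        for g, ds_ids in hits.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "score", "dataset_ids"])
    return df.sort_values(["score", "gene"], ascending=[False, True]).reset_index(
        drop=True
    )


@dataclass(frozen=True)
class CumulativeRow:
    k: int
    count: int
    fraction: float
    pct: float


def cumulative_summary(scores: pd.DataFrame, genome_size: int) -> pd.DataFrame:
    """For k = 1..max score, the number of genes significant in >= k datasets
    and its share of the genome (half-even, one decimal; the raw fraction is
    kept in the ``fraction`` column)."""
    nonzero = scores.loc[scores["score"] > 0, "score"]
    n_scored = (scores["score"] > 0).sum()
    if genome_size < len(scores):
        raise ValueError(
            f"genome_size {genome_size} smaller than the {len(scores)} scored genes"
        )
    max_k = int(nonzero.max()) if len(nonzero) else 0
    rows = []
    for k in range(1, max_k + 1):
        count = int((nonzero >= k).sum())
        rows.append(
            CumulativeRow(
                k=k,
                count=count,
                fraction=count / genome_size,
                pct=pct_one_decimal(count, genome_size),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows], columns=["k", "count", "fraction", "pct"])
    df.attrs["genome_size"] = genome_size
    df.attrs["n_scored"] = int(n_scored)
    return df


def dual_evidence_filter(
    scores: pd.DataFrame,
    literature_genes: Iterable[str],
) -> set[str]:
    """The regulon-enrichment query set: genes significant in >= 2 datasets,
    or in exactly 1 dataset with independent literature evidence.  Literature
    genes never significant in any dataset are ruled out."""
    lit = {canon(g) for g in literature_genes}
    by_gene = dict(zip(scores["gene"].map(canon), scores["score"]))
    keep = set()
    for gene, score in by_gene.items():
        if score >= 2 or (score == 1 and gene in lit):
            keep.add(gene)
    return keep
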