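"""Over-representation, frequency-ranked GSEA, and regulon enrichment.

Three enrichment routes share the hypergeometric upper tail:

* :func:`ora` — classical over-representation of a query gene set against a
  GMT collection, BH-corrected across sets;
* :func:`gsea` — gene-set enrichment analysis on the vote-count metric: the
  full gene universe ranked by the number of datasets in which each gene was
  differentially expressed (score 0 for never-significant genes), with a
  weighted Kolmogorov-Smirnov running score and a gene-label permutation
  null;
* :func:`regulon_enrichment` — the TF screen: for each regulon, the overlap
  with the query set is tested against the hypergeometric upper tail; TFs
  with raw p < alpha are kept (a BH column is reported alongside for a
  stricter reading) and ranked by overlap size, then p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from tfdegrome._util import canon
from tfdegrome.dge import benjamini_hochberg
from tfdegrome.tables import GeneSet, Regulon

logger = logging.getLogger(__name__)

ALPHA = 0.05


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for drawing n items
    from a universe of N containing K marked items."""
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def _resolve_universe(
    sets: Sequence[GeneSet], query: set[str], universe: Iterable[str] | None
) -> set[str]:
    if universe is not None:
        return {canon(g) for g in universe}
    out = set(query)
    for s in sets:
        out |= {canon(m) for m in s.members}
    return out


def ora(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe before testing; sets left empty
    are not tested.  BH correction is applied across the tested sets and
    results are sorted by raw p.  The default universe is the union of all
    set members and the query.
    """
    query = {canon(g) for g in query}
    uni = _resolve_universe(sets, query, universe)
    stray = query - uni
    if stray:
        raise ValueError(
            "query symbols outside the universe: " + ", ".join(sorted(stray))
        )
    N, n = len(uni), len(query)
    rows = []
    for s in sets:
        members = {canon(m) for m in s.members} & uni
        if not members:
            continue
        overlap = members & query
        k, K = len(overlap), len(members)
        rows.append(
            {
                "set_id": s.set_id,
                "name": s.name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper(k, K, n, N),
                "members": ",".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["set_id", "name", "k", "K", "n", "N", "p", "members"]
    )
    if len(df):
        df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
        df["significant"] = df["p_adj"] < alpha
        df = df.sort_values(["p", "set_id"]).reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


@dataclass
class GseaResult:
    set_id: str
    es: float
    nes: float
    p_perm: float
    running_profile: np.ndarray = field(repr=False)
    p_adj: float = float("nan")


def _running_scores(
    in_set: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted KS running sum over a ranked list.

    ``in_set`` marks hit positions; hit increments are proportional to the
    rank weight (score**weight), miss decrements are uniform.  The profile
    ends at 0 by construction (mass balance).
    """
    hit_mass = weights * in_set
    total_hit = hit_mass.sum()
    n_miss = int((~in_set.astype(bool)).sum())
    inc = np.where(in_set, hit_mass / total_hit, -1.0 / n_miss)
    return np.cumsum(inc)


def _es_from_profile(profile: np.ndarray) -> float:
    i = int(np.argmax(np.abs(profile)))
    return float(profile[i])


def gsea(
    scores: Mapping[str, float] | pd.DataFrame,
    sets: Sequence[GeneSet],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    tie_shuffle: bool = False,
) -> list[GseaResult]:
    """Frequency-ranked GSEA with a gene-label permutation null.

    ``scores`` covers the full gene universe (score 0 included).  The ranked
    list orders genes by (score descending, symbol ascending); with
    ``tie_shuffle`` ties are instead shuffled with the given seed.  The
    enrichment score is the signed extremum of the running profile; the
    permutation p-value uses (1 + exceedances) / (1 + n_perm) on the ES
    sign side, and NES divides ES by the mean |permuted ES| of the same
    sign.  Sets with no member in the universe, with no miss, or with zero
    total hit mass are skipped with a warning.  BH is applied across the
    scored sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if isinstance(scores, pd.DataFrame):
        score_map = dict(zip(scores["gene"].map(canon), scores["score"]))
    else:
        score_map = {canon(g): float(s) for g, s in scores.items()}
    genes = np.array(sorted(score_map, key=lambda g: (-score_map[g], g)))
    values = np.array([score_map[g] for g in genes], dtype=float)
    rng = np.random.default_rng(seed)
    if tie_shuffle:
        order = np.lexsort((rng.random(len(genes)), -values))
        genes, values = genes[order], values[order]
    weights = np.abs(values) ** weight
    universe = set(genes)
    index = {g: i for i, g in enumerate(genes)}

    results: list[GseaResult] = []
    for s in sets:
        members = {canon(m) for m in s.members} & universe
        if not members:
            logger.warning("GSEA: set %s has no member in the universe; skipped", s.set_id)
            continue
        if len(members) == len(universe):
            logger.warning("GSEA: set %s covers the whole universe; skipped", s.set_id)
            continue
        in_set = np.zeros(len(genes), dtype=bool)
        in_set[[index[g] for g in members]] = True
        if weights[in_set].sum() == 0:
            logger.warning("GSEA: set %s has zero hit mass; skipped", s.set_id)
            continue
        profile = _running_scores(in_set, weights)
        es = _es_from_profile(profile)

        n_hit = int(in_set.sum())
        perm_es = np.empty(n_perm)
        for j in range(n_perm):
            perm = np.zeros(len(genes), dtype=bool)
            perm[rng.choice(len(genes), size=n_hit, replace=False)] = True
            if weights[perm].sum() == 0:
                perm_es[j] = 0.0
                continue
            perm_es[j] = _es_from_profile(_running_scores(perm, weights))
        if es >= 0:
            exceed = int((perm_es >= es).sum())
            side = perm_es[perm_es >= 0]
        else:
            exceed = int((perm_es <= es).sum())
            side = -perm_es[perm_es < 0]
        p_perm = (1 + exceed) / (1 + n_perm)
        denom = float(np.mean(np.abs(side))) if len(side) else float("nan")
        nes = es / denom if denom and denom > 0 else float("nan")
        results.append(
            GseaResult(
                set_id=s.set_id, es=es, nes=nes, p_perm=p_perm,
                running_profile=profile,
            )
        )
    if results:
        adj = benjamini_hochberg([r.p_perm for r in results])
        for r, a in zip(results, adj):
            r.p_adj = float(a)
    return results


def regulon_enrichment(
    query: Iterable[str],
    regulons: Sequence[Regulon],
    universe: Iterable[str],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """The TF screen: hypergeometric upper-tail enrichment of each regulon
    in the query set.

    Returns TFs with raw p strictly below ``alpha`` (zero-overlap TFs have
    p = 1 and drop out), ranked by overlap size descending, ties by p
    ascending then symbol.  ``p_adj`` (BH across all tested TFs) is reported
    for the stricter multiplicity-corrected reading.
    """
    if not regulons:
        raise ValueError("empty regulon database")
    query = {canon(g) for g in query}
    uni = {canon(g) for g in universe}
    stray = query - uni
    if stray:
        raise ValueError(
            "query symbols outside the universe: " + ", ".join(sorted(stray))
        )
    N, n = len(uni), len(query)
    rows = []
    for reg in regulons:
        targets = {canon(t) for t in reg.targets} & uni
        if not targets:
            continue
        overlap = targets & query
        k, K = len(overlap), len(targets)
        rows.append(
            {
                "tf": reg.tf,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper(k, K, n, N),
                "targets": ",".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(rows, columns=["tf", "k", "K", "n", "N", "p", "targets"])
    if len(df):
        df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
    else:
        df["p_adj"] = pd.Series(dtype=float)
    kept = df[df["p"] < alpha].copy()
    kept = kept.sort_values(
        ["k", "p", "tf"], ascending=[False, True, True]
    ).reset_index(drop=True)
    kept.attrs["n_tested"] = len(df)
    kept.attrs["n_significant_adj"] = int((df["p_adj"] < alpha).sum()) if len(df) else 0
    return kept
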