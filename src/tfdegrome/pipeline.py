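"""Candidate classification and end-to-end pipeline orchestration.

The enriched-TF set T (regulon enrichment output) is classified against the
literature protein set L (distinct protein-level targets from the evidence
table) and the C2H2 zinc-finger list Z:

* T ∩ Z ∩ L — known C2H2 TFs already reported as IMiD-affected;
* T ∩ L \\ Z — known non-C2H2 TFs;
* T ∩ Z \\ L — **novel C2H2 candidates**, the prioritization focus;
* remaining T — other.

Novel candidates are then filtered by over-representation in
embryonic-development gene sets, and both protein networks (literature-only,
and augmented with the novel TFs) are ranked for essentiality.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from tfdegrome import dge, enrich, network
from tfdegrome import tables as tb

logger = logging.getLogger(__name__)

VENN_REGIONS = ("LTZ", "LT", "LZ", "TZ", "L", "T", "Z")

_CLASS_BY_REGION = {
    "LTZ": "known_C2H2",
    "LT": "known_nonC2H2",
    "TZ": "novel_C2H2",
    "T": "other",
}

_CLASS_PRIORITY = {"known_C2H2": 0, "novel_C2H2": 1, "known_nonC2H2": 2, "other": 3}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def venn_partition(
    L: Iterable[str], T: Iterable[str], Z: Iterable[str]
) -> dict[str, set[str]]:
    """The seven disjoint regions of the three-set Venn diagram over the
    literature proteins L, enriched TFs T, and C2H2 list Z.

    Region keys name the sets a member belongs to: ``"LTZ"`` is the center,
    ``"T"`` is T-only, and so on.  The union of the regions is L ∪ T ∪ Z.
    """
    L, T, Z = set(L), set(T), set(Z)
    return {
        "LTZ": L & T & Z,
        "LT": (L & T) - Z,
        "LZ": (L & Z) - T,
        "TZ": (T & Z) - L,
        "L": L - T - Z,
        "T": T - L - Z,
        "Z": Z - L - T,
    }


def classify_candidates(
    enriched: pd.DataFrame,
    L: Iterable[str],
    Z: Iterable[str],
) -> pd.DataFrame:
    """Assign each enriched TF its Venn region and candidate class."""
    L, Z = set(L), set(Z)
    regions = venn_partition(L, set(enriched["tf"]), Z)
    region_of = {tf: r for r, members in regions.items() for tf in members}
    out = enriched.copy()
    out["venn_region"] = out["tf"].map(lambda tf: region_of.get(tf, "T"))
    out["candidate_class"] = out["venn_region"].map(
        lambda r: _CLASS_BY_REGION.get(r, "other")
    )
    out = out.rename(columns={"k": "regulon_overlap_k"})
    return out


def embryonic_filter(
    candidates: pd.DataFrame,
    dev_sets: Sequence[tb.GeneSet],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ORA of the novel-C2H2 candidate list against development gene sets.

    A candidate gets ``dev_ontology_hit = True`` when it belongs to at least
    one set significant at BH < alpha; only hits survive into the prioritized
    output, but the full annotated table is returned for the report.  With no
    development sets the filter is skipped (everything passes, flagged)."""
    out = candidates.copy()
    novel = out[out["candidate_class"] == "novel_C2H2"]
    if not dev_sets:
        logger.warning("no development gene sets supplied; embryonic filter skipped")
        out["dev_ontology_hit"] = pd.NA
        return out, pd.DataFrame()
    if novel.empty:
        out["dev_ontology_hit"] = False
        return out.iloc[0:0], pd.DataFrame()
    ora_table = enrich.ora(set(novel["tf"]), list(dev_sets), universe=universe, alpha=alpha)
    significant_sets = set(ora_table.loc[ora_table["significant"], "set_id"])
    members: set[str] = set()
    for s in dev_sets:
        if s.set_id in significant_sets:
            members |= s.members
    out["dev_ontology_hit"] = out.apply(
        lambda row: row["candidate_class"] == "novel_C2H2" and row["tf"] in members,
        axis=1,
    )
    prioritized = out[out["dev_ontology_hit"] == True]  # noqa: E712
    return prioritized.reset_index(drop=True), ora_table


def final_report(
    candidates: pd.DataFrame,
    centralities_before: pd.DataFrame,
    essential_before: set[str],
    centralities_after: pd.DataFrame,
    essential_after: set[str],
    freq_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join candidate classes with pre/post-augmentation centrality ranks.

    Sorting: class priority (known_C2H2, novel_C2H2, known_nonC2H2, other),
    then regulon overlap descending.  The essential flag reads
    ``both`` / ``before`` / ``after`` / empty."""
    out = candidates.copy()
    if out.empty:
        return out

    def _join(cent: pd.DataFrame, suffix: str) -> None:
        lookup = cent.set_index("node")
        for m in network.METRICS:
            out[f"{m}_{suffix}"] = out["tf"].map(
                lambda v: lookup[m].get(v) if v in lookup.index else pd.NA
            )
            out[f"rank_{m}_{suffix}"] = out["tf"].map(
                lambda v: lookup[f"rank_{m}"].get(v) if v in lookup.index else pd.NA
            )

    _join(centralities_before, "before")
    _join(centralities_after, "after")

    def _flag(tf: str) -> str:
        before, after = tf in essential_before, tf in essential_after
        if before and after:
            return "both"
        if before:
            return "before"
        if after:
            return "after"
        return ""

    out["essential"] = out["tf"].map(_flag)
    out["_prio"] = out["candidate_class"].map(_CLASS_PRIORITY)
    out = out.sort_values(
        ["_prio", "regulon_overlap_k", "tf"], ascending=[True, False, True]
    ).drop(columns=["_prio"])
    return out.reset_index(drop=True)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Thresholds default to the study values: |logFC| > 1 and adjusted
    p < 0.05 for per-dataset DE, interaction score > 0.400, raw regulon
    p < 0.05 for the TF screen, BH < 0.05 for development ORA.
    """

    evidence: Path
    de_dir: Path
    edges: Path
    regulons: Path
    tf_annotations: Path
    dev_sets: Path
    outdir: Path
    universe: Path | None = None
    lfc: float = 1.0
    alpha_de: float = 0.05
    string_score: float = 0.400
    alpha_tf: float = 0.05
    alpha_ora: float = 0.05
    n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in ("lfc", "alpha_de", "string_score", "alpha_tf", "alpha_ora"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


_PATH_KEYS = (
    "evidence", "de_dir", "edges", "regulons", "tf_annotations",
    "dev_sets", "universe", "outdir",
)
_FLOAT_KEYS = ("lfc", "alpha_de", "string_score", "alpha_tf", "alpha_ora")
_INT_KEYS = ("n_perm", "seed")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key: value`` config file; relative paths resolve
    against the config file's directory."""
    path = Path(path)
    raw: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}: malformed config line {line!r}")
        key, value = line.split(":", 1)
        raw[key.strip()] = value.strip()
    kwargs: dict = {}
    base = path.parent
    for key, value in raw.items():
        if key in _PATH_KEYS:
            kwargs[key] = base / value
        elif key in _FLOAT_KEYS:
            kwargs[key] = float(value)
        elif key in _INT_KEYS:
            kwargs[key] = int(value)
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    summary: dict
    report: pd.DataFrame
    candidates: pd.DataFrame
    enriched: pd.DataFrame
    freq_scores: pd.DataFrame
    centralities_before: pd.DataFrame
    essential_before: set[str]
    centralities_after: pd.DataFrame
    essential_after: set[str]
    dev_ora: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write each intermediate table.

    Stages: evidence ingest -> per-dataset DE filter -> frequency scoring ->
    dual-evidence query -> regulon enrichment -> classification ->
    embryonic-development filter -> networks before/after augmentation ->
    final report.  Every random stage derives from ``config.seed``; two runs
    with identical config and inputs produce byte-identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    def _stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise StageError(name, str(exc)) from exc

    # 1. evidence
    evidence = _stage("evidence", tb.read_evidence_table, config.evidence)
    ev_summary = tb.summarize_evidence(evidence)
    tb.write_report(ev_summary.as_dict(), outdir / "evidence_summary.json")
    lit_genes = evidence.targets("gene")
    lit_proteins = evidence.targets("protein")
    summary["evidence_entries"] = ev_summary.total
    summary["evidence_by_drug"] = ev_summary.by_drug
    summary["lit_gene_targets"] = len(lit_genes)
    summary["lit_protein_targets"] = len(lit_proteins)
    logger.info("evidence: %d entries", ev_summary.total)

    # 2. per-dataset DE tables + significance filter
    de_dir = Path(config.de_dir)
    de_files = sorted(de_dir.glob("*.tsv"))
    if not de_files:
        raise StageError("de_filter", f"no DE tables found in {de_dir}")
    significant: dict[str, set[str]] = {}
    for f in de_files:
        ds = f.stem
        records = _stage("de_filter", dge.read_de_table, f)
        significant[ds] = dge.filter_significant(
            records, lfc_threshold=config.lfc, alpha=config.alpha_de
        )
    summary["n_datasets"] = len(significant)
    summary["significant_per_dataset"] = {k: len(v) for k, v in significant.items()}

    # 3. frequency scores (+ genome universe when supplied)
    universe: list[str] | None = None
    if config.universe is not None:
        universe = [
            tb.canon(line)
            for line in Path(config.universe).read_text().splitlines()
            if line.strip()
        ]
    freq = _stage("frequency", dge.frequency_scores, significant, universe)
    freq.to_csv(outdir / "frequency_scores.tsv", sep="\t", index=False)
    if universe is not None:
        cum = dge.cumulative_summary(freq, genome_size=len(universe))
        cum.to_csv(outdir / "cumulative_summary.tsv", sep="\t", index=False)
        summary["de_genes_ge1"] = int(cum.loc[cum["k"] == 1, "count"].iloc[0]) if len(cum) else 0

    # 4. dual-evidence query set
    query = _stage("dual_evidence", dge.dual_evidence_filter, freq, lit_genes)
    (outdir / "query_genes.txt").write_text("\n".join(sorted(query)) + "\n")
    summary["query_size"] = len(query)
    logger.info("dual-evidence query set: %d genes", len(query))

    # 5. regulon enrichment
    regulons = _stage("regulon_enrichment", tb.read_regulons, config.regulons)
    if universe is None:
        uni = set(query)
        for r in regulons:
            uni |= {tb.canon(t) for t in r.targets}
            uni.add(r.tf)
    else:
        uni = set(universe)
    enriched = _stage(
        "regulon_enrichment",
        enrich.regulon_enrichment,
        query, regulons, uni, config.alpha_tf,
    )
    enriched.to_csv(outdir / "regulon_enrichment.tsv", sep="\t", index=False)
    summary["enriched_tfs"] = len(enriched)
    summary["enriched_tfs_bh"] = enriched.attrs.get("n_significant_adj")

    # 6. classification (Venn over L = protein-level literature targets,
    #    T = enriched TFs, Z = C2H2 list)
    annotations = _stage("classification", tb.read_tf_annotations, config.tf_annotations)
    Z = tb.c2h2_symbols(annotations)
    T = set(enriched["tf"])
    venn = venn_partition(lit_proteins, T, Z)
    summary["venn"] = {region: len(members) for region, members in venn.items()}
    candidates = classify_candidates(enriched, lit_proteins, Z)
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    summary["candidate_classes"] = (
        candidates["candidate_class"].value_counts().to_dict()
    )

    # 7. embryonic-development filter; the ORA background is the full
    #    annotated TF list (plus any stray query symbols)
    dev_sets = _stage("dev_filter", tb.read_gmt, config.dev_sets)
    tf_universe = {a.symbol for a in annotations} | T
    for s in dev_sets:
        tf_universe |= s.members
    prioritized, dev_ora = _stage(
        "dev_filter", embryonic_filter, candidates, dev_sets, tf_universe, config.alpha_ora
    )
    if len(dev_ora):
        dev_ora.to_csv(outdir / "dev_ora.tsv", sep="\t", index=False)
    summary["novel_c2h2_prioritized"] = int(
        (prioritized["candidate_class"] == "novel_C2H2").sum()
    ) if len(prioritized) else 0

    # 8. networks before/after augmentation
    edges = _stage(
        "network", tb.read_string_edges, config.edges, config.string_score
    )
    g_before, unconnected = _stage("network", network.build_graph, edges, lit_proteins)
    if g_before.number_of_nodes() == 0:
        raise StageError("network", "no literature protein has a qualifying edge")
    g_main, excluded = network.main_component(g_before)
    stats = network.topology_stats(g_main)
    cent_before = network.centralities(g_main)
    ess_before = network.rank_essential(cent_before)
    network.write_centralities(
        cent_before, ess_before.essential, outdir / "centralities_before.tsv"
    )
    network.export_graph(g_main, cent_before, outdir / "network_before.graphml")
    summary["network_before"] = {
        "n_nodes": stats.n_nodes,
        "n_edges": stats.n_edges,
        "clustering_coefficient": round(stats.clustering_coefficient, 3),
        "avg_neighbors": round(stats.avg_neighbors, 3),
        "unconnected_query": len(unconnected),
        "excluded_from_main": len(excluded),
        "essential": sorted(ess_before.essential),
    }

    novel_tfs = set(
        prioritized.loc[prioritized["candidate_class"] == "novel_C2H2", "tf"]
    ) if len(prioritized) else set()
    g_after, unconnected_new = _stage(
        "network", network.augment_network, g_main, novel_tfs, edges
    )
    g_after_main, _ = network.main_component(g_after)
    cent_after = network.centralities(g_after_main)
    ess_after = network.rank_essential(cent_after)
    network.write_centralities(
        cent_after, ess_after.essential, outdir / "centralities_after.tsv"
    )
    network.export_graph(g_after_main, cent_after, outdir / "network_after.graphml")
    summary["network_after"] = {
        "n_nodes": g_after_main.number_of_nodes(),
        "n_edges": g_after_main.number_of_edges(),
        "new_tfs_joined": len(novel_tfs - unconnected_new),
        "new_tfs_unconnected": len(unconnected_new),
        "essential": sorted(ess_after.essential),
    }

    # 9. final report
    full_candidates = candidates.copy()
    if "dev_ontology_hit" not in full_candidates.columns:
        hits = set(prioritized["tf"]) if len(prioritized) else set()
        full_candidates["dev_ontology_hit"] = full_candidates["tf"].isin(hits)
    report = final_report(
        full_candidates,
        cent_before, ess_before.essential,
        cent_after, ess_after.essential,
        freq,
    )
    report.to_csv(outdir / "final_report.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        summary=summary,
        report=report,
        candidates=full_candidates,
        enriched=enriched,
        freq_scores=freq,
        centralities_before=cent_before,
        essential_before=ess_before.essential,
        centralities_after=cent_after,
        essential_after=ess_after.essential,
        dev_ora=dev_ora,
    )
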