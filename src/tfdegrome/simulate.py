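"""Self-contained synthetic scenarios with planted degraded TFs.

A scenario plants a small set of "degraded" C2H2 transcription factors whose
regulon targets are shifted in the case groups of several case/control
expression datasets, a literature evidence table covering part of those
targets, a scored protein-interaction network with a planted hub, a
heavy-tailed regulon database, TF annotations, and embryonic-development
gene sets containing the planted TFs.  Ground truth travels with the bundle
so recovery can be scored.

The expression model is deliberately simple — per-gene Gaussian baselines on
the log2 scale with an additive case shift — matching the |logFC| filter the
pipeline applies.  It does not emulate count distributions, batch effects,
or platform artifacts of real microarray/RNA-seq data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from tfdegrome import dge
from tfdegrome.tables import (
    EvidenceEntry,
    EvidenceTable,
    GeneSet,
    Regulon,
    ScoredEdge,
    TFAnnotation,
    write_evidence_table,
    write_gmt,
    write_regulons,
    write_string_edges,
    write_tf_annotations,
)

_SUBSTREAMS = ("regulons", "annotations", "expression", "evidence", "network", "gmt")


@dataclass(frozen=True)
class ScenarioParams:
    """Knobs of the synthetic study.

    Defaults describe the reference scenario used throughout the test suite:
    2000 genes, 60 TFs of which 3 are planted degraded C2H2 TFs, 8
    case/control datasets of 6 + 6 samples, a mean log2 shift of 2 on
    responding targets with a 0.6 per-dataset response probability, and
    Gaussian noise with standard deviation 0.5.
    """

    n_genes: int = 2000
    n_tfs: int = 60
    n_degraded_tfs: int = 3
    n_datasets: int = 8
    n_case: int = 6
    n_control: int = 6
    effect_lfc: float = 2.0
    detect_prob: float = 0.6
    noise_sd: float = 0.5
    regulon_exponent: float = 2.5
    regulon_min_size: int = 10
    regulon_max_size: int = 120
    ppi_edge_prob: float = 0.08
    hub_symbol: str = "HUB1"
    c2h2_fraction: float = 0.4
    lit_coverage: float = 0.3
    n_lit_proteins: int = 25
    n_lit_gene_noise: int = 10
    seed: int = 1

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_tfs": self.n_tfs,
            "n_degraded_tfs": self.n_degraded_tfs,
            "n_datasets": self.n_datasets,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "regulon_min_size": self.regulon_min_size,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for name in ("detect_prob", "ppi_edge_prob", "c2h2_fraction", "lit_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_degraded_tfs > self.n_tfs:
            raise ValueError("more degraded TFs than TFs")
        if self.n_tfs + self.n_lit_proteins >= self.n_genes:
            raise ValueError("gene universe too small for TFs plus literature proteins")
        if self.regulon_max_size + self.regulon_min_size >= self.n_genes - self.n_tfs:
            raise ValueError("regulon sizes would exhaust the gene universe")


@dataclass
class ScenarioBundle:
    params: ScenarioParams
    universe: list[str]
    expression: dict[str, tuple[pd.DataFrame, list[str]]]
    de_tables: dict[str, pd.DataFrame]
    evidence: EvidenceTable
    edges: list[ScoredEdge]
    regulons: list[Regulon]
    annotations: list[TFAnnotation]
    dev_sets: list[GeneSet]
    ground_truth: dict = field(default_factory=dict)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """One independent substream per scenario component, all derived from the
    single global seed so components are individually reproducible."""
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _power_law_sizes(
    rng: np.random.Generator, n: int, exponent: float, min_size: int, max_size: int
) -> np.ndarray:
    u = rng.random(n)
    sizes = np.floor(min_size * u ** (-1.0 / (exponent - 1.0))).astype(int)
    return np.clip(sizes, min_size, max_size)


def generate_scenario(params: ScenarioParams | None = None) -> ScenarioBundle:
    """Generate a full scenario; bit-identical for a fixed seed."""
    p = params or ScenarioParams()
    p.validate()
    rngs = _rngs(p.seed)

    tf_symbols = [f"TF{i + 1:03d}" for i in range(p.n_tfs)]
    n_plain = p.n_genes - p.n_tfs - 1
    plain_genes = [f"G{i + 1:04d}" for i in range(n_plain)]
    universe = tf_symbols + plain_genes + [p.hub_symbol]

    # --- regulons -----------------------------------------------------------
    rng = rngs["regulons"]
    degraded = sorted(rng.choice(tf_symbols, size=p.n_degraded_tfs, replace=False))
    sizes = _power_law_sizes(
        rng, p.n_tfs, p.regulon_exponent, p.regulon_min_size, p.regulon_max_size
    )
    # the first degraded TF is forced to the single largest regulon,
    # emulating the one-TF-dominates-the-target-count behavior
    sizes = dict(zip(tf_symbols, sizes))
    sizes[degraded[0]] = p.regulon_max_size + p.regulon_min_size
    regulons = []
    for tf in tf_symbols:
        targets = sorted(rng.choice(plain_genes, size=sizes[tf], replace=False))
        modes = {
            t: ("activation", "repression", "unknown")[rng.integers(3)] for t in targets
        }
        refs = {t: int(rng.integers(1, 6)) for t in targets}
        regulons.append(Regulon(tf=tf, targets=set(targets), modes=modes, references=refs))
    regulon_by_tf = {r.tf: r for r in regulons}
    degraded_targets = sorted(set().union(*(regulon_by_tf[tf].targets for tf in degraded)))

    # --- TF annotations -----------------------------------------------------
    rng = rngs["annotations"]
    annotations = []
    for tf in tf_symbols:
        if tf in degraded:
            dbd = "C2H2"
        else:
            dbd = "C2H2" if rng.random() < p.c2h2_fraction else "other"
        annotations.append(TFAnnotation(symbol=tf, is_tf=True, dbd_class=dbd))
    annotations.append(TFAnnotation(symbol=p.hub_symbol, is_tf=False, dbd_class="unknown"))

    # --- expression + DE tables --------------------------------------------
    rng = rngs["expression"]
    baseline = rng.uniform(4.0, 12.0, size=len(universe))
    direction = rng.choice([-1.0, 1.0], size=len(universe))
    target_idx = {g: i for i, g in enumerate(universe)}
    degraded_idx = np.array([target_idx[g] for g in degraded_targets], dtype=int)
    groups = ["case"] * p.n_case + ["control"] * p.n_control
    expression: dict[str, tuple[pd.DataFrame, list[str]]] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    for d in range(p.n_datasets):
        ds = f"d{d + 1:02d}"
        responds = rng.random(len(degraded_idx)) < p.detect_prob
        shift = np.zeros(len(universe))
        idx = degraded_idx[responds]
        shift[idx] = direction[idx] * p.effect_lfc
        n_samples = p.n_case + p.n_control
        values = baseline[:, None] + rng.normal(
            0.0, p.noise_sd, size=(len(universe), n_samples)
        )
        values[:, : p.n_case] += shift[:, None]
        mat = pd.DataFrame(values, index=universe, columns=[f"{ds}_s{j}" for j in range(n_samples)])
        expression[ds] = (mat, list(groups))
        de_tables[ds] = dge.call_de_simple(mat, groups, dataset_id=ds)

    # --- literature evidence ------------------------------------------------
    rng = rngs["evidence"]
    drug_p = np.array([0.75, 0.10, 0.15])  # thalidomide-heavy literature
    drugs = ("thalidomide", "lenalidomide", "pomalidomide")
    lit_proteins = sorted(
        rng.choice(
            [g for g in plain_genes if g not in degraded_targets],
            size=p.n_lit_proteins,
            replace=False,
        )
    )
    # a couple of non-degraded TFs are also literature proteins, so the
    # known-TF Venn regions are populated; planted TFs stay out of the
    # literature by construction (that is what makes them "novel")
    extra_tfs = sorted(
        rng.choice([t for t in tf_symbols if t not in degraded], size=2, replace=False)
    )
    protein_targets = lit_proteins + extra_tfs + [p.hub_symbol]
    entries: list[EvidenceEntry] = []
    source_counter = 0
    for sym in protein_targets:
        n_reports = int(rng.integers(1, 4))
        for _ in range(n_reports):
            source_counter += 1
            entries.append(
                EvidenceEntry(
                    drug=drugs[rng.choice(3, p=drug_p)],
                    target=sym,
                    level="protein",
                    effect=("downregulated", "degraded", "bound", "inhibited")[
                        rng.integers(4)
                    ],
                    system=("hESC", "HUVEC")[rng.integers(2)],
                    source_id=f"S{source_counter:03d}",
                )
            )
    n_covered = int(round(p.lit_coverage * len(degraded_targets)))
    covered = sorted(rng.choice(degraded_targets, size=n_covered, replace=False))
    never_de_pool = [
        g for g in plain_genes if g not in degraded_targets and g not in lit_proteins
    ]
    noise_genes = sorted(
        rng.choice(never_de_pool, size=p.n_lit_gene_noise, replace=False)
    )
    for sym in covered + noise_genes:
        source_counter += 1
        entries.append(
            EvidenceEntry(
                drug=drugs[rng.choice(3, p=drug_p)],
                target=sym,
                level="gene",
                effect=("downregulated", "upregulated")[rng.integers(2)],
                system=("hESC", "HUVEC")[rng.integers(2)],
                source_id=f"S{source_counter:03d}",
            )
        )
    evidence = EvidenceTable(entries=entries)

    # --- protein-interaction edges -----------------------------------------
    rng = rngs["network"]
    others = lit_proteins + extra_tfs
    edges: list[ScoredEdge] = []
    for i in range(len(others)):
        for j in range(i + 1, len(others)):
            if rng.random() < p.ppi_edge_prob:
                edges.append(
                    ScoredEdge(
                        a=others[i],
                        b=others[j],
                        score=float(np.round(rng.uniform(0.15, 0.95), 3)),
                        channels=frozenset({"experimental"}),
                    )
                )
    deg = {s: 0 for s in others}
    for e in edges:
        if e.score > 0.400:
            deg[e.a] += 1
            deg[e.b] += 1
    # +3 keeps the hub at least two edges ahead even after its partners each
    # gain one incident edge from the attachment itself
    hub_degree = max(deg.values(), default=0) + 3
    hub_partners = sorted(rng.choice(others, size=hub_degree, replace=False))
    for partner in hub_partners:
        edges.append(
            ScoredEdge(
                a=p.hub_symbol,
                b=partner,
                score=float(np.round(rng.uniform(0.60, 0.95), 3)),
                channels=frozenset({"experimental"}),
            )
        )
    # augmentation edges: each planted TF interacts with a few network
    # proteins (always including the hub, mirroring TF-hub crosstalk)
    for tf in degraded:
        partners = [p.hub_symbol] + list(
            rng.choice(others, size=int(rng.integers(1, 3)), replace=False)
        )
        for partner in partners:
            edges.append(
                ScoredEdge(
                    a=tf,
                    b=partner,
                    score=float(np.round(rng.uniform(0.50, 0.90), 3)),
                    channels=frozenset({"coexpression"}),
                )
            )

    # --- embryonic-development gene sets ------------------------------------
    rng = rngs["gmt"]
    non_degraded_tfs = [t for t in tf_symbols if t not in degraded]
    eye_extra = sorted(rng.choice(non_degraded_tfs, size=3, replace=False))
    heart_extra = sorted(rng.choice(non_degraded_tfs, size=3, replace=False))
    ctrl_members = sorted(rng.choice(non_degraded_tfs, size=8, replace=False))
    dev_sets = [
        GeneSet("DEV_EYE", "eye development", frozenset(degraded + eye_extra)),
        GeneSet("DEV_HEART", "heart development", frozenset(degraded + heart_extra)),
        GeneSet("CTRL_HOUSEKEEPING", "housekeeping control", frozenset(ctrl_members)),
    ]

    truth = {
        "degraded_tfs": [str(t) for t in degraded],
        "hub": p.hub_symbol,
        "degraded_targets": degraded_targets,
        "literature_proteins": protein_targets,
    }
    return ScenarioBundle(
        params=p,
        universe=universe,
        expression=expression,
        de_tables=de_tables,
        evidence=evidence,
        edges=edges,
        regulons=regulons,
        annotations=annotations,
        dev_sets=dev_sets,
        ground_truth=truth,
    )


def materialize(
    bundle: ScenarioBundle,
    outdir: str | Path,
    write_expression: bool = False,
) -> Path:
    """Write the bundle to ``outdir`` in the pipeline's file dialects and
    drop a ready-to-run pipeline config (``config.txt``) beside them."""
    outdir = Path(outdir)
    (outdir / "de").mkdir(parents=True, exist_ok=True)
    write_evidence_table(bundle.evidence, outdir / "evidence.tsv")
    write_string_edges(bundle.edges, outdir / "string_edges.tsv")
    write_regulons(bundle.regulons, outdir / "regulons.tsv")
    write_tf_annotations(bundle.annotations, outdir / "tf_annotations.tsv")
    write_gmt(bundle.dev_sets, outdir / "dev_sets.gmt")
    (outdir / "universe.txt").write_text("\n".join(bundle.universe) + "\n")
    for ds, df in bundle.de_tables.items():
        dge.write_de_table(df, outdir / "de" / f"{ds}.tsv")
    if write_expression:
        (outdir / "expression").mkdir(exist_ok=True)
        for ds, (mat, groups) in bundle.expression.items():
            mat.to_csv(outdir / "expression" / f"{ds}.tsv", sep="\t")
            (outdir / "expression" / f"{ds}.groups.txt").write_text(
                "\n".join(groups) + "\n"
            )
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    config = {
        "evidence": "evidence.tsv",
        "de_dir": "de",
        "edges": "string_edges.tsv",
        "regulons": "regulons.tsv",
        "tf_annotations": "tf_annotations.tsv",
        "dev_sets": "dev_sets.gmt",
        "universe": "universe.txt",
        "outdir": "results",
        "lfc": "1.0",
        "alpha_de": "0.05",
        "string_score": "0.400",
        "alpha_tf": "0.05",
        "alpha_ora": "0.05",
        "n_perm": "1000",
        "seed": str(bundle.params.seed),
    }
    with open(outdir / "config.txt", "w") as fh:
        for k, v in config.items():
            fh.write(f"{k}: {v}\n")
    return outdir


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float | None
    recall: float
    true_positives: int
    false_positives: int
    false_negatives: int


def ground_truth_metrics(
    candidates: Mapping | pd.DataFrame | set,
    truth: Mapping,
) -> RecoveryMetrics:
    """Precision/recall of planted-TF recovery over the novel-C2H2 class.

    ``candidates`` may be the candidate table (rows with a
    ``candidate_class`` column) or a plain set of predicted novel TFs.
    Precision is undefined (None) when nothing was predicted.
    """
    if isinstance(candidates, pd.DataFrame):
        predicted = set(
            candidates.loc[candidates["candidate_class"] == "novel_C2H2", "tf"]
        )
    elif isinstance(candidates, Mapping):
        predicted = set(candidates.get("novel_C2H2", set()))
    else:
        predicted = set(candidates)
    planted = set(truth["degraded_tfs"])
    tp = len(predicted & planted)
    fp = len(predicted - planted)
    fn = len(planted - predicted)
    precision = tp / (tp + fp) if predicted else None
    recall = tp / (tp + fn) if planted else 0.0
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
    )


def params_as_dict(params: ScenarioParams) -> dict:
    return asdict(params)
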