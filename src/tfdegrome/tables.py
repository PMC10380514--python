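"""Readers and writers for every external table the pipeline touches.

Formats handled:

* evidence table — tab-separated, header
  ``drug  target  level  effect  system  source_id``; one row per literature
  report of an IMiD effect on a gene or protein;
* scored protein-interaction edge lists in the STRING-export dialect
  (two protein columns plus one or more channel-score columns, scores on
  either the 0-1 or the 0-999 integer scale);
* TF -> target regulons in the TRRUST dialect
  (``tf  target  mode  references``);
* gene-set collections in the Broad GMT format;
* TF annotation tables (``symbol  is_tf  dbd_class``).

All readers canonicalize symbols (uppercase, stripped) and report row-level
problems instead of aborting on the first bad line.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from tfdegrome._util import canon, pct_one_decimal

logger = logging.getLogger(__name__)

DRUGS = ("thalidomide", "lenalidomide", "pomalidomide")
LEVELS = ("gene", "protein")
EFFECTS = ("downregulated", "upregulated", "degraded", "bound", "inhibited", "other")
REGULATION_MODES = ("activation", "repression", "unknown")
DBD_CLASSES = ("C2H2", "other", "unknown")

EVIDENCE_COLUMNS = ("drug", "target", "level", "effect", "system", "source_id")


class SchemaError(ValueError):
    """A file does not match the documented column layout."""


@dataclass(frozen=True)
class RowError:
    """One unparseable input row, kept so the caller can report all of them."""

    line: int
    message: str


@dataclass(frozen=True)
class EvidenceEntry:
    """One literature report of a drug effect on a gene or a protein."""

    drug: str
    target: str
    level: str
    effect: str
    system: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.target:
            raise ValueError("evidence entry with empty target symbol")
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")


@dataclass
class EvidenceTable:
    """Ordered, exact-duplicate-free collection of evidence entries."""

    entries: list[EvidenceEntry]
    n_duplicates_dropped: int = 0
    row_errors: list[RowError] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def targets(self, level: str | None = None) -> set[str]:
        """Distinct target symbols, optionally restricted to one level."""
        return {
            e.target for e in self.entries if level is None or e.level == level
        }


@dataclass(frozen=True)
class ScoredEdge:
    """An evidence-scored protein pair with unordered-pair semantics."""

    a: str
    b: str
    score: float
    channels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-loop on {self.a!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.a, self.b))


@dataclass
class Regulon:
    """A TF and the set of target genes experimentally known to be regulated."""

    tf: str
    targets: set[str]
    modes: dict[str, str] = field(default_factory=dict)
    references: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"regulon for {self.tf!r} has no targets")
        if self.tf in self.targets:
            logger.warning("regulon for %s contains the TF itself", self.tf)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass(frozen=True)
class TFAnnotation:
    symbol: str
    is_tf: bool
    dbd_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.dbd_class not in DBD_CLASSES:
            raise ValueError(f"unknown DNA-binding-domain class {self.dbd_class!r}")
        if self.dbd_class == "C2H2" and not self.is_tf:
            raise ValueError(f"{self.symbol}: C2H2 annotation on a non-TF")


@dataclass
class EvidenceSummary:
    """Headline counts over an evidence table.

    ``replicated_targets`` counts targets reported at the same level by two
    or more distinct sources; ``gene_protein_overlap`` counts targets
    reported at both levels.  Percentages are rounded half-even to one
    decimal; the raw fractions stay available via ``total``.
    """

    total: int
    by_drug: dict[str, int]
    by_level: dict[str, int]
    distinct_targets: dict[str, int]
    replicated_targets: dict[str, int]
    gene_protein_overlap: int
    level_pct: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "by_drug": self.by_drug,
            "by_level": self.by_level,
            "distinct_targets": self.distinct_targets,
            "replicated_targets": self.replicated_targets,
            "gene_protein_overlap": self.gene_protein_overlap,
            "level_pct": self.level_pct,
        }


# ---------------------------------------------------------------------------
# evidence table


def read_evidence_table(path: str | Path) -> EvidenceTable:
    """Parse an evidence table, dropping exact duplicates and collecting
    row-level errors (unknown drug/level/effect tokens) without aborting.

    Raises :class:`SchemaError` when a required column is missing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")

    entries: list[EvidenceEntry] = []
    seen: set[EvidenceEntry] = set()
    errors: list[RowError] = []
    n_dup = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            entry = EvidenceEntry(
                drug=row.drug.strip().lower(),
                target=canon(row.target),
                level=row.level.strip().lower(),
                effect=row.effect.strip().lower(),
                system=row.system.strip(),
                source_id=row.source_id.strip(),
            )
        except ValueError as exc:
            errors.append(RowError(line=i, message=str(exc)))
            continue
        if entry in seen:
            n_dup += 1
            continue
        seen.add(entry)
        entries.append(entry)
    if n_dup:
        logger.info("%s: dropped %d exact duplicate entries", path, n_dup)
    for err in errors:
        logger.warning("%s line %d: %s", path, err.line, err.message)
    return EvidenceTable(entries=entries, n_duplicates_dropped=n_dup, row_errors=errors)


def write_evidence_table(table: EvidenceTable, path: str | Path) -> None:
    rows = [
        (e.drug, e.target, e.level, e.effect, e.system, e.source_id)
        for e in table.entries
    ]
    pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def summarize_evidence(table: EvidenceTable) -> EvidenceSummary:
    """Count entries by drug and level, distinct and replicated targets per
    level, and the gene/protein target overlap.  An empty table yields an
    empty summary rather than an error."""
    by_drug = Counter(e.drug for e in table.entries)
    by_level = Counter(e.level for e in table.entries)
    distinct = {lvl: len(table.targets(lvl)) for lvl in LEVELS}
    replicated: dict[str, int] = {}
    for lvl in LEVELS:
        sources: dict[str, set[str]] = {}
        for e in table.entries:
            if e.level == lvl:
                sources.setdefault(e.target, set()).add(e.source_id)
        replicated[lvl] = sum(1 for s in sources.values() if len(s) >= 2)
    overlap = len(table.targets("gene") & table.targets("protein"))
    total = len(table.entries)
    level_pct = {
        lvl: (pct_one_decimal(by_level.get(lvl, 0), total) if total else 0.0)
        for lvl in LEVELS
    }
    return EvidenceSummary(
        total=total,
        by_drug={d: by_drug.get(d, 0) for d in DRUGS},
        by_level={lvl: by_level.get(lvl, 0) for lvl in LEVELS},
        distinct_targets=distinct,
        replicated_targets=replicated,
        gene_protein_overlap=overlap,
        level_pct=level_pct,
    )


# ---------------------------------------------------------------------------
# STRING-dialect edge lists

_PROTEIN_COLUMNS = ("protein1", "protein2", "node1", "node2", "a", "b")
_SCORE_PRIORITY = ("combined_score", "score")


def read_string_edges(
    path: str | Path,
    threshold: float = 0.400,
    channels: Iterable[str] | None = None,
) -> list[ScoredEdge]:
    """Read a STRING-export edge list and keep edges scoring strictly above
    ``threshold``.

    The two protein columns are the first two columns (or any of the usual
    header names).  The edge score is the ``combined_score`` column when
    present, otherwise the maximum over the requested ``channels`` columns
    (all remaining numeric columns by default).  Scores on the STRING 0-999
    integer dialect — detected when any score exceeds 1 — are divided by
    1000.  Self-loops are dropped; duplicate unordered pairs are merged
    keeping the maximum score and the union of channels.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = list(df.columns)
    if len(cols) < 3:
        raise SchemaError(f"{path}: need two protein columns and a score column")
    lower = [c.lower() for c in cols]
    if lower[0] in _PROTEIN_COLUMNS and lower[1] in _PROTEIN_COLUMNS:
        a_col, b_col = cols[0], cols[1]
    else:
        a_col, b_col = cols[0], cols[1]  # positional fallback
    score_cols: list[str]
    named = [c for c in cols if c.lower() in _SCORE_PRIORITY]
    if named:
        score_cols = [named[0]]
    elif channels is not None:
        score_cols = [c for c in cols if c.lower() in {ch.lower() for ch in channels}]
    else:
        score_cols = [c for c in cols[2:]]
    if not score_cols:
        raise SchemaError(f"{path}: no recognized score column")

    raw: list[tuple[str, str, float, frozenset[str]]] = []
    max_score = 0.0
    for i, rec in enumerate(df.to_dict("records"), start=2):
        vals = {}
        bad = False
        for c in score_cols:
            try:
                vals[c] = float(rec[c])
            except (TypeError, ValueError):
                logger.warning("%s line %d: non-numeric score %r", path, i, rec[c])
                bad = True
                break
        if bad:
            continue
        best_col = max(vals, key=lambda c: vals[c])
        score = vals[best_col]
        chans = frozenset(
            c.lower() for c, v in vals.items() if v == score and c.lower() not in _SCORE_PRIORITY
        )
        a, b = canon(str(rec[a_col])), canon(str(rec[b_col]))
        if a == b:
            continue
        max_score = max(max_score, score)
        raw.append((a, b, score, chans))

    divisor = 1000.0 if max_score > 1.0 else 1.0
    merged: dict[frozenset[str], ScoredEdge] = {}
    for a, b, score, chans in raw:
        score /= divisor
        if not score > threshold:
            continue
        key = frozenset((a, b))
        prev = merged.get(key)
        if prev is None or score > prev.score:
            chans = chans | (prev.channels if prev else frozenset())
            x, y = sorted((a, b))
            merged[key] = ScoredEdge(a=x, b=y, score=score, channels=chans)
        else:
            x, y = sorted((a, b))
            merged[key] = ScoredEdge(
                a=x, b=y, score=prev.score, channels=prev.channels | chans
            )
    return sorted(merged.values(), key=lambda e: (e.a, e.b))


def write_string_edges(edges: Sequence[ScoredEdge], path: str | Path) -> None:
    rows = [
        (e.a, e.b, f"{e.score:.3f}", ",".join(sorted(e.channels)))
        for e in sorted(edges, key=lambda e: (e.a, e.b))
    ]
    pd.DataFrame(rows, columns=["protein1", "protein2", "score", "channels"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# regulons (TRRUST dialect), GMT gene sets, TF annotations


def read_regulons(path: str | Path) -> list[Regulon]:
    """Read a TRRUST-dialect file (tf, target, mode, reference list) into one
    Regulon per TF.  The references column may be a comma-separated PMID
    list or a plain count."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        header=None,
        names=["tf", "target", "mode", "references"],
        comment="#",
    )
    grouped: dict[str, Regulon] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        tf, target = canon(row.tf), canon(row.target)
        if not tf or not target:
            logger.warning("%s line %d: empty symbol", path, i)
            continue
        mode = row.mode.strip().lower()
        mode = {"activation": "activation", "repression": "repression"}.get(
            mode, "unknown"
        )
        refs = row.references.strip()
        if refs.isdigit():
            n_refs = int(refs)
        else:
            n_refs = len([r for r in refs.replace(";", ",").split(",") if r.strip()])
        reg = grouped.get(tf)
        if reg is None:
            grouped[tf] = Regulon(
                tf=tf, targets={target}, modes={target: mode}, references={target: n_refs}
            )
        else:
            reg.targets.add(target)
            reg.modes[target] = mode
            reg.references[target] = n_refs
    return [grouped[tf] for tf in sorted(grouped)]


def write_regulons(regulons: Sequence[Regulon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for reg in sorted(regulons, key=lambda r: r.tf):
            for target in sorted(reg.targets):
                mode = reg.modes.get(target, "unknown")
                refs = reg.references.get(target, 0)
                fh.write(f"{reg.tf}\t{target}\t{mode}\t{refs}\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a Broad-GMT gene-set collection (set id, description, members...).

    Lines with fewer than three fields are reported with their line number
    and skipped."""
    sets: list[GeneSet] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s line %d: GMT line with <3 fields", path, i)
                continue
            set_id, name, *members = fields
            members = [canon(m) for m in members if m.strip()]
            if set_id in seen_ids:
                raise SchemaError(f"{path} line {i}: duplicate set id {set_id!r}")
            seen_ids.add(set_id)
            sets.append(GeneSet(set_id=set_id, name=name, members=frozenset(members)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


def read_tf_annotations(path: str | Path) -> list[TFAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"symbol", "is_tf", "dbd_class"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(sorted(missing))}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TFAnnotation(
                symbol=canon(row.symbol),
                is_tf=row.is_tf.strip().lower() in {"1", "true", "tf", "yes"},
                dbd_class=row.dbd_class.strip() or "unknown",
            )
        )
    return out


def write_tf_annotations(annotations: Sequence[TFAnnotation], path: str | Path) -> None:
    rows = [
        (a.symbol, "true" if a.is_tf else "false", a.dbd_class) for a in annotations
    ]
    pd.DataFrame(rows, columns=["symbol", "is_tf", "dbd_class"]).to_csv(
        path, sep="\t", index=False
    )


def c2h2_symbols(annotations: Iterable[TFAnnotation]) -> set[str]:
    """The C2H2 zinc-finger TF symbols from an annotation list."""
    return {a.symbol for a in annotations if a.dbd_class == "C2H2"}


def write_report(obj: Mapping | pd.DataFrame, path: str | Path) -> None:
    """Write a report object: DataFrames as TSV, mappings as JSON."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
    else:
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
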