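"""Gene-set compilation and Fisher-exact overrepresentation analysis.

Query gene lists (e.g. the PLS+ and PLS- lists) are tested against named
gene sets (cell-type markers, disease genes, or any GMT collection) with a
one-sided (greater) Fisher exact test on the 2x2 overlap table, using the
expression background as the universe.  Within each query x collection
family the p-values are BH-FDR adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class GeneSetCollection:
    name: str
    sets: tuple[GeneSet, ...]
    background: frozenset[str]

    def __post_init__(self):
        self.sets = tuple(self.sets)
        self.background = frozenset(self.background)
        for s in self.sets:
            extra = s.genes - self.background
            if extra:
                raise ValueError(
                    f"set {s.name!r} contains genes outside the background, "
                    f"e.g. {sorted(extra)[:5]}"
                )


@dataclass
class EnrichmentRecord:
    query_name: str
    set_name: str
    n_query: int
    n_set: int
    n_background: int
    n_overlap: int
    odds_ratio: float
    p: float
    q: float = float("nan")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file (name, description, then tab-separated gene ids)."""
    sets: list[GeneSet] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            genes = [g for g in fields[2:] if g]
            unique = set(genes)
            if len(unique) < len(genes):
                logger.info(
                    "GMT line %d (%s): %d duplicate gene(s) removed",
                    lineno,
                    fields[0],
                    len(genes) - len(unique),
                )
            sets.append(GeneSet(name=fields[0], genes=frozenset(unique), description=fields[1]))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{s.description}\t{genes}\n")


def read_background(path) -> frozenset[str]:
    """One gene id per line."""
    with open(path, "rt", encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_background(background: Iterable[str], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gene in sorted(background):
            fh.write(f"{gene}\n")


def compile_cell_type_sets(
    study_lists: Iterable[tuple[str, str, Iterable[str]]],
    background: Iterable[str],
    drop_labels: Iterable[str] = (),
    name: str = "cell_types",
) -> GeneSetCollection:
    """Merge study-specific marker lists by cell-type label.

    Genes are deduplicated across studies, labels in ``drop_labels`` are
    removed, genes absent from the background are discarded, and labels left
    empty are dropped with a log message.
    """
    background = frozenset(background)
    drop = set(drop_labels)
    merged: dict[str, set[str]] = {}
    for study_id, label, genes in study_lists:
        if label in drop:
            logger.info("dropping cell-type label %r (study %s)", label, study_id)
            continue
        merged.setdefault(label, set()).update(genes)
    sets = []
    for label in sorted(merged):
        genes = merged[label] & background
        removed = len(merged[label]) - len(genes)
        if removed:
            logger.info("label %r: %d gene(s) outside the background removed", label, removed)
        if not genes:
            logger.info("label %r empty after background restriction; dropped", label)
            continue
        sets.append(GeneSet(name=label, genes=frozenset(genes)))
    return GeneSetCollection(name=name, sets=tuple(sets), background=background)


def compile_disease_set(
    source_lists: Sequence[Iterable[str]],
    background: Iterable[str],
    name: str = "disease",
) -> GeneSet:
    """Union of the source lists, deduplicated and background-restricted."""
    if not source_lists:
        raise ValueError("at least one source list is required")
    background = frozenset(background)
    union: set[str] = set()
    for genes in source_lists:
        union.update(genes)
    genes = union & background
    if not genes:
        raise ValueError("disease set empty after background restriction")
    return GeneSet(name=name, genes=frozenset(genes))


def overlap_enrichment(
    query: GeneSet | Iterable[str],
    target: GeneSet | Iterable[str],
    background: Iterable[str],
    query_name: str = "query",
) -> EnrichmentRecord:
    """One-sided (greater) Fisher exact test of the query/target overlap.

    p is the hypergeometric upper tail P(X >= a) with
    X ~ Hypergeom(N=|background|, K=|target|, n=|query|); the odds ratio is
    the sample estimate a*d / (b*c) (inf when b*c = 0 with a*d > 0, 0 when
    the overlap is empty).
    """
    q_genes = frozenset(query.genes if isinstance(query, GeneSet) else query)
    t_genes = frozenset(target.genes if isinstance(target, GeneSet) else target)
    t_name = target.name if isinstance(target, GeneSet) else "target"
    bg = frozenset(background)
    if not (q_genes <= bg and t_genes <= bg):
        raise ValueError("query and target must be subsets of the background")
    N = len(bg)
    a = len(q_genes & t_genes)
    b = len(q_genes - t_genes)
    c = len(t_genes - q_genes)
    d = N - a - b - c
    p = float(sps.hypergeom.sf(a - 1, N, len(t_genes), len(q_genes)))
    if a == 0:
        odds = 0.0
    elif b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return EnrichmentRecord(
        query_name=query_name,
        set_name=t_name,
        n_query=len(q_genes),
        n_set=len(t_genes),
        n_background=N,
        n_overlap=a,
        odds_ratio=odds,
        p=min(p, 1.0),
    )


def enrichment_table(
    queries: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Test each query against every set of one collection.

    Query genes outside the background are dropped with a log message; the
    BH correction is applied within each query x collection family (over the
    collection's sets), never pooled across collections.
    """
    records: list[EnrichmentRecord] = []
    for query_name in queries:
        genes = frozenset(queries[query_name])
        inside = genes & collection.background
        dropped = len(genes) - len(inside)
        if dropped:
            logger.info(
                "query %r: %d gene(s) outside the background dropped",
                query_name,
                dropped,
            )
        family = [
            overlap_enrichment(inside, s, collection.background, query_name=query_name)
            for s in collection.sets
        ]
        qvals = bh_fdr([r.p for r in family]) if family else []
        for rec, qv in zip(family, qvals):
            rec.q = float(qv)
        records.extend(family)
    out = pd.DataFrame(
        {
            "query": [r.query_name for r in records],
            "collection": collection.name,
            "set": [r.set_name for r in records],
            "n_query": [r.n_query for r in records],
            "n_set": [r.n_set for r in records],
            "n_overlap": [r.n_overlap for r in records],
            "odds_ratio": [r.odds_ratio for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
        }
    )
    out["significant"] = out["q"] < 0.05
    return out
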