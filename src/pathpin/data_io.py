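"""Readers, writers, and core containers for the pipeline's file formats.

Expression matrices travel as genes x samples TSV with a header row of
sample names; sample group labels come either from a designated row of the
matrix or from a two-column sidecar file.  Pathways are carried in
Broad-dialect GMT (name TAB description TAB gene ...), protein interactions
as a three-column TSV with STRING-style confidence scores (0-1000, or
already on the unit scale).

All readers validate and reject malformed input rather than silently
coercing it.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE = "disease"
CONTROL = "control"
VALID_LABELS = frozenset({DISEASE, CONTROL})


@dataclass
class ExpressionStudy:
    """A genes x samples expression matrix with binary sample labels.

    ``values`` holds the (possibly raw) expression levels g_mn; after
    :func:`pathpin.preprocess.standardize_expression` the per-gene z-scores
    Z_mn live in ``standardized``.
    """

    values: pd.DataFrame
    labels: pd.Series
    standardized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        dup_genes = self.values.index[self.values.index.duplicated()]
        if len(dup_genes):
            raise ValueError(
                f"duplicate gene names: {sorted(set(dup_genes))[:5]}"
            )
        dup_samples = self.values.columns[self.values.columns.duplicated()]
        if len(dup_samples):
            raise ValueError(
                f"duplicate sample names: {sorted(set(dup_samples))[:5]}"
            )
        labels = pd.Series(self.labels)
        missing = [s for s in self.values.columns if s not in labels.index]
        if missing:
            raise ValueError(f"missing label for samples: {missing[:5]}")
        labels = labels.reindex(self.values.columns)
        bad = sorted(set(labels) - VALID_LABELS)
        if bad:
            raise ValueError(
                f"labels must be {DISEASE!r}/{CONTROL!r}, got {bad}"
            )
        if set(labels) != VALID_LABELS:
            raise ValueError("labels must cover both disease and control")
        self.labels = labels

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> pd.DataFrame:
        """Standardized values when available, raw values otherwise."""
        return self.standardized if self.standardized is not None else self.values

    def group_samples(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])


@dataclass(frozen=True)
class Pathway:
    name: str
    id: int
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


class PathwayCollection:
    """Named gene sets whose IDs are the 0-based alphabetical rank of the name.

    ID assignment is a pure function of the name set: any two collections
    over the same names agree on every ID, regardless of construction order.
    """

    def __init__(
        self,
        gene_sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        names = list(gene_sets)
        if len(set(names)) != len(names):
            raise ValueError("duplicate pathway names")
        entries = []
        for rank, name in enumerate(sorted(names)):
            genes = frozenset(gene_sets[name])
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")
            entries.append(Pathway(name=name, id=rank, genes=genes))
        self._entries: list[Pathway] = entries
        self.by_id: dict[int, Pathway] = {p.id: p for p in entries}
        self.by_name: dict[str, Pathway] = {p.name: p for p in entries}
        self.descriptions: dict[str, str] = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self._entries)

    @property
    def ids(self) -> list[int]:
        return [p.id for p in self._entries]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self._entries]

    def gene_sets(self) -> dict[str, frozenset[str]]:
        return {p.name: p.genes for p in self._entries}

    def gene_to_pathways(self) -> dict[str, set[int]]:
        mapping: dict[str, set[int]] = {}
        for p in self._entries:
            for g in p.genes:
                mapping.setdefault(g, set()).add(p.id)
        return mapping


class PPINetwork:
    """Undirected protein/gene interaction graph with confidence scores in [0,1]."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_interaction(self, a: str, b: str, confidence: float) -> None:
        if a == b:
            raise ValueError(f"self-interaction {a!r}")
        if not 0.0 <= confidence <= 1.0:
            raise ValueError(f"confidence {confidence} outside [0,1] for {a}-{b}")
        if self.graph.has_edge(a, b):
            # duplicate rows resolve to the maximum score
            if confidence > self.graph[a][b]["confidence"]:
                self.graph[a][b]["confidence"] = confidence
        else:
            self.graph.add_edge(a, b, confidence=confidence)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield (gene_a, gene_b, confidence) with gene_a < gene_b."""
        for a, b, data in self.graph.edges(data=True):
            x, y = sorted((a, b))
            yield x, y, data["confidence"]

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def confidence(self, a: str, b: str) -> float:
        return self.graph[a][b]["confidence"]

    def neighbors(self, gene: str) -> Iterator[str]:
        if gene not in self.graph:
            return iter(())
        return self.graph.neighbors(gene)

    def genes(self) -> set[str]:
        return set(self.graph.nodes)


# ---------------------------------------------------------------------------
# expression


def read_expression_tsv(
    path: str | Path,
    label_row_name: str | None = None,
    labels_path: str | Path | None = None,
) -> ExpressionStudy:
    """Read a genes x samples TSV; labels from a designated row or sidecar file."""
    if label_row_name is None and labels_path is None:
        raise ValueError("provide label_row_name or labels_path")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing cells")
    if label_row_name is not None:
        if label_row_name not in raw.index:
            raise ValueError(f"{path}: label row {label_row_name!r} not found")
        labels = raw.loc[label_row_name].astype(str)
        raw = raw.drop(index=label_row_name)
    else:
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
        if lab.shape[1] < 2:
            raise ValueError(f"{labels_path}: expected two columns (sample, label)")
        labels = pd.Series(
            lab.iloc[:, 1].values, index=lab.iloc[:, 0].values, dtype=str
        )
    try:
        values = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionStudy(values=values, labels=labels)


def write_expression_tsv(
    study: ExpressionStudy,
    path: str | Path,
    labels_path: str | Path | None = None,
    label_row_name: str | None = None,
) -> None:
    """Write raw values; labels as a top row or a sidecar two-column file."""
    df = study.values
    if label_row_name is not None:
        head = pd.DataFrame(
            [study.labels.values], index=[label_row_name], columns=df.columns
        )
        df = pd.concat([head, df])
    df.to_csv(path, sep="\t", index_label="gene")
    if labels_path is not None:
        pd.DataFrame(
            {"sample": study.labels.index, "label": study.labels.values}
        ).to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read Broad-dialect GMT; IDs follow alphabetical name order, not file order."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return PathwayCollection(sets, descriptions)


def write_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for p in pathways:
            desc = pathways.descriptions.get(p.name, "na") or "na"
            handle.write("\t".join([p.name, desc, *sorted(p.genes)]) + "\n")


# ---------------------------------------------------------------------------
# protein interactions


def read_ppi_tsv(path: str | Path, score_scale: str = "string1000") -> PPINetwork:
    """Read a three-column (geneA, geneB, score) TSV.

    ``score_scale='string1000'`` divides scores by 1000 (STRING combined
    scores); ``'unit'`` takes them as-is.  Duplicate pairs keep the maximum
    score; self-loops are dropped with a logged count.
    """
    if score_scale not in {"unit", "string1000"}:
        raise ValueError(f"unknown score_scale {score_scale!r}")
    divisor = 1000.0 if score_scale == "string1000" else 1.0
    net = PPINetwork()
    n_self = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected geneA, geneB, score")
            a, b, raw_score = fields[0], fields[1], fields[2]
            if lineno == 1:
                try:
                    float(raw_score)
                except ValueError:
                    continue  # header row
            score = float(raw_score)
            if score < 0:
                raise ValueError(f"{path}:{lineno}: negative score {score}")
            conf = score / divisor
            if conf > 1.0:
                raise ValueError(
                    f"{path}:{lineno}: score {score} exceeds the {score_scale} scale"
                )
            if a == b:
                n_self += 1
                continue
            net.add_interaction(a, b, conf)
    if n_self:
        logger.warning("dropped %d self-loop interaction rows", n_self)
    return net


def write_ppi_tsv(
    ppi: PPINetwork, path: str | Path, score_scale: str = "unit"
) -> None:
    if score_scale not in {"unit", "string1000"}:
        raise ValueError(f"unknown score_scale {score_scale!r}")
    factor = 1000.0 if score_scale == "string1000" else 1.0
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene_a\tgene_b\tscore\n")
        for a, b, conf in sorted(ppi.edges()):
            score = conf * factor
            handle.write(f"{a}\t{b}\t{score!r}\n")


# ---------------------------------------------------------------------------
# pathway interaction network and results


def write_network_tsv(
    pin: nx.Graph, pathways: PathwayCollection, path: str | Path
) -> None:
    """Write PIN edges as 'idA idB nameA nameB weight', heaviest first."""
    rows = []
    for a, b, data in pin.edges(data=True):
        ia, ib = sorted((a, b))
        rows.append((ia, ib, data.get("weight", 0.0)))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("id_a\tid_b\tname_a\tname_b\tweight\n")
        for ia, ib, w in rows:
            na = pathways.by_id[ia].name if ia in pathways.by_id else ""
            nb = pathways.by_id[ib].name if ib in pathways.by_id else ""
            handle.write(f"{ia}\t{ib}\t{na}\t{nb}\t{w!r}\n")


def read_network_tsv(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("id_a"):
            raise ValueError(f"{path}: missing network header")
        for line in handle:
            if not line.strip():
                continue
            ia, ib, _na, _nb, w = line.rstrip("\n").split("\t")
            graph.add_edge(int(ia), int(ib), weight=float(w))
    return graph


def write_results_json(result, path: str | Path, config: dict | None = None) -> None:
    """Serialize a SelectionResult (plus an optional config echo) as JSON."""
    payload = result.to_dict()
    if config is not None:
        payload["config"] = config
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_results_json(path: str | Path):
    from .selection import SelectionResult  # local import avoids a cycle

    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    return SelectionResult.from_dict(payload)
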