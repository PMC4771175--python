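"""Readers and writers for the external tab-separated formats.

Expression comes as a wide TSV (one sample per row, a sample-id column, a
cohort column, one column per antibody); the gold standard as a 2- or
3-column edge list (``A  B`` or ``A  relation  B``); gene lists as GMT plus
a 2-column parent/child relation file; annotation as a 4-column TSV.
Networks are written as ``antibody1  antibody2  weight  rank``.  Weights are
serialized with 12 significant digits so writer/reader pairs round-trip.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .data import ExpressionDataset, GoldStandardNetwork, canonical_pair, make_annotation
from .genelists import GeneListCollection, HierarchyIndex
from .inference import EdgeRanking, WeightedNetwork, rank_edges

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gold_standard",
    "write_gold_standard",
    "read_gene_lists",
    "write_gene_lists",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_network_tsv",
    "write_network_tsv",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.12g"

MISSING_POLICIES = ("drop_sample", "drop_antibody", "impute_median")


def read_expression_tsv(
    path,
    cohort_column: str = "cohort",
    sample_column: str | None = None,
    missing_policy: str = "impute_median",
    annotation: pd.DataFrame | None = None,
) -> ExpressionDataset:
    """Load a wide samples x antibodies TSV.

    The first column is taken as the sample id unless ``sample_column``
    names another.  ``missing_policy`` is one of ``drop_sample``,
    ``drop_antibody`` or ``impute_median`` (column median).
    """
    path = Path(path)
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise ValueError(f"duplicate antibody column {col!r} in {path.name}")
        seen.add(col)

    df = pd.read_csv(path, sep="\t")
    sample_column = sample_column or header[0]
    if cohort_column not in df.columns:
        raise ValueError(f"cohort column {cohort_column!r} not found in {path.name}")
    df = df.set_index(sample_column)
    cohorts = df.pop(cohort_column).astype(str)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any() and missing_policy != "impute_median":
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise ValueError(f"non-numeric cell at sample {row!r}, antibody {col!r}")
    df = numeric

    if df.isna().any().any():
        if missing_policy == "drop_sample":
            keep = ~df.isna().any(axis=1)
            df, cohorts = df.loc[keep], cohorts.loc[keep]
        elif missing_policy == "drop_antibody":
            df = df.loc[:, ~df.isna().any(axis=0)]
        else:
            df = df.fillna(df.median(axis=0))
    return ExpressionDataset(matrix=df, cohorts=cohorts, annotation=annotation)


def write_expression_tsv(dataset: ExpressionDataset, path, cohort_column: str = "cohort") -> None:
    df = dataset.matrix.copy()
    df.insert(0, cohort_column, dataset.cohorts)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_gold_standard(path, directed_input: bool = True) -> GoldStandardNetwork:
    """Load a 2- or 3-column (``A  relation  B``) TSV edge list.

    Direction is discarded, duplicates and self edges dropped; the universe
    is the set of antibodies appearing in at least one surviving pair.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                a, b = fields
            elif len(fields) >= 3:
                a, b = fields[0], fields[2]
            else:
                raise ValueError(f"malformed edge line {line!r} in {path.name}")
            if a == b:
                continue
            pairs.add(canonical_pair(a, b))
    if not pairs:
        raise ValueError(f"gold standard {path.name} has no edges")
    return GoldStandardNetwork(pairs=frozenset(pairs))


def write_gold_standard(gold: GoldStandardNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(gold.pairs):
            fh.write(f"{a}\t{b}\n")


def read_gene_lists(
    gmt_path,
    relation_path=None,
    id_filter: Callable[[str], bool] | None = None,
) -> tuple[GeneListCollection, HierarchyIndex]:
    """Load a GMT gene-list collection plus its parent/child relation file.

    GMT lines are ``name<TAB>description<TAB>gene...``.  Duplicate list names
    keep the first entry; lists failing ``id_filter`` are dropped together
    with any relation touching them; relations that reference unknown ids
    are dropped with a warning.
    """
    gmt_path = Path(gmt_path)
    lists: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(gmt_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {line!r} in {gmt_path.name}")
            lid, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if lid in lists:
                continue  # duplicate entry removed
            if id_filter is not None and not id_filter(lid):
                continue
            lists[lid] = frozenset(genes)
            names[lid] = desc
    relations: list[tuple[str, str]] = []
    if relation_path is not None:
        with open(relation_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parent, child = line.split("\t")[:2]
                if parent not in lists or child not in lists:
                    warnings.warn(f"relation ({parent!r}, {child!r}) references an unknown id; dropped")
                    continue
                relations.append((parent, child))
    collection = GeneListCollection(lists=lists, names=names)
    hierarchy = HierarchyIndex(relations, all_ids=list(lists))
    return collection, hierarchy


def write_gene_lists(
    collection: GeneListCollection, hierarchy: HierarchyIndex, gmt_path, relation_path
) -> None:
    with open(gmt_path, "w") as fh:
        for lid in collection.ids():
            genes = "\t".join(sorted(collection[lid]))
            fh.write(f"{lid}\t{collection.names.get(lid, lid)}\t{genes}\n")
    with open(relation_path, "w") as fh:
        for child in sorted(hierarchy.parents):
            for parent in sorted(hierarchy.parents[child]):
                fh.write(f"{parent}\t{child}\n")


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    genes = {r.antibody: r.genes.split(",") for r in df.itertuples()}
    phospho = {r.antibody: r.phosphospecific.lower() in ("true", "1") for r in df.itertuples()}
    sites = {r.antibody: r.phosphosite for r in df.itertuples()}
    return make_annotation(list(df["antibody"]), genes, phospho, sites)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "antibody": annotation.index,
            "genes": [",".join(g) for g in annotation["genes"]],
            "phosphosite": annotation["phosphosite"].to_numpy(),
            "phosphospecific": annotation["phosphospecific"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_network_tsv(net: WeightedNetwork, path, ranking: EdgeRanking | None = None) -> None:
    """Serialize a network as ``antibody1  antibody2  weight  rank``."""
    ranking = ranking or rank_edges(net)
    w = net.edge_weights()
    with open(path, "w") as fh:
        fh.write("antibody1\tantibody2\tweight\trank\n")
        for pair, r in zip(ranking.pairs, ranking.avg_rank):
            fh.write(f"{pair[0]}\t{pair[1]}\t{FLOAT_FORMAT % w[pair]}\t{FLOAT_FORMAT % r}\n")


def read_network_tsv(path, signed: bool | None = None, method: str = "") -> WeightedNetwork:
    """Read a network TSV back into a :class:`WeightedNetwork`.

    ``signed`` defaults to whether any stored weight is negative.
    """
    df = pd.read_csv(path, sep="\t")
    antibodies = sorted(set(df["antibody1"]) | set(df["antibody2"]))
    index = {a: i for i, a in enumerate(antibodies)}
    W = np.zeros((len(antibodies), len(antibodies)))
    for r in df.itertuples():
        i, j = index[r.antibody1], index[r.antibody2]
        W[i, j] = W[j, i] = r.weight
    if signed is None:
        signed = bool((df["weight"] < 0).any())
    return WeightedNetwork(antibodies, W, signed=signed, method=method)
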