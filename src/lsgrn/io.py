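"""Reading and writing expression matrices, gold standards, and networks.

Expression files are TSV or CSV (sniffed from the header line), genes in
rows with a leading gene-identifier column and a header row of observation
labels (time points or chip IDs).  Gold standards and predicted networks
use the DREAM-style whitespace/tab-separated edge-list convention.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "null"}


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass
class ExpressionMatrix:
    """Genes x observations expression levels.

    ``values`` may contain NaN before preprocessing; downstream stages
    require the interpolated, complete matrix.
    """

    gene_ids: list[str]
    values: np.ndarray
    observation_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
            raise FormatError(f"duplicate gene IDs: {sorted(dupes)}")
        if self.values.shape[0] != len(self.gene_ids):
            raise FormatError(
                f"{len(self.gene_ids)} gene IDs but {self.values.shape[0]} rows"
            )
        if self.values.shape[1] != len(self.observation_labels):
            raise FormatError(
                f"{len(self.observation_labels)} observation labels but "
                f"{self.values.shape[1]} columns"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.observation_labels)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(list(self.gene_ids), values, list(self.observation_labels))


@dataclass(frozen=True)
class GoldStandard:
    """Reference edge set (regulator, target) over a gene universe.

    Negatives are implicit: every ordered non-self pair of the universe
    that is not listed as an edge counts as a negative.
    """

    edges: frozenset
    universe: frozenset

    def __post_init__(self) -> None:
        for reg, tgt in self.edges:
            if reg == tgt:
                raise FormatError(f"self-pair {reg}->{tgt} in gold standard")
            if reg not in self.universe or tgt not in self.universe:
                raise FormatError(f"edge {reg}->{tgt} outside universe")


@dataclass
class RunConfig:
    """Run parameters for the full inference pipeline.

    lambda_mi : MI cutoff (nats) building the initial binary adjacency.
    theta : coefficient-magnitude cutoff turning regression weights into edges.
    candidate_fraction : top fraction of cross-module MI pairs admitted as
        external regressors (0 < fraction <= 1).
    cond_threshold : condition-number switch between the normal-equation and
        QR solver branches.
    ridge : optional Tikhonov term added to the normal equations (default 0,
        i.e. plain least squares).
    """

    lambda_mi: float = 1.2
    theta: float = 0.18
    candidate_fraction: float = 0.05
    workers: int = 1
    seed: int = 0
    cond_threshold: float = 1e6
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_mi < 0:
            raise ValueError("lambda_mi must be >= 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0 < self.candidate_fraction <= 1:
            raise ValueError("candidate_fraction must be in (0, 1]")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.cond_threshold <= 1:
            raise ValueError("cond_threshold must be > 1")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} must hold a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def _parse_cell(token: str, where: str) -> float:
    token = token.strip()
    if token.lower() in _MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell {token!r} at {where}") from exc


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x observations expression table.

    First column: gene IDs; header row: observation labels.  Empty cells or
    "NA" become NaN (to be filled by :func:`lsgrn.preprocess.interpolate_missing`).
    Duplicate gene IDs or ragged rows raise :class:`FormatError`.
    """
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        rows = [r for r in csv.reader(fh, delimiter=delim) if any(c.strip() for c in r)]
    header = rows[0]
    labels = [c.strip() for c in header[1:]]
    width = len(header)
    gene_ids: list[str] = []
    data: list[list[float]] = []
    for ln, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(f"{path}:{ln}: ragged row ({len(row)} fields, expected {width})")
        gene = row[0].strip()
        if not gene:
            raise FormatError(f"{path}:{ln}: empty gene ID")
        gene_ids.append(gene)
        data.append([_parse_cell(c, f"{path}:{ln}") for c in row[1:]])
    if not gene_ids:
        raise FormatError(f"{path}: no data rows")
    return ExpressionMatrix(gene_ids, np.array(data, dtype=float), labels)


def write_expression(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["gene"] + list(expr.observation_labels))
        for gid, row in zip(expr.gene_ids, expr.values):
            w.writerow([gid] + [format(v, ".17g") if not math.isnan(v) else "NA" for v in row])


def read_gold_standard(path, universe) -> GoldStandard:
    """Read a DREAM-style edge list into a :class:`GoldStandard`.

    Accepts three columns (regulator, target, 0/1 label) or two columns
    (positive list).  Only label-1 pairs with both endpoints in *universe*
    are kept; pairs touching unknown genes are dropped with a warning.
    """
    universe = frozenset(universe)
    edges = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2:
                reg, tgt, label = parts[0], parts[1], 1
            elif len(parts) == 3:
                reg, tgt = parts[0], parts[1]
                if parts[2] not in ("0", "1"):
                    raise FormatError(f"{path}:{ln}: label {parts[2]!r} not in {{0,1}}")
                label = int(parts[2])
            else:
                raise FormatError(f"{path}:{ln}: expected 2 or 3 columns, got {len(parts)}")
            if label == 0:
                continue
            if reg not in universe or tgt not in universe:
                logger.warning("gold edge %s->%s outside universe, dropped", reg, tgt)
                continue
            if reg == tgt:
                logger.warning("gold self-pair %s->%s dropped", reg, tgt)
                continue
            edges.add((reg, tgt))
    return GoldStandard(frozenset(edges), universe)


def _edge_sort_key(item):
    (reg, tgt), weight = item
    return (-abs(weight), reg, tgt)


def write_network(net, path, theta: float | None = None) -> None:
    """Write a weighted edge list, |weight|-descending, ties lexicographic.

    *net* is an object with a ``weights`` mapping (regulator, target) -> float
    (an :class:`lsgrn.inference.InferredNetwork`) or such a mapping itself.
    With *theta* given, a fourth 0/1 column marks edges passing the cut.
    """
    weights = getattr(net, "weights", net)
    with open(path, "w") as fh:
        header = "regulator\ttarget\tweight"
        if theta is not None:
            header += "\tlabel"
        fh.write(header + "\n")
        for (reg, tgt), w in sorted(weights.items(), key=_edge_sort_key):
            line = f"{reg}\t{tgt}\t{w:.12g}"
            if theta is not None:
                line += f"\t{int(abs(w) > theta)}"
            fh.write(line + "\n")


def read_network(path) -> dict:
    """Read back an edge list written by :func:`write_network`."""
    weights: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("regulator"):
            raise FormatError(f"{path}: missing header line")
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 columns")
            weights[(parts[0], parts[1])] = float(parts[2])
    return weights


def write_partition(partition, path) -> None:
    """Two-column TSV (gene, module_index) export of a ModulePartition."""
    with open(path, "w") as fh:
        fh.write("gene\tmodule\n")
        for idx, module in enumerate(partition.modules):
            for gene in module:
                fh.write(f"{gene}\t{idx}\n")
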