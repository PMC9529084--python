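"""Readers, writers and run configuration for the pipeline's file dialects.

The pipeline touches five plain-text formats:

* **genomicMatrix TSV** (UCSC Xena dialect): header row ``sample<TAB>id1<TAB>id2...``,
  one gene per row, integer GISTIC-thresholded copy-number calls in ``{-2,...,2}``.
* **expression matrix TSV**: same grid layout, non-negative values on a
  log2(TPM+1)-like scale, plus a sample annotation TSV mapping each sample to a
  cancer-type label and a tumour/normal flag.
* **clinical TSV**: per-sample survival time (days), event flag, stage, race, gender.
* **gene list TXT**: one symbol per line.
* **edge list TSV**: ``nodeA<TAB>nodeB<TAB>score`` with confidence either in [0,1]
  or on the STRING 0-1000 integer scale (auto-detected).

Missing clinical fields use the explicit token ``NA``. Missing cells in the
numeric matrices are rejected rather than imputed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("matriscore")

MISSING = "NA"
STAGES = ("I", "II", "III", "IV")
RACES = ("white", "black", "asian", "other")
GENDERS = ("male", "female")

GISTIC_CALLS = (-2, -1, 0, 1, 2)


class FormatError(ValueError):
    """Structural problem in an input file (ragged rows, duplicate ids, bad header)."""


def _check_unique(ids: Sequence[str], what: str, path) -> None:
    seen: set[str] = set()
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise FormatError(f"duplicate {what} id(s) in {path}: {sorted(set(dups))}")


@dataclass
class GisticMatrix:
    """Gene x sample integer copy-number calls, values in {-2,-1,0,1,2}."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids, dtype int

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(list(v.index), "gene", "<matrix>")
        _check_unique(list(v.columns), "sample", "<matrix>")
        arr = v.to_numpy()
        if arr.size and not np.isin(arr, GISTIC_CALLS).all():
            bad = np.argwhere(~np.isin(arr, GISTIC_CALLS))[0]
            raise ValueError(
                f"copy-number call outside {{-2..2}} at gene {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}: {arr[tuple(bad)]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression on a log2(TPM+1)-like scale with sample annotations.

    ``annotations`` is indexed by sample id with columns ``cancer_type`` (label)
    and ``is_tumour`` (bool). Every matrix sample must be annotated.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(list(v.index), "gene", "<matrix>")
        _check_unique(list(v.columns), "sample", "<matrix>")
        arr = v.to_numpy(dtype=float)
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            raise ValueError("expression values must be finite and >= 0")
        missing = [s for s in v.columns if s not in self.annotations.index]
        if missing:
            raise FormatError(f"samples lacking annotation: {missing}")

    def samples(self, cancer: str | None = None, tumour: bool | None = None) -> list[str]:
        """Sample ids restricted to a cancer type and/or tumour status."""
        ann = self.annotations.loc[list(self.values.columns)]
        keep = pd.Series(True, index=ann.index)
        if cancer is not None:
            keep &= ann["cancer_type"] == cancer
        if tumour is not None:
            keep &= ann["is_tumour"] == tumour
        return list(ann.index[keep])

    @property
    def cancer_types(self) -> list[str]:
        ann = self.annotations.loc[list(self.values.columns)]
        return sorted(ann["cancer_type"].unique())


@dataclass
class ClinicalTable:
    """Per-sample survival and demographic record.

    Columns: ``cancer_type``, ``time_days`` (>= 0), ``event`` (0/1), ``stage``
    (I-IV or NA), ``race``, ``gender``; indexed by sample id.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        _check_unique(list(d.index), "sample", "<clinical>")
        required = {"cancer_type", "time_days", "event", "stage", "race", "gender"}
        missing = required - set(d.columns)
        if missing:
            raise FormatError(f"clinical table missing columns: {sorted(missing)}")
        if (d["time_days"].to_numpy(dtype=float) < 0).any():
            raise ValueError("survival times must be >= 0")
        if not d["event"].isin([0, 1]).all():
            raise ValueError("event flags must be 0 or 1")
        for col, vocab in (("stage", STAGES), ("race", RACES), ("gender", GENDERS)):
            bad = set(d[col]) - set(vocab) - {MISSING}
            if bad:
                raise ValueError(f"{col} values outside vocabulary: {sorted(bad)}")

    def for_samples(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        present = [s for s in sample_ids if s in self.data.index]
        return self.data.loc[present]


@dataclass
class EdgeList:
    """Undirected, deduplicated interaction edges with confidence in [0,1]."""

    edges: pd.DataFrame  # columns gene_a, gene_b, confidence; gene_a < gene_b

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            conf = e["confidence"].to_numpy(dtype=float)
            if ((conf < 0) | (conf > 1)).any():
                raise ValueError("edge confidence must lie in [0,1]")
            if (e["gene_a"] == e["gene_b"]).any():
                raise ValueError("self-loops are not allowed")
            keys = set(zip(e["gene_a"], e["gene_b"]))
            if len(keys) != len(e):
                raise ValueError("duplicate edges are not allowed")

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["gene_a"], self.edges["gene_b"]))


@dataclass
class PipelineConfig:
    """Thresholds of the prioritization pipeline.

    Defaults follow the study design: top 5% copy-number selection, 75/25
    percentile survival split, two-fold expression change at alpha 0.05,
    >=3-cancer DEG overlap, >=2-cancer individual/pan intersection, degree >=1
    hubs, a 30-cancer breadth denominator and a 0.4 edge-confidence floor.
    """

    top_fraction: float = 0.05
    high_cutoff: float = 0.75
    low_cutoff: float = 0.25
    fold_change_threshold: float = 2.0
    alpha: float = 0.05
    min_cancers_overlap: int = 3
    min_cancers_individual: int = 2
    min_hub_degree: int = 1
    n_cancers_denominator: int = 30
    edge_confidence_min: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0 <= self.low_cutoff <= self.high_cutoff <= 1:
            raise ValueError("need 0 <= low_cutoff <= high_cutoff <= 1")
        if self.fold_change_threshold <= 1:
            raise ValueError("fold_change_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# matrix readers / writers (Xena genomicMatrix dialect)
# ---------------------------------------------------------------------------

def _read_grid(path) -> pd.DataFrame:
    """Parse a genomicMatrix TSV into a DataFrame of strings, validating shape."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = cols[1:]
        _check_unique(sample_ids, "sample", path)
        rows: list[list[str]] = []
        genes: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {len(cols)})"
                )
            genes.append(fields[0])
            rows.append(fields[1:])
    _check_unique(genes, "gene", path)
    return pd.DataFrame(rows, index=genes, columns=sample_ids)


def read_gistic_matrix(path) -> GisticMatrix:
    """Read GISTIC-thresholded calls from a Xena genomicMatrix TSV."""
    grid = _read_grid(path)
    values = pd.DataFrame(index=grid.index, columns=grid.columns, dtype=int)
    arr = np.empty(grid.shape, dtype=int)
    for i, gene in enumerate(grid.index):
        for j, sample in enumerate(grid.columns):
            cell = grid.iat[i, j]
            try:
                f = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric call at gene {gene!r}, sample {sample!r}: {cell!r} "
                    "(missing values are rejected, not imputed)"
                ) from None
            if not f.is_integer() or int(f) not in GISTIC_CALLS:
                raise ValueError(
                    f"{path}: call outside {{-2..2}} at gene {gene!r}, sample {sample!r}: {cell!r}"
                )
            arr[i, j] = int(f)
    values = pd.DataFrame(arr, index=grid.index, columns=grid.columns)
    return GisticMatrix(values)


def write_gistic_matrix(matrix: GisticMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="sample")


def read_expression_matrix(path, annotation_path) -> ExpressionMatrix:
    """Read an expression grid plus its sample annotation table."""
    grid = _read_grid(path)
    try:
        values = grid.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from None
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    required = {"sample", "cancer_type", "sample_type"}
    if missing := required - set(ann.columns):
        raise FormatError(f"{annotation_path}: missing columns {sorted(missing)}")
    _check_unique(list(ann["sample"]), "sample", annotation_path)
    ann = ann.set_index("sample")
    bad_type = set(ann["sample_type"]) - {"tumour", "normal"}
    if bad_type:
        raise ValueError(f"{annotation_path}: sample_type must be tumour/normal, got {sorted(bad_type)}")
    unannotated = [s for s in values.columns if s not in ann.index]
    if unannotated:
        raise FormatError(f"{path}: samples missing from annotations: {unannotated}")
    annotations = pd.DataFrame(
        {
            "cancer_type": ann["cancer_type"],
            "is_tumour": ann["sample_type"] == "tumour",
        }
    )
    return ExpressionMatrix(values, annotations.loc[list(values.columns)])


def write_expression_matrix(expr: ExpressionMatrix, path, annotation_path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="sample")
    ann = pd.DataFrame(
        {
            "sample": expr.annotations.index,
            "cancer_type": expr.annotations["cancer_type"].to_numpy(),
            "sample_type": np.where(expr.annotations["is_tumour"], "tumour", "normal"),
        }
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


def read_clinical_table(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample", "cancer_type", "time_days", "event", "stage", "race", "gender"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    _check_unique(list(df["sample"]), "sample", path)
    df = df.set_index("sample")
    df["time_days"] = df["time_days"].astype(float)
    df["event"] = df["event"].astype(int)
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, sep="\t", index_label="sample")


def read_gene_list(path) -> list[str]:
    """One symbol per line; blanks ignored; duplicates dropped keeping first."""
    symbols: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if not sym:
            continue
        if sym in seen:
            n_dup += 1
            continue
        seen.add(sym)
        symbols.append(sym)
    if not symbols:
        raise FormatError(f"{path}: empty gene list")
    if n_dup:
        logger.warning("%s: dropped %d duplicate symbol(s), keeping first occurrence", path, n_dup)
    return symbols


def write_gene_list(symbols: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in symbols))


def read_edge_list(path, min_confidence: float = 0.0) -> EdgeList:
    """Read a 3-column edge TSV, rescaling STRING 0-1000 scores when present.

    Self-loops and reciprocal duplicates are removed; edges below
    ``min_confidence`` are dropped. Any score > 1 flips the whole file onto the
    0-1000 scale (all scores divided by 1000).
    """
    raw = pd.read_csv(path, sep="\t", header=None, names=["gene_a", "gene_b", "score"], dtype=str)
    scores = raw["score"].astype(float).to_numpy()
    if ((scores < 0) | (scores > 1000)).any():
        raise ValueError(f"{path}: scores must lie in [0,1] or [0,1000]")
    if (scores > 1).any():
        scores = scores / 1000.0
    records: dict[tuple[str, str], float] = {}
    for (a, b), conf in zip(zip(raw["gene_a"], raw["gene_b"]), scores):
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        # keep the highest confidence among reciprocal duplicates
        if key not in records or conf > records[key]:
            records[key] = conf
    kept = [(a, b, c) for (a, b), c in sorted(records.items()) if c >= min_confidence]
    edges = pd.DataFrame(kept, columns=["gene_a", "gene_b", "confidence"])
    return EdgeList(edges)


def write_edge_list(edge_list: EdgeList, path) -> None:
    edge_list.edges.to_csv(path, sep="\t", header=False, index=False)
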