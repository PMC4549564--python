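"""Typed containers and tab-delimited readers/writers.

Handles the four table kinds of the pipeline: log-scale expression matrices
with per-feature annotations (biotype, genomic coordinates), log2 copy-number
matrices, per-cell-line drug-sensitivity (rIC50) tables, and per-animal
tumor-volume trajectories, plus generic feature-category collections for
enrichment. Expression supports both a plain annotated TSV dialect and
GCT 1.2. Genomic coordinates are 1-based inclusive internally; BED export
converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .response import VolumeSeries

__all__ = [
    "FeatureAnnotation",
    "ExpressionMatrix",
    "CopyNumberMatrix",
    "SensitivityProfile",
    "CategoryCollection",
    "ParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sensitivity_table",
    "write_sensitivity_table",
    "read_volume_table",
    "write_volume_table",
    "write_bed",
    "read_categories",
    "write_categories",
]

BIOTYPES = ("coding", "lincRNA")
STRANDS = ("+", "-", "unknown")

_HEADER_COMMENT = "# pdxsig table v1\n"


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class FeatureAnnotation:
    """Annotation for one array feature (probe/gene).

    Coordinates are 1-based inclusive (``chrN:start-end`` style).
    """

    feature_id: str
    biotype: str = "coding"
    chrom: str = "unknown"
    start: int = 1
    end: int = 1
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(
                f"feature {self.feature_id!r}: biotype must be one of {BIOTYPES}"
            )
        if self.strand not in STRANDS:
            raise ValueError(
                f"feature {self.feature_id!r}: strand must be one of {STRANDS}"
            )
        if self.start > self.end:
            raise ValueError(
                f"feature {self.feature_id!r}: start {self.start} > end {self.end}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on '+', ``end`` on '-'."""
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.end
        raise ValueError(f"feature {self.feature_id!r} has unknown strand")


class ExpressionMatrix:
    """Log-scale feature x sample matrix with feature annotations.

    ``values`` is a float array of shape (n_features, n_samples); rows align
    with ``features``, columns with ``sample_ids``.
    """

    def __init__(
        self,
        features: Sequence[FeatureAnnotation],
        sample_ids: Sequence[str],
        values: np.ndarray,
        allow_missing: bool = False,
    ) -> None:
        self.features = list(features)
        self.sample_ids = list(sample_ids)
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.features),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) == 0:
            raise ValueError("matrix must have at least one sample")
        if len(self.features) == 0:
            raise ValueError("matrix must have at least one feature")
        ids = self.feature_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({f for f in ids if ids.count(f) > 1})
            raise ValueError(f"duplicate feature ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not allow_missing and not np.all(np.isfinite(self.values)):
            raise ValueError(
                "matrix contains missing/non-finite values "
                "(pass allow_missing=True or impute on read)"
            )

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return type(self)(self.features, list(sample_ids), self.values[:, idx])

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return type(self)(
            [self.features[i] for i in idx], self.sample_ids, self.values[idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.features == other.features
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


class CopyNumberMatrix(ExpressionMatrix):
    """Log2 copy-number ratio matrix; same shape contract as expression."""


@dataclass(frozen=True)
class SensitivityProfile:
    """One (agent, cell line) rIC50 measurement; ``ric50`` in molar.

    Censored entries carry ``ric50`` equal to the maximum tested dose
    (no inhibition within dose range).
    """

    agent: str
    sample_id: str
    ric50: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not (self.ric50 > 0):
            raise ValueError(
                f"{self.agent}/{self.sample_id}: rIC50 must be > 0, got {self.ric50}"
            )

    @property
    def log10_ric50(self) -> float:
        return math.log10(self.ric50)


@dataclass
class CategoryCollection:
    """Named feature sets over a declared universe (for enrichment)."""

    categories: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.categories = {k: frozenset(v) for k, v in self.categories.items()}
        for name, members in self.categories.items():
            if not members:
                raise ValueError(f"category {name!r} is empty")
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"category {name!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


# ---------------------------------------------------------------------------
# expression matrices

_ANNOT_COLS = ("feature_id", "biotype", "chrom", "start", "end", "strand")


def _annotations_from_frame(frame: pd.DataFrame) -> list[FeatureAnnotation]:
    feats = []
    for _, row in frame.iterrows():
        feats.append(
            FeatureAnnotation(
                feature_id=str(row["feature_id"]),
                biotype=str(row.get("biotype", "coding")),
                chrom=str(row.get("chrom", "unknown")),
                start=int(row.get("start", 1)),
                end=int(row.get("end", 1)),
                strand=str(row.get("strand", "unknown")),
            )
        )
    return feats


def read_expression_matrix(
    path, dialect: str = "tsv", impute_missing: bool = False, cls=ExpressionMatrix
) -> ExpressionMatrix:
    """Read an expression (or copy-number) matrix.

    ``tsv`` dialect: comment lines starting '#', then a header with the
    annotation columns (feature_id required; biotype/chrom/start/end/strand
    tolerated missing, filled with defaults) followed by one column per
    sample. ``gct`` dialect: GCT 1.2 with annotations packed into the
    Description field.

    Missing values are rejected unless ``impute_missing`` (row-mean fill).
    """
    path = Path(path)
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", comment="#", dtype={0: str},
                            float_precision="round_trip")
        if "feature_id" not in frame.columns:
            raise ParseError(f"{path}: header lacks required column 'feature_id'")
        annot_present = [c for c in _ANNOT_COLS if c in frame.columns]
        sample_cols = [c for c in frame.columns if c not in _ANNOT_COLS]
        if not sample_cols:
            raise ParseError(f"{path}: no sample columns found")
        feats = _annotations_from_frame(frame[annot_present])
        values = frame[sample_cols].to_numpy(dtype=float)
        samples = [str(c) for c in sample_cols]
    elif dialect == "gct":
        feats, samples, values = _read_gct(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if impute_missing:
        values = _impute_row_means(values)
    ids = [f.feature_id for f in feats]
    if len(set(ids)) != len(ids):
        dupes = sorted({f for f in ids if ids.count(f) > 1})
        raise ValueError(f"{path}: duplicate feature ids: {dupes}")
    return cls(feats, samples, values)


def _pack_description(f: FeatureAnnotation) -> str:
    return f"biotype={f.biotype};chrom={f.chrom};start={f.start};end={f.end};strand={f.strand}"


def _unpack_description(feature_id: str, desc: str) -> FeatureAnnotation:
    fields: dict[str, str] = {}
    for part in str(desc).split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            fields[k] = v
    return FeatureAnnotation(
        feature_id=feature_id,
        biotype=fields.get("biotype", "coding"),
        chrom=fields.get("chrom", "unknown"),
        start=int(fields.get("start", 1)),
        end=int(fields.get("end", 1)),
        strand=fields.get("strand", "unknown"),
    )


def _read_gct(path: Path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise ParseError(f"{path}: line 1: expected GCT version header '#1.2'")
    try:
        n_rows, n_cols = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: line 2: malformed row/column counts") from exc
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name":
        raise ParseError(f"{path}: line 3: expected 'Name\\tDescription\\t<samples>'")
    samples = header[2:]
    if len(samples) != n_cols:
        raise ParseError(
            f"{path}: line 3: declared {n_cols} samples, header has {len(samples)}"
        )
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_rows:
        raise ParseError(
            f"{path}: declared {n_rows} data rows but file contains {len(body)}"
        )
    feats, rows = [], []
    for i, ln in enumerate(body, start=4):
        parts = ln.split("\t")
        if len(parts) != 2 + n_cols:
            raise ParseError(f"{path}: line {i}: expected {2 + n_cols} fields")
        feats.append(_unpack_description(parts[0], parts[1]))
        rows.append([float(x) if x != "" else np.nan for x in parts[2:]])
    return feats, samples, np.asarray(rows, dtype=float)


def _impute_row_means(values: np.ndarray) -> np.ndarray:
    values = values.copy()
    bad = ~np.isfinite(values)
    if bad.any():
        means = np.nanmean(np.where(bad, np.nan, values), axis=1)
        values[bad] = np.take(means, np.nonzero(bad)[0])
    return values


def write_expression_matrix(matrix: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    """Write a matrix; ``read_expression_matrix`` round-trips it exactly."""
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write(_HEADER_COMMENT)
            fh.write("\t".join(_ANNOT_COLS) + "\t" + "\t".join(matrix.sample_ids) + "\n")
            for f, row in zip(matrix.features, matrix.values):
                annot = f"{f.feature_id}\t{f.biotype}\t{f.chrom}\t{f.start}\t{f.end}\t{f.strand}"
                fh.write(annot + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    elif dialect == "gct":
        n_rows, n_cols = matrix.shape
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_rows}\t{n_cols}\n")
            fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
            for f, row in zip(matrix.features, matrix.values):
                fh.write(
                    f.feature_id
                    + "\t"
                    + _pack_description(f)
                    + "\t"
                    + "\t".join(repr(float(v)) for v in row)
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_bed(features: Iterable[FeatureAnnotation], path) -> None:
    """Export intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for f in features:
            strand = f.strand if f.strand in ("+", "-") else "."
            fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.feature_id}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# sensitivity tables

def read_sensitivity_table(path) -> list[SensitivityProfile]:
    """TSV with columns agent, sample_id, ric50_molar, censored."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"agent", "sample_id", "ric50_molar", "censored"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            SensitivityProfile(
                agent=str(row["agent"]),
                sample_id=str(row["sample_id"]),
                ric50=float(row["ric50_molar"]),
                censored=_parse_bool(row["censored"]),
            )
        )
    return out


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ParseError(f"cannot parse boolean value {x!r}")


def write_sensitivity_table(profiles: Sequence[SensitivityProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMENT)
        fh.write("agent\tsample_id\tric50_molar\tcensored\n")
        for p in profiles:
            fh.write(f"{p.agent}\t{p.sample_id}\t{float(p.ric50)!r}\t{str(p.censored).lower()}\n")


# ---------------------------------------------------------------------------
# volume tables

def read_volume_table(path) -> list[VolumeSeries]:
    """Long-format TSV: model_id, arm, animal_id, day, volume_mm3.

    Rows may be unsorted; each animal's series is sorted by day and must
    include a day-0 baseline.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"model_id", "arm", "animal_id", "day", "volume_mm3"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (model_id, arm, animal_id), grp in frame.groupby(
        ["model_id", "arm", "animal_id"], sort=False
    ):
        out.append(
            VolumeSeries(
                model_id=str(model_id),
                arm=str(arm),
                animal_id=str(animal_id),
                days=grp["day"].to_numpy(dtype=float),
                volumes=grp["volume_mm3"].to_numpy(dtype=float),
            )
        )
    return out


def write_volume_table(series_list: Sequence[VolumeSeries], path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMENT)
        fh.write("model_id\tarm\tanimal_id\tday\tvolume_mm3\n")
        for s in series_list:
            for d, v in zip(s.days, s.volumes):
                fh.write(f"{s.model_id}\t{s.arm}\t{s.animal_id}\t{float(d)!r}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# categories

def read_categories(path) -> CategoryCollection:
    """Two-section TSV: lines 'universe<TAB>id' and 'category<TAB>name<TAB>id'."""
    universe: set[str] = set()
    cats: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if parts[0] == "universe" and len(parts) == 2:
                universe.add(parts[1])
            elif parts[0] == "category" and len(parts) == 3:
                cats.setdefault(parts[1], set()).add(parts[2])
            else:
                raise ParseError(f"{path}: line {i}: unrecognized record {ln!r}")
    return CategoryCollection(
        categories={k: frozenset(v) for k, v in cats.items()},
        universe=frozenset(universe),
    )


def write_categories(collection: CategoryCollection, path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMENT)
        for fid in sorted(collection.universe):
            fh.write(f"universe\t{fid}\n")
        for name in sorted(collection.categories):
            for fid in sorted(collection.categories[name]):
                fh.write(f"category\t{name}\t{fid}\n")
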