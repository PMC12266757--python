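"""Readers and writers for the tabular formats used throughout the package.

Everything downstream (signature derivation, scoring, screening) consumes and
produces the domain types defined here:

* :class:`ExpressionMatrix` — a genes × samples real matrix with a declared
  scale (``linear`` for TPM-like values, ``log`` for already-log-transformed
  data), read from plain TSV or GCT v1.3.
* :class:`SampleGrouping` — a two-group sample assignment for scoring.
* :class:`DETable` — one young-vs-old differential-expression table
  (gene, log2 fold change, p-value) as produced by an upstream DE tool.
* :class:`AgingSignature` — one tissue class of the aging signature: an
  ordered top-N gene list with ±1 aging directions (the marker vector) and
  combined p-values.
* :class:`ScreenMetadata` — per-instance annotations of a perturbation
  screen matrix (perturbation, dose, time, plate, control flag).

All delimited files are tab-separated UTF-8 with a mandatory header row and
"." as the decimal separator.  Parsers never coerce silently: dropped rows
are counted and logged, and structural problems raise :class:`ParseError` or
:class:`ValidationError` naming the offending content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rnage")

#: float format used by every writer; round-trips IEEE doubles exactly and
#: keeps repeated runs byte-identical.
FLOAT_FORMAT = "%.17g"

SIGNATURE_CLASSES = ("Pan", "pF", "Neuronal", "FC", "SN")


class RnageError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(RnageError):
    """A file does not conform to its declared format."""


class ValidationError(RnageError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix on a declared scale.

    ``scale_tag`` is ``"linear"`` for non-negative raw-normalized values
    (TPM, FPKM, level-3 normalized intensities) and ``"log"`` for values
    already on a log scale.  The scorer decides its transform from this tag.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = "linear"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale_tag not in ("linear", "log"):
            raise ValidationError(f"scale_tag must be 'linear' or 'log', got {self.scale_tag!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {label} IDs: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.scale_tag == "linear" and np.any(self.values < 0):
            raise ValidationError("linear-scale expression values must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_columns(self, sample_ids: Iterable[str]) -> np.ndarray:
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        return self.values[:, [idx[s] for s in sample_ids]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_expression_matrix(
    path: str | Path,
    format: str | None = None,
    scale_tag: str = "linear",
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT v1.3.

    ``format`` is ``"tsv"`` or ``"gct"``; when ``None`` it is inferred from
    the file suffix (``.gct`` → GCT, anything else → TSV).  The TSV layout is
    a header row of sample IDs with the first column holding gene IDs.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        gene_ids, sample_ids, values = _read_gct(path)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str}, float_precision="round_trip")
        gene_ids = [str(g) for g in df.index]
        sample_ids = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ValidationError(f"duplicate gene IDs in {path.name}: {sorted(dupes)}")
    return ExpressionMatrix(gene_ids, sample_ids, values, scale_tag=scale_tag)


def _read_gct(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    """Parse GCT v1.3: a '#1.3' version line, a dimension line (rows, cols,
    row-metadata fields, column-metadata fields), a header row, optional
    column-metadata rows, then one data row per gene."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.3":
        got = lines[0] if lines else "<empty file>"
        raise ParseError(f"{path.name} line 1: expected GCT version '#1.3', got {got!r}")
    if len(lines) < 3:
        raise ParseError(f"{path.name}: truncated GCT file")
    dims = lines[1].split("\t")
    if len(dims) not in (2, 4):
        raise ParseError(f"{path.name} line 2: expected 2 or 4 dimension fields, got {lines[1]!r}")
    try:
        nums = [int(x) for x in dims]
    except ValueError:
        raise ParseError(f"{path.name} line 2: non-integer dimension in {lines[1]!r}") from None
    n_rows, n_cols = nums[0], nums[1]
    n_rmeta, n_cmeta = (nums[2], nums[3]) if len(nums) == 4 else (0, 0)
    header = lines[2].split("\t")
    expected_header_len = 1 + n_rmeta + n_cols
    if len(header) != expected_header_len:
        raise ParseError(
            f"{path.name} line 3: header has {len(header)} fields, expected {expected_header_len}"
        )
    sample_ids = header[1 + n_rmeta:]
    data_start = 3 + n_cmeta
    data_lines = lines[data_start:]
    data_lines = [ln for ln in data_lines if ln.strip() != ""]
    if len(data_lines) != n_rows:
        raise ParseError(
            f"{path.name}: dimension line declares {n_rows} data rows, found {len(data_lines)}"
        )
    gene_ids: list[str] = []
    values = np.empty((n_rows, n_cols), dtype=float)
    for i, ln in enumerate(data_lines):
        fields = ln.split("\t")
        if len(fields) != expected_header_len:
            raise ParseError(
                f"{path.name} data row {i + 1}: {len(fields)} fields, expected {expected_header_len}"
            )
        gene_ids.append(fields[0])
        try:
            values[i, :] = [float(x) for x in fields[1 + n_rmeta:]]
        except ValueError:
            raise ParseError(f"{path.name} data row {i + 1}: non-numeric value") from None
    return gene_ids, sample_ids, values


def write_expression_matrix(path: str | Path, expr: ExpressionMatrix, format: str | None = None) -> None:
    """Write a matrix as TSV or GCT v1.3 (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.3\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\t0\t0\n")
            fh.write("id\t" + "\t".join(expr.sample_ids) + "\n")
            for g, row in zip(expr.gene_ids, expr.values):
                fh.write(g + "\t" + "\t".join(FLOAT_FORMAT % v for v in row) + "\n")
    elif format == "tsv":
        expr.to_frame().to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# Sample groupings
# ---------------------------------------------------------------------------

@dataclass
class SampleGrouping:
    """Two disjoint sample groups (each of size >= 2) within a matrix."""

    group1: list[str]
    group2: list[str]

    def __post_init__(self) -> None:
        self.group1 = [str(s) for s in self.group1]
        self.group2 = [str(s) for s in self.group2]
        if len(self.group1) < 2 or len(self.group2) < 2:
            raise ValidationError(
                f"both groups need >= 2 samples (got {len(self.group1)} and {len(self.group2)})"
            )
        overlap = set(self.group1) & set(self.group2)
        if overlap:
            raise ValidationError(f"groups overlap: {sorted(overlap)}")

    def swapped(self) -> "SampleGrouping":
        return SampleGrouping(group2=list(self.group1), group1=list(self.group2))

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = (set(self.group1) | set(self.group2)) - set(expr.sample_ids)
        if missing:
            raise ValidationError(f"grouping references samples absent from matrix: {sorted(missing)}")


def read_grouping(path: str | Path) -> SampleGrouping:
    """Read a two-column TSV (sample, group) with group values group1/group2."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ParseError(f"{Path(path).name}: missing required column {col!r}")
    bad = set(df["group"]) - {"group1", "group2"}
    if bad:
        raise ValidationError(f"group labels must be group1/group2, got {sorted(bad)}")
    return SampleGrouping(
        group1=df.loc[df["group"] == "group1", "sample"].tolist(),
        group2=df.loc[df["group"] == "group2", "sample"].tolist(),
    )


def write_grouping(path: str | Path, grouping: SampleGrouping) -> None:
    rows = [(s, "group1") for s in grouping.group1] + [(s, "group2") for s in grouping.group2]
    pd.DataFrame(rows, columns=["sample", "group"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """One dataset's young-vs-old DE results: gene, log2fc, pvalue.

    ``log2fc`` is oriented log2(old/young): positive means up in aging.
    ``n_dropped`` counts input rows discarded for missing values.
    """

    dataset_id: str
    frame: pd.DataFrame  # columns: gene, log2fc, pvalue
    n_dropped: int = 0

    def __post_init__(self) -> None:
        required = ["gene", "log2fc", "pvalue"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"DETable {self.dataset_id}: missing columns {missing}")
        self.frame = self.frame[required].copy()
        self.frame["gene"] = self.frame["gene"].astype(str)
        self.frame["log2fc"] = self.frame["log2fc"].astype(float)
        self.frame["pvalue"] = self.frame["pvalue"].astype(float)
        dupes = _duplicates(self.frame["gene"].tolist())
        if dupes:
            raise ValidationError(f"DETable {self.dataset_id}: duplicate genes {sorted(dupes)[:10]}")
        if not np.all(np.isfinite(self.frame["log2fc"])):
            raise ValidationError(f"DETable {self.dataset_id}: non-finite log2fc")
        p = self.frame["pvalue"].to_numpy()
        if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
            raise ValidationError(f"DETable {self.dataset_id}: p-values must lie in [0, 1]")


def read_de_table(path: str | Path, dataset_id: str) -> DETable:
    """Read a DE table; rows with missing log2fc or pvalue are dropped and counted."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, float_precision="round_trip")
    for col in ("gene", "log2fc", "pvalue"):
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing required column {col!r}")
    n_in = len(df)
    df = df.dropna(subset=["log2fc", "pvalue"])
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.info("read_de_table(%s): dropped %d rows with missing values", path.name, n_dropped)
    return DETable(dataset_id=dataset_id, frame=df.reset_index(drop=True), n_dropped=n_dropped)


def write_de_table(path: str | Path, table: DETable) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Aging signatures
# ---------------------------------------------------------------------------

@dataclass
class AgingSignature:
    """One tissue class of the aging signature.

    ``entries`` has columns ``gene`` (str), ``direction`` (±1, the marker
    vector component: +1 rises with age, −1 falls), ``combined_p`` (the
    Edgington-combined p across all training datasets) and ``rank``
    (1-based, ascending combined_p under the total tie-break).
    """

    class_label: str
    entries: pd.DataFrame  # columns: gene, direction, combined_p, rank

    def __post_init__(self) -> None:
        required = ["gene", "direction", "combined_p", "rank"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ValidationError(f"signature {self.class_label}: missing columns {missing}")
        self.entries = self.entries[required].copy().reset_index(drop=True)
        self.entries["gene"] = self.entries["gene"].astype(str)
        self.entries["direction"] = self.entries["direction"].astype(int)
        self.entries["combined_p"] = self.entries["combined_p"].astype(float)
        self.entries["rank"] = self.entries["rank"].astype(int)
        if not set(np.unique(self.entries["direction"])) <= {-1, 1}:
            raise ValidationError(f"signature {self.class_label}: directions must be ±1")
        dupes = _duplicates(self.entries["gene"].tolist())
        if dupes:
            raise ValidationError(f"signature {self.class_label}: duplicate genes {sorted(dupes)}")
        cp = self.entries["combined_p"].to_numpy()
        if np.any(cp < 0) or np.any(cp > 1):
            raise ValidationError(f"signature {self.class_label}: combined_p outside [0, 1]")
        rk = self.entries["rank"].to_numpy()
        if len(rk) and (np.any(np.diff(rk) <= 0) or np.any(np.diff(cp) < 0)):
            raise ValidationError(
                f"signature {self.class_label}: ranks must increase and combined_p be nondecreasing"
            )

    @property
    def genes(self) -> list[str]:
        return self.entries["gene"].tolist()

    @property
    def directions(self) -> np.ndarray:
        """The marker vector M_k over the signature's genes."""
        return self.entries["direction"].to_numpy()

    def __len__(self) -> int:
        return len(self.entries)


def validate_signature_exclusivity(signatures: Sequence[AgingSignature]) -> None:
    """Signature classes must be mutually exclusive gene sets."""
    seen: dict[str, str] = {}
    for sig in signatures:
        for g in sig.genes:
            if g in seen:
                raise ValidationError(
                    f"gene {g!r} appears in both {seen[g]} and {sig.class_label} signatures"
                )
            seen[g] = sig.class_label


def write_signatures(path: str | Path, signatures: Sequence[AgingSignature]) -> None:
    validate_signature_exclusivity(signatures)
    parts = []
    for sig in signatures:
        df = sig.entries.copy()
        df.insert(0, "class", sig.class_label)
        parts.append(df)
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["class", "gene", "direction", "combined_p", "rank"]
    )
    out = out[["class", "rank", "gene", "direction", "combined_p"]]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_signatures(path: str | Path) -> list[AgingSignature]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "class": str}, float_precision="round_trip")
    for col in ("class", "rank", "gene", "direction", "combined_p"):
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing required column {col!r}")
    signatures = []
    for label in df["class"].drop_duplicates():
        sub = df[df["class"] == label].sort_values("rank")
        signatures.append(AgingSignature(class_label=str(label), entries=sub))
    validate_signature_exclusivity(signatures)
    return signatures


# ---------------------------------------------------------------------------
# Screen metadata
# ---------------------------------------------------------------------------

@dataclass
class ScreenMetadata:
    """Per-instance annotations for a perturbation screen matrix.

    One row per profiled instance: ``sample_id``, ``perturbation_id``,
    ``dose`` and ``time`` (value+unit strings), ``plate_id`` and
    ``is_control``.  Control instances are matched to perturbations by
    plate; every plate carrying a perturbation needs >= 2 controls for its
    groups to be scoreable (under-replicated plates are skipped downstream).
    """

    frame: pd.DataFrame

    COLUMNS = ("sample_id", "perturbation_id", "dose", "time", "plate_id", "is_control")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"screen metadata: missing columns {missing}")
        self.frame = self.frame[list(self.COLUMNS)].copy().reset_index(drop=True)
        for col in self.COLUMNS[:5]:
            self.frame[col] = self.frame[col].astype(str)
        self.frame["is_control"] = self.frame["is_control"].map(_parse_bool)
        dupes = _duplicates(self.frame["sample_id"].tolist())
        if dupes:
            raise ValidationError(f"screen metadata: duplicate sample IDs {sorted(dupes)[:10]}")

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = set(self.frame["sample_id"]) - set(expr.sample_ids)
        if missing:
            raise ValidationError(
                f"screen metadata references samples absent from matrix: {sorted(missing)[:10]}"
            )


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise ValidationError(f"cannot interpret is_control value {x!r}")


def read_screen_metadata(path: str | Path) -> ScreenMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ScreenMetadata(frame=df)


def write_screen_metadata(path: str | Path, meta: ScreenMetadata) -> None:
    out = meta.frame.copy()
    out["is_control"] = out["is_control"].map(lambda b: "1" if b else "0")
    out.to_csv(path, sep="\t", index=False)
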