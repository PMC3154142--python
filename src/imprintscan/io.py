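"""Domain types and plain-text I/O for methylation-array data.

The central container is :class:`BetaMatrix`, a probes x samples matrix of
methylation fractions (beta values in [0, 1]) with an optional parallel
matrix of detection p-values.  Probe annotation (probe id, gene symbol,
chromosome, 1-based position) and the sample sheet (sample id, study group)
are plain pandas DataFrames validated on read.

All on-disk formats are tab-separated text; BED output follows the usual
0-based half-open convention while annotation positions are 1-based.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: closed vocabulary of chromosome labels for the probe annotation
CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

#: closed vocabulary of study groups for the sample sheet
GROUPS = (
    "diandric",
    "digynic",
    "normal_placenta",
    "chm",
    "maternal_blood",
    "brain",
    "kidney",
    "muscle",
    "placenta_mid",
    "placenta_term",
)

_PROBE_ID_ALIASES = ("probe_id", "ID_REF", "TargetID")

_BETA_TOL = 1e-9


class BetaMatrix:
    """Probes x samples beta-value matrix with optional detection p-values.

    Parameters
    ----------
    beta
        DataFrame of methylation fractions; index = probe ids, columns =
        sample ids.  Values must lie in ``[0, 1]`` (tolerance 1e-9); NaN
        marks a missing measurement.
    detection_p
        Optional DataFrame of the same shape holding per-cell detection
        p-values in ``[0, 1]``.
    """

    def __init__(self, beta: pd.DataFrame, detection_p: pd.DataFrame | None = None):
        beta = beta.astype(float)
        if beta.index.has_duplicates:
            dups = beta.index[beta.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated probe ids: {dups}")
        if beta.columns.has_duplicates:
            dups = beta.columns[beta.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids: {dups}")
        bad = (beta.to_numpy() < -_BETA_TOL) | (beta.to_numpy() > 1 + _BETA_TOL)
        if np.any(bad & ~np.isnan(beta.to_numpy())):
            r, c = np.argwhere(bad & ~np.isnan(beta.to_numpy()))[0]
            raise ValidationError(
                f"beta value out of [0, 1] at probe {beta.index[r]!r}, "
                f"sample {beta.columns[c]!r}: {beta.iat[r, c]}"
            )
        if detection_p is not None:
            detection_p = detection_p.astype(float)
            if not detection_p.index.equals(beta.index) or not detection_p.columns.equals(
                beta.columns
            ):
                raise ValidationError("detection_p shape/keys do not match beta")
            dp = detection_p.to_numpy()
            if np.any(((dp < 0) | (dp > 1)) & ~np.isnan(dp)):
                raise ValidationError("detection p-values must lie in [0, 1]")
        self.beta = beta.clip(0.0, 1.0)
        self.detection_p = detection_p

    # -- convenience accessors -------------------------------------------------
    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> pd.Index:
        return self.beta.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        dp = None if self.detection_p is None else self.detection_p.loc[probe_ids]
        return BetaMatrix(self.beta.loc[probe_ids], dp)

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        dp = None if self.detection_p is None else self.detection_p[list(sample_ids)]
        return BetaMatrix(self.beta[list(sample_ids)], dp)

    def __eq__(self, other) -> bool:  # full-precision equality, for round-trips
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        same_beta = self.beta.equals(other.beta)
        if self.detection_p is None or other.detection_p is None:
            return same_beta and self.detection_p is other.detection_p
        return same_beta and self.detection_p.equals(other.detection_p)

    def __repr__(self) -> str:
        return f"BetaMatrix({self.shape[0]} probes x {self.shape[1]} samples)"


@dataclass
class DMLCall:
    """One candidate imprinted probe (differentially methylated locus)."""

    probe_id: str
    origin: str  # "maternal" | "paternal"
    mean_diandric: float
    mean_digynic: float
    mean_normal: float
    mean_chm: float
    delta_beta: float  # mean_diandric - mean_digynic, signed
    q_value: float
    consistent: bool | None = None
    elimination_reason: str = ""
    cnv_overlap: bool | None = None


@dataclass
class DMR:
    """A differentially methylated region: probes aggregated per (gene, origin)."""

    dmr_id: str
    gene_symbol: str
    origin: str
    probe_ids: list[str]
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    mean_abs_delta: float | None = None


# -----------------------------------------------------------------------------
# readers
# -----------------------------------------------------------------------------

def _check_header(path: Path, sep: str = "\t") -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if not header or header[0] not in _PROBE_ID_ALIASES:
        raise FormatError(
            f"{path}: first column must be a probe-id column "
            f"(one of {_PROBE_ID_ALIASES}), got {header[:1]}"
        )
    dups = [c for i, c in enumerate(header[1:]) if c in header[1 : 1 + i]]
    if dups:
        raise FormatError(f"{path}: duplicated sample columns: {sorted(set(dups))}")
    return header


def read_beta_table(path, detection_path=None) -> BetaMatrix:
    """Read a beta-value TSV (probe rows x sample columns) into a BetaMatrix.

    The first column must be named ``probe_id`` (``ID_REF``/``TargetID`` are
    accepted for series-matrix-style exports).  An optional second TSV with
    identical layout supplies detection p-values.  Missing cells are allowed
    and recorded as NaN; out-of-range or non-numeric cells raise
    :class:`ValidationError`/:class:`FormatError` naming the offending cell.
    """
    path = Path(path)
    _check_header(path)
    try:
        beta = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse beta table: {exc}") from exc
    for col in beta.columns:
        coerced = pd.to_numeric(beta[col], errors="coerce")
        newly_nan = coerced.isna() & beta[col].notna()
        if newly_nan.any():
            probe = beta.index[newly_nan.argmax()]
            raise ValidationError(
                f"{path}: non-numeric beta at probe {probe!r}, sample {col!r}: "
                f"{beta[col][newly_nan].iloc[0]!r}"
            )
        beta[col] = coerced
    detection = None
    if detection_path is not None:
        detection_path = Path(detection_path)
        _check_header(detection_path)
        detection = pd.read_csv(
            detection_path, sep="\t", index_col=0, float_precision="round_trip"
        )
        detection = detection.reindex(index=beta.index, columns=beta.columns)
    return BetaMatrix(beta, detection)


def write_beta_table(bm: BetaMatrix, path, detection_path=None) -> None:
    """Inverse of :func:`read_beta_table`; full float precision."""
    bm.beta.rename_axis("probe_id").to_csv(path, sep="\t")
    if detection_path is not None and bm.detection_p is not None:
        bm.detection_p.rename_axis("probe_id").to_csv(detection_path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    """Read probe annotation: probe_id, gene_symbol, chromosome, position.

    Positions are 1-based; chromosome labels must come from ``1..22, X, Y``.
    Returns a DataFrame indexed by probe_id.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"probe_id", "gene_symbol", "chromosome", "position"}
    missing = required - set(ann.columns)
    if missing:
        raise FormatError(f"{path}: annotation missing columns: {sorted(missing)}")
    if ann["probe_id"].duplicated().any():
        dups = ann.loc[ann["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"{path}: duplicated probe ids in annotation: {dups}")
    bad_chrom = ~ann["chromosome"].isin(CHROMOSOMES)
    if bad_chrom.any():
        raise ValidationError(
            f"{path}: chromosome labels outside 1..22/X/Y: "
            f"{sorted(ann.loc[bad_chrom, 'chromosome'].unique())}"
        )
    if (ann["position"] < 1).any():
        raise ValidationError(f"{path}: annotation positions must be >= 1")
    ann["gene_symbol"] = ann["gene_symbol"].fillna("")
    return ann.set_index("probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet (CSV or TSV) assigning samples to study groups.

    Columns: sample_id, group, optional sex and gestational_age.  Groups must
    come from the closed vocabulary in :data:`GROUPS`.  Returns a DataFrame
    indexed by sample_id.
    """
    path = Path(path)
    with open(path) as fh:
        sample = fh.readline()
    sep = "\t" if sample.count("\t") >= sample.count(",") else ","
    sheet = pd.read_csv(path, sep=sep)
    if "sample_id" not in sheet.columns or "group" not in sheet.columns:
        raise FormatError(f"{path}: sample sheet needs 'sample_id' and 'group' columns")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicated sample ids: {dups}")
    bad = ~sheet["group"].isin(GROUPS)
    if bad.any():
        raise ValidationError(
            f"{path}: unknown groups {sorted(sheet.loc[bad, 'group'].unique())}; "
            f"expected one of {GROUPS}"
        )
    if "sex" not in sheet.columns:
        sheet["sex"] = "unknown"
    if "gestational_age" not in sheet.columns:
        sheet["gestational_age"] = np.nan
    return sheet.set_index("sample_id")


# -----------------------------------------------------------------------------
# DML table round trip
# -----------------------------------------------------------------------------

_DML_COLUMNS = [f.name for f in fields(DMLCall)]


def write_dml_table(dml_calls: Iterable[DMLCall], path) -> None:
    """Write DML calls as a deterministic-column-order TSV (one row per probe)."""
    rows = [[getattr(c, col) for col in _DML_COLUMNS] for c in dml_calls]
    df = pd.DataFrame(rows, columns=_DML_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_dml_table(path) -> list[DMLCall]:
    """Inverse of :func:`write_dml_table`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_DML_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: DML table missing columns {sorted(missing)}")
    calls = []
    for _, row in df.iterrows():
        kw = {}
        for col in _DML_COLUMNS:
            val = row[col]
            if col in ("consistent", "cnv_overlap"):
                val = None if pd.isna(val) else bool(val)
            elif col == "elimination_reason":
                val = "" if pd.isna(val) else str(val)
            kw[col] = val
        calls.append(DMLCall(**kw))
    return calls


# -----------------------------------------------------------------------------
# BED output
# -----------------------------------------------------------------------------

def _chrom_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def to_bed_interval(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive span -> 0-based half-open BED interval."""
    if start_1based < 1 or end_1based < start_1based:
        raise ValidationError(f"invalid 1-based span [{start_1based}, {end_1based}]")
    return start_1based - 1, end_1based


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based inclusive span (inverse)."""
    if start < 0 or end <= start:
        raise ValidationError(f"invalid BED interval [{start}, {end})")
    return start + 1, end


def write_dmr_bed(dmrs: Iterable[DMR], path) -> None:
    """Write DMRs as BED6, sorted by chromosome then start.

    Name field is ``GENE|maternal`` or ``GENE|paternal``; score is
    ``round(1000 * mean |delta beta|)`` when available (browser shading),
    else 0.  A gene carrying both a maternal and a paternal region yields
    two distinct lines.
    """
    records = []
    for d in dmrs:
        start, end = to_bed_interval(d.start, d.end)
        score = 0 if d.mean_abs_delta is None else int(round(1000 * abs(d.mean_abs_delta)))
        records.append(
            (d.chromosome, start, end, f"{d.gene_symbol or d.dmr_id}|{d.origin}", score)
        )
    records.sort(key=lambda r: (_chrom_sort_key(r[0]), r[1]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for chrom, start, end, name, score in records:
            label = chrom if str(chrom).startswith("chr") else f"chr{chrom}"
            w.writerow([label, start, end, name, score, "."])


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED file into (chromosome, start, end) tuples (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED line needs >= 3 columns")
            chrom, start, end = parts[0].removeprefix("chr"), int(parts[1]), int(parts[2])
            if start >= end:
                raise ValidationError(f"{path}:{ln}: start >= end in interval")
            intervals.append((chrom, start, end))
    return intervals
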