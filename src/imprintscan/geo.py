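"""Optional real-data benchmark against the deposited GEO accession GSE25966.

The benchmark is download-gated so the package builds and tests fully
offline: the user fetches the series-matrix file for GSE25966 from the NCBI
Gene Expression Omnibus by hand (see docs/methods.md) and curates a CSV
mapping GEO sample accessions to study groups; :func:`prepare_gse25966`
then validates both into pipeline inputs.
"""

from __future__ import annotations

import gzip
import io as _io
import warnings
from pathlib import Path

import pandas as pd

from .errors import FormatError
from .io import GROUPS, BetaMatrix

#: the published triploid-comparison design (samples per group)
EXPECTED_DESIGN = {
    "diandric": 10,
    "digynic": 10,
    "normal_placenta": 10,
    "chm": 6,
    "maternal_blood": 10,
}

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_series_matrix(path) -> pd.DataFrame:
    """Parse the data table of a GEO series-matrix file (probes x GSM ids).

    Metadata lines (starting with ``!``) are skipped; the table between the
    begin/end markers is read as TSV with quoted headers.  A truncated file
    (no end marker) is a format error.
    """
    path = Path(path)
    lines, in_table, closed = [], False, False
    with _open_text(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped == TABLE_BEGIN:
                in_table = True
                continue
            if stripped == TABLE_END:
                closed = True
                break
            if in_table:
                lines.append(line)
    if not in_table:
        raise FormatError(f"{path}: no {TABLE_BEGIN} marker found")
    if not closed:
        raise FormatError(f"{path}: truncated series matrix (missing {TABLE_END})")
    if not lines:
        raise FormatError(f"{path}: empty series-matrix table")
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t")
    df.columns = [c.strip('"') for c in df.columns]
    df[df.columns[0]] = df[df.columns[0]].astype(str).str.strip('"')
    return df.set_index(df.columns[0])


def prepare_gse25966(series_matrix_path, groups_file) -> tuple[BetaMatrix, pd.DataFrame]:
    """Turn a downloaded series matrix plus a curated group map into
    pipeline inputs.

    ``groups_file`` is a CSV with columns ``sample_id`` (GSM accession) and
    ``group``.  Samples missing from the map are dropped with a warning
    naming them; a deviation from the published 10/10/10/6/10 triploid
    design is warned about with the per-group diff.  Probe order from the
    matrix is preserved.
    """
    table = read_series_matrix(series_matrix_path)
    mapping = pd.read_csv(groups_file)
    if "sample_id" not in mapping.columns or "group" not in mapping.columns:
        raise FormatError(f"{groups_file}: needs 'sample_id' and 'group' columns")
    bad = ~mapping["group"].isin(GROUPS)
    if bad.any():
        raise FormatError(
            f"{groups_file}: unknown groups {sorted(mapping.loc[bad, 'group'].unique())}"
        )
    mapping = mapping.set_index("sample_id")

    unmapped = [s for s in table.columns if s not in mapping.index]
    if unmapped:
        warnings.warn(f"samples without group assignment dropped: {unmapped}")
    keep = [s for s in table.columns if s in mapping.index]
    bm = BetaMatrix(table[keep])

    sheet = mapping.loc[keep].copy()
    counts = sheet["group"].value_counts().to_dict()
    diff = {
        g: (counts.get(g, 0), want)
        for g, want in EXPECTED_DESIGN.items()
        if counts.get(g, 0) != want
    }
    if diff:
        warnings.warn(
            "sample counts deviate from the published triploid design "
            f"(got, expected): {diff}"
        )
    sheet["sex"] = "unknown"
    sheet["gestational_age"] = float("nan")
    return bm, sheet
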