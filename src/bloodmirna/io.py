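"""Readers and writers for the pipeline's tabular formats.

Count matrices travel as plain CSV with a ``probe`` id column, a ``class``
column (Endogenous / Negative / Positive) and one column per sample, paired
with a sample sheet CSV (``sample, donor, cell_type``).  Deposited expression
data in GEO series-matrix form (tab-delimited, ``!``-prefixed metadata lines)
is read from a local file; no network retrieval is attempted.

Probe identity across codeset versions is the probe-name string after
stripping assay-version suffixes (a trailing ``|...`` accession tag or a
``_v1`` / ``_v2`` marker).  Multi-target probes whose sequences the platform
cannot distinguish (compound names like ``miR-106a-5p/17-5p``) are kept as
single rows under the compound name.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from .core import (
    CellPrepTable,
    ElectropherogramTrace,
    FormatError,
    RawCountMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

_VERSION_SUFFIX = re.compile(r"(\|.*$|[_-]v[12]$)", re.IGNORECASE)


def canonical_probe_id(probe: str) -> str:
    """Strip assay-version decorations from a probe name."""
    return _VERSION_SUFFIX.sub("", probe.strip())


# ---------------------------------------------------------------------------
# Count matrix + sample sheet
# ---------------------------------------------------------------------------


def write_count_matrix(matrix: RawCountMatrix, counts_path, samples_path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "class", matrix.probe_class)
    out.index.name = "probe"
    out.to_csv(counts_path)
    sheet = matrix.samples.copy()
    sheet.index.name = "sample"
    sheet.to_csv(samples_path)


def read_count_matrix(
    counts_path, samples_path, codeset_version: str = ""
) -> RawCountMatrix:
    """Read a probe x sample count CSV plus its sample sheet.

    Raises :class:`FormatError` when the probe-class column is absent and
    :class:`ValidationError` (naming probe and sample) on negative counts.
    """
    df = pd.read_csv(counts_path, index_col=0)
    if "class" not in df.columns:
        raise FormatError(f"{counts_path}: missing probe-class column 'class'")
    probe_class = df["class"]
    counts = df.drop(columns=["class"])
    sheet = pd.read_csv(samples_path, index_col=0)
    return RawCountMatrix(counts, probe_class, sheet, codeset_version=codeset_version)


# ---------------------------------------------------------------------------
# Electropherogram traces / cell records
# ---------------------------------------------------------------------------


def write_trace(trace: ElectropherogramTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace(path) -> ElectropherogramTrace:
    df = pd.read_csv(path)
    for col in ("size_nt", "intensity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return ElectropherogramTrace.from_frame(df)


def write_cell_records(records: CellPrepTable, path) -> None:
    out = records.table.copy()
    out.index.name = "cell_type"
    out.to_csv(path)


def read_cell_records(path) -> CellPrepTable:
    df = pd.read_csv(path, index_col=0)
    return CellPrepTable(df)


# ---------------------------------------------------------------------------
# GEO series-matrix
# ---------------------------------------------------------------------------


def read_geo_series_matrix(
    path, sample_map: dict[str, tuple[str, str]], codeset_version: str = "geo"
) -> RawCountMatrix:
    """Parse a GEO series-matrix text file from a local path.

    ``sample_map`` maps each sample title (the ``!Sample_title`` entries) to a
    ``(donor, cell_type)`` pair; values in the expression block are passed
    through unmodified.  Unmappable titles raise an error listing them all.
    Probe classes are not encoded in series-matrix files; all rows are taken
    as endogenous unless the id starts with ``NEG`` (negative control).
    """
    path = Path(path)
    titles: list[str] = []
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!Sample_title"):
                titles = [t.strip('"') for t in line.split("\t")[1:]]
            elif line.startswith("!series_matrix_table_begin"):
                in_table = True
            elif line.startswith("!series_matrix_table_end"):
                in_table = False
            elif in_table and line:
                table_lines.append(line)
    if not table_lines:
        raise FormatError(f"{path}: no series-matrix table block found")

    header = [t.strip('"') for t in table_lines[0].split("\t")]
    rows = []
    index = []
    for line in table_lines[1:]:
        parts = [t.strip('"') for t in line.split("\t")]
        index.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    counts = pd.DataFrame(rows, index=index, columns=header[1:])

    accessions = list(counts.columns)
    if titles and len(titles) == len(accessions):
        counts.columns = titles
    unmapped = [t for t in counts.columns if t not in sample_map]
    if unmapped:
        raise ValidationError(f"unmapped sample titles: {unmapped}")
    sheet = pd.DataFrame(
        {
            "donor": [sample_map[t][0] for t in counts.columns],
            "cell_type": [sample_map[t][1] for t in counts.columns],
        },
        index=pd.Index(counts.columns, name="sample"),
    )
    probe_class = pd.Series(
        ["Negative" if p.upper().startswith("NEG") else "Endogenous" for p in index],
        index=counts.index,
    )
    return RawCountMatrix(counts, probe_class, sheet, codeset_version=codeset_version)


# ---------------------------------------------------------------------------
# Probe-set merging across codeset versions
# ---------------------------------------------------------------------------


def intersect_probe_sets(
    a: RawCountMatrix, b: RawCountMatrix
) -> tuple[RawCountMatrix, RawCountMatrix]:
    """Restrict two matrices to their shared probes, same row order in both.

    Probe identity is the canonical (version-stripped) probe name; the shared
    set is the exact intersection, ordered as in ``a``.  Dropped-row counts
    per input are logged.
    """
    canon_a = {canonical_probe_id(p): p for p in a.probe_ids}
    canon_b = {canonical_probe_id(p): p for p in b.probe_ids}
    shared = [c for c in (canonical_probe_id(p) for p in a.probe_ids) if c in canon_b]
    if not shared:
        raise ValidationError("probe-set intersection is empty")
    logger.info(
        "intersect_probe_sets: %d shared probes (dropped %d from a, %d from b)",
        len(shared), a.n_probes - len(shared), b.n_probes - len(shared),
    )
    out_a = a.restrict_probes([canon_a[c] for c in shared])
    out_b = b.restrict_probes([canon_b[c] for c in shared])
    return out_a, out_b
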