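"""Reading/writing abundance tables and converting between quantification units.

Supported dialects: a generic feature x sample TSV, and the native per-sample
output tables of common quantifiers — HTSeq two-column count files, Kallisto
``abundance.tsv``, Salmon ``quant.sf``, RSEM ``.genes.results`` /
``.isoforms.results``, and Cufflinks FPKM tracking tables. Per-sample formats
are read as one file per sample and assembled into a single
:class:`~mixlin.matrix.QuantMatrix`.

Unit conversions implement the standard definitions: TPM divides a
length-normalized rate by the per-sample rate total (columns sum to 1e6);
FPKM divides counts by kilobase length and per-million library size; the log
transform is log2(x + 1). RPKM is accepted as an alias of FPKM.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .matrix import QuantMatrix, SampleInfo, infer_sample_info

#: feature_id -> length in bases; any positive-real mapping or pd.Series works.
FeatureLengths = pd.Series

FORMATS = ("generic_tsv", "htseq", "kallisto", "salmon", "rsem", "cufflinks")

# Column names of each per-sample dialect; "rpkm" aliases the FPKM column.
_ADAPTERS: dict[str, dict[str, str]] = {
    "kallisto": {"id": "target_id", "count": "est_counts", "tpm": "tpm",
                 "length": "eff_length"},
    "salmon": {"id": "Name", "count": "NumReads", "tpm": "TPM",
               "length": "EffectiveLength"},
    "rsem": {"id": None, "count": "expected_count", "tpm": "TPM",
             "fpkm": "FPKM", "rpkm": "FPKM", "length": "effective_length"},
    "cufflinks": {"id": "tracking_id", "fpkm": "FPKM", "rpkm": "FPKM"},
}
_RSEM_ID_COLUMNS = ("gene_id", "transcript_id")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_matrix(source, format: str = "generic_tsv", unit: str | None = None,
                sample_info: Mapping[str, SampleInfo] | None = None,
                level: str = "gene") -> QuantMatrix:
    """Read an abundance matrix in one of the supported dialects.

    ``source`` is a path for ``generic_tsv`` and a mapping
    ``sample_id -> path`` (one file per sample) for the per-sample formats.
    ``unit`` selects the value column where a format offers several
    (kallisto/salmon: count or tpm; rsem: count, tpm or fpkm); it defaults to
    the format's primary unit (htseq -> count, cufflinks -> fpkm,
    generic/kallisto/salmon/rsem -> count).
    """
    if format not in FORMATS:
        raise FormatError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "generic_tsv":
        return _read_generic(source, unit or "count", sample_info, level)
    if not isinstance(source, Mapping):
        raise FormatError(f"format {format!r} expects a mapping of sample_id -> path")

    unit = (unit or ("fpkm" if format == "cufflinks" else "count")).lower()
    columns: dict[str, pd.Series] = {}
    for sid, path in source.items():
        columns[sid] = _read_sample_file(Path(path), format, unit)
    values = _align_columns(columns)
    if sample_info is None:
        sample_info = infer_sample_info(values.columns)
    stored_unit = "fpkm" if unit == "rpkm" else unit
    return QuantMatrix(values=values, sample_info=sample_info, unit=stored_unit,
                       level=level)


def _read_generic(path, unit, sample_info, level) -> QuantMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise DataError(f"{path}: duplicate feature IDs: {dups}")
    df.index.name = "feature_id"
    if sample_info is None:
        sample_info = infer_sample_info(df.columns)
    return QuantMatrix(values=df, sample_info=sample_info, unit=unit, level=level)


def _read_sample_file(path: Path, format: str, unit: str) -> pd.Series:
    if format == "htseq":
        if unit != "count":
            raise FormatError(f"htseq files provide counts only, not {unit!r}")
        df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "count"])
        # HTSeq appends summary rows (__no_feature, __ambiguous, ...): drop them
        df = df[~df["feature_id"].astype(str).str.startswith("__")]
        s = pd.Series(df["count"].to_numpy(float),
                      index=pd.Index(df["feature_id"], name="feature_id"))
    else:
        spec = _ADAPTERS[format]
        df = pd.read_csv(path, sep="\t")
        id_col = spec["id"]
        if id_col is None:  # RSEM: gene or isoform table
            id_col = next((c for c in _RSEM_ID_COLUMNS if c in df.columns), None)
            if id_col is None:
                raise FormatError(
                    f"{path}: missing required column "
                    f"{' or '.join(map(repr, _RSEM_ID_COLUMNS))}")
        elif id_col not in df.columns:
            raise FormatError(f"{path}: missing required column {id_col!r}")
        value_col = spec.get(unit)
        if value_col is None:
            raise FormatError(f"format {format!r} does not provide unit {unit!r}")
        if value_col not in df.columns:
            raise FormatError(f"{path}: missing required column {value_col!r}")
        s = pd.Series(df[value_col].to_numpy(float),
                      index=pd.Index(df[id_col], name="feature_id"))
    if s.index.has_duplicates:
        dups = s.index[s.index.duplicated()].unique().tolist()[:5]
        raise DataError(f"{path}: duplicate feature IDs: {dups}")
    return s


def _align_columns(columns: dict[str, pd.Series]) -> pd.DataFrame:
    ids = None
    first = None
    for sid, s in columns.items():
        if ids is None:
            ids, first = set(s.index), sid
        elif set(s.index) != ids:
            missing = sorted(ids - set(s.index))[:5]
            extra = sorted(set(s.index) - ids)[:5]
            raise DataError(
                f"sample {sid!r} feature set differs from {first!r}: "
                f"missing {missing}, extra {extra}")
    order = columns[first].index
    return pd.DataFrame({sid: s.reindex(order) for sid, s in columns.items()})


def read_feature_lengths(source, format: str = "generic_tsv") -> FeatureLengths:
    """Read per-feature lengths.

    ``generic_tsv`` expects a two-column TSV (feature_id, length); the
    kallisto/salmon/rsem dialects take one of their per-sample files and use
    the tool's own (effective) length column.
    """
    if format == "generic_tsv":
        df = pd.read_csv(source, sep="\t", index_col=0)
        s = df.iloc[:, 0].astype(float)
    elif format in ("kallisto", "salmon", "rsem"):
        spec = _ADAPTERS[format]
        df = pd.read_csv(source, sep="\t")
        id_col = spec["id"] or next(
            (c for c in _RSEM_ID_COLUMNS if c in df.columns), None)
        if id_col is None or id_col not in df.columns:
            raise FormatError(f"{source}: missing feature-ID column")
        length_col = spec["length"]
        if length_col not in df.columns:
            raise FormatError(f"{source}: missing required column {length_col!r}")
        s = pd.Series(df[length_col].to_numpy(float),
                      index=pd.Index(df[id_col], name="feature_id"))
    else:
        raise FormatError(f"no length information in format {format!r}")
    s.index.name = "feature_id"
    validate_lengths(s, s.index)
    return s


def validate_lengths(lengths: FeatureLengths, feature_ids) -> pd.Series:
    """Check lengths are positive and cover every feature; return aligned Series."""
    lengths = pd.Series(lengths, dtype=float)
    missing = [f for f in feature_ids if f not in lengths.index]
    if missing:
        raise DataError(f"lengths missing for features: {missing[:5]}"
                        + ("..." if len(missing) > 5 else ""))
    aligned = lengths.reindex(feature_ids)
    if not np.isfinite(aligned.to_numpy()).all() or (aligned <= 0).any():
        raise DataError("feature lengths must be positive and finite")
    return aligned


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_matrix(m: QuantMatrix, path) -> None:
    """Write the generic matrix TSV: first column ``feature_id``, one column
    per sample, ``%.10g`` floats, tab-delimited."""
    m.values.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def _require_counts(m: QuantMatrix, op: str) -> None:
    if m.unit != "count":
        raise DataError(f"{op} expects unit 'count', got {m.unit!r}")


def _no_zero_samples(m: QuantMatrix, op: str) -> None:
    sums = m.values.sum(axis=0)
    zero = list(sums.index[sums == 0])
    if zero:
        raise DataError(f"{op} undefined for all-zero samples: {zero}")


def counts_to_tpm(m: QuantMatrix, lengths: FeatureLengths) -> QuantMatrix:
    """Transcripts Per Million: rate_i = count_i / length_i, then each sample
    column is scaled so rates sum to 1e6."""
    _require_counts(m, "counts_to_tpm")
    _no_zero_samples(m, "counts_to_tpm")
    L = validate_lengths(lengths, m.feature_ids)
    rate = m.values.div(L, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return m.with_values(tpm, unit="tpm")


def counts_to_fpkm(m: QuantMatrix, lengths: FeatureLengths) -> QuantMatrix:
    """Fragments Per Kilobase per Million mapped fragments:
    FPKM_i = count_i * 1e9 / (length_i * total_counts)."""
    _require_counts(m, "counts_to_fpkm")
    _no_zero_samples(m, "counts_to_fpkm")
    L = validate_lengths(lengths, m.feature_ids)
    totals = m.values.sum(axis=0)
    fpkm = m.values.div(L, axis=0).div(totals, axis=1) * 1e9
    return m.with_values(fpkm, unit="fpkm")


def log_transform(m: QuantMatrix) -> QuantMatrix:
    """log2(x + 1); zeros stay zero. The original unit is recorded in
    ``source_unit`` provenance."""
    arr = m.values.to_numpy()
    if (arr < 0).any():
        raise ValueError("log_transform requires non-negative values")
    logged = pd.DataFrame(np.log2(arr + 1.0), index=m.values.index,
                          columns=m.values.columns)
    return m.with_values(logged, unit="log", source_unit=m.unit)
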