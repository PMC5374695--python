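"""Feature-by-sample abundance matrices.

A :class:`QuantMatrix` is the central in-memory container of the package: a
features x samples table of non-negative abundances (counts, TPM, FPKM) or
log-scale values, together with per-sample metadata (sample type, replicate
index, library size) and a unit tag. All downstream stages — unit conversion,
mixture regression, concordance and residual analyses — operate on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError

VALID_UNITS = ("count", "tpm", "fpkm", "log")
VALID_LEVELS = ("gene", "isoform")

#: Every TPM sample column sums to one million by definition.
TPM_COLUMN_SUM = 1e6
TPM_RTOL = 1e-6


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sample column.

    Parameters
    ----------
    sample_type
        Sample-type label, e.g. ``"A"`` (pure) or ``"C"`` (mixture).
    replicate
        1-based replicate index within the sample type.
    library_size
        Expected total fragment count of the library, if known.
    """

    sample_type: str
    replicate: int
    library_size: float | None = None


def sample_id(sample_type: str, replicate: int) -> str:
    """Canonical sample identifier, e.g. ``A_2`` for replicate 2 of type A."""
    return f"{sample_type}_{replicate}"


def infer_sample_info(sample_ids) -> dict[str, SampleInfo]:
    """Parse ``TYPE_REP`` sample identifiers into :class:`SampleInfo` records.

    Identifiers that do not end in ``_<integer>`` are treated as a single
    replicate of a sample type named by the full identifier.
    """
    info: dict[str, SampleInfo] = {}
    for sid in sample_ids:
        stem, _, tail = str(sid).rpartition("_")
        if stem and tail.isdigit():
            info[sid] = SampleInfo(sample_type=stem, replicate=int(tail))
        else:
            info[sid] = SampleInfo(sample_type=str(sid), replicate=1)
    return info


@dataclass
class QuantMatrix:
    """Features x samples abundance table with unit and sample metadata.

    ``values`` is indexed by feature ID (unique, ordered) with one column per
    sample; ``sample_info`` maps every column to its :class:`SampleInfo`.
    ``unit`` is one of ``count``, ``tpm``, ``fpkm``, ``log``; for the log unit
    ``source_unit`` records the unit that was log-transformed.
    """

    values: pd.DataFrame
    sample_info: Mapping[str, SampleInfo]
    unit: str
    level: str = "gene"
    source_unit: str | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.unit not in VALID_UNITS:
            raise DataError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.level not in VALID_LEVELS:
            raise DataError(f"unknown level {self.level!r}; expected one of {VALID_LEVELS}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()[:5]
            raise DataError(f"duplicate feature IDs: {dups}")
        missing = [c for c in self.values.columns if c not in self.sample_info]
        if missing:
            raise DataError(f"samples without metadata: {missing}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise DataError("abundance matrix contains non-finite values")
        if self.unit != "log" and (arr < 0).any():
            raise DataError(f"negative values are invalid for unit {self.unit!r}")
        if self.unit == "tpm":
            sums = arr.sum(axis=0)
            bad = ~np.isclose(sums, TPM_COLUMN_SUM, rtol=TPM_RTOL)
            if bad.any():
                cols = list(self.values.columns[bad])[:5]
                raise DataError(f"TPM columns do not sum to 1e6: {cols}")

    # -- convenience accessors -------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def sample_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid in self.values.columns:
            seen.setdefault(self.sample_info[sid].sample_type, None)
        return list(seen)

    def replicate_indices(self, sample_type: str) -> list[int]:
        reps = sorted(
            info.replicate
            for sid, info in self.sample_info.items()
            if info.sample_type == sample_type and sid in self.values.columns
        )
        return reps

    def column(self, sample_type: str, replicate: int) -> pd.Series:
        """The abundance column of one (sample type, replicate)."""
        for sid in self.values.columns:
            info = self.sample_info[sid]
            if info.sample_type == sample_type and info.replicate == replicate:
                return self.values[sid]
        raise KeyError(f"no sample of type {sample_type!r} with replicate {replicate}")

    def columns_of_type(self, sample_type: str) -> pd.DataFrame:
        """All replicate columns of a sample type, ordered by replicate index."""
        sids = sorted(
            (sid for sid in self.values.columns
             if self.sample_info[sid].sample_type == sample_type),
            key=lambda s: self.sample_info[s].replicate,
        )
        if not sids:
            raise KeyError(f"no samples of type {sample_type!r}")
        return self.values[sids]

    def with_values(self, values: pd.DataFrame, unit: str,
                    source_unit: str | None = None) -> "QuantMatrix":
        """A new matrix sharing this one's metadata but with new values/unit."""
        return QuantMatrix(values=values, sample_info=dict(self.sample_info),
                           unit=unit, level=self.level, source_unit=source_unit)
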