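"""Readers and writers for joint repeat+gene count tables and sample metadata.

The count-table dialect follows TETranscripts output: a tab-separated table
whose first column holds feature identifiers and whose remaining columns hold
raw integer counts, one column per sample.  Repeat features are named as
colon-delimited ``subfamily:family:class`` triples (e.g.
``ALR/Alpha:centr:Satellite``); gene features are plain identifiers with no
colon.  Identifiers with one or three-or-more colons are rejected rather than
guessed, so unknown dialects fail loudly.

Metadata tables are tab-separated with a header; the only required column is
``sample``.  Missing cells are written as ``NA``.  Any column outside the
known clinical set is interpreted as a binary mutation flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE = "gene"
REPEAT = "repeat"

#: Metadata columns with fixed meaning; anything else is a 0/1 mutation flag.
KNOWN_META_COLUMNS = (
    "sample",
    "gender",
    "batch",
    "age",
    "cytogenetic_risk",
    "subtype",
    "survival_time",
    "event",
)

CYTOGENETIC_RISK_LEVELS = ("favorable", "intermediate", "adverse")

#: Header used for the feature-ID column when writing count tables
#: (TETranscripts uses "gene/TE").
ID_COLUMN_NAME = "gene/TE"


class TableFormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


@dataclass(frozen=True)
class FeatureID:
    """A count-table row identity: a gene or a repeat subfamily.

    Repeats carry the three TETranscripts name components; for genes all
    three repeat fields are empty strings.
    """

    raw_id: str
    kind: str  # GENE or REPEAT
    subfamily: str = ""
    family: str = ""
    repeat_class: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (GENE, REPEAT):
            raise ValueError(f"unknown feature kind {self.kind!r}")


def parse_feature_id(raw_id: str) -> FeatureID:
    """Classify a feature identifier as gene or repeat.

    Exactly two ``:`` separators mark a repeat (``subfamily:family:class``);
    zero colons mark a gene.  Any other colon count is an error.
    """
    n_colons = raw_id.count(":")
    if n_colons == 0:
        return FeatureID(raw_id=raw_id, kind=GENE)
    if n_colons == 2:
        subfamily, family, repeat_class = raw_id.split(":")
        return FeatureID(
            raw_id=raw_id,
            kind=REPEAT,
            subfamily=subfamily,
            family=family,
            repeat_class=repeat_class,
        )
    raise TableFormatError(
        f"feature ID {raw_id!r} has {n_colons} ':' separators; expected 0 "
        "(gene) or 2 (repeat subfamily:family:class)"
    )


@dataclass
class CountTable:
    """Features x samples matrix of raw non-negative integer counts."""

    features: list[FeatureID]
    samples: list[str]
    counts: np.ndarray  # (n_features, n_samples), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")
        ids = [f.raw_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature IDs")

    @property
    def kinds(self) -> np.ndarray:
        """Per-feature kind array ('gene'/'repeat')."""
        return np.array([f.kind for f in self.features])

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, keep: Sequence[str]) -> "CountTable":
        """Restrict to the given samples, preserving table order."""
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.samples) if s in keep_set]
        return CountTable(
            features=self.features,
            samples=[self.samples[i] for i in idx],
            counts=self.counts[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index([f.raw_id for f in self.features], name=ID_COLUMN_NAME),
            columns=self.samples,
        )


@dataclass
class SampleMetadata:
    """Clinical annotation for one sample.

    Optional fields are ``None`` when absent — never silently zero.
    Survival invariant: ``survival_time`` and ``event`` are present or absent
    together.
    """

    sample: str
    gender: Optional[str] = None
    batch: Optional[str] = None
    age: Optional[float] = None
    cytogenetic_risk: Optional[str] = None
    subtype: Optional[str] = None
    survival_time: Optional[float] = None
    event: Optional[int] = None
    mutations: dict[str, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.survival_time is None) != (self.event is None):
            raise ValueError(
                f"sample {self.sample!r}: survival_time and event must be "
                "present together"
            )
        if self.survival_time is not None and self.survival_time < 0:
            raise ValueError(f"sample {self.sample!r}: negative survival_time")
        if self.event is not None and self.event not in (0, 1):
            raise ValueError(f"sample {self.sample!r}: event must be 0 or 1")
        if self.cytogenetic_risk is not None and (
            self.cytogenetic_risk not in CYTOGENETIC_RISK_LEVELS
        ):
            raise ValueError(
                f"sample {self.sample!r}: cytogenetic_risk "
                f"{self.cytogenetic_risk!r} not in {CYTOGENETIC_RISK_LEVELS}"
            )
        for name, val in self.mutations.items():
            if val is not None and val not in (0, 1):
                raise ValueError(
                    f"sample {self.sample!r}: mutation flag {name!r} must be 0/1"
                )


# ---------------------------------------------------------------------------
# Count table I/O
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> CountTable:
    """Read a TETranscripts-dialect count table.

    Raises :class:`TableFormatError` naming the offending line for malformed
    rows, non-integer or negative counts, and duplicate feature IDs.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise TableFormatError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        if len(header) < 2:
            raise TableFormatError(f"{path}: header must name >=1 sample column")
        samples = header[1:]

        features: list[FeatureID] = []
        rows: list[list[int]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise TableFormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            raw_id = parts[0]
            if raw_id in seen:
                raise TableFormatError(
                    f"{path}: line {lineno}: duplicate feature ID {raw_id!r}"
                )
            seen.add(raw_id)
            try:
                counts = [int(v) for v in parts[1:]]
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}: line {lineno}: non-integer count ({exc})"
                ) from None
            if any(c < 0 for c in counts):
                raise TableFormatError(
                    f"{path}: line {lineno}: negative count"
                )
            features.append(parse_feature_id(raw_id))
            rows.append(counts)

    if not rows:
        raise TableFormatError(f"{path}: no data rows")
    return CountTable(
        features=features,
        samples=samples,
        counts=np.asarray(rows, dtype=np.int64),
    )


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table in the canonical dialect (round-trip safe)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join([ID_COLUMN_NAME, *table.samples]) + "\n")
        for feat, row in zip(table.features, table.counts):
            fh.write(feat.raw_id + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


# ---------------------------------------------------------------------------
# Metadata I/O
# ---------------------------------------------------------------------------

def _parse_optional_float(value: str, what: str, lineno: int) -> Optional[float]:
    if value == "NA" or value == "":
        return None
    try:
        out = float(value)
    except ValueError:
        raise TableFormatError(f"line {lineno}: non-numeric {what} {value!r}") from None
    if math.isnan(out):
        return None
    return out


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a tab-separated metadata table (required column: ``sample``)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise TableFormatError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        if "sample" not in header:
            raise TableFormatError(f"{path}: missing required column 'sample'")
        mutation_cols = [c for c in header if c not in KNOWN_META_COLUMNS]

        records: list[SampleMetadata] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise TableFormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            row = dict(zip(header, parts))
            name = row["sample"]
            if name in seen:
                raise TableFormatError(
                    f"{path}: line {lineno}: duplicate sample {name!r}"
                )
            seen.add(name)

            def _opt(key: str) -> Optional[str]:
                v = row.get(key, "NA")
                return None if v in ("NA", "") else v

            age = _parse_optional_float(row.get("age", "NA"), "age", lineno)
            time = _parse_optional_float(
                row.get("survival_time", "NA"), "survival_time", lineno
            )
            ev_raw = _opt("event")
            event = None if ev_raw is None else int(ev_raw)
            mutations: dict[str, Optional[int]] = {}
            for col in mutation_cols:
                v = _opt(col)
                mutations[col] = None if v is None else int(v)
            try:
                records.append(
                    SampleMetadata(
                        sample=name,
                        gender=_opt("gender"),
                        batch=_opt("batch"),
                        age=age,
                        cytogenetic_risk=_opt("cytogenetic_risk"),
                        subtype=_opt("subtype"),
                        survival_time=time,
                        event=event,
                        mutations=mutations,
                    )
                )
            except ValueError as exc:
                raise TableFormatError(f"{path}: line {lineno}: {exc}") from None
    return records


def _fmt(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_sample_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    """Write metadata as TSV with NA for missing cells (round-trip safe)."""
    mutation_cols = sorted({m for r in records for m in r.mutations})
    header = list(KNOWN_META_COLUMNS) + mutation_cols
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            row = [
                r.sample,
                _fmt(r.gender),
                _fmt(r.batch),
                _fmt(r.age),
                _fmt(r.cytogenetic_risk),
                _fmt(r.subtype),
                _fmt(r.survival_time),
                _fmt(r.event),
            ]
            row += [_fmt(r.mutations.get(c)) for c in mutation_cols]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_samples(
    table: CountTable, meta: Sequence[SampleMetadata]
) -> tuple[CountTable, list[SampleMetadata]]:
    """Restrict both inputs to their common samples, in table order.

    Dropped samples are logged as a warning; an empty intersection is an
    error.
    """
    meta_by_name = {m.sample: m for m in meta}
    common = [s for s in table.samples if s in meta_by_name]
    if not common:
        raise ValueError("no samples in common between count table and metadata")
    dropped_table = [s for s in table.samples if s not in meta_by_name]
    dropped_meta = [m.sample for m in meta if m.sample not in set(table.samples)]
    if dropped_table:
        logger.warning(
            "dropping %d count-table sample(s) without metadata: %s",
            len(dropped_table), ", ".join(dropped_table),
        )
    if dropped_meta:
        logger.warning(
            "dropping %d metadata sample(s) without counts: %s",
            len(dropped_meta), ", ".join(dropped_meta),
        )
    aligned_table = table.subset_samples(common) if dropped_table else table
    aligned_meta = [meta_by_name[s] for s in common]
    return aligned_table, aligned_meta
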