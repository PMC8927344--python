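"""Reading, writing and assembling nCounter RCC count data.

An RCC file is the per-sample output of an nCounter instrument: a handful
of XML-like tagged sections (``Header``, ``Sample_Attributes``,
``Lane_Attributes``, ``Code_Summary`` and optionally ``Messages``) whose
bodies are CSV lines.  ``Code_Summary`` carries one row per probe with its
code class (Endogenous assay genes, Housekeeping candidate references, and
the spiked Positive/Negative controls), probe name, transcript accession
and digital count.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class CodeClass(str, Enum):
    ENDOGENOUS = "Endogenous"
    HOUSEKEEPING = "Housekeeping"
    POSITIVE = "Positive"
    NEGATIVE = "Negative"


CODE_CLASSES = tuple(c.value for c in CodeClass)


class RCCFormatError(ValueError):
    """Raised when an RCC stream violates the expected dialect."""


@dataclass(frozen=True)
class ProbeRecord:
    """One Code_Summary row: probe class, name, accession and raw count."""

    code_class: str
    name: str
    accession: str
    count: int

    def __post_init__(self) -> None:
        if self.code_class not in CODE_CLASSES:
            raise ValueError(f"unknown code class {self.code_class!r}")
        if self.count < 0:
            raise ValueError(f"negative count for probe {self.name!r}")


@dataclass
class RCCSample:
    """A parsed RCC file: probes plus the sample/lane attribute sections."""

    sample_id: str
    probes: list[ProbeRecord]
    sample_attributes: dict[str, str] = field(default_factory=dict)
    lane_attributes: dict[str, str] = field(default_factory=dict)
    header: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise RCCFormatError(f"duplicate probe names: {dup}")
        classes = {p.code_class for p in self.probes}
        if CodeClass.NEGATIVE.value not in classes:
            raise RCCFormatError("RCC sample has no Negative control probe")
        if CodeClass.POSITIVE.value not in classes:
            raise RCCFormatError("RCC sample has no Positive control probe")

    @property
    def counts(self) -> pd.Series:
        return pd.Series(
            {p.name: p.count for p in self.probes}, dtype=int, name=self.sample_id
        )

    @property
    def code_classes(self) -> pd.Series:
        return pd.Series({p.name: p.code_class for p in self.probes})


_SECTION_ORDER = ("Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary")


def _split_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.rstrip("\r")
        if line.startswith("<") and line.endswith(">"):
            tag = line.strip("<>")
            if tag.startswith("/"):
                current = None
            else:
                current = tag
                sections[current] = []
            continue
        if current is not None and line.strip():
            sections[current].append(line)
    return sections


def _parse_kv(lines: Iterable[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in lines:
        key, _, value = line.partition(",")
        out[key] = value
    return out


def parse_rcc(stream: io.TextIOBase | str, sample_id: str | None = None) -> RCCSample:
    """Parse an RCC stream (text or open file) into an :class:`RCCSample`.

    The sample id is taken from the ``Sample_Attributes`` ``ID`` field when
    present; otherwise ``sample_id`` (typically the file stem) is used.
    Windows line endings and a trailing ``Messages`` section are tolerated.
    """
    text = stream if isinstance(stream, str) else stream.read()
    sections = _split_sections(text)
    if "Code_Summary" not in sections:
        raise RCCFormatError("missing Code_Summary section")
    header = _parse_kv(sections.get("Header", []))
    sample_attrs = _parse_kv(sections.get("Sample_Attributes", []))
    lane_attrs = _parse_kv(sections.get("Lane_Attributes", []))

    probes: list[ProbeRecord] = []
    for line in sections["Code_Summary"]:
        fields = [f.strip() for f in line.split(",")]
        if fields[0] == "CodeClass":  # column header row
            continue
        if len(fields) != 4:
            raise RCCFormatError(f"malformed Code_Summary row: {line!r}")
        code_class, name, accession, count_str = fields
        try:
            count = int(count_str)
        except ValueError:
            raise RCCFormatError(
                f"non-integer count {count_str!r} on Code_Summary line {line!r}"
            ) from None
        try:
            probes.append(ProbeRecord(code_class, name, accession, count))
        except ValueError as exc:
            raise RCCFormatError(str(exc)) from None

    sid = sample_attrs.get("ID") or sample_id
    if not sid:
        raise RCCFormatError("no sample id: Sample_Attributes ID absent and none given")
    return RCCSample(sid, probes, sample_attrs, lane_attrs, header)


def read_rcc(path: str | Path) -> RCCSample:
    """Read an RCC file; the filename stem is the fallback sample id."""
    path = Path(path)
    return parse_rcc(path.read_text(), sample_id=path.stem)


def write_rcc(sample: RCCSample) -> str:
    """Serialize an :class:`RCCSample` to RCC text (round-trips via parse_rcc)."""
    out: list[str] = []
    header = dict(sample.header) or {"FileVersion": "1.7", "SoftwareVersion": "4.0.0.3"}
    sample_attrs = dict(sample.sample_attributes)
    sample_attrs.setdefault("ID", sample.sample_id)
    for tag, kv in (
        ("Header", header),
        ("Sample_Attributes", sample_attrs),
        ("Lane_Attributes", sample.lane_attributes),
    ):
        out.append(f"<{tag}>")
        out.extend(f"{k},{v}" for k, v in kv.items())
        out.append(f"</{tag}>")
    out.append("<Code_Summary>")
    out.append("CodeClass,Name,Accession,Count")
    out.extend(
        f"{p.code_class},{p.name},{p.accession},{p.count}" for p in sample.probes
    )
    out.append("</Code_Summary>")
    out.append("<Messages>")
    out.append("</Messages>")
    return "\n".join(out) + "\n"


@dataclass
class CountMatrix:
    """Probes x samples count matrix with per-probe code classes.

    ``counts`` is a DataFrame indexed by probe name with sample-id columns;
    ``code_class`` is an aligned Series.  ``normalized`` flags real-valued
    post-normalization matrices so a matrix is never normalized twice.
    """

    counts: pd.DataFrame
    code_class: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("duplicate probe names")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate sample ids")
        if self.counts.isna().any().any():
            raise ValueError("count matrix has missing cells")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix has negative values")
        self.code_class = self.code_class.reindex(self.counts.index)
        if self.code_class.isna().any():
            missing = list(self.code_class.index[self.code_class.isna()])
            raise ValueError(f"probes without code class: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def probes(self) -> list[str]:
        return list(self.counts.index)

    def class_probes(self, code_class: CodeClass | str) -> list[str]:
        value = CodeClass(code_class).value
        return list(self.code_class.index[self.code_class == value])

    def class_counts(self, code_class: CodeClass | str) -> pd.DataFrame:
        return self.counts.loc[self.class_probes(code_class)]

    def copy_with(self, counts: pd.DataFrame, normalized: bool | None = None) -> "CountMatrix":
        return CountMatrix(
            counts,
            self.code_class.copy(),
            self.normalized if normalized is None else normalized,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "code_class", self.code_class)
        df.index.name = "probe"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probe")
        classes = df.pop("code_class")
        return cls(df, classes, normalized=normalized)


REGIONS = ("TF", "TC")
STAGES = ("cSI", "cSII_III")


@dataclass
class SampleAnnotation:
    """Per-sample region (TF/TC), stage arm (cSI/cSII_III) and patient id."""

    table: pd.DataFrame  # columns: sample_id, patient_id, region, stage

    def __post_init__(self) -> None:
        required = {"sample_id", "patient_id", "region", "stage"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in annotation")
        bad_region = set(self.table["region"]) - set(REGIONS)
        if bad_region:
            raise ValueError(f"unknown regions: {sorted(bad_region)}")
        bad_stage = set(self.table["stage"]) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stages: {sorted(bad_stage)}")
        if self.table.duplicated(subset=["patient_id", "region"]).any():
            raise ValueError("a (patient, region) pair appears more than once")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_for(self, region: str | None = None, stage: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if region is not None:
            mask &= self.table["region"] == region
        if stage is not None:
            mask &= self.table["stage"] == stage
        return list(self.table.loc[mask, "sample_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def build_count_matrix(
    samples: Sequence[RCCSample], annotation: SampleAnnotation | None = None
) -> CountMatrix:
    """Assemble RCC samples (identical probe sets) into a CountMatrix.

    Columns follow the order of ``samples``.  A probe-set mismatch between
    any two samples is an error naming the symmetric difference; when an
    annotation is given every sample id must be annotated.
    """
    if not samples:
        raise ValueError("no samples given")
    ref = samples[0]
    ref_names = [p.name for p in ref.probes]
    ref_set = set(ref_names)
    for s in samples[1:]:
        names = {p.name for p in s.probes}
        if names != ref_set:
            diff = sorted(names.symmetric_difference(ref_set))
            raise ValueError(
                f"probe-set mismatch between {ref.sample_id!r} and "
                f"{s.sample_id!r}: {diff}"
            )
    if annotation is not None:
        annotated = set(annotation.sample_ids)
        unannotated = [s.sample_id for s in samples if s.sample_id not in annotated]
        if unannotated:
            raise ValueError(f"samples without annotation: {unannotated}")
    counts = pd.DataFrame(
        {s.sample_id: s.counts.reindex(ref_names) for s in samples}, index=ref_names
    )
    return CountMatrix(counts, ref.code_classes.reindex(ref_names))
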