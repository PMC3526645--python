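"""Sequence and table I/O for the bite-mark matching pipeline.

Reads FASTQ (Sanger Phred+33) and FASTA amplicon files, writes
frequency-annotated unique-read FASTA (``id;size=N`` dereplication
dialect), and loads the sample manifest and the packaged per-locus
proportion tables.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

if TYPE_CHECKING:  # pragma: no cover
    from .qc import FilteredSample, UniqueRead

LOCI = ("16S", "ITS", "rnpB", "rpoB")
SAMPLE_TYPES = ("bite", "teeth", "skin")
POOLING_MODES = ("pooled_four_loci", "single_locus")

PHRED_OFFSET = 33
PHRED_MAX = 93


class FastqFormatError(ValueError):
    """A FASTQ record is malformed (names the offending record)."""


class TableFormatError(ValueError):
    """A proportion table cell is non-numeric or outside [0, 1]."""


class ManifestError(ValueError):
    """The sample manifest is inconsistent."""


# ---------------------------------------------------------------------------
# Read records


@dataclass
class ReadRecord:
    """One sequencing read.

    quality holds per-base integer Phred scores and is None for FASTA
    input. orientation records the sequencing direction: 'forward'
    (A-adapter), 'reverse' (B-adapter), or 'unknown' before demultiplexing.
    """

    read_id: str
    sequence: str
    quality: Optional[list[int]] = None
    orientation: str = "unknown"

    def __post_init__(self) -> None:
        if self.quality is not None:
            if len(self.quality) != len(self.sequence):
                raise FastqFormatError(
                    f"record {self.read_id!r}: quality length "
                    f"{len(self.quality)} != sequence length {len(self.sequence)}"
                )
            bad = [q for q in self.quality if not 0 <= q <= PHRED_MAX]
            if bad:
                raise FastqFormatError(
                    f"record {self.read_id!r}: Phred score {bad[0]} outside "
                    f"[0, {PHRED_MAX}]"
                )
        if self.orientation not in ("forward", "reverse", "unknown"):
            raise ValueError(f"invalid orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fastq(path) -> list[ReadRecord]:
    """Parse a Sanger Phred+33 FASTQ file into ReadRecords.

    Raises FastqFormatError naming the record on a sequence/quality
    length mismatch or an out-of-range quality character.
    """
    records: list[ReadRecord] = []
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqFormatError(f"record {index + 1}: {exc}") from exc
            index += 1
            read_id = title.split()[0] if title.split() else title
            scores = [ord(c) - PHRED_OFFSET for c in qual]
            if any(s < 0 or s > PHRED_MAX for s in scores):
                raise FastqFormatError(
                    f"record {index} ({read_id!r}): quality character outside "
                    "the Sanger Phred+33 range"
                )
            records.append(ReadRecord(read_id, seq.upper(), scores))
    return records


def read_fasta(path) -> list[ReadRecord]:
    """Parse a FASTA file into quality-less ReadRecords."""
    with open(path) as handle:
        return [
            ReadRecord(title.split()[0], seq.upper(), None)
            for title, seq in SimpleFastaParser(handle)
        ]


def write_fastq(records: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            if rec.quality is None:
                raise ValueError(f"record {rec.read_id!r} has no quality scores")
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.quality)
            handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Unique-read FASTA (";size=" dereplication dialect)

_SIZE_RE = re.compile(r";size=(\d+)$")


def write_unique_fasta(sample: "FilteredSample", path) -> None:
    """Write a sample's unique reads as FASTA with frequency headers.

    Headers follow the common dereplication dialect
    ``<sample_id>_<k>;size=<frequency>``; entries are ordered by
    descending frequency then sequence so output is deterministic.
    """
    with open(path, "w") as handle:
        for k, unique in enumerate(sample.unique_reads, start=1):
            handle.write(f">{sample.sample_id}_{k};size={unique.frequency}\n")
            handle.write(f"{unique.sequence}\n")


def read_unique_fasta(path) -> list["UniqueRead"]:
    """Read a ";size="-annotated FASTA back into UniqueReads."""
    from .qc import UniqueRead

    uniques = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            match = _SIZE_RE.search(title.split()[0])
            if not match:
                raise ValueError(f"header {title!r} lacks a ';size=N' annotation")
            uniques.append(UniqueRead(seq.upper(), int(match.group(1))))
    return uniques


# ---------------------------------------------------------------------------
# Sample manifest


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    participant_id: int
    sample_type: str
    pooling_mode: str
    read_file: str

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ManifestError(f"invalid sample_type {self.sample_type!r}")
        if self.pooling_mode not in POOLING_MODES:
            raise ManifestError(f"invalid pooling_mode {self.pooling_mode!r}")
        if self.participant_id < 1:
            raise ManifestError("participant_id must be positive")


@dataclass
class SampleManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ManifestError(f"duplicate sample_id {dup!r}")
        teeth = {e.participant_id for e in self.entries if e.sample_type == "teeth"}
        for entry in self.entries:
            if entry.sample_type == "bite" and entry.participant_id not in teeth:
                warnings.warn(
                    f"bite sample {entry.sample_id!r} has no teeth sample for "
                    f"participant {entry.participant_id}",
                    stacklevel=2,
                )

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def by_type(self, sample_type: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.sample_type == sample_type]

    def participant_of(self) -> dict[str, int]:
        return {e.sample_id: e.participant_id for e in self.entries}


MANIFEST_COLUMNS = ["sample_id", "participant_id", "sample_type", "pooling_mode", "read_file"]


def read_manifest(path) -> SampleManifest:
    frame = pd.read_csv(path, dtype={"sample_id": str, "read_file": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ManifestError(f"manifest missing columns {missing}")
    entries = [
        ManifestEntry(
            row.sample_id,
            int(row.participant_id),
            row.sample_type,
            row.pooling_mode,
            row.read_file,
        )
        for row in frame.itertuples()
    ]
    return SampleManifest(entries)


def write_manifest(manifest: SampleManifest, path) -> None:
    pd.DataFrame([e.__dict__ for e in manifest], columns=MANIFEST_COLUMNS).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Proportion matrices


@dataclass
class ProportionMatrix:
    """Teeth-rows x bite-columns grid of shared-identical-read proportions."""

    locus: str
    values: pd.DataFrame  # index: teeth ids, columns: bite ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise TableFormatError("duplicate row or column labels")
        self._validate_range()

    def _validate_range(self) -> None:
        for teeth in self.values.index:
            for bite in self.values.columns:
                cell = self.values.at[teeth, bite]
                if not (0.0 <= cell <= 1.0):
                    raise TableFormatError(
                        f"cell ({teeth}, {bite}) = {cell!r} outside [0, 1]"
                    )

    @property
    def teeth_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def bite_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, teeth_ids: Sequence[str], bite_ids: Sequence[str]) -> "ProportionMatrix":
        return ProportionMatrix(self.locus, self.values.loc[list(teeth_ids), list(bite_ids)])

    def to_tsv(self, path) -> None:
        """Export rounded to two decimals, matching the printed layout."""
        self.values.round(2).to_csv(path, sep="\t", index_label="")


def load_proportion_table(path, locus: str = "16S") -> ProportionMatrix:
    """Load a tab-separated proportion table (teeth rows, bite columns).

    Non-numeric cells and values outside [0, 1] raise TableFormatError
    with the cell address.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    raw.index = raw.index.astype(str)
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for teeth in raw.index:
        for bite in raw.columns:
            cell = raw.at[teeth, bite]
            try:
                value = float(cell)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"cell ({teeth}, {bite}) = {cell!r} is not numeric"
                ) from None
            if not 0.0 <= value <= 1.0:
                raise TableFormatError(
                    f"cell ({teeth}, {bite}) = {value} outside [0, 1]"
                )
            parsed.at[teeth, bite] = value
    return ProportionMatrix(locus, parsed)


# ---------------------------------------------------------------------------
# Packaged fixtures

FIXTURE_LOCI = ("16S", "ITS", "rpoB")


def _data_path(name: str):
    return resources.files("bitematch.data").joinpath(name)


def packaged_table(locus: str) -> ProportionMatrix:
    """The packaged published proportion matrix for one locus.

    Available for 16S, ITS and rpoB; the fourth locus (rnpB) was excluded
    from comparative analyses in the source study and has no table.
    """
    if locus not in FIXTURE_LOCI:
        raise ValueError(f"no packaged table for locus {locus!r}")
    with resources.as_file(_data_path(f"proportions_{locus}.tsv")) as path:
        return load_proportion_table(path, locus)


def packaged_tables() -> dict[str, ProportionMatrix]:
    return {locus: packaged_table(locus) for locus in FIXTURE_LOCI}


def packaged_read_counts() -> dict[str, dict[str, int]]:
    """Synthetic per-teeth-sample unique-read counts for tie-breaking.

    The true counts were published only graphically; this stand-in is
    synthetic but preserves the orderings implied by the published
    tie-break outcomes (see the fixture file header).
    """
    with resources.as_file(_data_path("teeth_unique_read_counts.synthetic.tsv")) as path:
        frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return {locus: frame[locus].astype(int).to_dict() for locus in frame.columns}


def printed_diagnostics() -> dict:
    """The published per-locus diagnostic summary (threshold, metrics, AUC)."""
    import json

    with resources.as_file(_data_path("printed_diagnostics.json")) as path:
        return json.loads(Path(path).read_text())


def pooled_subset_ids() -> tuple[list[str], list[str]]:
    """Teeth and bite ids of the pooled-library subset used for modelling.

    Participants 1 and 3-10: participant 2 was excluded for having fewer
    than ten unique reads, participant 11 likewise at one locus, and
    participants 12-16 were sequenced singly under a different protocol.
    """
    participants = [1] + list(range(3, 11))
    return [f"T{p}" for p in participants], [f"B{p}" for p in participants]
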