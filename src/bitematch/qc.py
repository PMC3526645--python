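"""Three-level quality filtering of streptococcal amplicon reads.

Level 1 discards short raw reads and demultiplexes the rest by their
fusion-primer prefix (sequencing adapter + locus primer), canonicalizing
reverse-direction reads to forward orientation. Level 2 strips primer
sequences and truncates each read at the first low-quality or ambiguous
base. Level 3 drops short trimmed reads, dereplicates by exact sequence
identity, and discards singletons, leaving per-sample sets of
high-quality unique reads. Samples with fewer than ten unique reads at a
locus are flagged for exclusion from comparative analyses at all loci.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

from .seq_io import ReadRecord, SampleManifest

ADAPTER_A = "GCCTCCCTCGCGCCATCAG"  # forward (A-key) sequencing adapter
ADAPTER_B = "GCCTTGCCAGCCCGCTCAG"  # reverse (B-key) sequencing adapter

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class AmbiguousLocusError(ValueError):
    """A read's primer prefix matches more than one locus."""


class PipelineConfigError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str, max_mismatches: int = 0) -> bool:
    """True if ``seq`` starts with ``pattern`` (IUPAC codes in the pattern
    match any of their bases) with at most ``max_mismatches`` mismatches."""
    if len(seq) < len(pattern):
        return False
    mismatches = 0
    for p, s in zip(pattern, seq):
        if s not in IUPAC.get(p, p):
            mismatches += 1
            if mismatches > max_mismatches:
                return False
    return True


# ---------------------------------------------------------------------------
# Configuration and primer sets


@dataclass(frozen=True)
class LocusPrimerSet:
    """Fusion-primer definition for one locus.

    Amplicon length range is in bp and includes both primers.
    """

    locus: str
    forward_primer: str
    reverse_primer: str
    amplicon_length_range: tuple[int, int]
    adapter_a: str = ADAPTER_A
    adapter_b: str = ADAPTER_B

    def __post_init__(self) -> None:
        for primer in (self.forward_primer, self.reverse_primer):
            bad = set(primer) - set(IUPAC)
            if bad:
                raise PipelineConfigError(f"invalid primer characters {bad}")

    @property
    def reverse_primer_rc(self) -> str:
        return reverse_complement(self.reverse_primer)

    @property
    def insert_length_range(self) -> tuple[int, int]:
        lo, hi = self.amplicon_length_range
        trim = len(self.forward_primer) + len(self.reverse_primer)
        return lo - trim, hi - trim


def packaged_primer_sets() -> list[LocusPrimerSet]:
    """The four streptococcal locus primer sets (16S, ITS, rnpB, rpoB)."""
    with resources.as_file(
        resources.files("bitematch.data").joinpath("primers.tsv")
    ) as path:
        frame = pd.read_csv(path, sep="\t")
    return [
        LocusPrimerSet(
            row.locus,
            row.forward_primer,
            row.reverse_primer,
            (int(row.amplicon_min), int(row.amplicon_max)),
        )
        for row in frame.itertuples()
    ]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the three-level filter.

    Defaults: raw reads shorter than 220 bp are discarded; bases with
    Phred < 20 (or any ambiguous base) truncate the read; trimmed reads
    shorter than 180 bp are discarded; reads observed only once are
    discarded; samples need at least ten unique reads to be included.
    """

    min_raw_length: int = 220
    min_trimmed_length: int = 180
    min_quality: int = 20
    min_frequency: int = 2
    min_unique_reads: int = 10
    max_primer_mismatches: int = 0

    def __post_init__(self) -> None:
        for name in ("min_raw_length", "min_trimmed_length", "min_quality",
                     "min_frequency", "min_unique_reads"):
            if getattr(self, name) <= 0:
                raise PipelineConfigError(f"{name} must be positive")
        if self.min_trimmed_length > self.min_raw_length:
            raise PipelineConfigError(
                "min_trimmed_length must not exceed min_raw_length"
            )
        if self.max_primer_mismatches < 0:
            raise PipelineConfigError("max_primer_mismatches must be >= 0")


# ---------------------------------------------------------------------------
# Level 1: length filter + demultiplex by fusion primer


@dataclass
class Level1Audit:
    reads_in: int = 0
    fail_min_length: int = 0
    unassigned: int = 0
    assigned: Counter = field(default_factory=Counter)


def level1_demultiplex(
    reads: Iterable[ReadRecord],
    primer_sets: Iterable[LocusPrimerSet],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[dict[str, list[ReadRecord]], Level1Audit]:
    """Assign length-passing reads to loci by their fusion-primer prefix.

    A forward read starts with adapter A + forward primer; a reverse read
    starts with adapter B + reverse primer and is returned
    reverse-complemented so that all reads share the forward orientation.
    Reads matching no locus are discarded and counted.
    """
    primer_sets = list(primer_sets)
    by_locus: dict[str, list[ReadRecord]] = {ps.locus: [] for ps in primer_sets}
    audit = Level1Audit()
    mm = config.max_primer_mismatches
    for read in reads:
        audit.reads_in += 1
        if len(read) < config.min_raw_length:
            audit.fail_min_length += 1
            continue
        hits: list[tuple[str, str]] = []
        for ps in primer_sets:
            if iupac_match(ps.adapter_a + ps.forward_primer, read.sequence, mm):
                hits.append((ps.locus, "forward"))
            if iupac_match(ps.adapter_b + ps.reverse_primer, read.sequence, mm):
                hits.append((ps.locus, "reverse"))
        loci_hit = {locus for locus, _ in hits}
        if len(loci_hit) > 1:
            raise AmbiguousLocusError(
                f"read {read.read_id!r} matches loci {sorted(loci_hit)}"
            )
        if not hits:
            audit.unassigned += 1
            continue
        locus, orientation = hits[0]
        if orientation == "reverse":
            quality = read.quality[::-1] if read.quality is not None else None
            read = ReadRecord(
                read.read_id,
                reverse_complement(read.sequence),
                quality,
                "reverse",
            )
        else:
            read = replace(read, orientation="forward")
        audit.assigned[locus] += 1
        by_locus[locus].append(read)
    return by_locus, audit


# ---------------------------------------------------------------------------
# Level 2: primer removal and quality/ambiguity truncation

_MIN_TAIL_OVERLAP = 6  # shortest reverse-primer fragment stripped at the 3' end


def _find_reverse_tail(seq: str, pattern: str) -> Optional[int]:
    """Position where the reverse-primer tail (full or end-truncated)
    begins in ``seq``, or None if absent."""
    n, m = len(seq), len(pattern)
    for start in range(n - m + 1):
        if iupac_match(pattern, seq[start:]):
            return start
    # read may end partway through the reverse primer
    for k in range(min(m - 1, n), _MIN_TAIL_OVERLAP - 1, -1):
        start = n - k
        if iupac_match(pattern[:k], seq[start:]):
            return start
    return None


def level2_trim(
    read: ReadRecord,
    primer_set: LocusPrimerSet,
    config: PipelineConfig = PipelineConfig(),
) -> ReadRecord:
    """Strip fusion-primer sequences and truncate at the first bad base.

    The read must be locus-assigned and in canonical (forward)
    orientation: an optional adapter-A prefix and the forward primer are
    removed from the 5' end, the reverse-complemented reverse primer (and
    whatever follows it) from the 3' end, and the remainder is cut
    immediately before the first base with Phred below the threshold or
    outside {A, C, G, T}. The result may be empty; level 3's length
    filter removes such reads.
    """
    seq, qual = read.sequence, read.quality
    mm = config.max_primer_mismatches

    if iupac_match(primer_set.adapter_a, seq):
        seq = seq[len(primer_set.adapter_a):]
        qual = qual[len(primer_set.adapter_a):] if qual is not None else None
    if iupac_match(primer_set.forward_primer, seq, mm):
        seq = seq[len(primer_set.forward_primer):]
        qual = qual[len(primer_set.forward_primer):] if qual is not None else None

    cut = len(seq)
    for i, base in enumerate(seq):
        if base not in "ACGT" or (qual is not None and qual[i] < config.min_quality):
            cut = i
            break
    seq = seq[:cut]
    qual = qual[:cut] if qual is not None else None

    # 3' tail removal runs after the quality cut (which may itself land
    # inside the reverse primer) and iterates to a fixpoint, so trimming
    # its own output changes nothing
    while True:
        tail = _find_reverse_tail(seq, primer_set.reverse_primer_rc)
        if tail is None:
            break
        seq = seq[:tail]
        qual = qual[:tail] if qual is not None else None

    return ReadRecord(read.read_id, seq, qual, read.orientation)


# ---------------------------------------------------------------------------
# Level 3: length filter, exact dereplication, singleton removal


@dataclass(frozen=True, order=True)
class UniqueRead:
    """A dereplicated sequence with its observation frequency."""

    sequence: str
    frequency: int

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"ambiguous bases {bad} in unique read")
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")


@dataclass
class Level3Audit:
    reads_in: int = 0
    fail_min_length: int = 0
    singleton_reads: int = 0
    kept_reads: int = 0


def level3_dereplicate(
    reads: Iterable[ReadRecord],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[UniqueRead], Level3Audit]:
    """Collapse trimmed reads into unique sequences, dropping rare ones.

    Reads shorter than the trimmed-length threshold are removed, the rest
    grouped by exact full-string equality; groups observed fewer than
    ``min_frequency`` times are discarded. Output is sorted by descending
    frequency then sequence, so it is independent of read order.
    """
    audit = Level3Audit()
    counts: Counter[str] = Counter()
    for read in reads:
        audit.reads_in += 1
        if len(read) < config.min_trimmed_length:
            audit.fail_min_length += 1
            continue
        counts[read.sequence] += 1
    uniques = []
    for sequence, freq in counts.items():
        if freq < config.min_frequency:
            audit.singleton_reads += freq
        else:
            audit.kept_reads += freq
            uniques.append(UniqueRead(sequence, freq))
    uniques.sort(key=lambda u: (-u.frequency, u.sequence))
    return uniques, audit


# ---------------------------------------------------------------------------
# Composed per-sample pipeline


@dataclass
class FilteredSample:
    """One sample at one locus after the full three-level filter."""

    sample_id: str
    participant_id: int
    sample_type: str
    locus: str
    unique_reads: tuple[UniqueRead, ...]
    audit: dict[str, int]
    min_unique_reads: int = 10

    @property
    def included(self) -> bool:
        return len(self.unique_reads) >= self.min_unique_reads

    @property
    def sequences(self) -> frozenset[str]:
        return frozenset(u.sequence for u in self.unique_reads)

    @property
    def total_frequency(self) -> int:
        return sum(u.frequency for u in self.unique_reads)


AUDIT_COLUMNS = [
    "sample_id", "locus", "raw_reads", "fail_len_raw", "unassigned",
    "reads_in", "fail_len_trimmed", "singletons", "kept_reads",
    "unique_reads", "included",
]


def filter_sample(
    sample_id: str,
    participant_id: int,
    sample_type: str,
    reads: Iterable[ReadRecord],
    primer_sets: Optional[Iterable[LocusPrimerSet]] = None,
    config: PipelineConfig = PipelineConfig(),
) -> list[FilteredSample]:
    """Run levels 1-3 on one sample's reads, one FilteredSample per locus
    to which at least one read was assigned."""
    if primer_sets is None:
        primer_sets = packaged_primer_sets()
    primer_sets = list(primer_sets)
    by_locus, audit1 = level1_demultiplex(reads, primer_sets, config)
    results = []
    for ps in primer_sets:
        assigned = by_locus[ps.locus]
        if not assigned:
            continue
        trimmed = [level2_trim(r, ps, config) for r in assigned]
        uniques, audit3 = level3_dereplicate(trimmed, config)
        audit = {
            "raw_reads": audit1.reads_in,
            "fail_len_raw": audit1.fail_min_length,
            "unassigned": audit1.unassigned,
            "reads_in": audit3.reads_in,
            "fail_len_trimmed": audit3.fail_min_length,
            "singletons": audit3.singleton_reads,
            "kept_reads": audit3.kept_reads,
        }
        results.append(
            FilteredSample(
                sample_id, participant_id, sample_type, ps.locus,
                tuple(uniques), audit, config.min_unique_reads,
            )
        )
    return results


@dataclass
class PipelineResult:
    samples: list[FilteredSample]
    # sample_ids failing the minimum-unique-reads rule at >= 1 locus; such
    # samples are excluded from comparative analyses at ALL loci
    cross_locus_exclusions: list[str]

    def at_locus(self, locus: str) -> list[FilteredSample]:
        return [s for s in self.samples if s.locus == locus]

    def audit_table(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append({
                "sample_id": s.sample_id, "locus": s.locus, **s.audit,
                "unique_reads": len(s.unique_reads), "included": s.included,
            })
        return pd.DataFrame(rows, columns=AUDIT_COLUMNS)


def run_pipeline(
    manifest: SampleManifest,
    reads_by_sample: Mapping[str, list[ReadRecord]],
    primer_sets: Optional[Iterable[LocusPrimerSet]] = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Filter every manifest sample and collect cross-locus exclusions.

    Skin control samples are processed like any other; with the
    streptococcus-specific primers they are expected to yield no assigned
    reads at any locus. Bite/teeth samples with fewer than the minimum
    unique reads at any locus where they produced reads enter the
    cross-locus exclusion list.
    """
    if primer_sets is None:
        primer_sets = packaged_primer_sets()
    missing = [e.sample_id for e in manifest if e.sample_id not in reads_by_sample]
    if missing:
        raise PipelineConfigError(f"no reads supplied for samples {missing}")
    samples: list[FilteredSample] = []
    excluded: list[str] = []
    for entry in manifest:
        per_locus = filter_sample(
            entry.sample_id, entry.participant_id, entry.sample_type,
            reads_by_sample[entry.sample_id], primer_sets, config,
        )
        samples.extend(per_locus)
        if entry.sample_type != "skin" and any(not s.included for s in per_locus):
            excluded.append(entry.sample_id)
    return PipelineResult(samples, excluded)
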