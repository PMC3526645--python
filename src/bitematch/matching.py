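"""Shared-identical-read comparison of bite-mark and teeth samples.

The predictor statistic is deliberately asymmetric: the number of
sequences present in both samples' unique-read sets, divided by the size
of the *bite-mark* set. Per-locus teeth x bite matrices of this statistic
are the input to the matching model, and best-match assignment uses the
column maximum with ties broken by the teeth data set with the fewest
unique reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .qc import FilteredSample
from .seq_io import ProportionMatrix


class LocusMismatchError(ValueError):
    pass


class EmptyBiteSampleError(ZeroDivisionError):
    """The bite sample has no unique reads; the proportion is undefined."""


class TieBreakError(KeyError):
    """A tied teeth sample has no unique-read count to break the tie."""


@dataclass(frozen=True)
class SharedReadResult:
    bite_id: str
    teeth_id: str
    locus: str
    shared_sequences: frozenset[str]
    proportion: float


def shared_proportion(
    bite: FilteredSample,
    teeth: FilteredSample,
    weighted: bool = False,
) -> SharedReadResult:
    """Proportion of a bite sample's unique reads found in a teeth sample.

    Sequences are compared by exact full-string identity. By default each
    unique read counts once regardless of its observation frequency;
    ``weighted=True`` weights both numerator and denominator by read
    frequency instead (a sensitivity-analysis variant, not the published
    statistic).
    """
    if bite.locus != teeth.locus:
        raise LocusMismatchError(
            f"locus mismatch: {bite.locus!r} (bite) vs {teeth.locus!r} (teeth)"
        )
    if not bite.unique_reads:
        raise EmptyBiteSampleError(
            f"bite sample {bite.sample_id!r} has no unique reads at {bite.locus}"
        )
    shared = bite.sequences & teeth.sequences
    if weighted:
        numer = sum(u.frequency for u in bite.unique_reads if u.sequence in shared)
        denom = bite.total_frequency
    else:
        numer = len(shared)
        denom = len(bite.unique_reads)
    return SharedReadResult(
        bite.sample_id, teeth.sample_id, bite.locus, frozenset(shared), numer / denom
    )


def _natural_key(label: str) -> tuple:
    return tuple(
        int(part) if part.isdigit() else part
        for part in re.split(r"(\d+)", label)
        if part
    )


def proportion_matrix(
    samples: Iterable[FilteredSample],
    locus: str,
    weighted: bool = False,
) -> ProportionMatrix:
    """Teeth-rows x bite-columns matrix of shared proportions at a locus.

    Only included samples (those meeting the minimum unique-read rule)
    enter the matrix. Rows and columns are ordered by participant id so
    the layout is independent of input order.
    """
    at_locus = [s for s in samples if s.locus == locus and s.included]
    teeth = sorted(
        (s for s in at_locus if s.sample_type == "teeth"),
        key=lambda s: (s.participant_id, s.sample_id),
    )
    bites = sorted(
        (s for s in at_locus if s.sample_type == "bite"),
        key=lambda s: (s.participant_id, s.sample_id),
    )
    if not teeth or not bites:
        raise ValueError(f"no included bite/teeth pair at locus {locus!r}")
    values = pd.DataFrame(
        index=[t.sample_id for t in teeth],
        columns=[b.sample_id for b in bites],
        dtype=float,
    )
    for t in teeth:
        for b in bites:
            values.at[t.sample_id, b.sample_id] = shared_proportion(
                b, t, weighted
            ).proportion
    return ProportionMatrix(locus, values)


def best_match(
    matrix: ProportionMatrix,
    bite_id: str,
    unique_read_counts: Optional[Mapping[str, int]] = None,
) -> str:
    """The teeth sample best matching a bite-mark column.

    Returns the teeth sample with the maximal shared proportion; ties go
    to the sample whose data set has the fewest unique reads (counts must
    be supplied when a tie occurs), then to the smallest sample label.
    """
    if bite_id not in matrix.values.columns:
        raise KeyError(f"bite sample {bite_id!r} not in matrix")
    column = matrix.values[bite_id]
    top = column.max()
    tied = [t for t in matrix.teeth_ids if column[t] == top]
    if len(tied) == 1:
        return tied[0]
    if unique_read_counts is None or any(t not in unique_read_counts for t in tied):
        missing = [t for t in tied if not unique_read_counts or t not in unique_read_counts]
        raise TieBreakError(
            f"tie among {tied} in column {bite_id!r}: missing unique-read "
            f"counts for {missing}"
        )
    tied.sort(key=lambda t: (unique_read_counts[t], _natural_key(t)))
    return tied[0]


def participant_from_label(label: str) -> int:
    """Participant id from a printed sample label such as 'T10' or 'B3'."""
    match = re.search(r"(\d+)$", label)
    if not match:
        raise ValueError(f"cannot parse participant from label {label!r}")
    return int(match.group(1))


def column_concordance(
    matrix: ProportionMatrix,
    unique_read_counts: Optional[Mapping[str, int]] = None,
    teeth_ids: Optional[Sequence[str]] = None,
    bite_ids: Optional[Sequence[str]] = None,
    participant_of: Optional[Mapping[str, int]] = None,
) -> tuple[int, int]:
    """(n correct, n columns): bite columns whose best match is the teeth
    sample from the same participant, optionally restricted to a block."""
    sub = matrix.subset(
        teeth_ids or matrix.teeth_ids, bite_ids or matrix.bite_ids
    )
    if participant_of is None:
        participant_of = {
            label: participant_from_label(label)
            for label in sub.teeth_ids + sub.bite_ids
        }
    correct = 0
    for bite in sub.bite_ids:
        chosen = best_match(sub, bite, unique_read_counts)
        if participant_of[chosen] == participant_of[bite]:
            correct += 1
    return correct, len(sub.bite_ids)
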