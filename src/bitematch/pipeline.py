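"""Stage orchestration: simulate/filter -> match -> evaluate.

``run_full`` composes the three-level filter, the per-locus proportion
matrices and the matching-model evaluation, handling locus- and
participant-level exclusions the way the comparative analysis requires.
``reproduce_printed_analysis`` runs the statistical stage directly from
the packaged published proportion tables, so the in-study numbers can be
recomputed without any read data or simulation choices.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .seq_io import (
    ProportionMatrix,
    SampleManifest,
    packaged_read_counts,
    packaged_tables,
    pooled_subset_ids,
    printed_diagnostics,
)
from .qc import PipelineConfig, PipelineResult, run_pipeline
from .matching import best_match, column_concordance, proportion_matrix
from .stats import ModelReport, UndefinedAUCError, fit_matching_model, label_pairs

POOLED_PARTICIPANTS = (1, 3, 4, 5, 6, 7, 8, 9, 10)


@dataclass
class RunConfig:
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    subset: Optional[Sequence[int]] = None  # participants used for statistics
    min_participants_per_locus: int = 2
    weighted: bool = False


@dataclass
class LocusResult:
    locus: str
    excluded: bool
    reason: Optional[str] = None
    matrix: Optional[ProportionMatrix] = None
    report: Optional[ModelReport] = None
    best_matches: Optional[dict[str, str]] = None


@dataclass
class RunResult:
    filtered: PipelineResult
    loci: dict[str, LocusResult]
    excluded_participants: list[int]
    provenance: dict

    def audit_table(self) -> pd.DataFrame:
        return self.filtered.audit_table()


def _input_digest(reads_by_sample: Mapping[str, list]) -> str:
    digest = hashlib.sha256()
    for sample_id in sorted(reads_by_sample):
        digest.update(sample_id.encode())
        for read in reads_by_sample[sample_id]:
            digest.update(read.sequence.encode())
    return digest.hexdigest()[:16]


def run_full(
    manifest: SampleManifest,
    reads_by_sample: Mapping[str, list],
    config: RunConfig = RunConfig(),
) -> RunResult:
    """Filter all samples, build per-locus matrices, fit matching models.

    A locus is marked excluded (not an error) when too few participants
    retain both an included bite and teeth sample there. Participants
    with an under-threshold sample at any retained locus are excluded
    from comparative analyses at all loci, mirroring the cross-locus
    exclusion rule of the comparative tables.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    filtered = run_pipeline(manifest, reads_by_sample, config=config.pipeline)

    loci_present = sorted({s.locus for s in filtered.samples})
    # participants with a complete, included bite+teeth pair per locus
    complete: dict[str, set[int]] = {}
    for locus in loci_present:
        at = [s for s in filtered.samples if s.locus == locus and s.included]
        teeth = {s.participant_id for s in at if s.sample_type == "teeth"}
        bites = {s.participant_id for s in at if s.sample_type == "bite"}
        complete[locus] = teeth & bites
    retained_loci = [
        locus for locus in loci_present
        if len(complete[locus]) >= config.min_participants_per_locus
    ]

    # cross-locus rule: an under-threshold sample at any *retained* locus
    # removes its participant everywhere (a wholly excluded locus does not)
    excluded_participants = sorted({
        s.participant_id
        for s in filtered.samples
        if s.locus in retained_loci and not s.included
        and s.sample_type in ("bite", "teeth")
    })

    results: dict[str, LocusResult] = {}
    for locus in loci_present:
        if locus not in retained_loci:
            results[locus] = LocusResult(
                locus, excluded=True,
                reason=f"only {len(complete[locus])} participant(s) with ten or "
                       "more unique reads in both samples",
            )
            continue
        keep = [
            s for s in filtered.samples
            if s.locus == locus and s.included
            and s.participant_id not in excluded_participants
            and s.sample_type in ("bite", "teeth")
        ]
        if not any(s.sample_type == "bite" for s in keep) or not any(
            s.sample_type == "teeth" for s in keep
        ):
            results[locus] = LocusResult(
                locus, excluded=True,
                reason="no included bite/teeth pair after cross-locus exclusions",
            )
            continue
        matrix = proportion_matrix(keep, locus, weighted=config.weighted)
        counts = {
            s.sample_id: len(s.unique_reads)
            for s in keep if s.sample_type == "teeth"
        }
        matches = {b: best_match(matrix, b, counts) for b in matrix.bite_ids}
        participant_of = {s.sample_id: s.participant_id for s in keep}
        pairs = label_pairs(matrix, participant_of, subset=config.subset)
        try:
            report = fit_matching_model(pairs, locus)
            reason = None
        except UndefinedAUCError:
            # e.g. a single retained participant: no negative pairs, so the
            # matching model is not estimable; the matrix still stands
            report = None
            reason = "matching model skipped: pairs are all one class"
        results[locus] = LocusResult(
            locus, excluded=False, reason=reason, matrix=matrix, report=report,
            best_matches=matches,
        )

    provenance = {
        "version": __version__,
        "input_digest": _input_digest(reads_by_sample),
        "pipeline_config": config.pipeline.__dict__,
        "subset": list(config.subset) if config.subset else None,
        "weighted": config.weighted,
    }
    return RunResult(filtered, results, excluded_participants, provenance)


# ---------------------------------------------------------------------------
# Direct statistical reproduction from the packaged published tables


def reproduce_printed_analysis(
    subset: Sequence[int] = POOLED_PARTICIPANTS,
) -> dict[str, dict]:
    """Re-run the matching evaluation from the packaged proportion tables.

    For each published locus: restrict to the pooled-library participants,
    label all teeth x bite pairs, run the ROC sweep, evaluate the
    confusion table at the selected optimum proportion, and fit the
    logistic model. Returns, per locus, the fresh ModelReport alongside
    the printed summary values for side-by-side comparison. Deterministic
    and pure with respect to the fixtures.
    """
    printed = printed_diagnostics()
    out: dict[str, dict] = {}
    for locus, matrix in packaged_tables().items():
        pairs = label_pairs(matrix, subset=subset)
        report = fit_matching_model(pairs, locus)
        confusion = report.confusion_at_op
        out[locus] = {
            "report": report,
            "printed": printed[locus],
            "comparison": {
                "op": (report.roc.optimal_threshold, printed[locus]["op"]),
                "sensitivity": (confusion.sensitivity, printed[locus]["sensitivity"]),
                "specificity": (confusion.specificity, printed[locus]["specificity"]),
                "ppv": (confusion.ppv, printed[locus]["ppv"]),
                "npv": (confusion.npv, printed[locus]["npv"]),
                "auc": (report.roc.auc, printed[locus]["auc"]),
            },
        }
    return out


# published comparative-table layout: pooled participants 1, 3-10 and
# singly sequenced participants 12-16
SINGLE_PARTICIPANTS = (12, 13, 14, 15, 16)


def concordance_summary() -> dict[str, dict[str, tuple[int, int]]]:
    """Column-maximum concordance counts on the packaged tables.

    For pooled bite columns the comparison is within the pooled teeth
    block; singly sequenced columns are compared against all teeth rows.
    Ties use the fewest-unique-reads rule with the packaged (synthetic,
    ordering-preserving) count fixture.
    """
    counts = packaged_read_counts()
    pooled_teeth, pooled_bites = pooled_subset_ids()
    single_bites = [f"B{p}" for p in SINGLE_PARTICIPANTS]
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for locus, matrix in packaged_tables().items():
        out[locus] = {
            "pooled": column_concordance(
                matrix, counts[locus], teeth_ids=pooled_teeth, bite_ids=pooled_bites
            ),
            "single": column_concordance(
                matrix, counts[locus], bite_ids=single_bites
            ),
        }
    return out


def mean_proportions() -> dict[str, dict[str, float]]:
    """Mean corresponding (diagonal) and non-corresponding proportions of
    the pooled blocks of the packaged tables."""
    pooled_teeth, pooled_bites = pooled_subset_ids()
    out = {}
    for locus, matrix in packaged_tables().items():
        block = matrix.subset(pooled_teeth, pooled_bites).values
        diagonal = [block.at[f"T{p}", f"B{p}"] for p in POOLED_PARTICIPANTS]
        off = [
            block.at[t, b]
            for t in block.index
            for b in block.columns
            if t[1:] != b[1:]
        ]
        out[locus] = {
            "corresponding": float(pd.Series(diagonal).mean()),
            "non_corresponding": float(pd.Series(off).mean()),
        }
    return out


def report_to_dict(report: ModelReport) -> dict:
    """JSON-ready summary of a ModelReport."""
    confusion = report.confusion_at_op
    return {
        "locus": report.locus,
        "n_pairs": report.n_pairs,
        "n_positive": report.n_positive,
        "p_value": report.p_value,
        "p_value_wald": report.p_value_wald,
        "pseudo_r2": report.pseudo_r2,
        "gof_p": report.gof_p,
        "separation": report.separation_flag,
        "model_note": report.model_note,
        "slope": report.slope,
        "intercept": report.intercept,
        "auc": report.roc.auc,
        "optimal_threshold": report.roc.optimal_threshold,
        "confusion": {
            "threshold": confusion.threshold,
            "tp": confusion.tp, "fp": confusion.fp,
            "tn": confusion.tn, "fn": confusion.fn,
            "sensitivity": confusion.sensitivity,
            "specificity": confusion.specificity,
            "ppv": confusion.ppv,
            "npv": confusion.npv,
            "ci_sensitivity": confusion.ci_sensitivity,
            "ci_specificity": confusion.ci_specificity,
            "ci_ppv": confusion.ci_ppv,
            "ci_npv": confusion.ci_npv,
        },
    }


def dump_report(report: ModelReport) -> str:
    return json.dumps(report_to_dict(report), indent=1)
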