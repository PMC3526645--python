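"""Synthetic amplicon study generator with full ground truth.

Emulates the study design end to end: each participant carries a pool of
oral streptococcal strains per locus, some drawn from a shared background
pool (strain sharing between mouths is common at the broadly conserved
16S/ITS loci and rare at the hyper-diverse rpoB locus), the rest private.
Teeth samples sequence the full repertoire; bite-mark samples see a
random subset of it (strain dropout modelling the transfer of oral flora
to skin); skin controls carry no streptococcal primer at all. Reads are
fusion-primer amplicons sequenced in both directions with
pyrosequencing-style substitution and indel errors (elevated inside
homopolymer runs), per-base Phred scores that decay along the read and
collapse at error positions, and a configurable fraction of one-off
contaminant reads destined for the singleton filter.

Strain sequences are random DNA of locus-appropriate length: the matching
statistic depends only on string-identity structure, so no biological
sequence data is required.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .seq_io import (
    ManifestEntry,
    ReadRecord,
    SampleManifest,
    write_fastq,
    write_manifest,
)
from .qc import ADAPTER_A, ADAPTER_B, IUPAC, LocusPrimerSet, packaged_primer_sets, reverse_complement

_BASES = "ACGT"


class SimulationConfigError(ValueError):
    pass


# Default per-locus probability that a participant strain comes from the
# shared background pool. Calibrated (see docs) so the realized fraction
# of a participant's strains common to ALL participants lands near the
# observed levels: ~11% for 16S, ~20% for ITS and ~1.6% for the
# S. mitis-specific rpoB locus. Between-participant commonality decays
# steeply in the number of participants, so the draw probabilities are
# closer together than the commonality levels they produce.
DEFAULT_SHARING = {"16S": 0.55, "ITS": 0.63, "rnpB": 0.45, "rpoB": 0.30}


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 8
    strains_per_participant_per_locus: int = 30
    background_pool_size: int = 8
    sharing_rate_per_locus: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHARING)
    )
    # reads per sample: split across the four loci in pooled mode, per
    # locus library in single-locus mode (matching the deeper per-locus
    # coverage of singly sequenced samples)
    reads_per_sample: int = 400
    bite_transfer_fraction: float = 0.7
    substitution_rate: float = 0.001
    indel_rate: float = 0.0005
    homopolymer_extra_indel_rate: float = 0.002
    quality_mean: float = 38.0
    quality_decay: float = 0.03  # Phred units lost per base along the read
    quality_sd: float = 2.0
    singleton_contaminant_rate: float = 0.02
    pooling_mode: str = "pooled_four_loci"
    include_skin: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise SimulationConfigError("n_participants must be >= 1")
        if self.strains_per_participant_per_locus < 1:
            raise SimulationConfigError("need at least one strain per participant")
        if self.background_pool_size < 1:
            raise SimulationConfigError("background_pool_size must be >= 1")
        for name in (
            "bite_transfer_fraction", "substitution_rate", "indel_rate",
            "homopolymer_extra_indel_rate", "singleton_contaminant_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1]")
        for locus, rate in self.sharing_rate_per_locus.items():
            if not 0.0 <= rate <= 1.0:
                raise SimulationConfigError(
                    f"sharing rate for {locus} must be in [0, 1]"
                )
        if self.pooling_mode not in ("pooled_four_loci", "single_locus"):
            raise SimulationConfigError(f"invalid pooling_mode {self.pooling_mode!r}")
        if self.reads_per_sample < 1:
            raise SimulationConfigError("reads_per_sample must be >= 1")


@dataclass(frozen=True)
class ReadProvenance:
    origin: str  # 'strain', 'contaminant' or 'skin'
    template: Optional[str]  # insert sequence the read was copied from
    participant: Optional[int]
    locus: Optional[str]
    n_errors: int


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    background_pool: dict[str, tuple[str, ...]]  # locus -> shared inserts
    strain_sequences: dict[tuple[int, str], tuple[str, ...]]
    sample_origin: dict[str, int] = field(default_factory=dict)
    sample_type: dict[str, str] = field(default_factory=dict)
    bite_subset: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    read_provenance: dict[str, ReadProvenance] = field(default_factory=dict)

    def repertoire(self, participant: int, locus: str) -> tuple[str, ...]:
        return self.strain_sequences[(participant, locus)]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _resolve_iupac(rng: np.random.Generator, primer: str) -> str:
    out = []
    for b in primer:
        choices = IUPAC[b]
        out.append(b if b in _BASES else choices[int(rng.integers(0, len(choices)))])
    return "".join(out)


def _sample_rng(config: SimulationConfig, sample_id: str) -> np.random.Generator:
    # stable per-sample stream so a sample's reads are reproducible in
    # isolation and independent of generation order
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(sample_id.encode())])
    )


# ---------------------------------------------------------------------------
# Strain pools


def generate_strain_pools(
    config: SimulationConfig,
    primer_sets: Optional[list[LocusPrimerSet]] = None,
) -> GroundTruth:
    """Draw the shared background pool and per-participant repertoires.

    Each of a participant's strain slots is filled from the background
    pool with the locus's sharing probability, otherwise with a private
    random sequence; repeated background draws collapse, so repertoires
    are sets of distinct inserts. Insert lengths follow each locus's
    amplicon length range minus its primers.
    """
    if primer_sets is None:
        primer_sets = packaged_primer_sets()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB17E]))
    background: dict[str, tuple[str, ...]] = {}
    strains: dict[tuple[int, str], tuple[str, ...]] = {}
    for ps in primer_sets:
        lo, hi = ps.insert_length_range
        pool = tuple(
            _random_dna(rng, int(rng.integers(lo, hi + 1)))
            for _ in range(config.background_pool_size)
        )
        background[ps.locus] = pool
        share = config.sharing_rate_per_locus.get(ps.locus, 0.0)
        for participant in range(1, config.n_participants + 1):
            repertoire: list[str] = []
            for _ in range(config.strains_per_participant_per_locus):
                if rng.random() < share:
                    strain = pool[rng.integers(0, len(pool))]
                else:
                    strain = _random_dna(rng, int(rng.integers(lo, hi + 1)))
                if strain not in repertoire:
                    repertoire.append(strain)
            strains[(participant, ps.locus)] = tuple(repertoire)
    return GroundTruth(background_pool=background, strain_sequences=strains)


# ---------------------------------------------------------------------------
# Read-level error and quality models


def _homopolymer_mask(seq: str, min_run: int = 3) -> np.ndarray:
    mask = np.zeros(len(seq), dtype=bool)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def _apply_errors(
    rng: np.random.Generator, seq: str, config: SimulationConfig
) -> tuple[str, list[int]]:
    """Substitutions and indels; returns the read and the positions (in
    the output string) of substituted/inserted bases."""
    homopolymer = _homopolymer_mask(seq)
    out: list[str] = []
    error_positions: list[int] = []
    for i, base in enumerate(seq):
        indel_rate = config.indel_rate + (
            config.homopolymer_extra_indel_rate if homopolymer[i] else 0.0
        )
        roll = rng.random()
        if roll < config.substitution_rate:
            alternatives = _BASES.replace(base, "")
            out.append(alternatives[rng.integers(0, 3)])
            error_positions.append(len(out) - 1)
        elif roll < config.substitution_rate + indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(base)  # duplication (insertion)
            out.append(base)
            error_positions.append(len(out) - 1)
        else:
            out.append(base)
    return "".join(out), error_positions


def _qualities(
    rng: np.random.Generator,
    length: int,
    error_positions: list[int],
    config: SimulationConfig,
) -> list[int]:
    base = (
        config.quality_mean
        - config.quality_decay * np.arange(length)
        + rng.normal(0.0, config.quality_sd, size=length)
    )
    quality = np.clip(np.rint(base), 2, 40).astype(int)
    for pos in error_positions:
        quality[pos] = rng.integers(5, 20)  # error bases read as low-confidence
    return quality.tolist()


# ---------------------------------------------------------------------------
# Sample reads


def _locus_allocation(
    config: SimulationConfig, primer_sets: list[LocusPrimerSet]
) -> list[str]:
    loci = [ps.locus for ps in primer_sets]
    if config.pooling_mode == "single_locus":
        return [locus for locus in loci for _ in range(config.reads_per_sample)]
    per_locus, remainder = divmod(config.reads_per_sample, len(loci))
    allocation = [locus for locus in loci for _ in range(per_locus)]
    allocation.extend(loci[:remainder])
    return allocation


def generate_sample_reads(
    truth: GroundTruth,
    sample_id: str,
    config: SimulationConfig,
    primer_sets: Optional[list[LocusPrimerSet]] = None,
) -> list[ReadRecord]:
    """Emit one sample's FASTQ-ready reads and record their provenance.

    Deterministic per (seed, sample_id), independent of other samples.
    """
    if sample_id not in truth.sample_origin:
        raise KeyError(f"unknown sample {sample_id!r}")
    if primer_sets is None:
        primer_sets = packaged_primer_sets()
    by_locus = {ps.locus: ps for ps in primer_sets}
    rng = _sample_rng(config, sample_id)
    participant = truth.sample_origin[sample_id]
    sample_type = truth.sample_type[sample_id]

    reads: list[ReadRecord] = []
    if sample_type == "skin":
        # streptococcus-specific primers find nothing on pre-bite skin:
        # emit primer-free background sequence only
        for i in range(config.reads_per_sample):
            read_id = f"{sample_id}_r{i:05d}"
            seq = _random_dna(rng, 240)
            reads.append(ReadRecord(read_id, seq, _qualities(rng, len(seq), [], config)))
            truth.read_provenance[read_id] = ReadProvenance("skin", None, participant, None, 0)
        return reads

    templates: dict[str, tuple[str, ...]] = {}
    for locus in by_locus:
        repertoire = truth.repertoire(participant, locus)
        if sample_type == "bite":
            key = (sample_id, locus)
            if key not in truth.bite_subset:
                kept = tuple(s for s in repertoire if rng.random() < config.bite_transfer_fraction)
                if not kept:
                    kept = (repertoire[int(rng.integers(0, len(repertoire)))],)
                truth.bite_subset[key] = kept
            templates[locus] = truth.bite_subset[key]
        else:
            templates[locus] = repertoire

    for i, locus in enumerate(_locus_allocation(config, primer_sets)):
        ps = by_locus[locus]
        read_id = f"{sample_id}_r{i:05d}"
        if rng.random() < config.singleton_contaminant_rate:
            lo, hi = ps.insert_length_range
            insert = _random_dna(rng, int(rng.integers(lo, hi + 1)))
            origin = "contaminant"
        else:
            pool = templates[locus]
            insert = pool[int(rng.integers(0, len(pool)))]
            origin = "strain"
        fwd = ps.forward_primer
        rev = _resolve_iupac(rng, ps.reverse_primer)
        if rng.random() < 0.5:
            raw = ADAPTER_A + fwd + insert + reverse_complement(rev)
        else:
            raw = ADAPTER_B + rev + reverse_complement(insert) + reverse_complement(fwd)
        seq, error_positions = _apply_errors(rng, raw, config)
        quality = _qualities(rng, len(seq), error_positions, config)
        reads.append(ReadRecord(read_id, seq, quality))
        truth.read_provenance[read_id] = ReadProvenance(
            origin, insert, participant, locus, len(error_positions)
        )
    return reads


# ---------------------------------------------------------------------------
# Whole study


@dataclass
class Study:
    manifest: SampleManifest
    reads_by_sample: dict[str, list[ReadRecord]]
    truth: GroundTruth
    config: SimulationConfig


def generate_study(
    config: SimulationConfig = SimulationConfig(),
    primer_sets: Optional[list[LocusPrimerSet]] = None,
) -> Study:
    """Teeth + bite (+ optional skin) samples for every participant,
    fully reproducible from the config seed."""
    if primer_sets is None:
        primer_sets = packaged_primer_sets()
    truth = generate_strain_pools(config, primer_sets)
    entries = []
    reads_by_sample: dict[str, list[ReadRecord]] = {}
    for participant in range(1, config.n_participants + 1):
        plan = [("teeth", f"T{participant}"), ("bite", f"B{participant}")]
        if config.include_skin:
            plan.append(("skin", f"S{participant}"))
        for sample_type, sample_id in plan:
            truth.sample_origin[sample_id] = participant
            truth.sample_type[sample_id] = sample_type
            entries.append(
                ManifestEntry(
                    sample_id, participant, sample_type, config.pooling_mode,
                    f"{sample_id}.fastq",
                )
            )
            reads_by_sample[sample_id] = generate_sample_reads(
                truth, sample_id, config, primer_sets
            )
    return Study(SampleManifest(entries), reads_by_sample, truth, config)


def write_study(study: Study, outdir) -> None:
    """Serialize a study: per-sample FASTQ, manifest CSV, ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for entry in study.manifest:
        write_fastq(study.reads_by_sample[entry.sample_id], outdir / entry.read_file)
    write_manifest(study.manifest, outdir / "manifest.csv")
    truth = study.truth
    payload = {
        "config": {
            **{k: v for k, v in asdict(study.config).items()},
        },
        "background_pool": {k: list(v) for k, v in truth.background_pool.items()},
        "strain_sequences": {
            f"{p}:{locus}": list(seqs)
            for (p, locus), seqs in truth.strain_sequences.items()
        },
        "sample_origin": truth.sample_origin,
        "sample_type": truth.sample_type,
        "read_provenance": {
            rid: asdict(prov) for rid, prov in truth.read_provenance.items()
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Calibration measurements


def common_to_all_fraction(truth: GroundTruth, locus: str) -> float:
    """Mean over participants of the fraction of their strains carried by
    every participant (the realized teeth-set commonality)."""
    participants = sorted({p for p, loc in truth.strain_sequences if loc == locus})
    sets = [set(truth.repertoire(p, locus)) for p in participants]
    core = set.intersection(*sets)
    return float(np.mean([len(core & s) / len(s) for s in sets]))


def mean_pairwise_overlap(truth: GroundTruth, locus: str) -> float:
    """Mean Jaccard-style overlap (|A&B|/|A|) over ordered participant pairs."""
    participants = sorted({p for p, loc in truth.strain_sequences if loc == locus})
    sets = [set(truth.repertoire(p, locus)) for p in participants]
    overlaps = [
        len(a & b) / len(a)
        for i, a in enumerate(sets)
        for j, b in enumerate(sets)
        if i != j
    ]
    return float(np.mean(overlaps)) if overlaps else 0.0
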