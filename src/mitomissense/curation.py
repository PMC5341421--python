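"""Pathogenicity curation rules and the stratified train/validation split.

A variant is labeled damaging only when it is disease-associated AND meets at
least one of two evidence criteria: (a) functional confirmation in cybrid or
single-fiber studies, or (b) rareness — seen in more than one affected
pedigree, at population frequency <= 0.1 per mille (1e-4), and absent from
internal branches of a phylogeny (negative selection removes deleterious
alleles, so recurrent internal-branch alleles are presumed tolerated).
Everything else is neutral.  Missing evidence fields fail their criterion
(and are logged), never pass it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqcore import MissenseVariant

logger = logging.getLogger(__name__)

DAMAGING = "damaging"
NEUTRAL = "neutral"

#: rareness cutoff: 0.1 per mille of surveyed human sequences
FREQUENCY_CUTOFF = 1e-4


@dataclass(frozen=True)
class VariantEvidence:
    disease_associated: bool = False
    functional_confirmation: bool = False
    pedigree_count: int = 0
    #: carrier fraction of surveyed human sequences, in [0, 1]
    population_frequency: float = 1.0
    on_internal_branches: bool = False
    heteroplasmy: Optional[bool] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.population_frequency <= 1.0:
            raise ValueError("population_frequency must be in [0, 1]")
        if self.pedigree_count < 0:
            raise ValueError("pedigree_count must be non-negative")


def classify_evidence(evidence: VariantEvidence) -> str:
    """Apply the curation rule; returns ``"damaging"`` or ``"neutral"``."""
    if not evidence.disease_associated:
        return NEUTRAL
    if evidence.functional_confirmation:
        return DAMAGING
    rare = (
        evidence.pedigree_count > 1
        and evidence.population_frequency <= FREQUENCY_CUTOFF
        and not evidence.on_internal_branches
    )
    return DAMAGING if rare else NEUTRAL


@dataclass(frozen=True)
class LabeledVariant:
    variant: MissenseVariant
    evidence: VariantEvidence
    label: str

    def __post_init__(self) -> None:
        if self.label not in (DAMAGING, NEUTRAL):
            raise ValueError(f"unknown label {self.label!r}")


def label_variant(variant: MissenseVariant, evidence: VariantEvidence) -> LabeledVariant:
    return LabeledVariant(variant, evidence, classify_evidence(evidence))


# ---------------------------------------------------------------------------
# Train / validation split
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(
    data: Sequence, labels: Sequence[str], train_fraction: float = 0.6, seed: int = 1
) -> tuple[list[int], list[int]]:
    """Label-stratified random split; returns (train, validation) index lists.

    Per label, round-half-up(train_fraction x n) items go to training and the
    rest to validation, so e.g. 57 damaging variants split 34/23 at the
    default 60/40.  Disjoint, exhaustive and reproducible per seed.
    """
    if len(data) != len(labels):
        raise ValueError("data and labels differ in length")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    present = sorted(set(labels.tolist()))
    if len(present) < 2:
        raise ValueError("both labels must be present to split")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for lab in present:
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            raise ValueError(f"label {lab!r} has fewer than 2 members")
        n_train = _round_half_up(train_fraction * len(idx))
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train].tolist())
        val_idx.extend(perm[n_train:].tolist())
    return sorted(train_idx), sorted(val_idx)


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

_EVIDENCE_COLS = [
    "disease_associated",
    "functional_confirmation",
    "pedigree_count",
    "population_frequency",
    "on_internal_branches",
]


def read_labeled_variants_tsv(path) -> pd.DataFrame:
    """Labeled-variant table: id columns, evidence fields and a label.

    Missing evidence fields are filled with their failing value and logged,
    matching the curation rule's missing-data convention.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("polypeptide", "position", "wild", "mutant", "label"):
        if col not in df.columns:
            raise ValueError(f"labeled-variant TSV is missing column {col!r}")
    fill = {
        "disease_associated": False,
        "functional_confirmation": False,
        "pedigree_count": 0,
        "population_frequency": 1.0,
        "on_internal_branches": False,
    }
    for col, default in fill.items():
        if col not in df.columns:
            logger.warning("evidence column %r absent; treated as failing", col)
            df[col] = default
        elif df[col].isna().any():
            logger.warning("missing values in %r treated as failing", col)
            df[col] = df[col].fillna(default)
    return df


def write_split_manifest(path, train_idx, val_idx, seed: int) -> None:
    """Record which row went where, and under which seed."""
    rows = [("train", i) for i in train_idx] + [("validation", i) for i in val_idx]
    df = pd.DataFrame(rows, columns=["partition", "row"])
    df["seed"] = seed
    df.to_csv(path, sep="\t", index=False)
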