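"""Membrane domains of the mtDNA-encoded polypeptides and Feature 3.

All 13 polypeptides are integral inner-membrane proteins whose residues fall
in one of three biochemical environments: the intermembrane space (IM), the
transmembrane helices (TM) or the matrix (M).  The same substitution can be
tolerated in one environment and selected against in another, so observed
substitution frequencies are pooled per domain across the 13 ortholog
alignments: for every reference position of a domain, the column's residue
counts are added into a 20x21 (wild-type residue x observed symbol) table,
and each wild-type row is renormalized over the off-diagonal non-gap symbols
to give the percentage of each specific replacement.  Feature 3 of a variant
is the cell freq[wild -> mutant] of its domain's table.

Pooling sums raw symbol counts (positions with more ungapped rows weigh
more), the maximum-likelihood estimate of the domain-conditional substitution
distribution; averaging per-position relative frequencies instead is
available via ``pooling="mean"``.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa import GAP, OrthologAlignment
from .seqcore import STANDARD_AAS

logger = logging.getLogger(__name__)

DOMAIN_LABELS = ("IM", "TM", "M")
_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AAS)}
#: observed-symbol axis of a substitution table: 20 residues then gap
OBS_SYMBOLS = tuple(STANDARD_AAS) + (GAP,)


class AnnotationError(ValueError):
    """Domain intervals do not tile the polypeptide."""


@dataclass(frozen=True)
class DomainAnnotation:
    """Partition of a polypeptide's residues into labeled intervals.

    Intervals are (start, end, label), 1-based inclusive; they must be
    sorted, non-overlapping and jointly cover 1..length with no holes.
    Coverage is validated here, at load time, so lookups can never fail.
    """

    polypeptide_id: str
    intervals: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise AnnotationError(f"{self.polypeptide_id}: no intervals")
        expect = 1
        for start, end, label in self.intervals:
            if label not in DOMAIN_LABELS:
                raise AnnotationError(
                    f"{self.polypeptide_id}: unknown domain label {label!r}"
                )
            if start != expect:
                raise AnnotationError(
                    f"{self.polypeptide_id}: interval gap/overlap at position {start} "
                    f"(expected {expect})"
                )
            if end < start:
                raise AnnotationError(
                    f"{self.polypeptide_id}: empty interval ({start},{end})"
                )
            expect = end + 1

    @property
    def length(self) -> int:
        return self.intervals[-1][1]

    def domain_of(self, position: int) -> str:
        """Domain label of a 1-based residue position."""
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} outside {self.polypeptide_id} "
                f"(length {self.length})"
            )
        starts = [iv[0] for iv in self.intervals]
        return self.intervals[bisect_right(starts, position) - 1][2]

    def validate_length(self, protein_length: int) -> None:
        if self.length != protein_length:
            raise AnnotationError(
                f"{self.polypeptide_id}: annotation covers {self.length} residues "
                f"but protein has {protein_length}"
            )


def read_domain_tsv(path) -> dict[str, DomainAnnotation]:
    """Read domain annotations from TSV columns polypeptide/start/end/domain."""
    df = pd.read_csv(path, sep="\t")
    required = {"polypeptide", "start", "end", "domain"}
    if not required <= set(df.columns):
        raise AnnotationError(f"domain TSV needs columns {sorted(required)}")
    out = {}
    for pid, grp in df.groupby("polypeptide", sort=True):
        grp = grp.sort_values("start")
        ivs = tuple(
            (int(r.start), int(r.end), str(r.domain)) for r in grp.itertuples()
        )
        out[str(pid)] = DomainAnnotation(str(pid), ivs)
    return out


def write_domain_tsv(annotations: dict[str, DomainAnnotation], path) -> None:
    rows = [
        {"polypeptide": pid, "start": s, "end": e, "domain": d}
        for pid, ann in sorted(annotations.items())
        for s, e, d in ann.intervals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Composition (per-domain amino acid frequency and mean CI)
# ---------------------------------------------------------------------------


def domain_composition(
    alignments: dict[str, OrthologAlignment],
    annotations: dict[str, DomainAnnotation],
) -> pd.DataFrame:
    """Per (domain, residue): position count N, percent of domain, mean CI.

    N counts reference positions carrying that residue in that domain across
    all polypeptides; percent normalizes within the domain; CI is the
    unweighted mean of the per-position conservation indices of those
    positions.  Polypeptides lacking an alignment are skipped with a warning.
    """
    from .features import conservation_index

    records: list[tuple[str, str, float]] = []  # (domain, aa, ci)
    for pid, ann in sorted(annotations.items()):
        aln = alignments.get(pid)
        if aln is None:
            logger.warning("no alignment for %s; skipped in composition", pid)
            continue
        ann.validate_length(aln.reference_length)
        for pos in range(1, aln.reference_length + 1):
            aa = aln.reference_residue(pos)
            ci = conservation_index(aln.column_profile(pos), aa).ci
            records.append((ann.domain_of(pos), aa, ci))
    if not records:
        raise AnnotationError("no polypeptide had both alignment and annotation")
    df = pd.DataFrame(records, columns=["domain", "aa", "ci"])
    comp = (
        df.groupby(["domain", "aa"])
        .agg(N=("ci", "size"), CI=("ci", "mean"))
        .reset_index()
    )
    totals = comp.groupby("domain")["N"].transform("sum")
    comp["percent"] = 100.0 * comp["N"] / totals
    comp["CI"] = comp["CI"].round(1)
    return comp[["domain", "aa", "N", "percent", "CI"]]


# ---------------------------------------------------------------------------
# Substitution tables and Feature 3
# ---------------------------------------------------------------------------


class DomainSubstitutionTable:
    """Observed replacements of each wild-type residue within one domain.

    ``counts`` is 20x21 (wild-type residue x observed symbol incl. gap),
    pooled over every reference position of the domain across alignments.
    ``freq`` renormalizes each wild-type row over mutant residues only —
    the diagonal (conservation) and the gap column are excluded — to
    percentages summing to 100 for any row with observed replacements.
    """

    def __init__(self, domain: str, counts: np.ndarray):
        if counts.shape != (20, 21):
            raise ValueError("substitution counts must be 20x21")
        self.domain = domain
        self.counts = counts.astype(float)
        off = self.counts[:, :20].copy()
        np.fill_diagonal(off, 0.0)  # drop conservation of the wild type
        row_sums = off.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.freq = np.where(row_sums > 0, 100.0 * off / row_sums, 0.0)

    def frequency(self, wild_aa: str, mutant_aa: str) -> float:
        """Percent of observed replacements of ``wild_aa`` that are ``mutant_aa``."""
        if wild_aa == mutant_aa:
            raise ValueError("wild-type and mutant residues must differ")
        return float(self.freq[_AA_INDEX[wild_aa], _AA_INDEX[mutant_aa]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freq, index=list(STANDARD_AAS), columns=list(STANDARD_AAS)
        )

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(STANDARD_AAS), columns=list(OBS_SYMBOLS)
        )


def build_substitution_tables(
    alignments: dict[str, OrthologAlignment],
    annotations: dict[str, DomainAnnotation],
    pooling: str = "counts",
) -> dict[str, DomainSubstitutionTable]:
    """One substitution table per domain, pooled across polypeptides.

    ``pooling="counts"`` (default) sums raw symbol counts; ``"mean"`` adds
    each position's relative-frequency vector instead, weighting positions
    equally.  Polypeptides missing either input are skipped with a warning.
    """
    if pooling not in ("counts", "mean"):
        raise ValueError(f"unknown pooling {pooling!r}")
    acc = {d: np.zeros((20, 21)) for d in DOMAIN_LABELS}
    used = 0
    for pid in sorted(set(alignments) | set(annotations)):
        aln, ann = alignments.get(pid), annotations.get(pid)
        if aln is None or ann is None:
            logger.warning("missing %s for %s; skipped in substitution tables",
                           "alignment" if aln is None else "annotation", pid)
            continue
        ann.validate_length(aln.reference_length)
        used += 1
        for pos in range(1, aln.reference_length + 1):
            wild = aln.reference_residue(pos)
            prof = aln.column_profile(pos)
            row = np.zeros(21)
            for k, sym in enumerate(OBS_SYMBOLS):
                row[k] = prof.count(sym)
            if pooling == "mean":
                total = row.sum()
                if total > 0:
                    row = row / total
            acc[ann.domain_of(pos)][_AA_INDEX[wild]] += row
    if used == 0:
        raise AnnotationError("no polypeptide had both alignment and annotation")
    return {d: DomainSubstitutionTable(d, acc[d]) for d in DOMAIN_LABELS}


def feature3(
    tables: dict[str, DomainSubstitutionTable],
    wild_aa: str,
    mutant_aa: str,
    domain: str,
) -> float:
    """F3: domain-conditional frequency (%) of the specific substitution.

    Zero when the replacement is never observed in that domain.
    """
    if domain not in tables:
        raise KeyError(f"unknown domain label {domain!r}")
    if wild_aa not in _AA_INDEX or mutant_aa not in _AA_INDEX:
        raise ValueError("wild-type and mutant must be standard amino acids")
    return tables[domain].frequency(wild_aa, mutant_aa)


def write_substitution_tables(
    tables: dict[str, DomainSubstitutionTable], outdir
) -> None:
    """Serialize each domain's frequency matrix as a TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for domain, table in sorted(tables.items()):
        table.to_frame().round(4).to_csv(
            outdir / f"substitutions_{domain}.tsv", sep="\t"
        )
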