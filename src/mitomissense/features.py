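"""Evolution-based discriminatory features for mtDNA missense variants.

Three per-variant attributes are derived from ortholog alignments:

* **F1 = CI + relative cMI.**  The conservation index (CI) of a position is
  the percentage of aligned orthologs carrying the human reference residue.
  The cumulative mutual information (cMI) measures how strongly the position
  participates in the polypeptide's coevolution network: pairwise mutual
  information (MI) between columns is computed from plug-in entropies in
  bits, average-product corrected, and the per-position sum over retained
  high-scoring pairs is min-max rescaled to 0-100% within the polypeptide.
  Adding the two lets a poorly conserved but strongly coevolving position
  still score high.

* **F2** — the percentage of orthologs carrying the *mutant* residue at the
  position.  Damaging substitutions typically introduce a residue essentially
  absent from the alignment.

* **F3** — the domain-conditional substitution frequency, computed in
  :mod:`mitomissense.domains`.

MI conventions: each column pair is tabulated over the rows where *both*
columns carry a standard residue (gaps and unknowns dropped pairwise);
MI = H(X) + H(Y) - H(X,Y) with plug-in (empirical) entropies in bits.  The
average-product correction APC(i,j) = mean_i * mean_j / mean_all is
subtracted by default to suppress phylogenetic and sampling background.
Pairs are retained for cMI when their corrected score's z-score over all
pairs of the polypeptide exceeds a threshold (default 6.5).  Every knob is an
argument because no single convention is canonical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .msa import ColumnProfile, OrthologAlignment
from .seqcore import STANDARD_AAS

logger = logging.getLogger(__name__)

N_AA = 20  # standard residue codes are 0..19 in the msa encoding


class EmptyAlignmentError(ValueError):
    """A profile with zero rows cannot yield a frequency."""


@dataclass(frozen=True)
class ConservationScore:
    """Conservation index of one reference position, as a percentage."""

    position: int
    ci: float


def conservation_index(profile: ColumnProfile, ref_aa: str) -> ConservationScore:
    """CI = 100 x (count of the human reference residue) / (total rows).

    Gaps and unknown symbols stay in the denominator: a gappy column is by
    construction poorly conserved.
    """
    if ref_aa not in STANDARD_AAS:
        raise ValueError(f"{ref_aa!r} is not a standard amino acid")
    if profile.n_rows == 0:
        raise EmptyAlignmentError("profile has zero rows")
    return ConservationScore(profile.position, 100.0 * profile.rel_freq(ref_aa))


def mutant_frequency(profile: ColumnProfile, mutant_aa: str) -> float:
    """F2: percentage of rows carrying the mutant residue at this position.

    Zero when the mutant never occurs in the alignment; equals the CI when the
    mutant is the reference residue itself.
    """
    if mutant_aa not in STANDARD_AAS:
        raise ValueError(f"{mutant_aa!r} is not a standard amino acid")
    if profile.n_rows == 0:
        raise EmptyAlignmentError("profile has zero rows")
    return 100.0 * profile.rel_freq(mutant_aa)


# ---------------------------------------------------------------------------
# Mutual information network
# ---------------------------------------------------------------------------


@dataclass
class MINetwork:
    """Pairwise MI between reference positions and the derived cMI scores.

    ``mi`` is symmetric, indexed by 0-based reference position, in bits
    (corrected when a correction was applied).  ``cmi_raw``/``cmi_rel`` are
    filled by :func:`cumulative_mi`.
    """

    polypeptide_id: str
    mi: np.ndarray
    correction: str
    cmi_raw: np.ndarray | None = None
    cmi_rel: np.ndarray | None = None
    retained: np.ndarray | None = field(default=None, repr=False)

    def cmi_rel_at(self, position: int) -> float:
        """Relative cMI (0-100%) of a 1-based reference position."""
        if self.cmi_rel is None:
            raise ValueError("cumulative_mi has not been run")
        return float(self.cmi_rel[position - 1])


def _plugin_entropy(counts: np.ndarray) -> float:
    """Empirical Shannon entropy in bits from a count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def pairwise_mi(aln: OrthologAlignment, correction: str = "apc") -> MINetwork:
    """Plug-in mutual information between every pair of reference columns.

    For each pair only rows where both columns carry one of the 20 standard
    residues contribute.  ``correction`` is ``"apc"`` (default; subtract the
    average-product correction) or ``"none"``.  A column with no usable rows
    in a pairing yields MI 0 with a logged warning.
    """
    if correction not in ("apc", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    L = aln.reference_length
    if L < 2 or aln.n_rows < 2:
        raise ValueError("need at least 2 reference positions and 2 rows")
    cols = aln.matrix[:, aln.column_map]  # (n_rows, L) int8
    valid = cols < N_AA  # standard residues only
    mi = np.zeros((L, L))
    warned = False
    for i, j in combinations(range(L), 2):
        keep = valid[:, i] & valid[:, j]
        if not keep.any():
            if not warned:
                logger.warning(
                    "%s: column pair (%d,%d) has no jointly ungapped rows; MI=0",
                    aln.polypeptide_id, i + 1, j + 1,
                )
                warned = True
            continue
        xi = cols[keep, i].astype(np.intp)
        xj = cols[keep, j].astype(np.intp)
        joint = np.bincount(xi * N_AA + xj, minlength=N_AA * N_AA).reshape(N_AA, N_AA)
        hx = _plugin_entropy(joint.sum(axis=1))
        hy = _plugin_entropy(joint.sum(axis=0))
        hxy = _plugin_entropy(joint.ravel())
        mi[i, j] = mi[j, i] = hx + hy - hxy
    if correction == "apc":
        mi = _apply_apc(mi)
    else:
        # uncorrected diagonal: MI of a column with itself is its entropy
        for i in range(L):
            counts = np.bincount(
                cols[valid[:, i], i].astype(np.intp), minlength=N_AA
            )
            mi[i, i] = _plugin_entropy(counts)
    return MINetwork(aln.polypeptide_id, mi, correction)


def _apply_apc(mi: np.ndarray) -> np.ndarray:
    """Subtract the average-product correction: APC(i,j) = m_i * m_j / m.

    Means are over off-diagonal entries.  Leaves the matrix unchanged when the
    overall mean is zero (no signal at all).
    """
    L = mi.shape[0]
    if L < 2:
        return mi.copy()
    row_mean = mi.sum(axis=1) / (L - 1)
    overall = mi.sum() / (L * (L - 1))
    if overall == 0:
        return mi.copy()
    apc = np.outer(row_mean, row_mean) / overall
    out = mi - apc
    np.fill_diagonal(out, 0.0)
    return out


def cumulative_mi(net: MINetwork, z_threshold: float = 6.5) -> MINetwork:
    """Per-position cumulative MI and its 0-100% rescaling, in place.

    A pair is retained when the z-score of its (corrected) MI over all L(L-1)/2
    pairs exceeds ``z_threshold``; ``cmi_raw[i]`` sums the retained scores
    involving position i.  ``cmi_rel`` min-max rescales cmi_raw to [0, 100]
    within the polypeptide; a degenerate scale (all positions equal) maps to 0
    everywhere with a warning.  Set ``z_threshold=None`` to retain every pair.
    """
    L = net.mi.shape[0]
    iu = np.triu_indices(L, k=1)
    scores = net.mi[iu]
    if z_threshold is None:
        retained_mask = np.ones_like(scores, dtype=bool)
    else:
        sd = scores.std()
        if sd == 0:
            retained_mask = np.zeros_like(scores, dtype=bool)
        else:
            z = (scores - scores.mean()) / sd
            retained_mask = z > z_threshold
    retained = np.zeros((L, L), dtype=bool)
    retained[iu[0][retained_mask], iu[1][retained_mask]] = True
    retained |= retained.T
    net.retained = retained
    net.cmi_raw = np.where(retained, net.mi, 0.0).sum(axis=1)
    lo, hi = net.cmi_raw.min(), net.cmi_raw.max()
    if hi == lo:
        warnings.warn(
            f"{net.polypeptide_id}: degenerate cMI scale (all positions equal); "
            "relative cMI set to 0",
            stacklevel=2,
        )
        net.cmi_rel = np.zeros(L)
    else:
        net.cmi_rel = 100.0 * (net.cmi_raw - lo) / (hi - lo)
    return net


def feature1(ci: ConservationScore, net: MINetwork, position: int) -> float:
    """F1 = CI + relative cMI at the same position, in [0, 200]."""
    if ci.position != position:
        raise ValueError(f"CI is for position {ci.position}, not {position}")
    return ci.ci + net.cmi_rel_at(position)


# ---------------------------------------------------------------------------
# Attribute report
# ---------------------------------------------------------------------------


def attribute_report(table: pd.DataFrame, label_col: str = "label",
                     feature_cols: tuple[str, ...] = ("f1", "f2", "f3")) -> dict:
    """Class-separation summary of a labeled feature table.

    Returns per-feature per-class mean/SD/n, the standardized mean difference
    between classes for each feature, and the pairwise Pearson correlations
    between features — the ingredients of a usefulness/redundancy screen.
    Requires at least two classes.
    """
    if table.empty:
        raise ValueError("empty feature table")
    classes = sorted(table[label_col].unique())
    if len(classes) < 2:
        raise ValueError("attribute report needs at least 2 classes")
    by_class = table.groupby(label_col)[list(feature_cols)].agg(["mean", "std", "count"])
    pooled = table[list(feature_cols)].std(ddof=1)
    smd = {}
    a, b = classes[0], classes[1]
    for f in feature_cols:
        ma = table.loc[table[label_col] == a, f].mean()
        mb = table.loc[table[label_col] == b, f].mean()
        smd[f] = float((ma - mb) / pooled[f]) if pooled[f] > 0 else 0.0
    corr = table[list(feature_cols)].corr()
    return {"by_class": by_class, "standardized_mean_diff": smd, "correlation": corr}
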