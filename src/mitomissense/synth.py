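"""Synthetic data generators: every pipeline stage is testable offline.

Two generators mirror the two kinds of real input:

* **Alignments** — i.i.d. rows given per-column parameters: each column
  carries the reference residue with probability ``p_i`` (its planted
  conservation) and otherwise a draw from a background distribution; chosen
  column pairs are coupled through a two-state symmetric joint distribution
  whose mixing parameter maps to mutual information in closed form; gaps are
  injected at a fixed rate, never into the reference row.  No phylogeny is
  simulated — rows are exchangeable, which is exactly what the plug-in
  estimators assume.

* **Labeled feature tables** — class-conditional truncated normals for
  (F1, F2, F3).  The default moments are the observed damaging/neutral
  class statistics of the curated variant corpus: F1 107.9+/-22.6 vs
  80.2+/-33.8, F2 1.4+/-5.1 vs 8.2+/-14.2, F3 9.4+/-8.8 vs 12.7+/-8.5,
  with 57 damaging and 2,778 neutral variants.  Truncation (F1 in [0,200],
  F2/F3 in [0,100]) is applied on the *distribution*, not by clipping, so
  the theoretical post-truncation moments are available for honest recovery
  tests — the damaging F2 distribution, for instance, is cut hard at 0.

Every generator is deterministic per seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .msa import GAP, OrthologAlignment
from .seqcore import STANDARD_AAS

# ---------------------------------------------------------------------------
# Alignment simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentSimSpec:
    polypeptide_id: str
    n_rows: int
    reference: str
    #: per-position probability of drawing the reference residue
    conservation: tuple[float, ...]
    #: (i, j, coupling) with 1-based positions; coupling in [0, 1] maps
    #: monotonically to MI (1 = deterministic two-state coupling, 1 bit)
    coevolving_pairs: tuple[tuple[int, int, float], ...] = ()
    gap_rate: float = 0.0
    #: background residue distribution over the 20 residues (uniform default)
    background: tuple[float, ...] = field(
        default_factory=lambda: tuple([1 / 20] * 20)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conservation) != len(self.reference):
            raise ValueError("conservation must match reference length")
        if not all(0.0 <= p <= 1.0 for p in self.conservation):
            raise ValueError("conservation probabilities must be in [0, 1]")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")
        L = len(self.reference)
        seen = set()
        for i, j, c in self.coevolving_pairs:
            if not (1 <= i <= L and 1 <= j <= L and i != j):
                raise ValueError(f"bad coevolving pair ({i},{j})")
            if not 0.0 <= c <= 1.0:
                raise ValueError("coupling must be in [0, 1]")
            seen |= {i, j}
        if abs(sum(self.background) - 1.0) > 1e-9 or len(self.background) != 20:
            raise ValueError("background must be a distribution over 20 residues")


def coupled_pair_mi(coupling: float) -> float:
    """Closed-form MI (bits) of the two-state symmetric coupled-pair model.

    Each member of a coupled pair is binary (residue A vs residue B, equal
    marginals); with probability ``coupling`` the pair copies one shared coin,
    otherwise the two coins are independent.  Joint probabilities are then
    p(same)= (1+c)/4 per concordant cell and (1-c)/4 per discordant cell,
    giving MI = 1 - H((1+c)/2) bits.
    """
    c = float(coupling)
    if c <= 0:
        return 0.0
    if c >= 1:
        return 1.0
    p = (1 + c) / 2
    return 1.0 + p * np.log2(p) + (1 - p) * np.log2(1 - p)


def simulate_alignment(spec: AlignmentSimSpec) -> OrthologAlignment:
    """Draw an ortholog alignment with planted conservation and coevolution.

    Row 1 is the ungapped reference.  Coupled pairs override the per-column
    conservation model for their two columns: both columns become two-state
    (reference residue vs one fixed alternative) with 50/50 marginals and the
    requested coupling, which makes their planted MI exactly
    :func:`coupled_pair_mi`.
    """
    rng = np.random.default_rng(spec.seed)
    L = len(spec.reference)
    n = spec.n_rows
    aas = np.array(list(STANDARD_AAS))
    ref_idx = np.array([STANDARD_AAS.index(a) for a in spec.reference])
    bg = np.asarray(spec.background)

    # start from the independent conservation model
    take_ref = rng.random((n, L)) < np.asarray(spec.conservation)
    bg_draw = rng.choice(20, size=(n, L), p=bg)
    cols = np.where(take_ref, ref_idx[None, :], bg_draw)

    # overwrite coupled pairs with the two-state joint model
    for i, j, c in spec.coevolving_pairs:
        alt_i = (ref_idx[i - 1] + 1) % 20
        alt_j = (ref_idx[j - 1] + 1) % 20
        shared = rng.random(n) < 0.5
        copy = rng.random(n) < c
        xi = np.where(copy, shared, rng.random(n) < 0.5)
        xj = np.where(copy, shared, rng.random(n) < 0.5)
        cols[:, i - 1] = np.where(xi, ref_idx[i - 1], alt_i)
        cols[:, j - 1] = np.where(xj, ref_idx[j - 1], alt_j)

    rows = ["".join(aas[r]) for r in cols]
    if spec.gap_rate > 0:
        gap_mask = rng.random((n, L)) < spec.gap_rate
        rows = [
            "".join(GAP if gap_mask[r, k] else rows[r][k] for k in range(L))
            for r in range(n)
        ]
    ids = ["REF_HUMAN"] + [f"sp{r:05d}" for r in range(1, n + 1)]
    all_rows = [spec.reference] + rows
    return OrthologAlignment(spec.polypeptide_id, ids, all_rows, "REF_HUMAN")


# ---------------------------------------------------------------------------
# Feature-table simulation
# ---------------------------------------------------------------------------

#: class-conditional (mean, sd) defaults observed on the curated corpus
DEFAULT_CLASS_MOMENTS = {
    "damaging": {"f1": (107.9, 22.6), "f2": (1.4, 5.1), "f3": (9.4, 8.8)},
    "neutral": {"f1": (80.2, 33.8), "f2": (8.2, 14.2), "f3": (12.7, 8.5)},
}
DEFAULT_CLASS_SIZES = {"damaging": 57, "neutral": 2778}
FEATURE_BOUNDS = {"f1": (0.0, 200.0), "f2": (0.0, 100.0), "f3": (0.0, 100.0)}


@dataclass(frozen=True)
class FeatureSimSpec:
    moments: dict = field(default_factory=lambda: DEFAULT_CLASS_MOMENTS)
    sizes: dict = field(default_factory=lambda: DEFAULT_CLASS_SIZES)
    bounds: dict = field(default_factory=lambda: FEATURE_BOUNDS)
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, feats in self.moments.items():
            for f, (_, sd) in feats.items():
                if sd <= 0:
                    raise ValueError(f"{cls}/{f}: SD must be positive")


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def truncated_moments(spec: FeatureSimSpec, label: str, feature: str) -> tuple[float, float]:
    """Theoretical (mean, sd) of a class/feature after truncation.

    Recovery tests compare sample statistics against these, not against the
    pre-truncation parameters — material for bounded features like the
    damaging F2 (1.4 +/- 5.1 truncated at 0).
    """
    mean, sd = spec.moments[label][feature]
    lo, hi = spec.bounds[feature]
    d = _truncnorm(mean, sd, lo, hi)
    return float(d.mean()), float(d.std())


def simulate_feature_table(spec: FeatureSimSpec | None = None) -> pd.DataFrame:
    """Labeled (f1, f2, f3) table with truncated-normal class conditionals."""
    if spec is None:
        spec = FeatureSimSpec()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for label in sorted(spec.sizes):
        n = spec.sizes[label]
        data = {"label": [label] * n}
        for f in sorted(spec.moments[label]):
            mean, sd = spec.moments[label][f]
            lo, hi = spec.bounds[f]
            data[f] = _truncnorm(mean, sd, lo, hi).rvs(size=n, random_state=rng)
        frames.append(pd.DataFrame(data))
    out = pd.concat(frames, ignore_index=True)
    return out[["f1", "f2", "f3", "label"]]


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

_TOY_PROTEINS = {
    # three toy polypeptides with IM/TM/M structure; ~60 positions total
    "p.TOY-A": ("MLKAVWTTPGYHLLSDERFC", ((1, 6, "IM"), (7, 14, "TM"), (15, 20, "M"))),
    "p.TOY-B": ("MTTLPAGHWYVLIKDESRNQ", ((1, 5, "M"), (6, 15, "TM"), (16, 20, "IM"))),
    "p.TOY-C": ("MAVLYWPHKTGSDLIRENCF", ((1, 7, "TM"), (8, 16, "M"), (17, 20, "TM"))),
}


def make_fixture_bundle(seed: int, outdir) -> dict[str, Path]:
    """Write a small self-consistent corpus used by tests and CLI examples.

    Three toy polypeptides (20 residues each), 200-row alignments with mixed
    conservation levels, one planted coevolving pair each, a full domain
    annotation, a labeled variant table spanning both classes, and a labeled
    feature table at the default class moments (scaled down).  Deterministic
    per seed; a digest file records the corpus hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rng = np.random.default_rng(seed)

    ann_rows = []
    var_rows = []
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for k, (pid, (protein, intervals)) in enumerate(sorted(_TOY_PROTEINS.items())):
        L = len(protein)
        conservation = tuple(rng.uniform(0.35, 0.95, size=L).tolist())
        spec = AlignmentSimSpec(
            polypeptide_id=pid,
            n_rows=200,
            reference=protein,
            conservation=conservation,
            coevolving_pairs=((3, 11, 0.9),),
            gap_rate=0.05,
            seed=seed + 101 * (k + 1),
        )
        aln = simulate_alignment(spec)
        p = aln_dir / f"{pid.replace('p.', '')}.afa"
        with open(p, "w") as fh:
            for rid, row in zip(aln.ids, ("".join(
                    "-" if c == 20 else ("?" if c == 21 else STANDARD_AAS[c])
                    for c in aln.matrix[r]) for r in range(aln.n_rows))):
                fh.write(f">{rid}\n{row}\n")
        paths[pid] = p
        for s, e, d in intervals:
            ann_rows.append({"polypeptide": pid, "start": s, "end": e, "domain": d})

        # labeled variants: a few per polypeptide, both classes
        for pos in rng.choice(np.arange(2, L + 1), size=6, replace=False):
            wild = protein[pos - 1]
            mutant = rng.choice([a for a in STANDARD_AAS if a != wild])
            damaging = bool(rng.random() < 0.3)
            var_rows.append({
                "polypeptide": pid, "position": int(pos), "wild": wild,
                "mutant": mutant,
                "disease_associated": damaging,
                "functional_confirmation": damaging,
                "pedigree_count": int(rng.integers(0, 4)),
                "population_frequency": float(10 ** rng.uniform(-5, -2)),
                "on_internal_branches": bool(rng.random() < 0.5),
                "label": "damaging" if damaging else "neutral",
            })

    ann_path = outdir / "domains.tsv"
    pd.DataFrame(ann_rows).to_csv(ann_path, sep="\t", index=False)
    paths["domains"] = ann_path

    var_path = outdir / "variants.tsv"
    pd.DataFrame(var_rows).to_csv(var_path, sep="\t", index=False)
    paths["variants"] = var_path

    feat_spec = FeatureSimSpec(
        sizes={"damaging": 40, "neutral": 160}, seed=seed + 977
    )
    feat_path = outdir / "features.tsv"
    simulate_feature_table(feat_spec).to_csv(feat_path, sep="\t", index=False)
    paths["features"] = feat_path

    digest = hashlib.sha256()
    for key in sorted(paths):
        digest.update(paths[key].read_bytes())
    digest_path = outdir / "DIGEST"
    digest_path.write_text(digest.hexdigest() + "\n")
    paths["digest"] = digest_path
    return paths
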