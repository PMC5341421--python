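"""Small published reference tables shipped with the package.

Two TSVs live in ``mitomissense/data``:

* ``benchmark_confusion_counts.tsv`` — confusion counts (TP/TN/FP/FN) of four
  predictors on the curated mtDNA missense corpus, on the held-out validation
  partition and on the full dataset, used to recompute benchmark
  sensitivity/specificity.
* ``rare_unclear_variants.tsv`` — feature values (F1-F3) for 16 extremely
  rare variants without confirmed pathogenicity that the classifier flags as
  damaging.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import ConfusionCounts


def _read(name: str) -> pd.DataFrame:
    with resources.files("mitomissense.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_benchmark_confusion() -> dict[tuple[str, str], ConfusionCounts]:
    """Published benchmark counts keyed by (predictor, dataset)."""
    df = _read("benchmark_confusion_counts.tsv")
    return {
        (r.predictor, r.dataset): ConfusionCounts(int(r.tp), int(r.tn),
                                                  int(r.fp), int(r.fn))
        for r in df.itertuples()
    }


def load_rare_variant_features() -> pd.DataFrame:
    """Feature values of the 16 rare unclear-pathogenicity variants."""
    return _read("rare_unclear_variants.tsv")
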