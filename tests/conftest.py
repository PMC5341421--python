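import numpy as np
import pytest

from mitomissense import AlignmentSimSpec, make_fixture_bundle, simulate_alignment


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The synthetic corpus (alignments, domains, variants, features) on disk."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = make_fixture_bundle(seed=42, outdir=outdir)
    return outdir, paths


@pytest.fixture(scope="session")
def small_alignment():
    """500-row alignment with mixed planted conservation and one coupled pair."""
    spec = AlignmentSimSpec(
        polypeptide_id="p.TOY",
        n_rows=500,
        reference="MKLVAWYHTP",
        conservation=(0.95, 0.8, 0.6, 0.9, 0.5, 0.7, 0.85, 0.65, 0.75, 0.55),
        coevolving_pairs=((2, 7, 0.95),),
        gap_rate=0.05,
        seed=7,
    )
    return spec, simulate_alignment(spec)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
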