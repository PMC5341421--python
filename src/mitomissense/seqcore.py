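"""Vertebrate mitochondrial genetic code, variant nomenclature and exhaustive
single-nucleotide missense enumeration for the 13 human mtDNA-encoded polypeptides.

The human mitochondrial genome (rCRS, NC_012920.1) encodes 13 OXPHOS subunits
translated under NCBI genetic code table 2, which differs from the standard code
at four codons: AGA/AGG are stops, TGA is tryptophan and ATA is methionine.
Several genes end in an incomplete stop codon (T or TA) completed by
polyadenylation of the mRNA, and some initiate at non-ATG codons that are
nevertheless read as methionine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable

# ---------------------------------------------------------------------------
# Genetic code (NCBI table 2, vertebrate mitochondrial)
# ---------------------------------------------------------------------------

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

#: codon -> single-letter amino acid, with '*' for the four mitochondrial stops
CODON_TO_AA: dict[str, str] = dict(_MITO_TABLE.forward_table)
for _stop in _MITO_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

NUCLEOTIDES = ("A", "C", "G", "T")
STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: rCRS coordinates (1-based, inclusive, L-strand numbering) of the 13
#: protein-coding genes.  strand -1 marks MT-ND6, the single L-strand gene,
#: whose CDS reads 3'->5' along rCRS numbering.
GENE_COORDS: dict[str, tuple[int, int, int]] = {
    "p.MT-ND1": (3307, 4262, 1),
    "p.MT-ND2": (4470, 5511, 1),
    "p.MT-CO1": (5904, 7445, 1),
    "p.MT-CO2": (7586, 8269, 1),
    "p.MT-ATP8": (8366, 8572, 1),
    "p.MT-ATP6": (8527, 9207, 1),
    "p.MT-CO3": (9207, 9990, 1),
    "p.MT-ND3": (10059, 10404, 1),
    "p.MT-ND4L": (10470, 10766, 1),
    "p.MT-ND4": (10760, 12137, 1),
    "p.MT-ND5": (12337, 14148, 1),
    "p.MT-ND6": (14149, 14673, -1),
    "p.MT-CYB": (14747, 15887, 1),
}


class InvalidSequenceError(ValueError):
    """A nucleotide sequence contains non-ACGT symbols or has a bad length."""


class InternalStopError(ValueError):
    """Translation hit a stop codon before the final codon."""


class ConsistencyError(ValueError):
    """A gene's CDS and protein disagree."""


class ReferenceMismatchError(ValueError):
    """The stated wild-type residue does not match the reference protein."""


class VariantParseError(ValueError):
    """A variant identifier could not be parsed."""


def translate_mito(cds: str) -> str:
    """Translate a coding sequence under the vertebrate mitochondrial code.

    The sequence must consist only of A/C/G/T and have length divisible by 3.
    A stop codon in the final position is dropped from the output; a stop at
    any earlier codon raises :class:`InternalStopError` rather than being
    silently truncated.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise InvalidSequenceError(f"CDS length {len(cds)} is not a multiple of 3")
    if not set(cds) <= set(NUCLEOTIDES):
        bad = sorted(set(cds) - set(NUCLEOTIDES))
        raise InvalidSequenceError(f"non-ACGT symbols in CDS: {bad}")
    aas = [CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3)]
    if "*" in aas[:-1]:
        pos = aas.index("*") + 1
        raise InternalStopError(f"internal stop codon at codon {pos}")
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodingGene:
    """One mtDNA protein-coding gene: CDS, protein and rCRS placement.

    ``coords`` is the (start, end, strand) rCRS interval from
    :data:`GENE_COORDS`; it may be absent for toy genes, in which case
    genome-coordinate bookkeeping is unavailable but protein-level operations
    all work.
    """

    polypeptide_id: str
    cds: str
    protein: str
    coords: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        n_codons = len(self.cds) // 3
        if not (len(self.protein) * 3 <= len(self.cds) <= len(self.protein) * 3 + 3):
            raise ConsistencyError(
                f"{self.polypeptide_id}: protein length {len(self.protein)} "
                f"inconsistent with CDS length {len(self.cds)}"
            )
        # codon 1 is read as Met regardless of the genomic codon
        translated = _translate_lenient(self.cds[: len(self.protein) * 3])
        if translated[1:] != self.protein[1:] or self.protein[0] != "M":
            raise ConsistencyError(
                f"{self.polypeptide_id}: CDS does not translate to protein"
            )
        del n_codons

    @classmethod
    def from_cds(
        cls,
        polypeptide_id: str,
        cds: str,
        coords: Optional[tuple[int, int, int]] = None,
    ) -> "CodingGene":
        """Build a gene from its CDS, handling incomplete stop codons.

        A trailing 1- or 2-nt remainder is treated as an incomplete stop codon
        (completed by polyadenylation in vivo) and excluded from translation.
        The first codon is read as methionine whatever its sequence.
        """
        cds = cds.upper()
        if not set(cds) <= set(NUCLEOTIDES):
            raise InvalidSequenceError(f"{polypeptide_id}: non-ACGT symbols in CDS")
        n_full = len(cds) // 3
        body = cds[: n_full * 3]
        aas = [CODON_TO_AA[body[i : i + 3]] for i in range(0, len(body), 3)]
        if not aas:
            raise InvalidSequenceError(f"{polypeptide_id}: empty CDS")
        aas[0] = "M"
        if aas[-1] == "*":
            aas.pop()
        if "*" in aas:
            raise InternalStopError(
                f"{polypeptide_id}: internal stop at codon {aas.index('*') + 1}"
            )
        if coords is None:
            coords = GENE_COORDS.get(polypeptide_id)
        return cls(polypeptide_id, cds, "".join(aas), coords)

    def codon(self, protein_position: int) -> str:
        """The genomic codon for a 1-based protein position."""
        if not 1 <= protein_position <= len(self.protein):
            raise IndexError(
                f"position {protein_position} outside {self.polypeptide_id} "
                f"(length {len(self.protein)})"
            )
        i = (protein_position - 1) * 3
        return self.cds[i : i + 3]

    def genome_position(self, protein_position: int, offset: int) -> int:
        """rCRS coordinate of base ``offset`` (0..2) of a codon.

        For the L-strand gene MT-ND6 the CDS runs backwards along rCRS
        numbering, so coordinates decrease with increasing codon index.
        """
        if self.coords is None:
            raise ConsistencyError(f"{self.polypeptide_id}: no rCRS coordinates")
        start, end, strand = self.coords
        i = (protein_position - 1) * 3 + offset
        return start + i if strand == 1 else end - i

    def rcrs_base(self, protein_position: int, offset: int) -> str:
        """rCRS L-strand base at a codon position (complemented for MT-ND6)."""
        base = self.codon(protein_position)[offset]
        if self.coords is not None and self.coords[2] == -1:
            base = base.translate(_COMPLEMENT)
        return base


def _translate_lenient(cds: str) -> str:
    """Codon-wise translation keeping '*' symbols; used for consistency checks."""
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds) - 2, 3))


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MissenseVariant:
    """A single amino acid substitution in one of the 13 polypeptides."""

    polypeptide_id: str
    protein_position: int
    wild_aa: str
    mutant_aa: str
    #: (rCRS position, L-strand ref base, L-strand alt base) when known
    nt_change: Optional[tuple[int, str, str]] = None

    def __post_init__(self) -> None:
        if self.wild_aa == self.mutant_aa:
            raise VariantParseError("wild-type and mutant residues are identical")
        for aa in (self.wild_aa, self.mutant_aa):
            if aa not in STANDARD_AAS:
                raise VariantParseError(f"{aa!r} is not a standard amino acid")

    @property
    def id_protein(self) -> str:
        return f"p.{self.wild_aa}{self.protein_position}{self.mutant_aa}"

    @property
    def id_dna(self) -> Optional[str]:
        if self.nt_change is None:
            return None
        pos, ref, alt = self.nt_change
        return f"m.{pos}{ref}>{alt}"


def enumerate_codon_neighbors(codon: str) -> dict[str, list[tuple[int, str, str, str]]]:
    """Partition the 9 single-nucleotide neighbors of a codon by consequence.

    Returns a dict with keys ``synonymous``, ``missense``, ``nonsense`` and
    ``stop_loss``, each a list of ``(offset, alt_base, neighbor_codon,
    product_aa)`` tuples.  The four classes partition all 9 neighbors:
    missense neighbors encode a different standard amino acid, nonsense
    neighbors turn a sense codon into a stop, stop-loss neighbors turn a stop
    codon into a sense codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= set(NUCLEOTIDES):
        raise InvalidSequenceError(f"invalid codon {codon!r}")
    wild = CODON_TO_AA[codon]
    out: dict[str, list[tuple[int, str, str, str]]] = {
        "synonymous": [],
        "missense": [],
        "nonsense": [],
        "stop_loss": [],
    }
    for offset in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[offset]:
                continue
            nb = codon[:offset] + alt + codon[offset + 1 :]
            aa = CODON_TO_AA[nb]
            if aa == wild:
                cls = "synonymous"
            elif wild == "*":
                cls = "stop_loss"
            elif aa == "*":
                cls = "nonsense"
            else:
                cls = "missense"
            out[cls].append((offset, alt, nb, aa))
    return out


def enumerate_all_missense(genes: Iterable[CodingGene]) -> list[MissenseVariant]:
    """Every single-nucleotide missense change of every codon of every gene.

    Stop-gain (nonsense) and stop-loss neighbors are excluded: only changes
    producing a different standard amino acid are returned.  The final
    incomplete stop codon of a gene is never enumerated (it is outside the
    protein), and codon 1 neighbors are classified against the translated
    protein, whose first residue is methionine by the mitochondrial start
    convention.  Order is deterministic: (polypeptide id, protein position,
    codon offset, alt base).
    """
    variants: list[MissenseVariant] = []
    for gene in sorted(genes, key=lambda g: g.polypeptide_id):
        has_coords = gene.coords is not None
        strand = gene.coords[2] if has_coords else 1
        for pos in range(1, len(gene.protein) + 1):
            wild = gene.protein[pos - 1]
            for offset, alt, _nb, aa in _missense_neighbors(gene.codon(pos), wild):
                nt = None
                if has_coords:
                    ref_l = gene.rcrs_base(pos, offset)
                    alt_l = alt.translate(_COMPLEMENT) if strand == -1 else alt
                    nt = (gene.genome_position(pos, offset), ref_l, alt_l)
                variants.append(
                    MissenseVariant(gene.polypeptide_id, pos, wild, aa, nt)
                )
    return variants


def _missense_neighbors(codon: str, wild: str):
    """Neighbors of ``codon`` encoding a standard amino acid other than ``wild``.

    ``wild`` is the protein residue, which at codon 1 may differ from the
    codon's table-2 product (non-ATG starts read as Met).
    """
    for offset in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[offset]:
                continue
            nb = codon[:offset] + alt + codon[offset + 1 :]
            aa = CODON_TO_AA[nb]
            if aa != "*" and aa != wild:
                yield offset, alt, nb, aa


def count_distinct_aa_changes(variants: Iterable[MissenseVariant]) -> int:
    """Number of distinct (polypeptide, position, mutant residue) changes.

    Two single-nucleotide events at the same codon can yield the same amino
    acid replacement (e.g. ATA -> CTA and ATA -> TTA are both M->L); this
    collapses them to one amino acid change.
    """
    return len(
        {(v.polypeptide_id, v.protein_position, v.mutant_aa) for v in variants}
    )


# ---------------------------------------------------------------------------
# Identifier parsing
# ---------------------------------------------------------------------------

_P_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z])$")
_M_RE = re.compile(r"^m\.(\d+)([ACGT])>([ACGT])$")


def parse_variant_id(text: str, reference: CodingGene) -> MissenseVariant:
    """Parse a ``p.A132T`` or ``m.3700G>A`` identifier against a reference gene.

    The protein dialect is validated against the reference protein; the DNA
    dialect is mapped through the gene's rCRS coordinates and CDS, so both
    identifiers come out populated and mutually consistent.  A wild-type
    residue or reference base that disagrees with the reference raises
    :class:`ReferenceMismatchError` — the input is reported, never corrected.
    """
    text = text.strip()
    m = _P_RE.match(text)
    if m:
        wild, pos_s, mut = m.group(1), m.group(2), m.group(3)
        pos = int(pos_s)
        if wild not in STANDARD_AAS or mut not in STANDARD_AAS or wild == mut:
            raise VariantParseError(f"invalid protein variant {text!r}")
        if not 1 <= pos <= len(reference.protein):
            raise ReferenceMismatchError(
                f"{text}: position outside {reference.polypeptide_id}"
            )
        if reference.protein[pos - 1] != wild:
            raise ReferenceMismatchError(
                f"{text}: reference residue at {pos} is "
                f"{reference.protein[pos - 1]}, not {wild}"
            )
        nt = _protein_to_nt(reference, pos, mut)
        return MissenseVariant(reference.polypeptide_id, pos, wild, mut, nt)

    m = _M_RE.match(text)
    if m:
        gpos, ref_l, alt_l = int(m.group(1)), m.group(2), m.group(3)
        if reference.coords is None:
            raise VariantParseError(
                f"{reference.polypeptide_id} has no rCRS coordinates"
            )
        start, end, strand = reference.coords
        if not start <= gpos <= end:
            raise ReferenceMismatchError(
                f"{text}: position outside {reference.polypeptide_id} "
                f"({start}..{end})"
            )
        i = gpos - start if strand == 1 else end - gpos
        pos, offset = divmod(i, 3)
        pos += 1
        if pos > len(reference.protein):
            raise VariantParseError(f"{text}: falls in the stop codon")
        ref_cds = ref_l if strand == 1 else ref_l.translate(_COMPLEMENT)
        alt_cds = alt_l if strand == 1 else alt_l.translate(_COMPLEMENT)
        codon = reference.codon(pos)
        if codon[offset] != ref_cds:
            raise ReferenceMismatchError(
                f"{text}: rCRS base at {gpos} is "
                f"{reference.rcrs_base(pos, offset)}, not {ref_l}"
            )
        wild = reference.protein[pos - 1]
        mut_codon = codon[:offset] + alt_cds + codon[offset + 1 :]
        mut = CODON_TO_AA[mut_codon]
        if mut == "*":
            raise VariantParseError(f"{text}: nonsense change, not missense")
        if mut == wild:
            raise VariantParseError(f"{text}: synonymous change, not missense")
        return MissenseVariant(
            reference.polypeptide_id, pos, wild, mut, (gpos, ref_l, alt_l)
        )

    raise VariantParseError(f"unrecognized variant identifier {text!r}")


def _protein_to_nt(
    gene: CodingGene, pos: int, mut: str
) -> Optional[tuple[int, str, str]]:
    """Find a single-nucleotide change producing ``mut`` at codon ``pos``.

    Returns None when no single-nucleotide neighbor encodes the mutant (the
    substitution would need two hits in one codon) or when the gene carries no
    rCRS coordinates.  Deterministic: first hit in (offset, alt) order.
    """
    if gene.coords is None:
        return None
    strand = gene.coords[2]
    for offset, alt, _nb, aa in _missense_neighbors(
        gene.codon(pos), gene.protein[pos - 1]
    ):
        if aa == mut:
            ref_l = gene.rcrs_base(pos, offset)
            alt_l = alt.translate(_COMPLEMENT) if strand == -1 else alt
            return (gene.genome_position(pos, offset), ref_l, alt_l)
    return None


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------


def read_cds_fasta(path) -> dict[str, str]:
    """Read CDS nucleotide sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_variants_tsv(variants: Iterable[MissenseVariant], path) -> None:
    """Write enumerated variants as TSV (polypeptide, m_id, p_id, position, wild, mutant)."""
    with open(path, "w") as fh:
        fh.write("polypeptide\tm_id\tp_id\tposition\twild\tmutant\n")
        for v in variants:
            fh.write(
                f"{v.polypeptide_id}\t{v.id_dna or '.'}\t{v.id_protein}\t"
                f"{v.protein_position}\t{v.wild_aa}\t{v.mutant_aa}\n"
            )
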