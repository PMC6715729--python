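"""Reference oligo handling, variant naming, translation and Hamming utilities.

The mutagenized region is the 177-nt (59-codon) helix-turn-helix domain of
the lambda repressor CI.  The synthesized oligo ships with the package as a
FASTA record in which the constant PCR flanks are uppercase and the doped
region lowercase; parsing is case-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class Oligo:
    """The synthesized library oligo split into flanks and doped region."""

    upstream: str
    doped: str
    downstream: str

    @property
    def full(self) -> str:
        return self.upstream + self.doped + self.downstream

    @property
    def n_codons(self) -> int:
        return len(self.doped) // 3

    @property
    def protein(self) -> str:
        return str(Seq(self.doped).translate())


def load_oligo() -> Oligo:
    """Load the packaged oligo and split it by letter case.

    Returns the 36-nt upstream flank, the 177-nt doped region and the 37-nt
    downstream flank of the 250-nt oligo.
    """
    with resources.files("cidms.data").joinpath("oligo.fasta").open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return split_oligo(str(record.seq))


def split_oligo(sequence: str) -> Oligo:
    """Split an oligo string into (uppercase flank, lowercase doped, flank)."""
    is_lower = [c.islower() for c in sequence]
    if not any(is_lower):
        raise ValueError("oligo contains no lowercase doped region")
    start = is_lower.index(True)
    end = len(sequence) - is_lower[::-1].index(True)
    doped = sequence[start:end]
    if not all(is_lower[start:end]):
        raise ValueError("doped region is not contiguous")
    if len(doped) % 3 != 0:
        raise ValueError("doped region length is not a multiple of 3")
    if any(c not in "acgt" for c in doped):
        raise ValueError("doped region contains non-ACGT characters")
    return Oligo(sequence[:start].upper(), doped.upper(), sequence[end:].upper())


def validate_reference(reference: str) -> str:
    ref = reference.upper()
    if any(c not in NUCLEOTIDES for c in ref):
        raise ValueError("reference contains non-ACGT characters")
    if len(ref) % 3 != 0:
        raise ValueError("reference length must be divisible by 3")
    return ref


WT_ID = "WT"


def format_variant_id(reference: str, changes: tuple[tuple[int, str], ...]) -> str:
    """Name a variant by its nucleotide changes, e.g. ``c5T|g100A``.

    ``changes`` are 0-based (position, alternative base) pairs within the
    doped region; positions are printed 1-based with the reference base in
    lowercase.  The empty change set is named ``WT``.
    """
    if not changes:
        return WT_ID
    parts = [
        f"{reference[pos].lower()}{pos + 1}{alt.upper()}"
        for pos, alt in sorted(changes)
    ]
    return "|".join(parts)


def parse_variant_id(variant_id: str) -> tuple[tuple[int, str], ...]:
    """Invert :func:`format_variant_id` back to 0-based (position, alt) pairs."""
    if variant_id == WT_ID:
        return ()
    changes = []
    for part in variant_id.split("|"):
        pos = int(part[1:-1]) - 1
        changes.append((pos, part[-1].upper()))
    return tuple(changes)


def apply_changes(reference: str, changes: tuple[tuple[int, str], ...]) -> str:
    seq = list(reference)
    for pos, alt in changes:
        seq[pos] = alt
    return "".join(seq)


_CODON_TABLE = {
    str(Seq(a + b + c)): str(Seq(a + b + c).translate())
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
}


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon.upper()]


def describe_variant(
    reference: str, changes: tuple[tuple[int, str], ...]
) -> tuple[str, str]:
    """Amino-acid level description of a nucleotide variant.

    Returns ``(aa_changes, variant_class)`` where ``aa_changes`` is a
    comma-joined list like ``K3R`` (``*`` for stop) over the affected codons
    and ``variant_class`` is one of ``syn``, ``missense``, ``nonsense``.
    Only mutated codons are re-translated.
    """
    if not changes:
        return "", "syn"
    mutated = apply_changes(reference, changes)
    codon_idx = sorted({pos // 3 for pos, _ in changes})
    aa_changes = []
    has_stop = False
    for ci in codon_idx:
        wt_aa = translate_codon(reference[3 * ci : 3 * ci + 3])
        mut_aa = translate_codon(mutated[3 * ci : 3 * ci + 3])
        if mut_aa == wt_aa:
            continue
        if mut_aa == "*":
            has_stop = True
        aa_changes.append(f"{wt_aa}{ci + 1}{mut_aa}")
    if not aa_changes:
        return "", "syn"
    cls = "nonsense" if has_stop else "missense"
    return ",".join(aa_changes), cls


def hamming_distance(variant_id: str) -> int:
    """Nucleotide Hamming distance from the reference, from the variant name."""
    return 0 if variant_id == WT_ID else variant_id.count("|") + 1


def count_single_nt_variants(reference: str) -> int:
    """Number of distinct 1-Hamming nucleotide variants (3 per position)."""
    return 3 * len(validate_reference(reference))


def enumerate_single_nt_variants(reference: str):
    """Yield all 1-Hamming variants as (variant_id, changes) pairs."""
    ref = validate_reference(reference)
    for pos, base in enumerate(ref):
        for alt in NUCLEOTIDES:
            if alt != base:
                changes = ((pos, alt),)
                yield format_variant_id(ref, changes), changes
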