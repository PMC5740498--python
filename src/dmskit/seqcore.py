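"""Sequence and variant data model for deep mutational scanning maps.

Conventions used throughout the package:

* residue and codon positions are 1-based (Met1 is codon 1);
* nucleotide intervals are half-open 0-based internally, 1-based in files;
* amino-acid variants are written compactly as ``K48E`` (missense),
  ``K48*`` (nonsense) and ``K48=`` (synonymous);
* codon-level variants are written ``c.142:AAA>GAA`` where 142 is the
  1-based position of the codon's first nucleotide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "OrfSequence",
    "CodonVariant",
    "AaVariant",
    "translate",
    "classify_codon_variant",
    "snv_accessible_substitutions",
    "possible_substitution_count",
    "read_orf_fasta",
    "write_fasta",
    "read_variant_table",
    "write_variant_table",
]

NUCLEOTIDES = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"


class GeneticCode:
    """Codon -> amino-acid lookup (standard nuclear code).

    Stop codons translate to ``"*"``.  64 codons: 61 sense, 3 stop.
    """

    def __init__(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[1]
        self._map: dict[str, str] = dict(table.forward_table)
        for stop in table.stop_codons:
            self._map[stop] = STOP
        assert len(self._map) == 64

    def __getitem__(self, codon: str) -> str:
        return self._map[codon.upper()]

    def translate_codon(self, codon: str) -> str:
        return self[codon]

    @property
    def codons(self) -> list[str]:
        return sorted(self._map)

    @property
    def stop_codons(self) -> list[str]:
        return sorted(c for c, aa in self._map.items() if aa == STOP)

    def codons_for(self, aa: str) -> list[str]:
        return sorted(c for c, a in self._map.items() if a == aa)


#: module-level standard genetic code instance
STANDARD_CODE = GeneticCode()


class OrfValidationError(ValueError):
    """Raised when a sequence does not satisfy the ORF invariants."""


@dataclass(frozen=True)
class OrfSequence:
    """A validated open reading frame.

    Invariants: length divisible by 3, starts with ATG, contains exactly
    one stop codon which is the final codon, alphabet {A,C,G,T}.
    """

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        nt = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", nt)
        if set(nt) - set(NUCLEOTIDES):
            raise OrfValidationError(
                f"{self.id}: non-ACGT characters {sorted(set(nt) - set(NUCLEOTIDES))}"
            )
        if len(nt) % 3 != 0:
            raise OrfValidationError(f"{self.id}: length {len(nt)} not divisible by 3")
        if len(nt) < 6:
            raise OrfValidationError(f"{self.id}: too short for start + stop")
        if nt[:3] != "ATG":
            raise OrfValidationError(f"{self.id}: does not begin with ATG")
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        stops = [i for i, c in enumerate(codons) if STANDARD_CODE[c] == STOP]
        if stops != [len(codons) - 1]:
            raise OrfValidationError(
                f"{self.id}: expected exactly one terminal stop codon, "
                f"found stops at codon indices {[i + 1 for i in stops]}"
            )

    @property
    def n_codons(self) -> int:
        """Number of codons including the stop."""
        return len(self.nucleotides) // 3

    @property
    def protein_length(self) -> int:
        """Residue count of the encoded protein (stop excluded)."""
        return self.n_codons - 1

    def codon(self, codon_index: int) -> str:
        """Return the codon at a 1-based index."""
        if not 1 <= codon_index <= self.n_codons:
            raise IndexError(f"codon index {codon_index} out of range")
        i = (codon_index - 1) * 3
        return self.nucleotides[i : i + 3]

    @property
    def codons(self) -> list[str]:
        return [self.codon(i) for i in range(1, self.n_codons + 1)]

    @property
    def protein(self) -> str:
        return translate(self)


def translate(orf: OrfSequence) -> str:
    """Translate a validated ORF, dropping the terminal stop."""
    return str(Seq(orf.nucleotides).translate())[:-1]


@dataclass(frozen=True)
class CodonVariant:
    """A single codon replacement at a 1-based codon position."""

    codon_index: int
    wt_codon: str
    mut_codon: str

    def __post_init__(self) -> None:
        wt, mut = self.wt_codon.upper(), self.mut_codon.upper()
        object.__setattr__(self, "wt_codon", wt)
        object.__setattr__(self, "mut_codon", mut)
        if len(wt) != 3 or len(mut) != 3:
            raise ValueError("codons must be 3-mers")
        if wt == mut:
            raise ValueError("wt and mutant codon are identical")
        if self.codon_index < 1:
            raise ValueError("codon_index is 1-based")

    def validate_against(self, orf: OrfSequence) -> None:
        actual = orf.codon(self.codon_index)
        if actual != self.wt_codon:
            raise ValueError(
                f"wt codon mismatch at codon {self.codon_index}: "
                f"ORF has {actual}, variant claims {self.wt_codon}"
            )

    @property
    def wt_aa(self) -> str:
        return STANDARD_CODE[self.wt_codon]

    @property
    def mut_aa(self) -> str:
        return STANDARD_CODE[self.mut_codon]

    def aa_variant(self) -> "AaVariant":
        """The amino-acid level consequence (synonymous allowed)."""
        return AaVariant(self.codon_index, self.wt_aa, self.mut_aa)

    def __str__(self) -> str:
        nt_pos = (self.codon_index - 1) * 3 + 1
        return f"c.{nt_pos}:{self.wt_codon}>{self.mut_codon}"

    @classmethod
    def from_string(cls, s: str) -> "CodonVariant":
        m = re.fullmatch(r"c\.(\d+):([ACGT]{3})>([ACGT]{3})", s.strip())
        if not m:
            raise ValueError(f"cannot parse codon variant {s!r}")
        nt_pos = int(m.group(1))
        if (nt_pos - 1) % 3 != 0:
            raise ValueError(f"nucleotide position {nt_pos} is not a codon start")
        return cls((nt_pos - 1) // 3 + 1, m.group(2), m.group(3))


@dataclass(frozen=True)
class AaVariant:
    """An amino-acid substitution at a 1-based residue position.

    ``mut_aa`` may equal ``wt_aa`` (synonymous, written ``K48=``) or be
    ``"*"`` (nonsense).
    """

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_ALPHABET:
            raise ValueError(f"invalid wt residue {self.wt_aa!r}")
        if self.mut_aa not in AA_ALPHABET + STOP:
            raise ValueError(f"invalid mutant residue {self.mut_aa!r}")
        if self.position < 1:
            raise ValueError("position is 1-based")

    @property
    def is_synonymous(self) -> bool:
        return self.wt_aa == self.mut_aa

    @property
    def is_nonsense(self) -> bool:
        return self.mut_aa == STOP

    @property
    def is_missense(self) -> bool:
        return not (self.is_synonymous or self.is_nonsense)

    def validate_against(self, orf: OrfSequence) -> None:
        protein = translate(orf)
        if self.position > len(protein):
            raise ValueError(f"position {self.position} beyond protein end")
        if protein[self.position - 1] != self.wt_aa:
            raise ValueError(
                f"wt residue mismatch at {self.position}: protein has "
                f"{protein[self.position - 1]}, variant claims {self.wt_aa}"
            )

    def __str__(self) -> str:
        mut = "=" if self.is_synonymous else self.mut_aa
        return f"{self.wt_aa}{self.position}{mut}"

    @classmethod
    def from_string(cls, s: str) -> "AaVariant":
        m = re.fullmatch(r"([A-Y])(\d+)([A-Y*=])", s.strip())
        if not m:
            raise ValueError(f"cannot parse amino-acid variant {s!r}")
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
        if mut == "=":
            mut = wt
        return cls(pos, wt, mut)


def classify_codon_variant(v: CodonVariant, code: GeneticCode = STANDARD_CODE) -> str:
    """Classify a codon change as synonymous, missense or nonsense.

    A change *to* a stop codon is nonsense regardless of the wild-type
    amino acid; wild-type stop codons are not expected here.
    """
    wt_aa, mut_aa = code[v.wt_codon], code[v.mut_codon]
    if mut_aa == STOP:
        return "nonsense"
    if wt_aa == mut_aa:
        return "synonymous"
    return "missense"


def snv_accessible_substitutions(
    orf: OrfSequence,
    include_synonymous: bool = False,
    include_stop: bool = False,
) -> set[AaVariant]:
    """Amino-acid substitutions reachable by one nucleotide change.

    Enumerates, for each non-stop codon of the ORF, all nine single-
    nucleotide neighbors of the actual codon and translates them.
    Synonymous and nonsense outcomes are excluded unless flagged.
    """
    out: set[AaVariant] = set()
    for idx in range(1, orf.n_codons):  # skip the stop codon
        wt_codon = orf.codon(idx)
        wt_aa = STANDARD_CODE[wt_codon]
        for i in range(3):
            for nt in NUCLEOTIDES:
                if nt == wt_codon[i]:
                    continue
                mut_codon = wt_codon[:i] + nt + wt_codon[i + 1 :]
                mut_aa = STANDARD_CODE[mut_codon]
                if mut_aa == STOP and not include_stop:
                    continue
                if mut_aa == wt_aa and not include_synonymous:
                    continue
                out.add(AaVariant(idx, wt_aa, mut_aa))
    return out


def possible_substitution_count(protein_length: int) -> int:
    """Number of possible single amino-acid changes: 19 per residue."""
    if protein_length < 1:
        raise ValueError("protein length must be positive")
    return 19 * protein_length


def all_possible_substitutions(
    protein: str, include_nonsense: bool = False
) -> list[AaVariant]:
    """Every possible missense variant of a protein (optionally + stops)."""
    out = []
    for pos, wt in enumerate(protein, start=1):
        for mut in AA_ALPHABET:
            if mut != wt:
                out.append(AaVariant(pos, wt, mut))
        if include_nonsense:
            out.append(AaVariant(pos, wt, STOP))
    return out


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_orf_fasta(path: str | Path) -> OrfSequence:
    """Read the first record of a FASTA file as a validated ORF."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return OrfSequence(record.id, str(record.seq))


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs to FASTA."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences]
    SeqIO.write(records, str(path), "fasta")


VARIANT_TABLE_COLUMNS = [
    "gene",
    "position",
    "wt_aa",
    "mut_aa",
    "codon_index",
    "wt_codon",
    "mut_codon",
]


def write_variant_table(
    variants: Iterable[CodonVariant], gene: str, path: str | Path
) -> None:
    rows = []
    for v in variants:
        aa = v.aa_variant()
        rows.append(
            {
                "gene": gene,
                "position": aa.position,
                "wt_aa": aa.wt_aa,
                "mut_aa": aa.mut_aa,
                "codon_index": v.codon_index,
                "wt_codon": v.wt_codon,
                "mut_codon": v.mut_codon,
            }
        )
    pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}")
    return df
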