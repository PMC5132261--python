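"""Protein sequence databases: FASTA IO, decoy construction, tryptic digestion.

The search database used for MudPIT-style spectral counting is the
concatenation of the target proteome, a small set of usual contaminants
(keratins, IgGs, proteolytic enzymes), and one shuffled decoy per target
entry.  Decoy hits among accepted peptide-spectrum matches estimate the
false discovery rate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import parser as _pyt_parser

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: cleavage after K or R, never before P; protein termini always count
TRYPSIN_RULE = r"[KR](?!P)"

DECOY_PREFIX = "DECOY_"

CATEGORIES = ("target", "decoy", "contaminant")


class FastaParseError(ValueError):
    """Malformed FASTA input (bad header, illegal residue, duplicate accession)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: a target, decoy, or contaminant protein."""

    accession: str
    sequence: str
    category: str = "target"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.accession}: unknown category {self.category!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"{self.accession}: illegal residue(s) {''.join(sorted(bad))}"
            )

    @property
    def length(self) -> int:
        """Residue count L, the length term of the NSAF denominator."""
        return len(self.sequence)

    @property
    def is_decoy(self) -> bool:
        return self.category == "decoy"


@dataclass(frozen=True)
class PeptideOccurrence:
    """One placement of a peptide inside one parent protein.

    ``start``/``end`` are 0-based half-open; tryptic status is judged from
    the flanking residues of this particular occurrence.
    """

    accession: str
    start: int
    end: int
    tryptic_status: str  # "fully" | "half" | "non"
    missed_cleavages: int = 0


@dataclass
class DigestPeptide:
    """A peptide sequence together with every parent occurrence."""

    sequence: str
    occurrences: list[PeptideOccurrence] = field(default_factory=list)

    @property
    def parents(self) -> frozenset[str]:
        return frozenset(o.accession for o in self.occurrences)

    @property
    def is_fully_tryptic(self) -> bool:
        """True if ANY parent occurrence is fully tryptic."""
        return any(o.tryptic_status == "fully" for o in self.occurrences)


def read_fasta(path: str | Path, category: str = "target") -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` entries, order preserved.

    Raises :class:`FastaParseError` naming the offending line on duplicate
    accessions or illegal residues.
    """
    path = Path(path)
    # line numbers of each header, for error reporting
    header_lines: dict[int, int] = {}
    with open(path) as fh:
        idx = 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                if len(line.rstrip()) == 1:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                header_lines[idx] = lineno
                idx += 1

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        lineno = header_lines.get(i, 0)
        if rec.id in seen:
            raise FastaParseError(
                f"{path}:{lineno}: duplicate accession {rec.id!r} "
                f"(first seen near line {seen[rec.id]})"
            )
        seen[rec.id] = lineno
        try:
            records.append(
                ProteinRecord(accession=rec.id, sequence=str(rec.seq), category=category)
            )
        except ValueError as exc:
            raise FastaParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    SeqIO.write(seq_records, str(Path(path)), "fasta")


def make_decoy_db(
    targets: Sequence[ProteinRecord],
    seed: int | np.random.Generator,
    prefix: str = DECOY_PREFIX,
) -> list[ProteinRecord]:
    """Build one shuffled decoy per target entry.

    Each decoy is a uniform random permutation of its source's residues, so
    length and amino-acid composition (hence the tryptic-peptide length
    distribution) are preserved.  Deterministic given ``seed``.
    """
    if not targets:
        raise ValueError("make_decoy_db: empty target list")
    rng = np.random.default_rng(seed)
    decoys = []
    for rec in targets:
        shuffled = "".join(rng.permutation(list(rec.sequence)))
        decoys.append(
            ProteinRecord(
                accession=prefix + rec.accession, sequence=shuffled, category="decoy"
            )
        )
    return decoys


def build_search_db(
    targets: Sequence[ProteinRecord],
    contaminants: Sequence[ProteinRecord] = (),
    seed: int | np.random.Generator = 0,
) -> list[ProteinRecord]:
    """Concatenated search database: targets + contaminants + 1:1 decoys.

    Contaminants behave as targets in search and quantification but keep
    category ``contaminant`` so reports can flag them; decoys are generated
    for targets and contaminants alike (one per non-decoy entry).
    """
    non_decoy = list(targets) + [
        ProteinRecord(c.accession, c.sequence, "contaminant") for c in contaminants
    ]
    return non_decoy + make_decoy_db(non_decoy, seed)


def _terminus_status(sequence: str, start: int, end: int) -> str:
    """Tryptic status of sequence[start:end] from its flanking residues."""
    n_ok = start == 0 or (sequence[start - 1] in "KR" and sequence[start] != "P")
    c_ok = end == len(sequence) or (sequence[end - 1] in "KR" and sequence[end] != "P")
    if n_ok and c_ok:
        return "fully"
    if n_ok or c_ok:
        return "half"
    return "non"


def digest(
    protein: ProteinRecord, max_missed_cleavages: int = 0
) -> list[DigestPeptide]:
    """In-silico tryptic digestion (Lys-C/trypsin modelled as one rule).

    Cleaves after K or R except before P; the protein's own termini count as
    valid tryptic termini.  Returns every peptide with at most
    ``max_missed_cleavages`` internal cleavage sites.  No length filter is
    applied here — that is the PSM filter's job.
    """
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    pieces = _pyt_parser.xcleave(
        protein.sequence, TRYPSIN_RULE, missed_cleavages=max_missed_cleavages
    )
    by_seq: dict[str, DigestPeptide] = {}
    seen: set[tuple[int, str]] = set()
    for start, pep in pieces:
        if (start, pep) in seen:  # xcleave can repeat boundary pieces
            continue
        seen.add((start, pep))
        n_sites = sum(
            1
            for i in range(start, start + len(pep) - 1)
            if protein.sequence[i] in "KR" and protein.sequence[i + 1] != "P"
        )
        occ = PeptideOccurrence(
            accession=protein.accession,
            start=start,
            end=start + len(pep),
            tryptic_status="fully",
            missed_cleavages=n_sites,
        )
        by_seq.setdefault(pep, DigestPeptide(pep)).occurrences.append(occ)
    return list(by_seq.values())


def map_peptides(
    peptides: Iterable[str], db: Sequence[ProteinRecord]
) -> list[DigestPeptide]:
    """Map peptide strings onto every database protein containing them.

    Every substring occurrence is recorded with its per-occurrence tryptic
    status.  Peptides matching nothing are retained with an empty occurrence
    list — the caller decides their fate.

    Uses a sliding-window scan over the database (one pass per distinct
    peptide length), which is much faster than per-pair substring search for
    large peptide sets.
    """
    peps = sorted(set(p.upper() for p in peptides))
    by_len: dict[int, set[str]] = {}
    for p in peps:
        by_len.setdefault(len(p), set()).add(p)
    result = {p: DigestPeptide(p) for p in peps}
    for rec in db:
        seq = rec.sequence
        n = len(seq)
        for k, wanted in by_len.items():
            if k > n:
                continue
            for i in range(n - k + 1):
                window = seq[i : i + k]
                if window in wanted:
                    result[window].occurrences.append(
                        PeptideOccurrence(
                            accession=rec.accession,
                            start=i,
                            end=i + k,
                            tryptic_status=_terminus_status(seq, i, i + k),
                        )
                    )
    return [result[p] for p in peps]


def write_peptide_map(mapping: Iterable[DigestPeptide], path: str | Path) -> None:
    """Tab-delimited peptide map: peptide, accession, start, end (1-based
    inclusive), status."""
    with open(path, "w") as fh:
        fh.write("peptide\taccession\tstart\tend\tstatus\n")
        for dp in mapping:
            for occ in dp.occurrences:
                fh.write(
                    f"{dp.sequence}\t{occ.accession}\t{occ.start + 1}\t{occ.end}\t"
                    f"{occ.tryptic_status}\n"
                )


def mapping_index(mapping: Iterable[DigestPeptide]) -> dict[str, DigestPeptide]:
    """Peptide-sequence lookup table for a mapping."""
    return {dp.sequence: dp for dp in mapping}
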