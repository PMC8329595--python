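"""Sequence, tree and tabular I/O plus six-frame translation.

FASTA parsing/writing is delegated to Bio.SeqIO; this module adds
alphabet validation, taxon-aware records, six-frame translation with
nucleotide/protein coordinate maps, and newick tree loading via dendropy.

Coordinates are 0-based half-open internally; written reports use
1-based inclusive coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Alphabet = Literal["nucleotide", "protein"]

# IUPAC nucleotide codes (ambiguity allowed) and amino-acid codes + X and *.
NUCLEOTIDE_CODES = set("ACGTURYSWKMBDHVN")
PROTEIN_CODES = set("ACDEFGHIKLMNPQRSTVWYX*")
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the declared alphabet or format."""


class DuplicateTipError(ValueError):
    """Raised when a newick tree carries duplicate tip labels."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with an optional taxon label.

    ``residues`` is stored uppercased; the invariants of the declared
    alphabet are enforced at construction time.
    """

    id: str
    residues: str
    alphabet: Alphabet = "protein"
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        allowed = NUCLEOTIDE_CODES if self.alphabet == "nucleotide" else PROTEIN_CODES
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.alphabet} residue(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TranslatedFrame:
    """One of the six reading frames of a nucleotide record.

    ``frame`` follows the BLAST convention: +1..+3 read the given strand
    at offsets 0..2, -1..-3 read the reverse complement at offsets 0..2.
    ``codon_interval(i)`` maps protein position i (0-based) back to the
    half-open nucleotide interval on the *original* (plus) strand.
    """

    source_id: str
    frame: int
    residues: str
    source_length: int
    taxon: str | None = None

    def codon_interval(self, i: int) -> tuple[int, int]:
        if not 0 <= i < len(self.residues):
            raise IndexError(f"protein position {i} outside frame of length {len(self.residues)}")
        off = abs(self.frame) - 1
        if self.frame > 0:
            start = off + 3 * i
            return start, start + 3
        end = self.source_length - off - 3 * i
        return end - 3, end

    def subject_nt_interval(self, p_start: int, p_end: int) -> tuple[int, int]:
        """Nucleotide interval (plus strand, half-open) covered by protein
        positions [p_start, p_end)."""
        if p_end <= p_start:
            raise ValueError("empty protein interval")
        a = self.codon_interval(p_start)
        b = self.codon_interval(p_end - 1)
        lo = min(a[0], b[0])
        hi = max(a[1], b[1])
        return lo, hi


def _validate_residues(rec: SeqRecord, alphabet: Alphabet, path: Path) -> None:
    allowed = NUCLEOTIDE_CODES if alphabet == "nucleotide" else PROTEIN_CODES
    seq = str(rec.seq).upper()
    bad = set(seq) - allowed
    if bad:
        # locate the offending line for the error message
        lineno = _find_line(path, rec.id, bad)
        raise FastaParseError(
            f"{path}:{lineno}: record {rec.id!r} contains illegal "
            f"{alphabet} residue(s) {''.join(sorted(bad))!r}"
        )


def _find_line(path: Path, rec_id: str, bad: set[str]) -> int:
    in_rec = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                in_rec = line[1:].split()[0] == rec_id if line[1:].strip() else False
            elif in_rec and (set(line.strip().upper()) & bad):
                return lineno
    return 0


def read_fasta(path: str | Path, alphabet: Alphabet, taxon: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into validated SequenceRecords (order preserved)."""
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        _validate_residues(rec, alphabet, path)
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), alphabet=alphabet, taxon=taxon))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# --- translation -----------------------------------------------------------

_NON_STANDARD_AA = str.maketrans({c: "X" for c in "BZJUO"})


def _translate(nt: str) -> str:
    """Standard-code translation; ambiguity codes yield a residue only when
    every expansion agrees, else X; stop codons yield '*'."""
    usable = len(nt) - len(nt) % 3
    if usable < 3:
        return ""
    aa = str(Seq(nt[:usable]).translate(table=1))
    # Biopython emits B/Z/J for partially-resolved ambiguity: collapse to X.
    return aa.translate(_NON_STANDARD_AA)


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def six_frame_translate(record: SequenceRecord) -> list[TranslatedFrame]:
    """Translate a nucleotide record in all six frames (+1..+3, -1..-3)."""
    if record.alphabet != "nucleotide":
        raise ValueError(f"record {record.id!r} is not nucleotide")
    nt = record.residues.replace("U", "T")
    rc = reverse_complement(nt)
    frames = []
    for off in range(3):
        frames.append(TranslatedFrame(record.id, off + 1, _translate(nt[off:]),
                                      len(nt), record.taxon))
    for off in range(3):
        frames.append(TranslatedFrame(record.id, -(off + 1), _translate(rc[off:]),
                                      len(nt), record.taxon))
    return frames


# --- trees -----------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Load a rooted newick tree; auto-label unnamed internal nodes by
    preorder index and reject duplicate tip labels."""
    try:
        if isinstance(source, (str,)) and source.strip().startswith("("):
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=str(source), schema="newick")
    except dendropy.utility.error.DataParseError as exc:
        if "uplicate" in str(exc):
            raise DuplicateTipError(str(exc)) from exc
        raise
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise DuplicateTipError(f"duplicate tip labels: {', '.join(dupes)}")
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.is_internal() and not node.label:
            node.label = f"node{i}"
    return tree


# --- tabular ---------------------------------------------------------------

def write_tsv(rows: Sequence[dict], path: str | Path, header_comment: str | None = None) -> None:
    """Write dict rows as TSV; optional '#'-prefixed header line first."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        if not rows:
            return
        fields: list[str] = []
        for row in rows:
            fields.extend(k for k in row if k not in fields)
        writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t", restval="")
        writer.writeheader()
        writer.writerows(rows)


@dataclass(frozen=True)
class ManifestEntry:
    """One dataset of the study design: a FASTA file, its taxon and type."""

    file_path: str
    taxon: str
    data_type: Literal["transcriptome", "proteome"]


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read the per-dataset manifest (TSV: file_path, taxon, data_type)."""
    entries = []
    with open(path) as fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t")
        for row in reader:
            dt = row["data_type"].strip()
            if dt not in ("transcriptome", "proteome"):
                raise ValueError(f"manifest {path}: bad data_type {dt!r}")
            entries.append(ManifestEntry(row["file_path"].strip(), row["taxon"].strip(), dt))
    if not entries:
        raise ValueError(f"manifest {path}: no entries")
    return entries
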