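"""Standard-format readers and writers.

Internal coordinates are 0-based half-open everywhere; conversion from the
1-based formats (VCF, CT, GFF3) happens here and only here.  The matrix TSV
is the canonical exchange format for dependency maps: first row and column
carry 1-based position labels with the reference base ("17:G"), the
diagonal is left empty, floats are written with 6 significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .depcore import DependencyMap, VariantSpec
from .models import clean_sequence

logger = logging.getLogger("nucdep")


class ParseError(Exception):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, cleaned sequence) with U mapped to T."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append((rec.id, clean_sequence(str(rec.seq))))
        except Exception as exc:
            raise ParseError(f"record {rec.id!r}: {exc}") from exc
    if not out:
        raise ParseError(f"no FASTA records in {path}")
    return out


def write_fasta(records, path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# dot-bracket / CT structure files
# ---------------------------------------------------------------------------

_TIER_PAIRS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_TIER_PAIRS.update({c: c.lower() for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"})
_OPENERS = set(_TIER_PAIRS)
_CLOSER_TO_OPENER = {v: k for k, v in _TIER_PAIRS.items()}


@dataclass
class ContactSet:
    """Unordered base-pair contacts, i < j, 0-based.

    ``pseudoknot`` flags pairs from any bracket tier other than the first
    (round brackets): the non-nested pairings invisible to plain
    secondary-structure notation.
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)
    pseudoknot: list[bool] = field(default_factory=list)

    def canonical_pairs(self) -> list[tuple[int, int]]:
        return [p for p, pk in zip(self.pairs, self.pseudoknot) if not pk]

    def pseudoknot_pairs(self) -> list[tuple[int, int]]:
        return [p for p, pk in zip(self.pairs, self.pseudoknot) if pk]

    def as_set(self) -> set[tuple[int, int]]:
        return set(self.pairs)


def parse_dotbracket(structure: str) -> ContactSet:
    """Stack-match a multi-tier dot-bracket string.

    Tier ``()`` yields canonical nested pairs; ``[]``, ``{}``, ``<>`` and
    ``Aa``–``Zz`` yield pseudoknot-tier pairs.  Dots and unrecognized
    characters are unpaired.
    """
    stacks: dict[str, list[int]] = {}
    contacts = ContactSet()
    for pos, ch in enumerate(structure):
        if ch in _OPENERS:
            stacks.setdefault(ch, []).append(pos)
        elif ch in _CLOSER_TO_OPENER:
            opener = _CLOSER_TO_OPENER[ch]
            stack = stacks.get(opener, [])
            if not stack:
                raise ParseError(
                    f"unbalanced tier {opener}{ch}: unmatched {ch!r} at position {pos}"
                )
            i = stack.pop()
            contacts.pairs.append((i, pos))
            contacts.pseudoknot.append(opener != "(")
    for opener, stack in stacks.items():
        if stack:
            raise ParseError(
                f"unbalanced tier {opener}{_TIER_PAIRS[opener]}: "
                f"unmatched {opener!r} at position {stack[-1]}"
            )
    order = np.argsort([p[0] for p in contacts.pairs]) if contacts.pairs else []
    contacts.pairs = [contacts.pairs[k] for k in order]
    contacts.pseudoknot = [contacts.pseudoknot[k] for k in order]
    return contacts


def read_ct(path) -> ContactSet:
    """Read a CT file (1-based, 0 = unpaired) into 0-based contacts."""
    contacts = ContactSet()
    seen = set()
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    for ln in lines[1:]:  # first line is the header
        fields = ln.split()
        if len(fields) < 6:
            raise ParseError(f"malformed CT row: {ln.strip()!r}")
        try:
            idx, partner = int(fields[0]), int(fields[4])
        except ValueError as exc:
            raise ParseError(f"non-integer CT row: {ln.strip()!r}") from exc
        if partner == 0:
            continue
        i, j = sorted((idx - 1, partner - 1))
        if (i, j) not in seen:
            seen.add((i, j))
            contacts.pairs.append((i, j))
            contacts.pseudoknot.append(False)
    return contacts


# ---------------------------------------------------------------------------
# BED / GFF3 / VCF
# ---------------------------------------------------------------------------


def read_bed(path) -> list[tuple[str, int, int]]:
    """Minimal BED reader: (chrom, start, end), already 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
            out.append((fields[0], start, end))
    return out


@dataclass
class Feature:
    seqid: str
    source: str
    type: str
    start: int  # 0-based half-open internally
    end: int
    strand: str
    attributes: dict


def read_gff3(path) -> list[Feature]:
    """GFF3 reader returning features with 0-based half-open coordinates."""
    import gffutils

    out = []
    try:
        for f in gffutils.iterators.DataIterator(str(path)):
            out.append(Feature(
                seqid=f.seqid, source=f.source, type=f.featuretype,
                start=f.start - 1, end=f.end, strand=f.strand or ".",
                attributes={k: list(v) for k, v in f.attributes.items()},
            ))
    except Exception as exc:
        raise ParseError(f"malformed GFF3 {path}: {exc}") from exc
    return out


def read_vcf_min(path) -> tuple[list[tuple[str, VariantSpec]], int]:
    """Minimal VCF reader: SNVs only, 1-based POS converted to 0-based.

    Returns (records, n_skipped): records are (CHROM, VariantSpec) pairs;
    non-SNV rows (indels, multi-allelic composites) are skipped and counted.
    """
    import pysam

    records: list[tuple[str, VariantSpec]] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = rec.ref or ""
            alts = rec.alts or ()
            for alt in alts:
                if len(ref) == 1 and alt is not None and len(alt) == 1 and \
                        ref in "ACGT" and alt in "ACGT":
                    records.append(
                        (rec.chrom,
                         VariantSpec(pos=rec.pos - 1, ref=ref, alt=alt,
                                     name=rec.id or f"{rec.chrom}:{rec.pos}"))
                    )
                else:
                    skipped += 1
    if skipped:
        logger.info("skipped=%d non-SNV VCF records", skipped)
    return records, skipped


# ---------------------------------------------------------------------------
# matrix TSV
# ---------------------------------------------------------------------------


def position_labels(seq: str) -> list[str]:
    return [f"{i + 1}:{b}" for i, b in enumerate(seq)]


def write_matrix_tsv(m: DependencyMap | np.ndarray, seq: str, path) -> None:
    """Write a dependency map as the canonical TSV (empty diagonal cells)."""
    e = m.e if isinstance(m, DependencyMap) else np.asarray(m, dtype=float)
    n = e.shape[0]
    if len(seq) != n:
        raise ValueError("sequence length does not match matrix size")
    labels = position_labels(seq)
    lines = ["\t".join(["pos"] + labels)]
    for i in range(n):
        cells = [labels[i]]
        for j in range(n):
            v = e[i, j]
            cells.append("" if np.isnan(v) else f"{v:.6g}")
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix_tsv(path) -> tuple[np.ndarray, str]:
    """Read the canonical matrix TSV; returns (matrix with NaN diagonal, seq)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"empty matrix file {path}")
    header = lines[0].split("\t")[1:]
    n = len(header)
    seq = "".join(lbl.split(":")[1] for lbl in header)
    e = np.full((n, n), np.nan)
    if len(lines) - 1 != n:
        raise ParseError(f"{path}: expected {n} matrix rows, got {len(lines) - 1}")
    for i, ln in enumerate(lines[1:]):
        cells = ln.split("\t")[1:]
        if len(cells) != n:
            raise ParseError(f"{path}: row {i} has {len(cells)} cells, expected {n}")
        for j, cell in enumerate(cells):
            if cell != "":
                e[i, j] = float(cell)
    return e, seq
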