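"""Readers and writers for every external representation the pipeline touches.

Formats handled here: FASTA protein sequences (via Biopython), PSI-BLAST
ASCII position-specific scoring matrices (the ``-out_ascii_pssm`` dialect),
tab-separated label files (``id<TAB>label`` with label 0/1), GMT-like
term-to-gene annotation files, tab-separated binding-site tables, and
TSV feature matrices.

PSSMs are produced externally, typically with::

    psiblast -query seq.fasta -db swissprot -num_iterations 3 \\
        -evalue 0.01 -out_ascii_pssm out.pssm

and this module only parses the resulting ASCII file.  The file carries two
20-column blocks: position-specific log-odds scores and weighted percent
frequencies; the reader returns either, recording which block was read in
``PssmMatrix.source_kind``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids in alphabetical single-letter order.  This is
#: the canonical residue order used for feature naming throughout the package.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence.

    The parser does not enforce the standard 20-letter alphabet; dataset
    hygiene (minimum length, unknown residues) is applied explicitly by
    :func:`apply_dataset_filters` so that rejections are recorded, never
    silent.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if any(ch.isspace() for ch in self.id):
            raise ValueError(f"protein id {self.id!r} contains whitespace")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def is_standard(self) -> bool:
        """True iff the sequence uses only the 20 standard residues."""
        return set(self.sequence) <= _STANDARD_SET


@dataclass
class PssmMatrix:
    """An L x 20 position-specific score matrix paired to one protein.

    ``column_order`` is taken verbatim from the file header (PSI-BLAST
    order, not alphabetical); downstream indexing must go through it.
    ``row_residues`` keeps the per-position residue letters from the file so
    the profile can be cross-checked against the FASTA sequence.
    ``source_kind`` records whether the scores came from the log-odds block
    or the percent-frequency block of the ASCII file.
    """

    protein_id: str
    scores: np.ndarray
    column_order: str
    source_kind: str = "log_odds"
    row_residues: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.protein_id!r} must be L x 20, got {self.scores.shape}"
            )
        if sorted(self.column_order) != sorted(STANDARD_AA):
            raise ValueError(
                "column_order must be a permutation of the 20 standard amino acids"
            )
        if self.source_kind not in ("log_odds", "percent_frequency"):
            raise ValueError(f"unknown source_kind {self.source_kind!r}")
        if self.row_residues and len(self.row_residues) != self.scores.shape[0]:
            raise ValueError("row_residues length must equal the row count")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def column_index(self, residue: str) -> int:
        """Index of the profile column for ``residue`` in this matrix."""
        return self.column_order.index(residue)

    def check_sequence(self, record: ProteinRecord) -> None:
        """Raise if this PSSM does not match ``record`` row for row."""
        if self.length != record.length:
            raise ValueError(
                f"PSSM for {self.protein_id!r} has {self.length} rows but the "
                f"sequence has {record.length} residues"
            )
        if self.row_residues and self.row_residues != record.sequence:
            raise ValueError(
                f"PSSM row residues for {self.protein_id!r} disagree with the "
                "FASTA sequence"
            )


@dataclass
class AnnotationSet:
    """Term-to-gene annotation sets over a background universe.

    ``background`` is the universe of all annotated identifiers (the N of the
    hypergeometric test); every term's gene set must be contained in it.
    """

    term_to_genes: dict[str, frozenset[str]]
    background: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.term_to_genes = {t: frozenset(g) for t, g in self.term_to_genes.items()}
        self.background = frozenset(self.background)
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            if not genes <= self.background:
                raise ValueError(
                    f"background_incomplete: term {term!r} has genes outside the background"
                )

    @property
    def n_terms(self) -> int:
        return len(self.term_to_genes)

    @property
    def universe_size(self) -> int:
        return len(self.background)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, in file order.

    Sequences are uppercased.  An entry with an empty sequence raises
    :class:`ParseError` naming the header line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    try:
        with open(path) as fh:
            parsed = list(SeqIO.parse(fh, "fasta"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    for rec in parsed:
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: FASTA entry with an empty header")
        if not seq:
            line = _find_header_line(path, rec.description)
            raise ParseError(
                f"{path}:{line}: FASTA entry {rec.id!r} has an empty sequence"
            )
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        # SeqIO silently yields nothing for non-FASTA text; make that loud.
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith(">"):
            raise ParseError(f"{path}:1: not a FASTA file (no '>' header)")
    return records


def _find_header_line(path: Path, description: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].strip() == description:
                return i
    return 0


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write records to ``path`` in FASTA format (round-trips read_fasta)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(
    path: str | Path,
    protein_id: str | None = None,
    block: str = "log_odds",
) -> PssmMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Parameters
    ----------
    path:
        The ASCII PSSM file.
    protein_id:
        Identifier for the paired protein; defaults to the file stem.
    block:
        ``"log_odds"`` (default) reads the first 20 score columns;
        ``"percent_frequency"`` reads columns 21-40 divided by 100.

    The column order is taken verbatim from the file header.  Row residues
    are retained for cross-checking against the FASTA sequence.
    """
    path = Path(path)
    if block not in ("log_odds", "percent_frequency"):
        raise ValueError(f"unknown block {block!r}")
    if protein_id is None:
        protein_id = path.stem

    with open(path) as fh:
        lines = fh.readlines()

    header_idx = None
    column_order = ""
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(len(t) == 1 and t in _STANDARD_SET for t in toks[:20]):
            header_idx = i
            column_order = "".join(toks[:20])
            break
    if header_idx is None:
        raise ParseError(f"{path}: missing PSSM column-header line")

    rows: list[list[float]] = []
    residues: list[str] = []
    expected_pos = 1
    for i in range(header_idx + 1, len(lines)):
        toks = lines[i].split()
        if not toks:
            break  # blank line terminates the matrix block
        if not toks[0].isdigit():
            break  # trailing K/Lambda statistics
        if int(toks[0]) != expected_pos:
            raise ParseError(f"{path}: row {expected_pos}: unexpected position index {toks[0]}")
        if len(toks) < 42:
            raise ParseError(
                f"{path}: row {expected_pos}: expected 20 score and 20 percent columns, "
                f"got {len(toks) - 2} values"
            )
        residue = toks[1]
        cells = toks[2:42]
        try:
            values = [float(c) for c in cells]
        except ValueError as exc:
            raise ParseError(f"{path}: row {expected_pos}: non-numeric cell ({exc})") from None
        if block == "log_odds":
            rows.append(values[:20])
        else:
            rows.append([v / 100.0 for v in values[20:40]])
        residues.append(residue)
        expected_pos += 1

    if not rows:
        raise ParseError(f"{path}: no score rows found (truncated file?)")

    return PssmMatrix(
        protein_id=protein_id,
        scores=np.array(rows, dtype=float),
        column_order=column_order,
        source_kind=block,
        row_residues="".join(residues),
    )


def write_pssm(matrix: PssmMatrix, path: str | Path, percents: np.ndarray | None = None) -> None:
    """Write an ASCII PSSM in the BLAST+ ``-out_ascii_pssm`` dialect.

    ``matrix.scores`` is written as the log-odds block (rounded to integers,
    as BLAST+ prints).  ``percents`` (L x 20 fractions in [0, 1]) fills the
    percent-frequency block; when omitted, zeros are written.
    """
    scores = matrix.scores
    length = matrix.length
    if percents is None:
        percents = np.zeros_like(scores)
    residues = matrix.row_residues or "X" * length
    buf = io.StringIO()
    buf.write("\n")
    buf.write(
        "Last position-specific scoring matrix computed, weighted observed percentages "
        "rounded down, information per position, and relative weight of gapless real "
        "matches to pseudocounts\n"
    )
    cols = "  ".join(matrix.column_order)
    buf.write(f"            {cols}   {cols}\n")
    for i in range(length):
        lo = " ".join(f"{int(round(v)):3d}" for v in scores[i])
        pc = " ".join(f"{int(round(p * 100)):3d}" for p in percents[i])
        buf.write(f"{i + 1:5d} {residues[i]}  {lo}  {pc}  0.00 0.00\n")
    buf.write("\n")
    buf.write("                      K         Lambda\n")
    buf.write("Standard Ungapped    0.1344     0.3167\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Dataset hygiene


def apply_dataset_filters(
    records: list[ProteinRecord], min_len: int = 50
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Apply the benchmark-dataset filters: minimum length and standard alphabet.

    Sequences shorter than ``min_len`` residues are rejected with reason
    ``"too_short"`` (shorter chains tend to be peptides rather than complete
    proteins); sequences containing letters outside the 20 standard amino
    acids are rejected with reason ``"nonstandard_residue"``.  Exactly
    ``min_len`` residues is kept.

    Returns ``(kept, rejected)`` where ``rejected`` pairs each record with a
    machine-readable reason.
    """
    kept: list[ProteinRecord] = []
    rejected: list[tuple[ProteinRecord, str]] = []
    for rec in records:
        if not rec.is_standard():
            rejected.append((rec, "nonstandard_residue"))
        elif rec.length < min_len:
            rejected.append((rec, "too_short"))
        else:
            kept.append(rec)
    return kept, rejected


# ---------------------------------------------------------------------------
# Labels


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of ``id<TAB>label`` with label in {0, 1}."""
    path = Path(path)
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'id<TAB>label'")
            pid, lab = parts
            if lab not in ("0", "1"):
                raise ParseError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            if pid in labels:
                raise ParseError(f"{path}:{lineno}: duplicate id {pid!r}")
            labels[pid] = int(lab)
    return labels


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, lab in labels.items():
            fh.write(f"{pid}\t{lab}\n")


# ---------------------------------------------------------------------------
# Annotations (GMT-like)


def read_annotations(
    path: str | Path, background_path: str | Path | None = None
) -> AnnotationSet:
    """Read a GMT-like annotation file: ``term<TAB>description<TAB>gene...``.

    The background defaults to the union of all gene sets; an explicit
    background file (one id per line) may widen it, but a background missing
    an annotated gene is an error (``background_incomplete``).  A term id
    listed twice is an error.
    """
    path = Path(path)
    term_to_genes: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 'term<TAB>description<TAB>gene...'"
                )
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in term_to_genes:
                raise ParseError(f"{path}:{lineno}: duplicate term id {term!r}")
            if not genes:
                raise ParseError(f"{path}:{lineno}: term {term!r} has no genes")
            term_to_genes[term] = frozenset(genes)
            descriptions[term] = desc

    union: set[str] = set()
    for genes in term_to_genes.values():
        union |= genes

    if background_path is not None:
        with open(background_path) as fh:
            background = frozenset(line.strip() for line in fh if line.strip())
        if not union <= background:
            missing = sorted(union - background)[:5]
            raise ParseError(
                f"background_incomplete: annotated genes missing from the "
                f"background file (e.g. {missing})"
            )
    else:
        background = frozenset(union)

    return AnnotationSet(term_to_genes, background, descriptions)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in annotations.term_to_genes.items():
            desc = annotations.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Binding-site tables


def read_sites(path: str | Path) -> list[tuple[str, int]]:
    """Read a binding-site TSV of ``protein_id<TAB>position`` (1-based)."""
    path = Path(path)
    rows: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].lstrip("-").isdigit():
                raise ParseError(f"{path}:{lineno}: expected 'protein_id<TAB>position'")
            pos = int(parts[1])
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: position must be >= 1, got {pos}")
            rows.append((parts[0], pos))
    return rows


def write_sites(rows: list[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, pos in rows:
            fh.write(f"{pid}\t{pos}\n")
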