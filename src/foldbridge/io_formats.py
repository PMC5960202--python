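"""Readers and writers for the on-disk formats the pipeline touches.

Sequence I/O (FASTA, Stockholm) is delegated to Biopython; the HMMER3
per-domain tabular format (``domtblout``) and the TSV mapping tables are
parsed here.  All alignment coordinates are stored 1-based inclusive, the
domtblout convention; conversions to half-open intervals happen only
inside coverage arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-.")

#: id pattern of designed linker sequences: DS_<fold>_<famA>_<famB>_<serial>
DESIGNED_ID_RE = re.compile(r"^DS_([^_]+)_([^_]+)_([^_]+)_(\d+)$")


class ParseError(ValueError):
    """A file failed to parse; the message names the offending line."""


class DataError(ValueError):
    """Input data violates a contract (unknown id, conflicting mapping ...)."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence (or one aligned row), 20-letter alphabet.

    ``residues`` may contain ``-`` only when the record is part of an
    alignment, and ``X`` for unknown residues (scored at background).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence record with empty id")
        if not self.residues:
            raise DataError(f"sequence {self.id!r} has empty residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return "".join(c for c in self.residues if c not in GAP_CHARS)


def _validate_residues(rec: SequenceRecord, *, alignment: bool, where: str) -> None:
    allowed = set(AMINO_ACIDS) | {"X"} | (GAP_CHARS if alignment else set())
    bad = set(rec.residues.upper()) - allowed
    if bad:
        raise ParseError(
            f"{where}: sequence {rec.id!r} contains invalid characters {sorted(bad)}"
        )


def read_fasta(path: str | Path, *, alignment: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    With ``alignment=True`` gap characters are retained and all records are
    required to have equal length; otherwise gaps are stripped.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        residues = str(bio.seq).upper()
        if not alignment:
            residues = "".join(c for c in residues if c not in GAP_CHARS)
        if not bio.id:
            raise ParseError(f"{path}: record with empty id")
        if not residues:
            raise ParseError(f"{path}: record {bio.id!r} has an empty sequence")
        if bio.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {bio.id!r}")
        seen.add(bio.id)
        desc = bio.description[len(bio.id):].strip() if bio.description else ""
        rec = SequenceRecord(id=bio.id, residues=residues, description=desc)
        _validate_residues(rec, alignment=alignment, where=str(path))
        records.append(rec)
    if alignment and records:
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise ParseError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    return records


def write_fasta(path: str | Path, records: Iterable[SequenceRecord]) -> None:
    """Write FASTA with 60-column wrapping (round-trips byte-identically)."""
    bio_records = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio_records, fh, "fasta")


def read_stockholm(path: str | Path) -> list[SequenceRecord]:
    """Read a Stockholm alignment (gaps retained, '.' normalized to '-')."""
    aln = AlignIO.read(str(path), "stockholm")
    records = [
        SequenceRecord(
            id=row.id, residues=str(row.seq).upper().replace(".", "-")
        )
        for row in aln
    ]
    for rec in records:
        _validate_residues(rec, alignment=True, where=str(path))
    return records


def read_alignment(path: str | Path) -> list[SequenceRecord]:
    """Read an alignment from aligned FASTA or Stockholm, by extension."""
    suffix = Path(path).suffix.lower()
    if suffix in {".sto", ".stk", ".stockholm"}:
        return read_stockholm(path)
    return read_fasta(path, alignment=True)


# ---------------------------------------------------------------------------
# hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hit:
    """One retrieved target domain for one query.

    ``evalue`` is the per-domain independent E-value; coordinates are
    1-based inclusive.  ``iteration_found`` is the first search round in
    which the target was retrieved (1 for a single-pass search).
    """

    query_id: str
    target_id: str
    evalue: float
    bitscore: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    q_len: int
    t_len: int
    full_evalue: float | None = None
    iteration_found: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.q_start <= self.q_end <= self.q_len):
            raise DataError(
                f"hit {self.query_id}->{self.target_id}: bad query coords "
                f"{self.q_start}..{self.q_end} (len {self.q_len})"
            )
        if not (0 < self.t_start <= self.t_end <= self.t_len):
            raise DataError(
                f"hit {self.query_id}->{self.target_id}: bad target coords "
                f"{self.t_start}..{self.t_end} (len {self.t_len})"
            )
        if not self.evalue > 0:
            raise DataError(
                f"hit {self.query_id}->{self.target_id}: E-value must be > 0"
            )

    @property
    def query_coverage(self) -> float:
        """Fraction of the query spanned by the aligned region."""
        return (self.q_end - self.q_start + 1) / self.q_len

    @property
    def target_coverage(self) -> float:
        return (self.t_end - self.t_start + 1) / self.t_len


class HitTable:
    """An ordered collection of :class:`Hit` objects."""

    def __init__(self, hits: Iterable[Hit] = ()) -> None:
        self.hits: list[Hit] = list(hits)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[Hit]:
        return iter(self.hits)

    def __getitem__(self, i: int) -> Hit:
        return self.hits[i]

    def sorted_by_evalue(self) -> "HitTable":
        return HitTable(sorted(self.hits, key=lambda h: (h.evalue, h.target_id)))

    def best_domain_per_target(self) -> "HitTable":
        """Keep only the lowest-E-value domain of each target sequence."""
        best: dict[str, Hit] = {}
        for h in self.hits:
            cur = best.get(h.target_id)
            if cur is None or h.evalue < cur.evalue:
                best[h.target_id] = h
        return HitTable(sorted(best.values(), key=lambda h: (h.evalue, h.target_id)))


# domtblout columns (HMMER3): 0 target, 2 tlen, 3 query, 5 qlen, 6 full E,
# 12 i-Evalue, 13 dom score, 15-16 hmm coords, 17-18 ali coords.
_DOMTBL_MIN_COLS = 23


def read_domtblout(path: str | Path) -> HitTable:
    """Parse a HMMER3 per-domain tabular file into a :class:`HitTable`.

    The query (hmm) coordinates come from the ``hmm from/to`` columns and
    the target coordinates from the ``ali from/to`` columns; the E-value
    retained for downstream filtering is the per-domain independent
    E-value (``i-Evalue``).
    """
    path = Path(path)
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, "
                    f"got {len(cols)}"
                )
            try:
                hits.append(
                    Hit(
                        target_id=cols[0],
                        t_len=int(cols[2]),
                        query_id=cols[3],
                        q_len=int(cols[5]),
                        full_evalue=float(cols[6]),
                        evalue=float(cols[12]),
                        bitscore=float(cols[13]),
                        q_start=int(cols[15]),
                        q_end=int(cols[16]),
                        t_start=int(cols[17]),
                        t_end=int(cols[18]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return HitTable(hits)


def write_hits(path: str | Path, hits: HitTable) -> None:
    """Write a hit table as TSV, mirroring the domtblout columns used."""
    header = (
        "query_id\ttarget_id\tevalue\tbitscore\tq_start\tq_end\t"
        "t_start\tt_end\tq_len\tt_len\titeration_found\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.evalue:.6g}\t{h.bitscore:.2f}\t"
                f"{h.q_start}\t{h.q_end}\t{h.t_start}\t{h.t_end}\t"
                f"{h.q_len}\t{h.t_len}\t{h.iteration_found}\n"
            )


def read_hits(path: str | Path) -> HitTable:
    """Read the TSV produced by :func:`write_hits`."""
    hits: list[Hit] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("query_id\t"):
            raise ParseError(f"{path}: missing hits TSV header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 11:
                raise ParseError(f"{path}:{lineno}: expected 11 columns")
            hits.append(
                Hit(
                    query_id=cols[0],
                    target_id=cols[1],
                    evalue=float(cols[2]),
                    bitscore=float(cols[3]),
                    q_start=int(cols[4]),
                    q_end=int(cols[5]),
                    t_start=int(cols[6]),
                    t_end=int(cols[7]),
                    q_len=int(cols[8]),
                    t_len=int(cols[9]),
                    iteration_found=int(cols[10]),
                )
            )
    return HitTable(hits)


# ---------------------------------------------------------------------------
# mapping tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldMapEntry:
    family_id: str
    fold_id: str
    designed: bool = False
    parent_families: tuple[str, str] | None = None


@dataclass
class FoldMap:
    """Mapping target sequence id -> (family, fold), with designed flags.

    Designed-sequence ids follow ``DS_<fold>_<famA>_<famB>_<serial>`` and
    are recognized on read; a designed entry records both parent families.
    Lookups of unknown ids raise :class:`DataError` rather than defaulting.
    """

    entries: dict[str, FoldMapEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, target_id: str) -> bool:
        return target_id in self.entries

    def add(self, target_id: str, family_id: str, fold_id: str) -> None:
        designed_match = DESIGNED_ID_RE.match(target_id)
        entry = FoldMapEntry(
            family_id=family_id,
            fold_id=fold_id,
            designed=designed_match is not None,
            parent_families=(
                (designed_match.group(2), designed_match.group(3))
                if designed_match
                else None
            ),
        )
        existing = self.entries.get(target_id)
        if existing is not None:
            if existing.fold_id != fold_id:
                raise DataError(
                    f"duplicate target id {target_id!r} with conflicting folds "
                    f"{existing.fold_id!r} vs {fold_id!r}"
                )
            return  # identical duplicate: deduplicate silently
        self.entries[target_id] = entry

    def fold_of(self, target_id: str) -> str:
        entry = self.entries.get(target_id)
        if entry is None:
            raise DataError(f"target id {target_id!r} not in fold map")
        return entry.fold_id

    def family_of(self, target_id: str) -> str:
        entry = self.entries.get(target_id)
        if entry is None:
            raise DataError(f"target id {target_id!r} not in fold map")
        return entry.family_id

    def is_designed(self, target_id: str) -> bool:
        entry = self.entries.get(target_id)
        if entry is None:
            raise DataError(f"target id {target_id!r} not in fold map")
        return entry.designed


def read_fold_map(path: str | Path) -> FoldMap:
    """Read a TSV ``target_id<TAB>family_id<TAB>fold_id`` file (with header)."""
    fm = FoldMap()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise ParseError(f"{path}: fold map header needs >= 3 columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            fm.add(cols[0], cols[1], cols[2])
    return fm


def write_fold_map(path: str | Path, fm: FoldMap) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\tfamily_id\tfold_id\n")
        for tid in sorted(fm.entries):
            e = fm.entries[tid]
            fh.write(f"{tid}\t{e.family_id}\t{e.fold_id}\n")


def read_clan_map(path: str | Path) -> dict[str, str]:
    """Read a TSV ``family_id<TAB>clan_id`` file (with header)."""
    clans: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            family, clan = cols[0], cols[1]
            if family in clans and clans[family] != clan:
                raise DataError(f"family {family!r} mapped to two clans")
            clans[family] = clan
    return clans


def read_truth(path: str | Path) -> dict[str, str]:
    """Read a TSV ``family_id<TAB>fold_id`` truth table (with header)."""
    truth: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if cols[0] in truth and truth[cols[0]] != cols[1]:
                raise DataError(f"family {cols[0]!r} has conflicting true folds")
            truth[cols[0]] = cols[1]
    return truth


def write_assignments(path: str | Path, assignments: Sequence) -> None:
    """Write one TSV row per query family: fold call, nff, coverage, label."""
    with open(path, "w") as fh:
        fh.write(
            "query_family\tfold_id\tnff\tbest_query_coverage\tconfidence\t"
            "n_folds\tn_hits_used\thigh_confidence\tinferred_via_clan\n"
        )
        for a in assignments:
            fold = a.fold_id if a.fold_id is not None else "NONE"
            fh.write(
                f"{a.query_family}\t{fold}\t{a.nff:.6f}\t"
                f"{a.best_query_coverage:.6f}\t{a.confidence}\t{a.n_folds}\t"
                f"{a.n_hits_used}\t{int(a.high_confidence)}\t"
                f"{int(a.inferred_via_clan)}\n"
            )


def read_config_yaml(path: str | Path) -> Mapping:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return data
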