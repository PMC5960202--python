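"""Synthetic folds and families with controllable divergence.

The generator emulates, at toy scale, the structure the method assumes:
a structural fold is a set of protein families descending from a common
ancestor, with between-family divergence large enough that direct
sequence search fails, and within-family divergence small enough that a
family is still coherent.  Substitutions follow a uniform replacement
model (each mutated site is redrawn uniformly from the 20 residues);
indels are geometric-length insertion/deletion events.  Everything is
deterministic per seed.

The module also provides the representative-selection step (a greedy
single-linkage emulation of blastclust at 60% identity / 90% mutual
length coverage) and the benchmark builder that assembles a search
database, fold map and truth table, optionally enriched with designed
linker sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from zlib import crc32

from .io_formats import AMINO_ACIDS, DataError, FoldMap, SequenceRecord
from .linker_design import DEFAULT_LINKERS_PER_PAIR, design_linkers
from .profiles import BACKGROUND

DEFAULT_N_FOLDS = 3
DEFAULT_N_FAMILIES = 3
DEFAULT_SEQS_PER_FAMILY = 20
DEFAULT_LENGTH = 120
DEFAULT_WITHIN_DIV = 0.1
DEFAULT_BETWEEN_DIV = 0.65
DEFAULT_INDEL_RATE = 0.005


@dataclass
class SimulatedCorpus:
    """Families (as alignments), truth table, and unaligned members."""

    families: dict[str, list[SequenceRecord]]  # family id -> alignment
    truth: dict[str, str]  # family id -> fold id
    members: dict[str, list[SequenceRecord]]  # family id -> unaligned members
    params: dict = field(default_factory=dict)

    def all_members(self) -> list[SequenceRecord]:
        out: list[SequenceRecord] = []
        for fam in sorted(self.members):
            out.extend(self.members[fam])
        return out


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Uniform replacement: each site redrawn uniformly with probability
    ``rate`` (so the expected retained-identity is 1 - 19/20 * rate)."""
    chars = list(seq)
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        chars[i] = AMINO_ACIDS[rng.integers(0, 20)]
    return "".join(chars)


def _member_with_indels(
    founder: str, within_div: float, indel_rate: float, rng: np.random.Generator
) -> tuple[list[str], dict[int, str]]:
    """Evolve one member from the founder, in founder coordinates.

    Returns (core, insertions): ``core[i]`` is the member's residue at
    founder position i or '-' if deleted; ``insertions[i]`` is the
    string inserted immediately before founder position i (i may equal
    len(founder) for a terminal insertion).  Indel events occur per site
    with probability ``indel_rate`` and have Geometric(1/2) lengths.
    """
    mutated = _mutate(founder, within_div, rng)
    core = list(mutated)
    insertions: dict[int, str] = {}
    L = len(founder)
    i = 0
    while i < L:
        if rng.random() < indel_rate:
            k = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # deletion of k sites
                for j in range(i, min(i + k, L)):
                    core[j] = "-"
                i += k
                continue
            insertions[i] = _random_sequence(k, rng)
        i += 1
    return core, insertions


def _assemble_alignment(
    family_id: str,
    rows: list[tuple[str, list[str], dict[int, str]]],
    founder_len: int,
) -> list[SequenceRecord]:
    """Merge per-member founder-coordinate rows into one MSA."""
    ins_len = [0] * (founder_len + 1)
    for _, _, insertions in rows:
        for pos, chunk in insertions.items():
            ins_len[pos] = max(ins_len[pos], len(chunk))
    records = []
    for name, core, insertions in rows:
        parts: list[str] = []
        for pos in range(founder_len + 1):
            chunk = insertions.get(pos, "")
            parts.append(chunk + "-" * (ins_len[pos] - len(chunk)))
            if pos < founder_len:
                parts.append(core[pos])
        records.append(SequenceRecord(id=name, residues="".join(parts)))
    return records


def simulate_fold(
    fold_id: str,
    n_families: int,
    seqs_per_family: int,
    length: int,
    within_div: float,
    between_div: float,
    indel_rate: float,
    seed: int,
    chimeric_last: bool = True,
) -> SimulatedCorpus:
    """Simulate one fold: a fold ancestor, diverged family founders, and
    family members with substitutions and indels.

    With ``chimeric_last`` (and at least three families) the last
    family's founder is a recombinant of the first two founders — its
    N-terminal half from one, its C-terminal half from the other.  This
    emulates the continuity of real fold space, where a sequence family
    can lie *between* two structurally characterized families: each
    characterized family then matches only part of such a query family,
    which is exactly the regime in which designed linker sequences (that
    span both halves) matter.
    """
    if not (0.0 <= within_div < between_div <= 1.0):
        raise DataError("need 0 <= within_div < between_div <= 1")
    if not 0.0 <= indel_rate <= 0.2:
        raise DataError("indel_rate must be in [0, 0.2]")
    if length < 30:
        raise DataError("length must be >= 30")
    rng = np.random.default_rng([seed, crc32(fold_id.encode())])
    ancestor = _random_sequence(length, rng)
    families: dict[str, list[SequenceRecord]] = {}
    members: dict[str, list[SequenceRecord]] = {}
    truth: dict[str, str] = {}
    founders: list[str] = []
    for fi in range(n_families):
        family_id = f"{fold_id}{chr(ord('a') + fi)}"
        if chimeric_last and fi == n_families - 1 and len(founders) >= 2:
            half = length // 2
            founder = founders[0][:half] + founders[1][half:]
        else:
            founder = _mutate(ancestor, between_div, rng)
        founders.append(founder)
        rows = []
        for si in range(seqs_per_family):
            name = f"{family_id}_s{si + 1:03d}"
            rows.append((name, *_member_with_indels(founder, within_div, indel_rate, rng)))
        alignment = _assemble_alignment(family_id, rows, length)
        families[family_id] = alignment
        members[family_id] = [
            SequenceRecord(id=r.id, residues=r.ungapped) for r in alignment
        ]
        truth[family_id] = fold_id
    return SimulatedCorpus(families=families, truth=truth, members=members)


def simulate_corpus(
    n_folds: int = DEFAULT_N_FOLDS,
    n_families: int = DEFAULT_N_FAMILIES,
    seqs_per_family: int = DEFAULT_SEQS_PER_FAMILY,
    length: int = DEFAULT_LENGTH,
    within_div: float = DEFAULT_WITHIN_DIV,
    between_div: float = DEFAULT_BETWEEN_DIV,
    indel_rate: float = DEFAULT_INDEL_RATE,
    seed: int = 1,
    chimeric_last: bool = True,
) -> SimulatedCorpus:
    """Simulate ``n_folds`` independent folds (ids f1, f2, ...)."""
    families: dict[str, list[SequenceRecord]] = {}
    members: dict[str, list[SequenceRecord]] = {}
    truth: dict[str, str] = {}
    for k in range(n_folds):
        fold = simulate_fold(
            f"f{k + 1}",
            n_families,
            seqs_per_family,
            length,
            within_div,
            between_div,
            indel_rate,
            seed + k,
            chimeric_last=chimeric_last,
        )
        families.update(fold.families)
        members.update(fold.members)
        truth.update(fold.truth)
    return SimulatedCorpus(
        families=families,
        truth=truth,
        members=members,
        params=dict(
            n_folds=n_folds,
            n_families=n_families,
            seqs_per_family=seqs_per_family,
            length=length,
            within_div=within_div,
            between_div=between_div,
            indel_rate=indel_rate,
            seed=seed,
        ),
    )


# ---------------------------------------------------------------------------
# representative selection (blastclust emulation)
# ---------------------------------------------------------------------------

def _pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / min(len(a), len(b))


def representative_select(
    sequences: list[SequenceRecord],
    identity: float = 0.60,
    coverage: float = 0.90,
) -> list[SequenceRecord]:
    """Greedy single-linkage clustering; one representative per cluster.

    Two sequences are linked when their global-alignment identity is at
    least ``identity`` and their mutual length coverage
    ``min(len)/max(len)`` is at least ``coverage``.  The representative
    of a cluster is its longest sequence (ties by lexicographic id).
    Output order follows the representatives' ids.
    """
    if not sequences:
        raise DataError("representative_select needs at least one sequence")
    seqs = sorted(sequences, key=lambda r: r.id)
    n = len(seqs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=0.0,
        open_gap_score=-1.0,
        extend_gap_score=-0.5,
    )
    for i in range(n):
        for j in range(i + 1, n):
            la, lb = len(seqs[i]), len(seqs[j])
            if min(la, lb) / max(la, lb) < coverage:
                continue
            if _pairwise_identity(seqs[i].residues, seqs[j].residues, aligner) >= identity:
                parent[find(i)] = find(j)

    clusters: dict[int, list[SequenceRecord]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(seqs[i])
    reps = [
        min(group, key=lambda r: (-len(r), r.id)) for group in clusters.values()
    ]
    return sorted(reps, key=lambda r: r.id)


# ---------------------------------------------------------------------------
# benchmark assembly
# ---------------------------------------------------------------------------

@dataclass
class Benchmark:
    db: list[SequenceRecord]
    fold_map: FoldMap
    truth: dict[str, str]  # query family -> true fold
    queries: dict[str, list[SequenceRecord]]  # query family -> held-out queries


def make_benchmark(
    corpus: SimulatedCorpus,
    with_linkers: bool,
    linkers_per_pair: int = DEFAULT_LINKERS_PER_PAIR,
    seed: int = 1,
    holdout: str = "representative",
    queries_per_family: int = 1,
) -> Benchmark:
    """Assemble a search database, fold map, truth table and queries.

    ``holdout="representative"`` holds out up to ``queries_per_family``
    cluster representatives per family; the family's remaining members
    stay in the database.  ``holdout="family"`` designates the first
    family of every fold as the query family and removes all its members
    from the database — the regime of a query family with no sequenced
    relative, where fold recognition must go through the other families
    of the fold.  Designed linkers are generated for every same-fold
    pair of database families.
    """
    if holdout not in ("representative", "family"):
        raise DataError(f"unknown holdout mode {holdout!r}")
    fold_map = FoldMap()
    db: list[SequenceRecord] = []
    queries: dict[str, list[SequenceRecord]] = {}
    truth: dict[str, str] = {}

    fold_families: dict[str, list[str]] = {}
    for fam in sorted(corpus.families):
        fold_families.setdefault(corpus.truth[fam], []).append(fam)

    query_families: set[str] = set()
    if holdout == "family":
        # the last family of a fold (the recombinant intermediate when the
        # corpus was simulated with chimeric_last) plays the uncharacterized
        # query family; the remaining families stand for the structure db
        for fold in sorted(fold_families):
            query_families.add(fold_families[fold][-1])

    for fam in sorted(corpus.families):
        members = corpus.members[fam]
        reps = representative_select(members)
        # hold out cluster representatives first; if more queries are
        # requested than clusters exist, top up with further members
        rep_ids = {r.id for r in reps}
        pool = reps + [m for m in members if m.id not in rep_ids]
        held = pool[:queries_per_family]
        if holdout == "family" and fam not in query_families:
            held = []
        held_ids = {r.id for r in held}
        if held:
            queries[fam] = held
            truth[fam] = corpus.truth[fam]
        if holdout == "family" and fam in query_families:
            continue  # whole query family withheld from the db
        for rec in members:
            if rec.id in held_ids:
                continue
            db.append(rec)
            fold_map.add(rec.id, fam, corpus.truth[fam])

    if with_linkers:
        db_families = {
            fold: [f for f in fams if f not in query_families]
            for fold, fams in fold_families.items()
        }
        for fold in sorted(db_families):
            fams = db_families[fold]
            for i in range(len(fams)):
                for j in range(i + 1, len(fams)):
                    fam_a, fam_b = fams[i], fams[j]
                    pair_seed = np.random.default_rng(
                        [seed, crc32(f"{fold}|{fam_a}|{fam_b}".encode())]
                    ).integers(0, 2**31)
                    linkers, linker_map = design_linkers(
                        corpus.families[fam_a],
                        corpus.families[fam_b],
                        fold_id=fold,
                        n=linkers_per_pair,
                        seed=int(pair_seed),
                        fam_a_id=fam_a,
                        fam_b_id=fam_b,
                    )
                    db.extend(linkers)
                    for tid, entry in linker_map.entries.items():
                        fold_map.add(tid, entry.family_id, entry.fold_id)
    return Benchmark(db=db, fold_map=fold_map, truth=truth, queries=queries)
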