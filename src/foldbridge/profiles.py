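"""Per-column frequency profiles of family alignments, and their alignment.

A family alignment is condensed into a :class:`FamilyProfile`: one
20-vector of post-pseudocount residue probabilities per column, with
Henikoff position-based sequence weighting.  Two profiles are compared
column-by-column with a Jensen-Shannon-based similarity and aligned
globally under affine gap penalties; the resulting column correspondence
is what linker design samples from.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import AA_INDEX, AMINO_ACIDS, GAP_CHARS, DataError, SequenceRecord

# Robinson & Robinson amino-acid background frequencies, order ACDEFGHIKLMNPQRSTVWY
BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856,
        0.07377, 0.02199, 0.05142, 0.05744, 0.09019,
        0.02243, 0.04487, 0.05203, 0.04264, 0.05129,
        0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

DEFAULT_PSEUDOCOUNT_WEIGHT = 0.1
DEFAULT_GAP_OPEN = 3.0
DEFAULT_GAP_EXTEND = 0.3

GAP = None  # sentinel used in alignment pair lists


@dataclass(frozen=True)
class ProfileColumn:
    """Residue probabilities of one alignment column.

    ``freqs`` sums to 1 over the 20 standard residues (post pseudocount);
    ``gap_fraction`` is the weighted fraction of gap characters;
    ``n_eff`` is the effective residue diversity used to scale pseudocounts.
    """

    freqs: np.ndarray
    gap_fraction: float
    n_eff: float

    def __post_init__(self) -> None:
        if abs(float(self.freqs.sum()) - 1.0) > 1e-9:
            raise DataError("column frequencies must sum to 1")
        if not (0.0 <= self.gap_fraction <= 1.0):
            raise DataError("gap_fraction must be in [0, 1]")


@dataclass(frozen=True)
class FamilyProfile:
    family_id: str
    columns: tuple[ProfileColumn, ...]

    @property
    def consensus_length(self) -> int:
        return len(self.columns)

    def freq_matrix(self) -> np.ndarray:
        """(consensus_length, 20) matrix of column frequencies."""
        return np.stack([c.freqs for c in self.columns])

    def gap_fractions(self) -> np.ndarray:
        return np.array([c.gap_fraction for c in self.columns])


@dataclass(frozen=True)
class ProfilePairAlignment:
    """Global column correspondence between two profiles.

    ``pairs`` is an ordered list of ``(i, j)`` with 0-based column indices;
    a gap on either side is ``None``.  Indices are strictly increasing
    along each profile and each non-gap index is used exactly once.
    """

    pairs: tuple[tuple[int | None, int | None], ...]
    score: float

    def transposed(self) -> "ProfilePairAlignment":
        return ProfilePairAlignment(
            pairs=tuple((j, i) for i, j in self.pairs), score=self.score
        )


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def henikoff_weights(rows: Sequence[str]) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights, summing to 1.

    Gap characters count as their own symbol class, so heavily gapped
    sequences are not over-weighted.
    """
    n = len(rows)
    length = len(rows[0])
    weights = np.zeros(n)
    for j in range(length):
        column = [row[j] for row in rows]
        symbols: dict[str, int] = {}
        for c in column:
            key = "-" if c in GAP_CHARS else c
            symbols[key] = symbols.get(key, 0) + 1
        r = len(symbols)
        for i, c in enumerate(column):
            key = "-" if c in GAP_CHARS else c
            weights[i] += 1.0 / (r * symbols[key])
    total = weights.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return weights / total


def build_profile(
    alignment: Sequence[SequenceRecord],
    pseudocount_weight: float = DEFAULT_PSEUDOCOUNT_WEIGHT,
    background: np.ndarray | None = None,
    family_id: str = "",
    weighting: str = "henikoff",
) -> FamilyProfile:
    """Estimate a :class:`FamilyProfile` from an alignment.

    Observed residue frequencies (Henikoff-weighted) are mixed with the
    background via a per-column pseudocount admixture
    ``alpha = min(1, pseudocount_weight / n_eff)`` where ``n_eff`` is the
    number of distinct residue types in the column.  Unknown residues
    ('X') contribute background-shaped counts.  Columns that are more
    than half gaps are retained (they are masked later, at the
    linker-design stage); an all-gap column is an error.
    """
    if len(alignment) < 2:
        raise DataError("build_profile requires >= 2 aligned sequences")
    if background is None:
        background = BACKGROUND
    rows = [rec.residues.upper() for rec in alignment]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise DataError(f"ragged alignment: row lengths {sorted(lengths)}")
    length = lengths.pop()
    for rec, row in zip(alignment, rows):
        bad = set(row) - set(AMINO_ACIDS) - {"X"} - GAP_CHARS
        if bad:
            raise DataError(f"sequence {rec.id!r}: invalid characters {sorted(bad)}")

    if weighting == "henikoff":
        weights = henikoff_weights(rows)
    elif weighting == "uniform":
        weights = np.full(len(rows), 1.0 / len(rows))
    else:
        raise DataError(f"unknown weighting scheme {weighting!r}")
    columns: list[ProfileColumn] = []
    for j in range(length):
        counts = np.zeros(20)
        gap_weight = 0.0
        seen: set[str] = set()
        for i, row in enumerate(rows):
            c = row[j]
            if c in GAP_CHARS:
                gap_weight += weights[i]
            elif c == "X":
                counts += weights[i] * background
            else:
                counts[AA_INDEX[c]] += weights[i]
                seen.add(c)
        total = counts.sum()
        if total == 0:
            raise DataError(f"column {j + 1} is all gaps")
        observed = counts / total
        n_eff = max(len(seen), 1)
        alpha = min(1.0, pseudocount_weight / n_eff) if pseudocount_weight > 0 else 0.0
        freqs = (1.0 - alpha) * observed + alpha * background
        freqs = freqs / freqs.sum()
        columns.append(
            ProfileColumn(freqs=freqs, gap_fraction=float(gap_weight), n_eff=float(n_eff))
        )
    return FamilyProfile(family_id=family_id or alignment[0].id, columns=tuple(columns))


# ---------------------------------------------------------------------------
# column similarity and profile-profile alignment
# ---------------------------------------------------------------------------

def _entropy2(p: np.ndarray) -> np.ndarray:
    """Base-2 Shannon entropy along the last axis (0 log 0 := 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=-1)


def column_similarity_matrix(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Pairwise column similarity ``1 - 2*JSD`` between two profiles.

    The Jensen-Shannon divergence (base 2) lies in [0, 1]; the affine map
    ``1 - 2*JSD`` sends identical columns to +1 and centres unrelated
    column pairs (JSD near 0.5) around 0, so that matching random columns
    carries no systematic reward.
    """
    m = 0.5 * (fa[:, None, :] + fb[None, :, :])
    jsd = _entropy2(m) - 0.5 * _entropy2(fa)[:, None] - 0.5 * _entropy2(fb)[None, :]
    jsd = np.clip(jsd, 0.0, 1.0)
    return 1.0 - 2.0 * jsd


def centered_similarity_matrix(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Column similarity centred to mean 0 over the profile pair.

    Subtracting the all-pairs mean makes the expected score of an
    unrelated column pair ~0 (for unrelated profiles every pair is a
    "random pair"), so that gap penalties — not an arbitrary similarity
    offset — decide where gaps go.  This is what makes the stated
    defaults ``gap_open=3.0, gap_extend=0.3`` meaningful: a gap must be
    paid for, while matching two unrelated columns is cost-neutral on
    average.
    """
    S = column_similarity_matrix(fa, fb)
    return S - S.mean()


_M, _X, _Y = 0, 1, 2  # match / gap-in-B (consume A) / gap-in-A (consume B)


def align_profiles(
    a: FamilyProfile,
    b: FamilyProfile,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ProfilePairAlignment:
    """Global affine-gap alignment of two profiles (Gotoh recursion).

    A gap run of length k costs ``gap_open + k * gap_extend``.  Ties are
    broken deterministically: match preferred over a gap in ``b``
    preferred over a gap in ``a``.
    """
    if a.consensus_length == 0 or b.consensus_length == 0:
        raise DataError("cannot align empty profiles")
    S = centered_similarity_matrix(a.freq_matrix(), b.freq_matrix())
    n, m = S.shape
    NEG = -np.inf

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b: consumes columns of a
    Y = np.full((n + 1, m + 1), NEG)  # gap in a: consumes columns of b
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + gap_extend * i)
        ptrX[i, 0] = _M if i == 1 else _X
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + gap_extend * j)
        ptrY[0, j] = _M if j == 1 else _Y

    def _argmax3(vm: float, vx: float, vy: float) -> tuple[float, int]:
        # deterministic tie-break: M over X over Y
        if vm >= vx and vm >= vy:
            return vm, _M
        if vx >= vy:
            return vx, _X
        return vy, _Y

    for i in range(1, n + 1):
        Si = S[i - 1]
        for j in range(1, m + 1):
            best, state = _argmax3(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best + Si[j - 1]
            ptrM[i, j] = state

            open_from, open_state = _argmax3(M[i - 1, j], NEG, Y[i - 1, j])
            open_score = open_from - gap_open - gap_extend
            ext_score = X[i - 1, j] - gap_extend
            if open_score >= ext_score:
                X[i, j], ptrX[i, j] = open_score, open_state
            else:
                X[i, j], ptrX[i, j] = ext_score, _X

            open_from, open_state = _argmax3(M[i, j - 1], X[i, j - 1], NEG)
            open_score = open_from - gap_open - gap_extend
            ext_score = Y[i, j - 1] - gap_extend
            if open_score >= ext_score:
                Y[i, j], ptrY[i, j] = open_score, open_state
            else:
                Y[i, j], ptrY[i, j] = ext_score, _Y

    score, state = _argmax3(M[n, m], X[n, m], Y[n, m])
    pairs: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _M:
            pairs.append((i - 1, j - 1))
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == _X:
            pairs.append((i - 1, GAP))
            state = int(ptrX[i, j])
            i -= 1
        else:
            pairs.append((GAP, j - 1))
            state = int(ptrY[i, j])
            j -= 1
    pairs.reverse()
    return ProfilePairAlignment(pairs=tuple(pairs), score=float(score))


def alignment_score(
    a: FamilyProfile,
    b: FamilyProfile,
    pairs: Sequence[tuple[int | None, int | None]],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Recompute the affine-gap score of an explicit pair list."""
    S = centered_similarity_matrix(a.freq_matrix(), b.freq_matrix())
    score = 0.0
    prev_gap_side = 0  # 0 none, 1 gap-in-b, 2 gap-in-a
    for i, j in pairs:
        if i is not None and j is not None:
            score += S[i, j]
            prev_gap_side = 0
        elif j is None:
            score -= gap_extend + (gap_open if prev_gap_side != 1 else 0.0)
            prev_gap_side = 1
        else:
            score -= gap_extend + (gap_open if prev_gap_side != 2 else 0.0)
            prev_gap_side = 2
    return score


def write_profile_tsv(path: str | Path, profile: FamilyProfile) -> None:
    """Serialize a profile as one TSV row per column, for inspection."""
    with open(path, "w") as fh:
        fh.write("column\tgap_fraction\tn_eff\t" + "\t".join(AMINO_ACIDS) + "\n")
        for k, col in enumerate(profile.columns, start=1):
            freqs = "\t".join(f"{f:.6f}" for f in col.freqs)
            fh.write(f"{k}\t{col.gap_fraction:.4f}\t{col.n_eff:.2f}\t{freqs}\n")
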