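"""Directed design of linker sequences between two protein families.

Two family profiles are aligned column-to-column and merged into a
combined model — a per-position mixture of the two families' residue
preferences.  Designed ("linker") sequences are then emitted by
roulette-wheel sampling: at each emitted position one residue is drawn
with probability equal to its merged frequency.  Placed in a search
database, such sequences act as intermediates between families of the
same fold that have diverged beyond direct detectability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AA_INDEX, AMINO_ACIDS, DataError, FoldMap, SequenceRecord
from .profiles import (
    BACKGROUND,
    FamilyProfile,
    ProfilePairAlignment,
    align_profiles,
    build_profile,
)

GAP_EMIT_THRESHOLD = 0.5  # positions more than half gapped are not emitted
DEFAULT_LINKERS_PER_PAIR = 50
DEFAULT_WEIGHT_A = 0.5


@dataclass(frozen=True)
class CombinedPosition:
    merged_freqs: np.ndarray
    source: tuple[int | None, int | None]
    emit: bool


@dataclass(frozen=True)
class CombinedModel:
    """Position-wise merged residue preferences of two aligned profiles."""

    positions: tuple[CombinedPosition, ...]
    fold_id: str
    parent_families: tuple[str, str]

    @property
    def n_emit(self) -> int:
        return sum(1 for p in self.positions if p.emit)

    def emit_freq_matrix(self) -> np.ndarray:
        """(n_emit, 20) matrix of the sampled positions' distributions."""
        return np.stack([p.merged_freqs for p in self.positions if p.emit])


@dataclass(frozen=True)
class DesignedSequence:
    id: str
    residues: str
    seed: int


def combine_profiles(
    a: FamilyProfile,
    b: FamilyProfile,
    alignment: ProfilePairAlignment,
    weight_a: float = DEFAULT_WEIGHT_A,
    fold_id: str = "",
) -> CombinedModel:
    """Merge two aligned profiles into a :class:`CombinedModel`.

    At a paired position the merged distribution is the ``weight_a``
    mixture of the two column distributions; at a position present in
    only one profile it is that profile's distribution.  A position whose
    combined gap fraction (the absent profile counting as fully gapped)
    exceeds one half is kept in the model but marked ``emit=False``.
    """
    if not 0.0 <= weight_a <= 1.0:
        raise DataError("weight_a must be in [0, 1]")
    used_a = [i for i, _ in alignment.pairs if i is not None]
    used_b = [j for _, j in alignment.pairs if j is not None]
    if used_a != list(range(a.consensus_length)) or used_b != list(
        range(b.consensus_length)
    ):
        raise DataError("alignment does not match the given profiles")

    positions: list[CombinedPosition] = []
    for i, j in alignment.pairs:
        if i is not None and j is not None:
            merged = weight_a * a.columns[i].freqs + (1 - weight_a) * b.columns[j].freqs
            gap = weight_a * a.columns[i].gap_fraction + (1 - weight_a) * b.columns[
                j
            ].gap_fraction
        elif i is not None:
            merged = a.columns[i].freqs.copy()
            gap = weight_a * a.columns[i].gap_fraction + (1 - weight_a) * 1.0
        else:
            merged = b.columns[j].freqs.copy()
            gap = weight_a * 1.0 + (1 - weight_a) * b.columns[j].gap_fraction
        merged = merged / merged.sum()
        positions.append(
            CombinedPosition(
                merged_freqs=merged,
                source=(i, j),
                emit=gap <= GAP_EMIT_THRESHOLD,
            )
        )
    return CombinedModel(
        positions=tuple(positions),
        fold_id=fold_id,
        parent_families=(a.family_id, b.family_id),
    )


def sample_linker(model: CombinedModel, rng_seed: int) -> DesignedSequence:
    """Draw one designed sequence from the model by roulette-wheel sampling.

    The wheel is the inverse CDF over each emitted position's cumulative
    merged frequencies: a single uniform variate per position selects the
    residue whose cumulative interval it falls in.  Deterministic for a
    given seed.
    """
    if model.n_emit == 0:
        raise DataError("combined model has no emittable positions")
    rng = np.random.default_rng(rng_seed)
    residues: list[str] = []
    for pos in model.positions:
        if not pos.emit:
            continue
        wheel = np.cumsum(pos.merged_freqs)
        wheel[-1] = 1.0  # guard against rounding shortfall
        u = rng.random()
        k = int(np.searchsorted(wheel, u, side="right"))
        residues.append(AMINO_ACIDS[min(k, 19)])
    return DesignedSequence(id="", residues="".join(residues), seed=rng_seed)


def score_sequence(model: CombinedModel, residues: str) -> float:
    """Mean per-position log2 probability of a sequence under the model."""
    freqs = model.emit_freq_matrix()
    if len(residues) != freqs.shape[0]:
        raise DataError(
            f"sequence length {len(residues)} != emitted positions {freqs.shape[0]}"
        )
    idx = np.array([AA_INDEX[c] for c in residues])
    p = freqs[np.arange(len(idx)), idx]
    return float(np.mean(np.log2(np.maximum(p, 1e-300))))


def design_linkers(
    fam_a_alignment: list[SequenceRecord],
    fam_b_alignment: list[SequenceRecord],
    fold_id: str,
    n: int,
    seed: int,
    fam_a_id: str = "A",
    fam_b_id: str = "B",
    weight_a: float = DEFAULT_WEIGHT_A,
    pseudocount_weight: float | None = None,
    background: np.ndarray | None = None,
) -> tuple[list[SequenceRecord], FoldMap]:
    """Design ``n`` linker sequences between two family alignments.

    Runs the full pipeline profile -> profile alignment -> combined model
    -> roulette-wheel sampling, with per-sequence seeds ``seed, seed+1,
    ...`` so that generation is reproducible and parallelizable.  Returns
    the designed records (ids ``DS_<fold>_<famA>_<famB>_<serial>``) and
    the fold-map entries declaring their fold and parent families.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    kwargs = {}
    if pseudocount_weight is not None:
        kwargs["pseudocount_weight"] = pseudocount_weight
    if background is not None:
        kwargs["background"] = background
    prof_a = build_profile(fam_a_alignment, family_id=fam_a_id, **kwargs)
    prof_b = build_profile(fam_b_alignment, family_id=fam_b_id, **kwargs)
    pair_alignment = align_profiles(prof_a, prof_b)
    model = combine_profiles(prof_a, prof_b, pair_alignment, weight_a, fold_id)

    records: list[SequenceRecord] = []
    fold_map = FoldMap()
    for serial in range(1, n + 1):
        designed = sample_linker(model, seed + serial - 1)
        seq_id = f"DS_{fold_id}_{fam_a_id}_{fam_b_id}_{serial:04d}"
        records.append(SequenceRecord(id=seq_id, residues=designed.residues))
        fold_map.add(seq_id, f"{fam_a_id}+{fam_b_id}", fold_id)
    return records, fold_map
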