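"""Fold assignment from filtered hit tables.

A query family's hits are reduced to a single structural fold call in
three steps: (1) filter on E-value and query coverage, keeping the best
domain per target sequence; (2) compute the normalized fold frequency
(nff) — for each fold, the fraction of qualifying target sequences
belonging to it; (3) classify the call into one of the confidence
levels:

* ``NO_AMBIGUITY``  — only one fold occurs among the hits;
* ``CONFIDENT_STAR`` — the top-nff fold has a hit covering >= 95% of the query;
* ``CONFIDENT``     — the top-nff fold also provides the best coverage (< 95%);
* ``CONFLICT``      — the top-nff fold does not provide the best coverage.

An assignment is additionally marked high-confidence when the chosen
fold's nff is at least 0.8.  Families left unassigned can inherit the
fold of a clan sibling (clan extension).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .io_formats import DataError, FoldMap, Hit, HitTable

DEFAULT_EVALUE_MAX = 1e-4
DEFAULT_MIN_QUERY_COV = 0.6
DEFAULT_NFF_CONFIDENT = 0.8
CONFIDENT_STAR_COV = 0.95

CONFIDENT_STAR = "CONFIDENT_STAR"
CONFIDENT = "CONFIDENT"
CONFLICT = "CONFLICT"
NO_AMBIGUITY = "NO_AMBIGUITY"
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class FoldAssignment:
    query_family: str
    fold_id: str | None
    nff: float
    best_query_coverage: float
    confidence: str
    n_folds: int
    n_hits_used: int
    high_confidence: bool = False
    inferred_via_clan: bool = False


def filter_hits(
    hits: HitTable,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    min_query_cov: float = DEFAULT_MIN_QUERY_COV,
) -> HitTable:
    """Keep hits with E-value strictly below ``evalue_max`` and query
    coverage strictly above ``min_query_cov``; one best domain per target."""
    kept = [
        h
        for h in hits
        if h.evalue < evalue_max and h.query_coverage > min_query_cov
    ]
    return HitTable(kept).best_domain_per_target()


def normalized_fold_frequency(
    filtered: HitTable, foldmap: FoldMap
) -> dict[str, float]:
    """Per-fold fraction of qualifying target sequences (sums to 1).

    Counts distinct target sequences (the table is already reduced to the
    best domain per target); designed linker targets count toward their
    fold exactly like natural ones.
    """
    unresolved = sorted({h.target_id for h in filtered if h.target_id not in foldmap})
    if unresolved:
        raise DataError(f"target ids not in fold map: {unresolved}")
    counts: dict[str, int] = {}
    for h in filtered:
        fold = foldmap.fold_of(h.target_id)
        counts[fold] = counts.get(fold, 0) + 1
    total = sum(counts.values())
    return {fold: c / total for fold, c in counts.items()}


def classify(
    per_fold_nff: dict[str, float],
    per_fold_best_cov: dict[str, float],
    per_fold_best_evalue: dict[str, float] | None = None,
) -> tuple[str | None, str]:
    """Choose a fold and a confidence label from per-fold statistics.

    nff ties break by higher best coverage, then lower best E-value,
    then lexicographic fold id.  Returns ``(fold, label)``; empty input
    yields ``(None, UNASSIGNED)``.
    """
    if not per_fold_nff:
        return None, UNASSIGNED
    if len(per_fold_nff) == 1:
        (fold,) = per_fold_nff
        return fold, NO_AMBIGUITY
    evalues = per_fold_best_evalue or {}
    top = min(
        sorted(per_fold_nff),
        key=lambda f: (
            -per_fold_nff[f],
            -per_fold_best_cov.get(f, 0.0),
            evalues.get(f, float("inf")),
            f,
        ),
    )
    best_cov_overall = max(per_fold_best_cov.values())
    top_cov = per_fold_best_cov[top]
    if top_cov >= CONFIDENT_STAR_COV:
        return top, CONFIDENT_STAR
    if top_cov >= best_cov_overall:
        return top, CONFIDENT
    return top, CONFLICT


def assign_fold(
    query_family: str,
    hits: HitTable,
    foldmap: FoldMap,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    min_query_cov: float = DEFAULT_MIN_QUERY_COV,
    nff_confident: float = DEFAULT_NFF_CONFIDENT,
) -> FoldAssignment:
    """Full per-family call: filter -> nff -> classify.

    Hits may be pooled over several representative queries of the same
    family; pooling before assignment is equivalent to concatenating the
    tables.  With no qualifying hit the family is UNASSIGNED.
    """
    filtered = filter_hits(hits, evalue_max, min_query_cov)
    if len(filtered) == 0:
        return FoldAssignment(
            query_family=query_family,
            fold_id=None,
            nff=0.0,
            best_query_coverage=0.0,
            confidence=UNASSIGNED,
            n_folds=0,
            n_hits_used=0,
        )
    nff = normalized_fold_frequency(filtered, foldmap)
    best_cov: dict[str, float] = {}
    best_ev: dict[str, float] = {}
    for h in filtered:
        fold = foldmap.fold_of(h.target_id)
        best_cov[fold] = max(best_cov.get(fold, 0.0), h.query_coverage)
        best_ev[fold] = min(best_ev.get(fold, float("inf")), h.evalue)
    fold, label = classify(nff, best_cov, best_ev)
    return FoldAssignment(
        query_family=query_family,
        fold_id=fold,
        nff=nff[fold],
        best_query_coverage=best_cov[fold],
        confidence=label,
        n_folds=len(nff),
        n_hits_used=len(filtered),
        high_confidence=nff[fold] >= nff_confident,
    )


def clan_extension(
    assignments: list[FoldAssignment], clan_map: dict[str, str]
) -> tuple[list[FoldAssignment], set[str]]:
    """Propagate fold calls to unassigned clan members.

    A family with no direct assignment inherits the fold of a clan
    sibling that holds a non-CONFLICT assignment.  Clans whose directly
    assigned members disagree are flagged (returned as the second value)
    and nothing is propagated within them.  Direct assignments are never
    overwritten.
    """
    by_clan: dict[str, list[FoldAssignment]] = {}
    for a in assignments:
        clan = clan_map.get(a.query_family)
        if clan is not None:
            by_clan.setdefault(clan, []).append(a)

    flagged: set[str] = set()
    clan_fold: dict[str, FoldAssignment] = {}
    for clan, members in by_clan.items():
        donors = [
            m
            for m in members
            if m.confidence not in (UNASSIGNED, CONFLICT) and m.fold_id is not None
        ]
        folds = {d.fold_id for d in donors}
        if len(folds) > 1:
            flagged.add(clan)
        elif donors:
            clan_fold[clan] = max(donors, key=lambda d: (d.nff, d.best_query_coverage))

    out: list[FoldAssignment] = []
    for a in assignments:
        clan = clan_map.get(a.query_family)
        if (
            a.confidence == UNASSIGNED
            and clan in clan_fold
            and clan not in flagged
        ):
            donor = clan_fold[clan]
            out.append(
                replace(
                    a,
                    fold_id=donor.fold_id,
                    confidence=donor.confidence,
                    inferred_via_clan=True,
                )
            )
        else:
            out.append(a)
    return out, flagged
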