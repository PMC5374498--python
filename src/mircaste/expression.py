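"""miRNA expression matrices: construction, per-total normalization, and a
replicate-consistency screen for poorly normalizing libraries.

Normalization is read count per total: each library's counts are scaled so
its accepted-read total (post-filter, pre-mapping) equals a fixed
normalization total, by default 4,000,000 — the convention of taking the
median accepted total across libraries rounded up to the nearest million.
Normalized values are kept real-valued; nothing is rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_NORMALIZATION_TOTAL = 4_000_000
DEFAULT_ABUNDANCE_FLOOR = 200.0
DEFAULT_SCORE_THRESHOLD = 0.8


@dataclass
class ExpressionMatrix:
    """miRNA x library count matrix, raw and (optionally) normalized.

    ``raw`` rows are miRNA names, columns library ids.  ``accepted_totals``
    holds each library's accepted-read total, the normalization
    denominator.
    """

    raw: pd.DataFrame
    accepted_totals: pd.Series
    normalized: pd.DataFrame | None = None
    normalization_total: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.raw.columns if c not in self.accepted_totals]
        if missing:
            raise ValueError(f"no accepted totals for libraries: {missing}")
        self.accepted_totals = self.accepted_totals.loc[list(self.raw.columns)]


def build_matrix(
    assignments: Mapping[str, Mapping[str, float]],
    sample_sheet: pd.DataFrame,
    accepted_totals: Mapping[str, int],
) -> ExpressionMatrix:
    """Assemble per-library miRNA count dicts into an ExpressionMatrix.

    ``assignments`` maps library_id -> {miRNA: summed count contribution};
    libraries come from the sample sheet, and absent pairs are 0.
    """
    libs = list(sample_sheet["library_id"])
    if len(set(libs)) != len(libs):
        raise ValueError("duplicate library ids in sample sheet")
    missing = [lib for lib in libs if lib not in assignments]
    if missing:
        raise ValueError(f"no assignment set for libraries: {missing}")
    raw = pd.DataFrame({lib: pd.Series(assignments[lib], dtype=float)
                        for lib in libs}).fillna(0.0)
    raw = raw.sort_index()
    totals = pd.Series({lib: accepted_totals[lib] for lib in libs}, dtype=float)
    return ExpressionMatrix(raw=raw, accepted_totals=totals)


def choose_normalization_total(accepted_totals: Sequence[int]) -> int:
    """Median accepted total across libraries, rounded up to the nearest
    million (an even number of libraries takes the mean of the central two
    before rounding)."""
    totals = list(accepted_totals)
    if not totals:
        raise ValueError("no library totals given")
    med = float(np.median(totals))
    return int(math.ceil(med / 1_000_000)) * 1_000_000


def normalize_per_total(
    matrix: ExpressionMatrix, normalization_total: float = DEFAULT_NORMALIZATION_TOTAL
) -> ExpressionMatrix:
    """Scale each library so its accepted total maps to ``normalization_total``.

    Returns a new ExpressionMatrix with ``normalized`` filled; raw counts
    are untouched.
    """
    zero = [lib for lib, t in matrix.accepted_totals.items() if t <= 0]
    if zero:
        raise ValueError(f"zero accepted-read total for libraries: {zero}")
    factors = normalization_total / matrix.accepted_totals
    normalized = matrix.raw * factors
    return ExpressionMatrix(
        raw=matrix.raw,
        accepted_totals=matrix.accepted_totals,
        normalized=normalized,
        normalization_total=float(normalization_total),
    )


@dataclass
class LibraryQuality:
    """Replicate-similarity score for one library; excluded libraries take
    no part in differential-expression calls."""

    library_id: str
    score: float | None
    excluded: bool
    reason: str = ""


def screen_libraries(
    matrix: ExpressionMatrix,
    sample_sheet: pd.DataFrame,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    abundance_floor: float = DEFAULT_ABUNDANCE_FLOOR,
    offset: float = 20.0,
    exclude: Iterable[str] | None = None,
) -> list[LibraryQuality]:
    """Score each library's consistency with its phenotype's replicates.

    For every miRNA whose normalized count reaches ``abundance_floor`` in
    at least one replicate of the library's phenotype, the library's
    offset fold change against the replicate-median profile is computed;
    the score is the fraction of those miRNAs with |log2 OFC| < 1.
    Libraries scoring below ``score_threshold`` are flagged excluded.  An
    explicit ``exclude`` list overrides the scores entirely.
    """
    if matrix.normalized is None:
        raise ValueError("screen_libraries requires a normalized matrix")
    exclude = set(exclude or ())
    norm = matrix.normalized
    out: list[LibraryQuality] = []
    by_phen = sample_sheet.groupby("phenotype")["library_id"].apply(list)
    lib_phen = dict(zip(sample_sheet["library_id"], sample_sheet["phenotype"]))
    for lib in sample_sheet["library_id"]:
        siblings = sorted(by_phen[lib_phen[lib]])
        if len(siblings) < 2:
            out.append(LibraryQuality(lib, None, lib in exclude,
                                      "single replicate: score undefined"))
            continue
        sub = norm[siblings]
        expressed = sub.max(axis=1) >= abundance_floor
        if not expressed.any():
            score = 1.0
        else:
            median = sub.loc[expressed].median(axis=1)
            vals = norm.loc[expressed.index[expressed], lib]
            ofc = np.log2((vals + offset) / (median + offset))
            score = float((ofc.abs() < 1.0).mean())
        if exclude:
            excluded = lib in exclude
            reason = "config exclusion list" if excluded else ""
        else:
            excluded = score < score_threshold
            reason = f"score {score:.3f} < {score_threshold}" if excluded else ""
        out.append(LibraryQuality(lib, score, excluded, reason))
    return out


def quality_frame(qualities: Iterable[LibraryQuality]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"library_id": q.library_id, "score": q.score,
             "excluded": q.excluded, "reason": q.reason}
            for q in qualities
        ]
    )
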