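"""Differential expression by expression-interval disjointness and the log
offset fold change (OFC).

A miRNA is called differentially expressed between two phenotypes when

* the maximal expression intervals — the [min, max] of normalized counts
  across each phenotype's included replicate libraries — do not overlap
  (strict disjointness),
* |log2 OFC| of the phenotype means is at least the threshold (default 1,
  inclusive), where OFC(a, b) = (a + offset) / (b + offset) with a small
  additive offset (default 20) stabilizing ratios at low counts, and
* the more abundant phenotype mean reaches the abundance floor (default
  200 normalized reads per 4 million).

No p-values and no multiplicity correction: the caller is threshold-based.
The standard 2x2 larval design compares castes within each instar (EW vs
EQ, LW vs LQ) and instars within each caste (EW vs LW, EQ vs LQ).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mircaste.expression import ExpressionMatrix, LibraryQuality

logger = logging.getLogger(__name__)

DEFAULT_OFFSET = 20.0
DEFAULT_OFC_THRESHOLD = 1.0
DEFAULT_ABUNDANCE_FLOOR = 200.0


@dataclass(frozen=True)
class Comparison:
    label: str
    phenotype_a: str
    phenotype_b: str


@dataclass
class ComparisonDesign:
    """The set of pairwise phenotype comparisons to run."""

    comparisons: list[Comparison]

    @classmethod
    def default(cls) -> "ComparisonDesign":
        """Caste within instar, then instar within caste."""
        return cls(
            [
                Comparison("EW_vs_EQ", "EW", "EQ"),
                Comparison("LW_vs_LQ", "LW", "LQ"),
                Comparison("EW_vs_LW", "EW", "LW"),
                Comparison("EQ_vs_LQ", "EQ", "LQ"),
            ]
        )


@dataclass(frozen=True)
class PhenotypeInterval:
    """[min, max] of normalized counts across one phenotype's replicates."""

    mirna: str
    phenotype: str
    lo: float
    hi: float


def expression_interval(values: Sequence[float]) -> tuple[float, float]:
    """(min, max) of the replicate values; a single value gives lo == hi."""
    vals = list(values)
    if not vals:
        raise ValueError("expression_interval needs at least one value")
    return (min(vals), max(vals))


def offset_fold_change(
    mean_a: float, mean_b: float, offset: float = DEFAULT_OFFSET
) -> float:
    """Signed log2 offset fold change, log2((a + offset) / (b + offset)).

    Antisymmetric in its arguments; the offset damps ratios between small
    counts.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("expression means must be nonnegative")
    if offset <= 0:
        raise ValueError("offset must be positive")
    return math.log2((mean_a + offset) / (mean_b + offset))


@dataclass
class DEResult:
    mirna: str
    comparison: str
    mean_a: float
    mean_b: float
    lo_a: float
    hi_a: float
    lo_b: float
    hi_b: float
    ofc: float
    intervals_disjoint: bool
    abundance_pass: bool
    de: bool
    direction: str  # phenotype with the higher mean ('' on exact tie)

    @property
    def fold_change(self) -> float:
        return 2.0 ** abs(self.ofc)


def _edge_ofc(
    lo_a: float, hi_a: float, lo_b: float, hi_b: float, offset: float
) -> float:
    """Conservative OFC variant: ratio of the nearest interval edges.

    Zero when the intervals overlap (the nearest edges cross).
    """
    if lo_a > hi_b:
        return math.log2((lo_a + offset) / (hi_b + offset))
    if lo_b > hi_a:
        return -math.log2((lo_b + offset) / (hi_a + offset))
    return 0.0


def call_de(
    matrix: ExpressionMatrix,
    sample_sheet: pd.DataFrame,
    design: ComparisonDesign,
    qualities: Iterable[LibraryQuality] = (),
    ofc_threshold: float = DEFAULT_OFC_THRESHOLD,
    abundance_floor: float = DEFAULT_ABUNDANCE_FLOOR,
    offset: float = DEFAULT_OFFSET,
    ofc_variant: str = "mean",
) -> list[DEResult]:
    """Emit a DEResult for every miRNA x comparison over included libraries.

    ``ofc_variant`` selects the statistic used for the threshold test:
    ``"mean"`` (OFC of phenotype means, the default) or ``"edge"`` (OFC of
    the nearest interval edges, more conservative).  Comparisons where a
    phenotype retains fewer than two included libraries are skipped with a
    warning.
    """
    if matrix.normalized is None:
        raise ValueError("call_de requires a normalized matrix")
    if ofc_variant not in ("mean", "edge"):
        raise ValueError(f"unknown ofc_variant {ofc_variant!r}")
    excluded = {q.library_id for q in qualities if q.excluded}
    norm = matrix.normalized
    by_phen = {
        phen: [l for l in libs if l not in excluded and l in norm.columns]
        for phen, libs in sample_sheet.groupby("phenotype")["library_id"]
        .apply(list)
        .items()
    }
    results: list[DEResult] = []
    for comp in design.comparisons:
        libs_a = by_phen.get(comp.phenotype_a, [])
        libs_b = by_phen.get(comp.phenotype_b, [])
        if len(libs_a) < 2 or len(libs_b) < 2:
            logger.warning(
                "skipping %s: fewer than 2 included libraries in a phenotype",
                comp.label,
            )
            continue
        sub_a = norm[libs_a]
        sub_b = norm[libs_b]
        for mirna in norm.index:
            va = sub_a.loc[mirna]
            vb = sub_b.loc[mirna]
            lo_a, hi_a = float(va.min()), float(va.max())
            lo_b, hi_b = float(vb.min()), float(vb.max())
            mean_a, mean_b = float(va.mean()), float(vb.mean())
            disjoint = hi_a < lo_b or hi_b < lo_a
            ofc = offset_fold_change(mean_a, mean_b, offset)
            stat = (
                ofc
                if ofc_variant == "mean"
                else _edge_ofc(lo_a, hi_a, lo_b, hi_b, offset)
            )
            abundance_pass = max(mean_a, mean_b) >= abundance_floor
            de = disjoint and abundance_pass and abs(stat) >= ofc_threshold
            if mean_a > mean_b:
                direction = comp.phenotype_a
            elif mean_b > mean_a:
                direction = comp.phenotype_b
            else:
                direction = ""
            results.append(
                DEResult(
                    mirna=str(mirna), comparison=comp.label,
                    mean_a=mean_a, mean_b=mean_b,
                    lo_a=lo_a, hi_a=hi_a, lo_b=lo_b, hi_b=hi_b,
                    ofc=stat, intervals_disjoint=disjoint,
                    abundance_pass=abundance_pass, de=de, direction=direction,
                )
            )
    return results


def results_frame(results: Iterable[DEResult]) -> pd.DataFrame:
    rows = [
        {
            "miRNA": r.mirna, "comparison": r.comparison,
            "mean_a": r.mean_a, "mean_b": r.mean_b,
            "lo_a": r.lo_a, "hi_a": r.hi_a, "lo_b": r.lo_b, "hi_b": r.hi_b,
            "ofc": r.ofc, "fold_change": r.fold_change,
            "intervals_disjoint": r.intervals_disjoint,
            "abundance_pass": r.abundance_pass,
            "de": r.de, "direction": r.direction,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["miRNA", "comparison", "mean_a", "mean_b", "lo_a", "hi_a",
                 "lo_b", "hi_b", "ofc", "fold_change", "intervals_disjoint",
                 "abundance_pass", "de", "direction"],
    )


def run_comparisons(
    matrix: ExpressionMatrix,
    sample_sheet: pd.DataFrame,
    design: ComparisonDesign,
    qualities: Iterable[LibraryQuality] = (),
    **kwargs,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """One ranked DE table per comparison plus a cross-comparison summary.

    Tables are sorted by |OFC| descending, ties broken by miRNA name; the
    summary lists the DE calls of all comparisons together.
    """
    results = call_de(matrix, sample_sheet, design, qualities, **kwargs)
    frame = results_frame(results)
    tables: dict[str, pd.DataFrame] = {}
    for comp in design.comparisons:
        sub = frame[frame["comparison"] == comp.label].copy()
        if sub.empty and comp.label not in set(frame["comparison"]):
            continue  # comparison was skipped
        sub["abs_ofc"] = sub["ofc"].abs()
        sub = (
            sub.sort_values(["abs_ofc", "miRNA"], ascending=[False, True])
            .drop(columns="abs_ofc")
            .reset_index(drop=True)
        )
        tables[comp.label] = sub
    summary = (
        frame[frame["de"].astype(bool)]
        .sort_values(["comparison", "miRNA"])
        .reset_index(drop=True)
    )
    return tables, summary
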