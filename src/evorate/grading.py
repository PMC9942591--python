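"""Conservation grades.

Posterior rates over the query's positions are standardized to z-scores
(positive = rapidly evolving) and binned into nine grades: 1 = most
variable, 5 = average, 9 = most conserved. Each side of zero is first
scaled by its own extreme (so the most conserved site sits at -1 and the
most variable at +1), then nine equal-width bins are laid over [-1, +1].
This pins all four anchor semantics: fastest -> 1, average -> 5,
slowest -> 9, and both extreme sites always occupy the extreme bins,
regardless of how skewed the score distribution is.

Each site's credible interval is pushed through the same standardization
and binning; a site is flagged unreliable when the interval spans more than
3 grades or fewer than 6 sequences carry information at the site.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import InvalidGradeError
from .rates import SiteRateResult
from .seq_io import Alignment, QueryPositionMap

N_GRADES = 9
MAX_RELIABLE_SPAN = 3
MIN_INFORMATIVE = 6

# 9-entry RGB tables, index = grade - 1 (grade 1 first).
# standard scale: teal/cyan (variable) through white to maroon (conserved)
COLORS_STANDARD: tuple[tuple[int, int, int], ...] = (
    (16, 200, 209),    # 1 most variable
    (140, 255, 255),
    (215, 255, 255),
    (234, 255, 255),
    (255, 255, 255),   # 5 average
    (252, 237, 244),
    (250, 201, 222),
    (240, 125, 171),
    (160, 37, 96),     # 9 most conserved
)
# color-blind-safe scale: green (variable) through white to purple (conserved)
COLORS_COLOR_BLIND: tuple[tuple[int, int, int], ...] = (
    (36, 131, 71),     # 1 most variable
    (121, 183, 133),
    (183, 219, 190),
    (224, 240, 227),
    (255, 255, 255),   # 5 average
    (233, 222, 240),
    (200, 173, 220),
    (153, 112, 183),
    (94, 48, 134),     # 9 most conserved
)

ColorScale = Literal["standard", "color_blind"]


@dataclass(frozen=True)
class GradeResult:
    """Grade and reliability for one ungapped query position."""

    query_position: int
    query_residue: str
    score: float
    grade: int
    ci_grade_low: int
    ci_grade_high: int
    reliable: bool
    n_informative: int
    color_standard: tuple[int, int, int]
    color_blind: tuple[int, int, int]


def standardize(rates: Sequence[float]) -> np.ndarray:
    """z-scores of the per-position rates (population sd); all zero if the
    rates are constant."""
    r = np.asarray(rates, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 positions to standardize")
    sd = float(r.std())
    if sd == 0.0:
        return np.zeros_like(r)
    return (r - r.mean()) / sd


def _side_scales(scores: np.ndarray) -> tuple[float, float]:
    """Per-sign scale factors (|most negative|, most positive); a side with
    no scores (or only zeros) falls back to 1 so zeros stay at zero."""
    neg = -float(scores.min()) if scores.size and scores.min() < 0 else 1.0
    pos = float(scores.max()) if scores.size and scores.max() > 0 else 1.0
    return neg, pos


def _normalize_side(score: float, neg: float, pos: float) -> float:
    return score / neg if score < 0 else score / pos


def bin_score(score: float, h: float) -> int:
    """Grade of one score given the half-range h: nine equal bins on
    [-h, +h], grade 9 at -h (conserved), 5 at 0, 1 at +h (variable)."""
    w = 2.0 * h / N_GRADES
    q = (score + h) / w
    # snap to bin edges so round-off cannot flip a boundary score's grade
    if abs(q - round(q)) < 1e-9:
        q = round(q)
    g = N_GRADES - math.floor(q)
    return max(1, min(N_GRADES, g))


def bin_grades(scores: Sequence[float]) -> list[int]:
    """Nine-grade binning of a score vector: each sign is scaled by its own
    extreme, then :func:`bin_score` is applied on [-1, +1]. The minimum-score
    site therefore always receives grade 9 and the maximum-score site grade 1
    (for non-degenerate inputs spanning both signs)."""
    s = np.asarray(scores, dtype=float)
    neg, pos = _side_scales(s)
    return [bin_score(_normalize_side(float(x), neg, pos), 1.0) for x in s]


def flag_reliability(ci_grade_low: int, ci_grade_high: int, n_informative: int) -> bool:
    """Reliable iff the credible interval spans <= 3 grades and at least
    6 sequences are informative at the site."""
    return (ci_grade_high - ci_grade_low) <= MAX_RELIABLE_SPAN and (
        n_informative >= MIN_INFORMATIVE
    )


def colorize(grade: int, scale: ColorScale = "standard") -> tuple[int, int, int]:
    if not (1 <= int(grade) <= N_GRADES) or int(grade) != grade:
        raise InvalidGradeError(f"grade must be an integer in 1..{N_GRADES}, got {grade!r}")
    table = COLORS_STANDARD if scale == "standard" else COLORS_COLOR_BLIND
    return table[int(grade) - 1]


def grade_query_positions(
    site_results: Sequence[SiteRateResult],
    alignment: Alignment,
    query_map: QueryPositionMap,
) -> list[GradeResult]:
    """Standardize and bin rates over the query's ungapped positions.

    The CI bounds are standardized with the same mean/sd and binned with the
    same half-range, so the interval maps to a contiguous grade range; note
    a low rate bound maps to a high grade.
    """
    by_site = {r.site: r for r in site_results}
    cols = query_map.msa_col_for_query_pos
    picked = [by_site[c] for c in cols]
    rates = np.array([r.rate_hat for r in picked])
    scores = standardize(rates)
    mean, sd = float(rates.mean()), float(rates.std())
    neg, pos_scale = _side_scales(scores)

    def to_grade(rate: float) -> int:
        z = 0.0 if sd == 0.0 else (rate - mean) / sd
        return bin_score(_normalize_side(z, neg, pos_scale), 1.0)

    query_res = alignment.query.residues
    out = []
    for pos, (col, site, score) in enumerate(zip(cols, picked, scores), start=1):
        g = bin_score(_normalize_side(float(score), neg, pos_scale), 1.0)
        g_from_hi_rate = to_grade(site.ci_high)  # variable end
        g_from_lo_rate = to_grade(site.ci_low)   # conserved end
        ci_lo, ci_hi = min(g_from_hi_rate, g_from_lo_rate), max(
            g_from_hi_rate, g_from_lo_rate
        )
        ci_lo, ci_hi = min(ci_lo, g), max(ci_hi, g)
        reliable = flag_reliability(ci_lo, ci_hi, site.n_informative)
        out.append(
            GradeResult(
                query_position=pos,
                query_residue=query_res[col],
                score=float(score),
                grade=g,
                ci_grade_low=ci_lo,
                ci_grade_high=ci_hi,
                reliable=reliable,
                n_informative=site.n_informative,
                color_standard=colorize(g, "standard"),
                color_blind=colorize(g, "color_blind"),
            )
        )
    return out


def write_grades_tsv(results: Sequence[GradeResult], path: str | Path) -> None:
    """Human-readable grades table; '*' marks unreliable grades."""
    with open(path, "w") as fh:
        fh.write("POS\tSEQ\tSCORE\tGRADE\tCI_GRADES\tN_INFORMATIVE\tCOLOR\n")
        for r in results:
            mark = "" if r.reliable else "*"
            rgb = ",".join(str(c) for c in r.color_standard)
            fh.write(
                f"{r.query_position}\t{r.query_residue}\t{r.score:.4f}\t"
                f"{r.grade}{mark}\t{r.ci_grade_low},{r.ci_grade_high}\t"
                f"{r.n_informative}\t{rgb}\n"
            )


def write_grades_json(results: Sequence[GradeResult], path: str | Path) -> None:
    payload = [
        {
            "query_position": r.query_position,
            "query_residue": r.query_residue,
            "score": round(r.score, 6),
            "grade": r.grade,
            "ci_grade_low": r.ci_grade_low,
            "ci_grade_high": r.ci_grade_high,
            "reliable": r.reliable,
            "n_informative": r.n_informative,
            "color_standard": list(r.color_standard),
            "color_blind": list(r.color_blind),
        }
        for r in results
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
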