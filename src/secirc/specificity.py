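"""Tissue- and stage-specificity scoring and SE/circRNA association tests.

The tissue-specificity index of an expression profile is the
Jensen-Shannon specificity used for lincRNA catalogs: normalize the RPM
profile to a distribution p, take the one-hot distribution e at the
profile's argmax tissue, and score

    JS_spec(p) = 1 - sqrt(JSD2(p, e))

where JSD2 is the Jensen-Shannon divergence with log base 2 (bounded in
[0, 1]). A perfectly tissue-restricted profile scores 1; broader profiles
score lower (a uniform profile over k tissues scores 1 - sqrt(1 - (1/2)
log2 of the (k -> mixture) term), about 0.54 at k=2 and falling with k).

Stage-specific super-enhancers are defined by reciprocal base coverage:
an SE is specific to its stage iff the fraction of its bases covered by the
union of the other stage's SEs is below a threshold (default 0.5).

Association between binary labels (tissue-specific SE x tissue-specific
circRNA; SE-circRNA x differential expression) uses Fisher's exact test,
and SE- vs TE-circRNA expression levels are compared with a two-sided
Mann-Whitney U test (exact null at small n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .circ_association import CircClass, SE_LABEL, TE_LABEL
from .io_formats import ExpressionMatrix, Interval

DEFAULT_TAU = 0.8
DEFAULT_MAX_OTHER_COVER = 0.5


@dataclass(frozen=True)
class SpecificityScore:
    entity_id: str
    score: float
    argmax_tissue: str


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def specificity_index(
    profile: np.ndarray | list[float],
    tissues: list[str] | None = None,
    entity_id: str = "",
) -> SpecificityScore:
    """Jensen-Shannon specificity of a non-negative expression profile.

    Ties at the argmax resolve to the first tissue in input order. An
    all-zero profile has no defined specificity and raises ``ValueError``.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("profile must be a non-empty 1-D array")
    if np.any(p < 0):
        raise ValueError("profile values must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero profile has no specificity")
    p = p / total
    k = int(np.argmax(p))  # first maximum
    e = np.zeros_like(p)
    e[k] = 1.0
    # scipy's jensenshannon returns the JS *distance* = sqrt(JSD)
    score = 1.0 - float(jensenshannon(p, e, base=2))
    score = min(max(score, 0.0), 1.0)
    tissue = tissues[k] if tissues is not None else str(k)
    return SpecificityScore(entity_id, score, tissue)


def is_specific(score: float | SpecificityScore, tau: float = DEFAULT_TAU) -> bool:
    """Closed-threshold binary call: specific iff score >= tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    value = score.score if isinstance(score, SpecificityScore) else score
    return value >= tau


def tissue_specificity_scores(matrix: ExpressionMatrix) -> dict[str, SpecificityScore]:
    """Per-circRNA JS specificity over tissue-mean RPM profiles.

    All-zero circRNAs are skipped (no profile to score).
    """
    by_tissue = matrix.mean_by_tissue()
    tissues = list(by_tissue.columns)
    out: dict[str, SpecificityScore] = {}
    for circ_id, row in by_tissue.iterrows():
        vals = row.to_numpy()
        if vals.sum() == 0:
            continue
        out[circ_id] = specificity_index(vals, tissues, circ_id)
    return out


# ---------------------------------------------------------------------------
# stage-specific super-enhancers
# ---------------------------------------------------------------------------

def _covered_fraction(region: Interval, others: list[Interval]) -> float:
    """Fraction of region bases covered by the union of `others`."""
    spans = sorted(
        (max(o.start, region.start), min(o.end, region.end))
        for o in others
        if o.chrom == region.chrom and o.start < region.end and region.start < o.end
    )
    covered = 0
    cursor = region.start
    for s, e in spans:
        s = max(s, cursor)
        if e > s:
            covered += e - s
            cursor = e
    return covered / region.length


def stage_specific_ses(
    se_sets: dict[str, list[Interval]],
    max_other_cover: float = DEFAULT_MAX_OTHER_COVER,
) -> dict[str, dict[str, list[Interval]]]:
    """Split each stage's SEs into stage-specific vs shared.

    An SE is specific to its stage iff the fraction of its bases covered by
    the union of all other stages' SEs is < ``max_other_cover``.
    Returns ``{stage: {"specific": [...], "shared": [...]}}``.
    """
    if not 0.0 <= max_other_cover <= 1.0:
        raise ValueError("max_other_cover must be in [0, 1]")
    out: dict[str, dict[str, list[Interval]]] = {}
    for stage, regions in se_sets.items():
        others = [iv for other, ivs in se_sets.items() if other != stage for iv in ivs]
        specific, shared = [], []
        for region in regions:
            (specific if _covered_fraction(region, others) < max_other_cover else shared).append(region)
        out[stage] = {"specific": specific, "shared": shared}
    return out


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def fisher_association(table: ContingencyTable2x2) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, two-sided p). The odds ratio is the sample ratio
    ad/bc: +inf when bc = 0 with ad > 0, NaN when both products are 0.
    The p-value sums, over the hypergeometric null with fixed margins, all
    tables at most as probable as the observed one.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("nan") if ad == 0 else float("inf")
    else:
        odds = ad / bc
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def mann_whitney(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    exact_max_n: int = 10,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact null when both n <= ``exact_max_n``
    and there are no cross-group ties, normal approximation with continuity
    correction otherwise. Returns (U of the first sample, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(set(x) & set(y)) > 0 or len(set(x)) < len(x) or len(set(y)) < len(y)
    method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ClassExpressionSummary:
    median_rpm: dict[str, float]  # label -> median of per-circ mean RPM
    n_by_class: dict[str, int]
    u_statistic: float | None
    p_value: float | None  # SE-circRNA vs TE-circRNA


def class_expression_summary(
    matrix: ExpressionMatrix, classes: list[CircClass]
) -> ClassExpressionSummary:
    """Median expression per circRNA class plus an SE-vs-TE rank-sum test.

    Expression per circRNA is its mean RPM across all samples. The test is
    skipped (with a warning) when either the SE or TE class is empty.
    """
    label_by_circ = {c.circ_id: c.label for c in classes}
    mean_rpm = matrix.values.mean(axis=1)
    groups: dict[str, list[float]] = {}
    for circ_id, value in mean_rpm.items():
        label = label_by_circ.get(circ_id)
        if label is not None:
            groups.setdefault(label, []).append(float(value))
    medians = {lab: float(np.median(v)) for lab, v in groups.items()}
    counts = {lab: len(v) for lab, v in groups.items()}
    se, te = groups.get(SE_LABEL, []), groups.get(TE_LABEL, [])
    if not se or not te:
        warnings.warn("SE or TE class empty; rank-sum test skipped", stacklevel=2)
        return ClassExpressionSummary(medians, counts, None, None)
    u, p = mann_whitney(se, te)
    return ClassExpressionSummary(medians, counts, u, p)


def specificity_report(
    matrix: ExpressionMatrix,
    classes: list[CircClass],
    tau: float = DEFAULT_TAU,
) -> dict:
    """JSON-ready specificity summary: per-class mean JS specificity, the
    tissue-specific call fraction per class, the SE x specific Fisher test,
    and the SE-vs-TE expression comparison."""
    scores = tissue_specificity_scores(matrix)
    label_by_circ = {c.circ_id: c.label for c in classes}
    per_class: dict[str, list[float]] = {}
    for circ_id, sc in scores.items():
        label = label_by_circ.get(circ_id)
        if label is not None:
            per_class.setdefault(label, []).append(sc.score)
    is_se = {cid: label_by_circ.get(cid) == SE_LABEL for cid in scores}
    spec = {cid: is_specific(sc.score, tau) for cid, sc in scores.items()}
    a = sum(1 for cid in scores if is_se[cid] and spec[cid])
    b = sum(1 for cid in scores if is_se[cid] and not spec[cid])
    c = sum(1 for cid in scores if not is_se[cid] and spec[cid])
    d = sum(1 for cid in scores if not is_se[cid] and not spec[cid])
    odds, p = fisher_association(ContingencyTable2x2(a, b, c, d))
    expr = class_expression_summary(matrix, classes)
    return {
        "tau": tau,
        "n_scored": len(scores),
        "mean_specificity_by_class": {k: float(np.mean(v)) for k, v in per_class.items()},
        "fraction_specific_by_class": {
            k: float(np.mean([s >= tau for s in v])) for k, v in per_class.items()
        },
        "fisher_se_by_specific": {
            "table": [a, b, c, d],
            "odds_ratio": None if np.isnan(odds) else odds,
            "p_two_sided": p,
        },
        "median_rpm_by_class": expr.median_rpm,
        "se_vs_te_rank_sum": {"U": expr.u_statistic, "p_two_sided": expr.p_value},
        "scores": {cid: sc.score for cid, sc in sorted(scores.items())},
    }
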