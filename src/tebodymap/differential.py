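"""Differential TE subfamily calling.

A subfamily is differentially expressed (DETE) between two sample groups
when a two-sample t-test on log2(RPKM + 1) gives a Bonferroni-corrected
p <= alpha AND the fold change of raw group means is >= 2 (overexpressed)
or <= 0.5 (underexpressed). Fold changes use a +1 pseudocount,
(mean_A + 1) / (mean_B + 1), so they are finite for silent features and
consistent with the +1 of the log transform.

Derived callers:

* organ-enriched: called over versus *every* other organ at a stage
  (strict intersection of the pairwise calls);
* development-dependent: any non-none call among the stage pairs of an organ;
* sex-dependent: male vs female within each dual-sex (organ, stage) group;
* temporal pattern: per organ, the three adjacent-stage transitions
  (6v2, 21v6, 104v21; older stage as numerator) each labelled
  U (over) / D (under) / M (otherwise), giving one of 27 strings.
"""

from __future__ import annotations

import logging
from itertools import combinations
import numpy as np
import pandas as pd
from scipy import stats

from .design import Group
from .expression import ExpressionMatrix, group_columns

logger = logging.getLogger(__name__)

FC_OVER = 2.0
FC_UNDER = 0.5
ALPHA = 0.05
CALLS = ("over", "under", "none")


def _resolve_columns(matrix: ExpressionMatrix, group) -> list[str]:
    if isinstance(group, Group):
        cols = group_columns(matrix.design, group)
    else:
        cols = list(group)
    if len(cols) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    return cols


def _ttest(la: np.ndarray, lb: np.ndarray, flavor: str) -> np.ndarray:
    """Vectorized two-sample t-test p-values over feature rows.

    Degenerate rows (zero variance in both groups): p = 1 when the means are
    equal, p = 0 otherwise.
    """
    na, nb = la.shape[1], lb.shape[1]
    ma, mb = la.mean(axis=1), lb.mean(axis=1)
    va, vb = la.var(axis=1, ddof=1), lb.var(axis=1, ddof=1)
    if flavor == "student":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1 / na + 1 / nb)
        df = np.full(la.shape[0], na + nb - 2, dtype=float)
    elif flavor == "welch":
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        raise ValueError(f"unknown t-test flavor {flavor!r}")
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = 0.0
    return p


def dete_test(
    matrix: ExpressionMatrix,
    group_a,
    group_b,
    m_tests: int | None = None,
    fc_threshold: float = FC_OVER,
    alpha: float = ALPHA,
    flavor: str = "student",
    comparison: str | None = None,
) -> pd.DataFrame:
    """Call DETEs for group A vs group B (A as fold-change numerator).

    ``group_a``/``group_b`` are Group objects or explicit sample-id lists.
    ``m_tests`` is the Bonferroni family size, defaulting to the number of
    features tested. Returns a DataFrame with columns feature, comparison,
    fold_change, p_raw, p_bonferroni, call.
    """
    cols_a = _resolve_columns(matrix, group_a)
    cols_b = _resolve_columns(matrix, group_b)
    if m_tests is None:
        m_tests = len(matrix.features)
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    raw_a = matrix.rpkm[cols_a].values
    raw_b = matrix.rpkm[cols_b].values
    fc = (raw_a.mean(axis=1) + 1.0) / (raw_b.mean(axis=1) + 1.0)
    p_raw = _ttest(np.log2(raw_a + 1.0), np.log2(raw_b + 1.0), flavor)
    p_bonf = np.minimum(1.0, p_raw * m_tests)
    call = np.full(len(fc), "none", dtype=object)
    sig = p_bonf <= alpha
    call[sig & (fc >= fc_threshold)] = "over"
    call[sig & (fc <= 1.0 / fc_threshold)] = "under"
    if comparison is None:
        la = group_a.label if isinstance(group_a, Group) else "A"
        lb = group_b.label if isinstance(group_b, Group) else "B"
        comparison = f"{la}_vs_{lb}"
    return pd.DataFrame(
        {
            "feature": matrix.features,
            "comparison": comparison,
            "fold_change": fc,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "call": call,
        }
    )


def organ_enriched(
    matrix: ExpressionMatrix,
    stage: int,
    m_tests: int | None = None,
    fc_threshold: float = FC_OVER,
    alpha: float = ALPHA,
) -> dict[str, set[str]]:
    """Organ-enriched subfamilies per organ at one developmental stage.

    A subfamily is enriched in organ O when it is called over in O versus
    every other organ of the design. Sexes are pooled within (organ, stage),
    matching how organ contrasts are presented per stage without a sex split.
    """
    design = matrix.design
    if len(design.organs) < 2:
        raise ValueError("need >= 2 organs for enrichment")

    def cols(organ: str) -> list[str]:
        return group_columns(design, Group(organ, stage))

    enriched: dict[str, set[str]] = {}
    for organ in design.organs:
        called: set[str] | None = None
        for other in design.organs:
            if other == organ:
                continue
            res = dete_test(
                matrix, cols(organ), cols(other), m_tests, fc_threshold, alpha,
                comparison=f"{organ}_vs_{other}_{stage}w",
            )
            over = set(res.loc[res["call"] == "over", "feature"])
            called = over if called is None else called & over
            if not called:
                break
        enriched[organ] = called or set()
    return enriched


def development_dependent(
    matrix: ExpressionMatrix,
    organ: str,
    m_tests: int | None = None,
    fc_threshold: float = FC_OVER,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """DETE results over all stage pairs within one organ (sexes pooled).

    The older stage is the fold-change numerator. The organ's
    development-dependent set is the union of features with a non-none call
    in any pair (see :func:`development_dependent_set`).
    """
    design = matrix.design
    stages = design.stages
    if len(stages) < 2:
        raise ValueError("need >= 2 stages")
    frames = []
    for young, old in combinations(stages, 2):
        res = dete_test(
            matrix,
            group_columns(design, Group(organ, old)),
            group_columns(design, Group(organ, young)),
            m_tests,
            fc_threshold,
            alpha,
            comparison=f"{organ}_{old}w_vs_{young}w",
        )
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def development_dependent_set(results: pd.DataFrame) -> set[str]:
    return set(results.loc[results["call"] != "none", "feature"])


def sex_dependent(
    matrix: ExpressionMatrix,
    m_tests: int | None = None,
    fc_threshold: float = FC_OVER,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Male-vs-female DETEs per dual-sex (organ, stage) group.

    Single-sex organs are skipped with a log notice. Male is the fold-change
    numerator. Output carries organ and stage columns next to the DETE
    columns.
    """
    design = matrix.design
    frames = []
    for organ in design.organs:
        if len(design.sexes_for(organ)) < 2:
            logger.info("organ %s is single-sex; no sex comparison emitted", organ)
            continue
        for stage in design.stages:
            res = dete_test(
                matrix,
                group_columns(design, Group(organ, stage, "male")),
                group_columns(design, Group(organ, stage, "female")),
                m_tests,
                fc_threshold,
                alpha,
                comparison=f"{organ}_{stage}w_male_vs_female",
            )
            res.insert(1, "organ", organ)
            res.insert(2, "stage", stage)
            frames.append(res)
    return pd.concat(frames, ignore_index=True)


def temporal_pattern(
    matrix: ExpressionMatrix,
    organ: str,
    m_tests: int | None = None,
    fc_threshold: float = FC_OVER,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Classify each subfamily's trajectory in one organ into a 3-letter pattern.

    Each adjacent-stage transition (older stage as numerator) is called
    U when over, D when under, M otherwise; the pattern string reads
    chronologically (6v2 first, 104v21 last). With 4 stages the label space
    is {U, M, D}^3 = 27 patterns.
    """
    design = matrix.design
    if len(design.stages) < 2:
        raise ValueError("need all stages for pattern classification")
    steps = []
    for older, younger in design.stage_transitions():
        res = dete_test(
            matrix,
            group_columns(design, Group(organ, older)),
            group_columns(design, Group(organ, younger)),
            m_tests,
            fc_threshold,
            alpha,
            comparison=f"{organ}_{older}w_vs_{younger}w",
        )
        step = res.set_index("feature")["call"].map({"over": "U", "under": "D", "none": "M"})
        steps.append(step)
    pattern = steps[0].str.cat(steps[1:])
    out = pd.DataFrame({"organ": organ, "subfamily": pattern.index, "pattern": pattern.values})
    for i, step in enumerate(steps, start=1):
        out[f"step{i}"] = step.values
    return out


def pattern_counts(patterns: pd.DataFrame) -> pd.Series:
    """Frequency of each observed pattern label."""
    return patterns["pattern"].value_counts()
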