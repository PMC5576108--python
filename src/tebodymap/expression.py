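"""Expression normalization, the expressed/not-expressed rule and the
expression-class taxonomy.

A feature (TE subfamily, TE instance or gene) is *expressed* in a group when
its mean raw RPKM over the group's replicates is >= 1; the threshold applies
before the log2(RPKM + 1) transform used for all downstream statistics.
Subfamilies are then classified by which of the (organ, stage, sex) groups
they are expressed in: in all groups (common), none (zero), exactly one
(group_specific), only groups of a single organ (organ_specific), or
anything else (other).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .design import Group, SampleDesign, enumerate_groups, enumerate_samples

logger = logging.getLogger(__name__)

EXPRESSED_RPKM = 1.0
CLASS_LABELS = ("common", "zero", "organ_specific", "group_specific", "other")


@dataclass
class ExpressionMatrix:
    """features x samples RPKM matrix aligned to a SampleDesign.

    ``rpkm`` is a DataFrame with feature ids as index and sample ids as
    columns; the log view is log2(RPKM + 1).
    """

    rpkm: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if (self.rpkm.values < 0).any():
            raise ValueError("RPKM values must be non-negative")
        if self.rpkm.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        expected = [s.sample_id for s in enumerate_samples(self.design)]
        if set(self.rpkm.columns) != set(expected):
            missing = set(expected) - set(self.rpkm.columns)
            extra = set(self.rpkm.columns) - set(expected)
            raise ValueError(
                f"sample ids do not match the design (missing={sorted(missing)[:5]}, "
                f"extra={sorted(extra)[:5]})"
            )
        # canonical design order
        self.rpkm = self.rpkm[expected]

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.rpkm + 1.0)

    @property
    def features(self) -> pd.Index:
        return self.rpkm.index


def group_columns(design: SampleDesign, group: Group) -> list[str]:
    return [
        s.sample_id
        for s in enumerate_samples(design)
        if s.organ == group.organ
        and (group.stage is None or s.stage == group.stage)
        and (group.sex is None or s.sex == group.sex)
    ]


def group_mean_rpkm(
    matrix: ExpressionMatrix, groups: list[Group] | None = None
) -> pd.DataFrame:
    """Arithmetic mean of raw RPKM per group (features x groups).

    Means are taken on the raw scale, not on logs, because the expressed
    threshold applies to raw RPKM.
    """
    if groups is None:
        groups = enumerate_groups(matrix.design, "organ_stage_sex")
    out = {}
    for g in groups:
        cols = group_columns(matrix.design, g)
        if not cols:
            raise ValueError(f"group {g.label} has no member samples")
        out[g.label] = matrix.rpkm[cols].mean(axis=1)
    return pd.DataFrame(out)


@dataclass
class ExpressionClassification:
    labels: pd.Series  # feature -> class label
    expressed_groups: dict[str, list[Group]]  # feature -> expressed group list

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(CLASS_LABELS, fill_value=0)

    def frame(self) -> pd.DataFrame:
        rows = []
        for feat, label in self.labels.items():
            groups = self.expressed_groups[feat]
            rows.append(
                {
                    "subfamily": feat,
                    "label": label,
                    "n_expressed_groups": len(groups),
                    "organs": ",".join(sorted({g.organ for g in groups})),
                }
            )
        return pd.DataFrame(rows)


def classify_expression(
    matrix: ExpressionMatrix, threshold: float = EXPRESSED_RPKM
) -> ExpressionClassification:
    """Classify every feature by its expressed-group set over the per-sex cells."""
    groups = enumerate_groups(matrix.design, "organ_stage_sex")
    means = group_mean_rpkm(matrix, groups)
    expressed = means >= threshold
    n_groups = len(groups)
    labels = {}
    expressed_in: dict[str, list[Group]] = {}
    for feat in matrix.features:
        mask = expressed.loc[feat].values
        sel = [g for g, m in zip(groups, mask) if m]
        expressed_in[feat] = sel
        n = len(sel)
        if n == n_groups:
            labels[feat] = "common"
        elif n == 0:
            labels[feat] = "zero"
        elif n == 1:
            labels[feat] = "group_specific"
        elif len({g.organ for g in sel}) == 1:
            labels[feat] = "organ_specific"
        else:
            labels[feat] = "other"
    return ExpressionClassification(
        pd.Series(labels, name="label").reindex(matrix.features), expressed_in
    )


def replicate_reproducibility(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise replicate Pearson correlations per (organ, stage, sex) group.

    For each group, computes the C(n_replicates, 2) pairwise PCCs between
    replicate columns on the log2(RPKM + 1) view across all features, and a
    per-group mean and standard error. Replicates with zero variance across
    features yield undefined PCCs; those pairs are excluded and logged.

    Returns one row per group with columns organ, stage, sex, n_pairs,
    pcc_values (list), pcc_mean, pcc_se.
    """
    log = matrix.log2
    rows = []
    for g in enumerate_groups(matrix.design, "organ_stage_sex"):
        cols = group_columns(matrix.design, g)
        vals = []
        for a, b in combinations(cols, 2):
            x, y = log[a].values, log[b].values
            if x.std() == 0 or y.std() == 0:
                logger.warning("zero-variance replicate in group %s; pair (%s, %s) excluded",
                               g.label, a, b)
                continue
            vals.append(float(np.corrcoef(x, y)[0, 1]))
        vals_arr = np.asarray(vals)
        rows.append(
            {
                "organ": g.organ,
                "stage": g.stage,
                "sex": g.sex,
                "n_pairs": len(vals),
                "pcc_values": vals,
                "pcc_mean": float(vals_arr.mean()) if len(vals) else np.nan,
                "pcc_se": float(vals_arr.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
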