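"""Factorial sample design: organs x developmental stages x sexes x replicates.

The default design mirrors a rat body-map style survey: 11 organs sampled at
4 ages (2, 6, 21 and 104 weeks) in both sexes with 4 biological replicates,
except testis (male only) and uterus (female only), giving

    9 * 4 * 2 * 4  +  2 * 4 * 1 * 4  =  320 samples.

Every downstream stage (expression classes, differential calling, variance
decomposition) indexes samples through the group structures defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

DEFAULT_ORGANS = ("Ad", "Br", "He", "Ki", "Li", "Lu", "Mu", "Sp", "Th", "Te", "Ut")
DEFAULT_STAGES = (2, 6, 21, 104)
SEXES = ("male", "female")

#: grouping keys accepted by :func:`enumerate_groups`
GROUPINGS = ("organ_stage_sex", "organ_stage", "organ")


class DesignError(ValueError):
    """Raised when a sample design violates its invariants."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    organ: str
    stage: int
    sex: str
    replicate: int


@dataclass(frozen=True)
class Group:
    """A cell of the design; ``sex`` is None when grouping pools sexes."""

    organ: str
    stage: int | None = None
    sex: str | None = None

    @property
    def label(self) -> str:
        parts = [self.organ]
        if self.stage is not None:
            parts.append(f"{self.stage}w")
        if self.sex is not None:
            parts.append(self.sex)
        return "_".join(parts)


def _default_sexes_per_organ() -> dict[str, tuple[str, ...]]:
    sexes = {organ: SEXES for organ in DEFAULT_ORGANS}
    sexes["Te"] = ("male",)
    sexes["Ut"] = ("female",)
    return sexes


@dataclass(frozen=True)
class SampleDesign:
    """The factorial layout of a multi-organ, multi-stage expression survey.

    Stages are ordered categorically (2 < 6 < 21 < 104 weeks by default);
    the temporal pattern classifier relies on this ordering, so it lives in
    the design rather than in callers.
    """

    organs: tuple[str, ...] = DEFAULT_ORGANS
    stages: tuple[int, ...] = DEFAULT_STAGES
    sexes_per_organ: Mapping[str, tuple[str, ...]] = field(
        default_factory=_default_sexes_per_organ
    )
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if len(set(self.organs)) != len(self.organs):
            raise DesignError("organs: duplicate organ codes")
        if len(set(self.stages)) != len(self.stages):
            raise DesignError("stages: duplicate stage labels")
        if self.n_replicates < 2:
            raise DesignError("n_replicates: need >= 2 replicates (t-tests need df >= 1)")
        for organ in self.organs:
            if organ not in self.sexes_per_organ:
                raise DesignError(f"sexes_per_organ: missing organ {organ!r}")
            allowed = self.sexes_per_organ[organ]
            if not allowed or any(s not in SEXES for s in allowed):
                raise DesignError(f"sexes_per_organ: invalid sexes for organ {organ!r}")

    # -- convenience -------------------------------------------------------
    def sexes_for(self, organ: str) -> tuple[str, ...]:
        return tuple(self.sexes_per_organ[organ])

    def dual_sex_organs(self) -> tuple[str, ...]:
        return tuple(o for o in self.organs if len(self.sexes_for(o)) == 2)

    def subset(self, organs: Iterable[str]) -> "SampleDesign":
        """Restrict the design to the given organs (order preserved)."""
        wanted = set(organs)
        keep = tuple(o for o in self.organs if o in wanted)
        return SampleDesign(
            organs=keep,
            stages=self.stages,
            sexes_per_organ={o: self.sexes_per_organ[o] for o in keep},
            n_replicates=self.n_replicates,
        )

    def exclude(self, organs: Iterable[str]) -> "SampleDesign":
        drop = set(organs)
        return self.subset(o for o in self.organs if o not in drop)

    def stage_order(self, stage: int) -> int:
        return self.stages.index(stage)

    def stage_transitions(self) -> list[tuple[int, int]]:
        """Adjacent stage pairs as (older, younger), oldest transition last."""
        return [(self.stages[i + 1], self.stages[i]) for i in range(len(self.stages) - 1)]


def sample_id(organ: str, stage: int, sex: str, replicate: int) -> str:
    return f"{organ}_{stage}w_{sex}_{replicate}"


def enumerate_samples(design: SampleDesign) -> list[Sample]:
    """Full cross-product of the design, respecting per-organ sexes.

    Deterministic ordering: organ, stage, sex (as listed), replicate.
    """
    samples = []
    for organ in design.organs:
        for stage in design.stages:
            for sex in design.sexes_for(organ):
                for rep in range(1, design.n_replicates + 1):
                    samples.append(
                        Sample(sample_id(organ, stage, sex, rep), organ, stage, sex, rep)
                    )
    return samples


def enumerate_groups(design: SampleDesign, by: str = "organ_stage_sex") -> list[Group]:
    """Enumerate the design's groups under a grouping key.

    ``by`` is one of ``organ_stage_sex`` (the per-sex cells, 80 in the default
    design), ``organ_stage`` (36 after excluding the single-sex organs) or
    ``organ``.
    """
    if by not in GROUPINGS:
        raise DesignError(f"unknown grouping key {by!r}; expected one of {GROUPINGS}")
    groups: list[Group] = []
    for organ in design.organs:
        if by == "organ":
            groups.append(Group(organ))
            continue
        for stage in design.stages:
            if by == "organ_stage":
                groups.append(Group(organ, stage))
            else:
                for sex in design.sexes_for(organ):
                    groups.append(Group(organ, stage, sex))
    return groups


def group_members(design: SampleDesign, group: Group) -> list[Sample]:
    """Samples belonging to a group (matching all non-None key fields)."""
    out = []
    for s in enumerate_samples(design):
        if s.organ != group.organ:
            continue
        if group.stage is not None and s.stage != group.stage:
            continue
        if group.sex is not None and s.sex != group.sex:
            continue
        out.append(s)
    return out


def metadata_frame(design: SampleDesign) -> pd.DataFrame:
    """Sample metadata as a DataFrame indexed by sample_id."""
    samples = enumerate_samples(design)
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "organ": [s.organ for s in samples],
            "stage_weeks": [s.stage for s in samples],
            "sex": [s.sex for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    return df.set_index("sample_id")


def design_from_metadata(meta: pd.DataFrame, n_replicates: int | None = None) -> SampleDesign:
    """Reconstruct a SampleDesign from a metadata table.

    Organs and stages are ordered by first appearance; stages sorted
    numerically.
    """
    organs = tuple(dict.fromkeys(meta["organ"]))
    stages = tuple(sorted(set(int(s) for s in meta["stage_weeks"])))
    sexes = {
        o: tuple(s for s in SEXES if s in set(meta.loc[meta["organ"] == o, "sex"]))
        for o in organs
    }
    if n_replicates is None:
        n_replicates = int(meta.groupby(["organ", "stage_weeks", "sex"]).size().max())
    return SampleDesign(organs, stages, sexes, n_replicates)


def replicate_pairs(n_replicates: int) -> list[tuple[int, int]]:
    """All unordered replicate index pairs, C(n, 2) of them."""
    return list(combinations(range(1, n_replicates + 1), 2))


def pattern_alphabet(n_transitions: int = 3) -> list[str]:
    """All temporal pattern labels over {U, M, D}^n_transitions (27 for 3)."""
    labels = [""]
    for _ in range(n_transitions):
        labels = [p + step for p in labels for step in "UMD"]
    return labels
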