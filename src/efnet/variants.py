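"""Three-variant framework separating sources of target-FC variability.

The study's two-level design pairs E-field seeds with connectomes in three
ways:

* ``GEOM``     — subject-specific E-field seed x group-average connectome:
                 variability due purely to head/cortical geometry;
* ``FCONLY``   — fixed template E-field seed x subject connectome:
                 variability due purely to individual FC;
* ``COMBINED`` — subject seed x subject connectome: the real-world case.

Engagement profiles are computed per subject under each variant, and
profiles are compared across variants by Pearson correlation of each
network's engagement percentage across subjects.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import (
    DenseConnectome,
    EngagementProfile,
    SeedFCMap,
    assign_vertices,
    engagement_profile,
    most_engaged,
    seed_fc_map,
)
from .networks import NETWORKS, network_index
from .stats import pearson_r
from .surface import DEFAULT_THRESHOLD, EmptySeedError, SeedRegion, extract_seed
from .synthetic import Cohort

log = logging.getLogger(__name__)


class VariantKind(enum.Enum):
    GEOM = "geom"  # subject E-field x group FC
    FCONLY = "fconly"  # template E-field x subject FC
    COMBINED = "combined"  # subject E-field x subject FC


@dataclass
class SubjectVariantOutput:
    subject_id: int
    seed: SeedRegion
    fc_map: SeedFCMap
    profile: EngagementProfile

    @property
    def most_engaged(self) -> str:
        return most_engaged(self.profile)


@dataclass
class VariantResult:
    """Per-subject seeds, FC maps and engagement under one variant."""

    variant: VariantKind
    target: str
    threshold: float
    subjects: dict[int, SubjectVariantOutput]
    excluded: list[int] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return len(self.subjects)

    def engagement_matrix(self) -> pd.DataFrame:
        """Subjects x eight-networks matrix of engagement percentages."""
        rows = {
            sid: out.profile.percent for sid, out in sorted(self.subjects.items())
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(NETWORKS)
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (subject_id, target, variant, network, percent)."""
        records = []
        for sid, out in sorted(self.subjects.items()):
            for net, pct in zip(NETWORKS, out.profile.percent):
                records.append(
                    {
                        "subject_id": sid,
                        "target": self.target,
                        "variant": self.variant.value,
                        "network": net,
                        "percent": pct,
                    }
                )
        return pd.DataFrame.from_records(records)


def run_variant(
    cohort: Cohort,
    target: str,
    variant: "VariantKind | str",
    threshold: float = DEFAULT_THRESHOLD,
) -> VariantResult:
    """Run the engagement pipeline for one target under one variant.

    Subjects whose E-field never reaches the threshold are recorded as
    excluded (with a warning) rather than failing the whole cohort; the
    study's real E-fields always exceeded threshold, so exclusions signal
    an unusually weak synthetic field.
    """
    variant = VariantKind(variant)
    template_seed: SeedRegion | None = None
    if variant is VariantKind.FCONLY:
        template_seed = extract_seed(
            cohort.template_efield(target), cohort.mesh, threshold
        )
    group_fc: DenseConnectome | None = None
    if variant is VariantKind.GEOM:
        group_fc = cohort.group_fc()

    subjects: dict[int, SubjectVariantOutput] = {}
    excluded: list[int] = []
    for sid in cohort.subject_ids:
        try:
            if variant is VariantKind.FCONLY:
                seed = template_seed
            else:
                seed = extract_seed(
                    cohort.subject_efield(sid, target), cohort.mesh, threshold
                )
        except EmptySeedError as err:
            log.warning("subject %d excluded (%s): %s", sid, target, err)
            excluded.append(sid)
            continue
        fc = group_fc if variant is VariantKind.GEOM else cohort.subject_fc(sid)
        fc_map = seed_fc_map(fc, seed)
        assignments = assign_vertices(fc, seed, cohort.parcellation)
        subjects[sid] = SubjectVariantOutput(
            subject_id=sid,
            seed=seed,
            fc_map=fc_map,
            profile=engagement_profile(assignments),
        )
    if excluded:
        log.warning(
            "%d/%d subjects excluded from %s/%s (empty seeds)",
            len(excluded),
            cohort.spec.n_subjects,
            target,
            variant.value,
        )
    return VariantResult(
        variant=variant,
        target=target,
        threshold=threshold,
        subjects=subjects,
        excluded=excluded,
    )


def cross_variant_engagement_correlation(
    res_a: VariantResult, res_b: VariantResult, network: str
) -> float:
    """Pearson r of one network's engagement percentage across subjects,
    between two variants of the same cohort/target.

    Subjects missing from either variant (empty seeds) are dropped
    pairwise (complete-case).
    """
    if res_a.target != res_b.target:
        raise ValueError("variant results are for different targets")
    idx = network_index(network)
    common = sorted(set(res_a.subjects) & set(res_b.subjects))
    dropped = (len(res_a.subjects) + len(res_b.subjects)) / 2 - len(common)
    if dropped:
        log.warning(
            "cross-variant correlation on %d paired subjects "
            "(~%d dropped pairwise)",
            len(common),
            int(dropped),
        )
    if len(common) < 3:
        raise ValueError("need at least 3 paired subjects")
    a = np.array([res_a.subjects[s].profile.percent[idx] for s in common])
    b = np.array([res_b.subjects[s].profile.percent[idx] for s in common])
    if a.std() == 0 or b.std() == 0:
        raise ValueError(
            f"engagement of {network} has zero variance; correlation undefined"
        )
    return pearson_r(a, b)


def most_engaged_counts(res: VariantResult) -> dict[str, int]:
    """How many included subjects had each network as their most engaged."""
    if not res.subjects:
        raise ValueError("variant result has no included subjects")
    counts = dict.fromkeys(NETWORKS, 0)
    for out in res.subjects.values():
        counts[out.most_engaged] += 1
    return counts
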