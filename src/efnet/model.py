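"""Model/results front end for the network-engagement analysis.

``TargetEngagement`` bundles a cohort, a stimulation target and a pairing
variant; ``fit`` runs seed extraction, seed FC and vertex-wise network
assignment for every subject and returns a ``TargetEngagementResults``
carrying the engagement matrix, the repeated-measures ANOVA over the
NETWORK factor, Tukey-corrected post hocs and summary tables.

Example
-------
>>> from efnet import CohortSpec, generate_cohort
>>> from efnet.model import TargetEngagement
>>> cohort = generate_cohort(CohortSpec(master_seed=7, n_subjects=8,
...                                     mesh_subdivision=3))
>>> res = TargetEngagement(cohort, target="dlpfc", variant="combined").fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import NETWORKS
from .reporting import spider_polygon_area, summarize_variant, topk_coverage
from .stats import (
    AnovaResult,
    PosthocResult,
    paired_target_contrast,
    rm_anova_network,
    tukey_posthoc,
)
from .surface import DEFAULT_THRESHOLD
from .synthetic import Cohort, CohortSpec, generate_cohort
from .variants import (
    VariantKind,
    VariantResult,
    cross_variant_engagement_correlation,
    most_engaged_counts,
    run_variant,
)


class TargetEngagement:
    """Network engagement of one TMS target under one pairing variant."""

    def __init__(
        self,
        cohort: Cohort,
        target: str,
        variant: "VariantKind | str" = VariantKind.COMBINED,
    ) -> None:
        self.cohort = cohort
        self.target = target
        self.variant = VariantKind(variant)

    @classmethod
    def from_spec(
        cls,
        spec: CohortSpec,
        target: str,
        variant: "VariantKind | str" = VariantKind.COMBINED,
    ) -> "TargetEngagement":
        return cls(generate_cohort(spec), target, variant)

    def fit(self, threshold: float = DEFAULT_THRESHOLD) -> "TargetEngagementResults":
        res = run_variant(self.cohort, self.target, self.variant, threshold)
        return TargetEngagementResults(model=self, variant_result=res)


@dataclass
class TargetEngagementResults:
    """Fitted engagement results for one (target, variant) pair."""

    model: TargetEngagement
    variant_result: VariantResult

    # -- core tables ------------------------------------------------------
    @property
    def engagement(self) -> pd.DataFrame:
        """Subjects x networks engagement percentages."""
        return self.variant_result.engagement_matrix()

    @property
    def n_subjects(self) -> int:
        return self.variant_result.n_included

    def summary_table(self) -> pd.DataFrame:
        return summarize_variant(self.variant_result)

    def most_engaged_counts(self) -> dict[str, int]:
        return most_engaged_counts(self.variant_result)

    def coverage(self, networks: "list[str]") -> int:
        """Display-rounded sum of mean engagement over chosen networks."""
        return topk_coverage(self.summary_table(), networks)

    def spider_areas(self) -> pd.Series:
        return pd.Series(
            {
                sid: spider_polygon_area(out.profile)
                for sid, out in sorted(self.variant_result.subjects.items())
            },
            name="spider_area_fraction",
        )

    # -- inference --------------------------------------------------------
    def anova(self, gg_correction: bool = False) -> AnovaResult:
        """RM one-way ANOVA with the within-subject factor NETWORK."""
        return rm_anova_network(self.engagement, gg_correction=gg_correction)

    def tukey(self) -> PosthocResult:
        return tukey_posthoc(self.engagement, levels=list(NETWORKS))

    def correlate_with(
        self, other: "TargetEngagementResults", network: str
    ) -> float:
        """Cross-variant Pearson r of one network's engagement."""
        return cross_variant_engagement_correlation(
            self.variant_result, other.variant_result, network
        )

    def contrast_with(
        self, other: "TargetEngagementResults", network: str
    ) -> tuple[float, float]:
        """Paired t contrast of one network's engagement vs another target."""
        common = sorted(
            set(self.variant_result.subjects) & set(other.variant_result.subjects)
        )
        idx = NETWORKS.index(network)
        a = [self.variant_result.subjects[s].profile.percent[idx] for s in common]
        b = [other.variant_result.subjects[s].profile.percent[idx] for s in common]
        return paired_target_contrast(a, b)

    # -- display ----------------------------------------------------------
    def summary(self) -> str:
        tab = self.summary_table()
        an = self.anova()
        lines = [
            "Network engagement"
            f" — target {self.variant_result.target},"
            f" variant {self.variant_result.variant.value},"
            f" threshold {self.variant_result.threshold:g} V/m",
            f"subjects included: {self.n_subjects}"
            + (
                f" (excluded: {len(self.variant_result.excluded)})"
                if self.variant_result.excluded
                else ""
            ),
            "",
            f"{'network':>8} {'mean %':>8} {'sd %':>8} {'top-count':>10}",
        ]
        for _, row in tab.iterrows():
            lines.append(
                f"{row['network']:>8} {row['mean_percent']:8.1f} "
                f"{row['sd_percent']:8.1f} {row['most_engaged_count']:10d}"
            )
        lines += ["", f"RM-ANOVA (NETWORK): {an}"]
        return "\n".join(lines)
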