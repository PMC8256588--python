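"""Staged prevalence composition for airway luminal eosinophilia.

Three nested tiers estimate how common the eosinophilic endotype really is
in a sputum database:

1. *intact-only* — the fraction of samples whose intact eosinophil
   differential meets the cutoff (the conventional single-time-point
   estimate);
2. *FEG-augmented* — adding samples positive only by free eosinophil
   granules, including degenerated samples with no intact differential;
3. *extrapolated total* — adding the re-emergence (unmasking) fraction
   observed in repeatedly-sampled patients, extrapolated to the whole
   cohort: of the samples still negative after FEG augmentation, the
   fraction ``q`` that would be expected to turn positive on a further
   examination, giving ``total = p + (1 - p) * q``.

Two tally conventions are supported for tier 2.  The *nested* convention
counts every non-viable sample whose FEG grade qualifies under the
threshold's own grade set, so the 2.3% tier is a subset of the 1.2% tier.
The *paper_tally* convention reproduces the published arithmetic, which
assigned non-viable few-granule samples to the 1.2% tier only and
moderate/many to the 2.3% tier only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .classify import CohortTallies
from .cohort import FegGrade, ValidationError

__all__ = [
    "PrevalenceEstimate",
    "compose_feg_augmented",
    "extrapolate_total",
    "underestimation",
    "euler_composition",
    "estimate_from_tallies",
    "plot_euler",
]


def compose_feg_augmented(
    n_intact_pos: int,
    n_feg_with_diff: int,
    n_feg_no_diff: int,
    n_total: int,
) -> float:
    """FEG-augmented prevalence from disjoint category counts.

    ``(n_intact_pos + n_feg_with_diff + n_feg_no_diff) / n_total`` — the
    three categories (intact-positive; differential present but below
    cutoff with qualifying FEG; no differential with qualifying FEG) are
    disjoint by construction.
    """
    counts = (n_intact_pos, n_feg_with_diff, n_feg_no_diff)
    if any(c < 0 for c in counts) or n_total <= 0:
        raise ValidationError("counts must be non-negative, n_total > 0")
    if sum(counts) > n_total:
        raise ValidationError(
            "category counts exceed n_total; categories must be disjoint"
        )
    return sum(counts) / n_total


def extrapolate_total(
    prev_feg_aug: float, emergence_fraction: float
) -> tuple[float, float]:
    """Extrapolate the re-emergence fraction to the whole sample.

    Returns ``(additional, total)`` where ``additional`` is the share of
    all samples expected to convert — ``(1 - p) * q`` with ``p`` the
    FEG-augmented prevalence and ``q`` the emergence fraction observed in
    multi-sample patients — and ``total = p + additional``.
    """
    for name, v in (
        ("prev_feg_aug", prev_feg_aug),
        ("emergence_fraction", emergence_fraction),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name}={v} outside [0, 1]")
    additional = (1.0 - prev_feg_aug) * emergence_fraction
    return additional, prev_feg_aug + additional


def underestimation(prev_intact: float, prev_total: float) -> float:
    """Relative underestimation of the single-time-point intact estimate:
    ``(prev_total - prev_intact) / prev_total``."""
    if not (0.0 < prev_total <= 1.0):
        raise ValidationError("prev_total must lie in (0, 1]")
    if prev_intact > prev_total:
        raise ValidationError("prev_intact exceeds prev_total")
    return (prev_total - prev_intact) / prev_total


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Staged prevalence estimate at one threshold."""

    threshold_name: str
    tally_mode: str
    n_total: int
    n_intact_pos: int
    n_feg_with_diff: int
    n_feg_no_diff: int
    emergence_fraction: Optional[float]

    def __post_init__(self) -> None:
        # re-derive to enforce invariants
        compose_feg_augmented(
            self.n_intact_pos,
            self.n_feg_with_diff,
            self.n_feg_no_diff,
            self.n_total,
        )

    @property
    def prev_intact(self) -> float:
        return self.n_intact_pos / self.n_total

    @property
    def prev_feg_aug(self) -> float:
        return compose_feg_augmented(
            self.n_intact_pos,
            self.n_feg_with_diff,
            self.n_feg_no_diff,
            self.n_total,
        )

    @property
    def additional_extrapolated(self) -> Optional[float]:
        if self.emergence_fraction is None:
            return None
        return extrapolate_total(self.prev_feg_aug, self.emergence_fraction)[0]

    @property
    def prev_total(self) -> Optional[float]:
        if self.emergence_fraction is None:
            return None
        return extrapolate_total(self.prev_feg_aug, self.emergence_fraction)[1]

    @property
    def underestimation(self) -> Optional[float]:
        if self.prev_total is None or self.prev_total == 0:
            return None
        return underestimation(self.prev_intact, self.prev_total)

    def to_dict(self) -> dict:
        return {
            "threshold_name": self.threshold_name,
            "tally_mode": self.tally_mode,
            "n_total": self.n_total,
            "n_intact_pos": self.n_intact_pos,
            "n_feg_with_diff": self.n_feg_with_diff,
            "n_feg_no_diff": self.n_feg_no_diff,
            "prev_intact": self.prev_intact,
            "prev_feg_aug": self.prev_feg_aug,
            "emergence_fraction": self.emergence_fraction,
            "additional_extrapolated": self.additional_extrapolated,
            "prev_total": self.prev_total,
            "underestimation": self.underestimation,
        }


def estimate_from_tallies(
    tallies: CohortTallies,
    emergence_fraction: Optional[float] = None,
    tally_mode: str = "nested",
) -> PrevalenceEstimate:
    """Build a :class:`PrevalenceEstimate` from classification tallies.

    ``tally_mode="nested"`` counts non-viable FEG samples by the
    threshold's own qualifying grade set; ``"paper_tally"`` assigns
    few-granule non-viable samples to thresholds whose qualifying set
    includes *few* and moderate/many-only otherwise, reproducing the
    published composition arithmetic.
    """
    if tally_mode == "nested":
        n_no_diff = tallies.n_feg_no_diff_qualifying
    elif tally_mode == "paper_tally":
        if FegGrade.FEW in tallies._qualifying:
            n_no_diff = tallies.n_feg_no_diff_few
        else:
            n_no_diff = tallies.n_feg_no_diff_modmany
    else:
        raise ValidationError(f"unknown tally mode {tally_mode!r}")
    return PrevalenceEstimate(
        threshold_name=tallies.threshold_name,
        tally_mode=tally_mode,
        n_total=tallies.n_total,
        n_intact_pos=tallies.n_intact_pos,
        n_feg_with_diff=tallies.n_feg_with_diff,
        n_feg_no_diff=n_no_diff,
        emergence_fraction=emergence_fraction,
    )


def euler_composition(estimate: PrevalenceEstimate) -> dict:
    """Nested three-tier set sizes (intact ⊆ +FEG ⊆ +re-emergence).

    Returns absolute counts and proportions for the three tiers, suitable
    for a proportional-area diagram.  The outermost tier is only available
    when an emergence fraction was supplied.
    """
    n = estimate.n_total
    tiers = {
        "intact": {
            "count": estimate.n_intact_pos,
            "proportion": estimate.prev_intact,
        },
        "feg_augmented": {
            "count": estimate.n_intact_pos
            + estimate.n_feg_with_diff
            + estimate.n_feg_no_diff,
            "proportion": estimate.prev_feg_aug,
        },
    }
    if estimate.prev_total is not None:
        tiers["extrapolated_total"] = {
            "count": round(estimate.prev_total * n),
            "proportion": estimate.prev_total,
        }
    return tiers


def plot_euler(estimate: PrevalenceEstimate, ax=None):
    """Render the staged composition as proportional nested circles.

    Requires matplotlib; imported lazily so the library has no hard
    plotting dependency.
    """
    import math

    import matplotlib.pyplot as plt

    tiers = euler_composition(estimate)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    colors = {"intact": "#c0392b", "feg_augmented": "#e67e22",
              "extrapolated_total": "#f1c40f"}
    ordered = sorted(
        tiers.items(), key=lambda kv: kv[1]["proportion"], reverse=True
    )
    for name, tier in ordered:
        r = math.sqrt(max(tier["proportion"], 0.0))
        circ = plt.Circle(
            (0, 0), r, color=colors.get(name, "grey"), alpha=0.8, ec="black"
        )
        ax.add_patch(circ)
        ax.annotate(
            f"{name}: {100 * tier['proportion']:.1f}%",
            xy=(0, r),
            xytext=(0, r + 0.05),
            ha="center",
            fontsize=8,
        )
    lim = 1.15
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"Eosinophilia tiers at {estimate.threshold_name}%")
    return ax
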