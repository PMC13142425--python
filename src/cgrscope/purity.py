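"""Tumor purity from coverage depth at an engineered biallelic-deletion locus.

Model: in tumor cells both copies of the edit region are deleted, so coverage
there comes only from contaminating normal cells. With mean depths over the
edit region and a flanking region,

    purity = 1 - depth_edit / depth_flank

clamped to [0, 1]. This is a model assumption (the deletion must be biallelic
in all tumor cells); it is recorded in the estimate metadata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["PurityEstimate", "estimate_purity", "estimate_purity_from_table"]


class PurityError(ValueError):
    pass


@dataclass(frozen=True)
class PurityEstimate:
    sample_id: str | None
    depth_edit: float
    depth_flank: float
    purity: float
    qc_flag: bool = False  # ratio within noise of 1: estimate unreliable
    model: str = "biallelic-deletion depth ratio"


def estimate_purity(depth_edit: float, depth_flank: float,
                    sample_id: str | None = None,
                    n_positions: int | None = None) -> PurityEstimate:
    """Estimate tumor purity from the edit/flank mean-depth ratio.

    Parameters
    ----------
    depth_edit, depth_flank:
        Mean coverage depth over the engineered deletion and a flanking
        region. ``depth_flank`` must be positive.
    n_positions:
        Number of positions the means were taken over; used only to decide
        the QC flag (ratio within ~2 Poisson SE of 1).
    """
    if depth_flank <= 0:
        raise PurityError("depth_flank must be positive")
    if depth_edit < 0:
        raise PurityError("depth_edit must be >= 0")
    ratio = depth_edit / depth_flank
    if ratio > 1:
        warnings.warn(
            f"edit depth exceeds flank depth (ratio {ratio:.3f}); clamping purity to 0",
            stacklevel=2)
    purity = min(1.0, max(0.0, 1.0 - ratio))
    se = math.sqrt(max(depth_edit, 1.0) / max(n_positions or 1, 1)) / depth_flank
    qc = abs(ratio - 1.0) <= 2 * se
    return PurityEstimate(sample_id, depth_edit, depth_flank, purity, qc_flag=qc)


def estimate_purity_from_table(depth_table: pd.DataFrame,
                               edit_label: str = "edit",
                               flank_label: str = "flank") -> list[PurityEstimate]:
    """Per-sample estimates from a depth summary (columns sample/region/mean_depth)."""
    estimates = []
    for sample, group in depth_table.groupby("sample", sort=True):
        by_region = dict(zip(group["region"], group["mean_depth"]))
        if edit_label not in by_region or flank_label not in by_region:
            raise PurityError(
                f"sample {sample}: depth table must contain regions "
                f"{edit_label!r} and {flank_label!r}")
        n_pos = None
        if "n_positions" in group.columns:
            n_pos = int(group["n_positions"].iloc[0])
        estimates.append(estimate_purity(
            float(by_region[edit_label]), float(by_region[flank_label]),
            sample_id=str(sample), n_positions=n_pos))
    return estimates
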