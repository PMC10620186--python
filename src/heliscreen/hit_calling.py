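"""Hit-strength computation and trimerizer calling.

Hit strength is the fold-change of spike-normalized counts between a
selection condition and its control wells. In a trimerizer screen the
selection well is the highest-target-concentration well containing free
presenter; the controls are (i) target wells without presenter — peptides
that bind the target regardless of presenter enrich there too, so their
fold-change stays near 1 — and (ii) blank beads with free presenter, the
counter-screen that removes bead and presenter binders. A trimerizer call
requires both fold-changes to clear the threshold (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import CountTable, ScreenSample, normalize

__all__ = ["HitRecord", "hit_strength", "call_trimerizers", "hits_frame"]

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_THRESHOLD = 5.0


@dataclass
class HitRecord:
    peptide: str
    hs_target: float
    hs_counter: float | None
    mode: str  # "naive" or "trimerizer"
    is_hit: bool = False

    def __post_init__(self) -> None:
        if self.hs_target < 0:
            raise ValueError("hit strength cannot be negative")


class ScreenConfigurationError(ValueError):
    """A well class required by the requested mode is missing."""


def _well_ids(samples: list[ScreenSample], **conds) -> list[str]:
    out = []
    for s in samples:
        if conds.get("bead") is not None and s.bead != conds["bead"]:
            continue
        if conds.get("presenter") is not None and s.has_presenter != conds["presenter"]:
            continue
        if conds.get("top_conc") and (s.target_conc is None):
            continue
        out.append(s.sample_id)
    return out


def _mean_over(norm: pd.DataFrame, ids: list[str]) -> pd.Series:
    return norm[ids].mean(axis=1)


def _ratio(num: pd.Series, den: pd.Series, pseudocount: float) -> pd.Series:
    den = den.where(den > 0, pseudocount)
    return num / den


def hit_strength(
    table: CountTable,
    mode: str = "trimerizer",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[HitRecord]:
    """Compute fold-change hit strengths for every peptide.

    ``trimerizer``: hs_target = norm(top-conc target + presenter) /
    mean(norm(target, no presenter)); hs_counter uses blank+presenter
    wells as the denominator. ``naive``: hs = norm(target beads) /
    mean(norm(blank beads)). When a denominator's replicate mean is 0 the
    pseudocount (0.5, on the normalized scale) is used instead; a zero
    numerator always gives hs 0.
    """
    norm = normalize(table)
    usable = [s for s in table.samples if s.sample_id in norm.columns]

    if mode == "trimerizer":
        with_pres = [s for s in usable if s.bead == "target" and s.has_presenter]
        if not with_pres:
            raise ScreenConfigurationError("no target+presenter wells in the sample sheet")
        top = max(s.target_conc or 0 for s in with_pres)
        num_ids = [s.sample_id for s in with_pres if (s.target_conc or 0) == top]
        den_ids = [s.sample_id for s in usable if s.bead == "target" and not s.has_presenter]
        counter_ids = [s.sample_id for s in usable if s.bead == "blank" and s.has_presenter]
        if not den_ids:
            raise ScreenConfigurationError("no target-only (no presenter) wells")
        if not counter_ids:
            raise ScreenConfigurationError("no blank-beads+presenter counter wells")
        num = _mean_over(norm, num_ids)
        hs_t = _ratio(num, _mean_over(norm, den_ids), pseudocount)
        hs_c = _ratio(num, _mean_over(norm, counter_ids), pseudocount)
        records = [
            HitRecord(p, float(hs_t[p]), float(hs_c[p]), "trimerizer") for p in norm.index
        ]
    elif mode == "naive":
        num_ids = [s.sample_id for s in usable if s.bead == "target"]
        den_ids = [s.sample_id for s in usable if s.bead == "blank" and not s.has_presenter]
        if not num_ids:
            raise ScreenConfigurationError("no target-bead wells")
        if not den_ids:
            raise ScreenConfigurationError("no blank-bead wells")
        hs = _ratio(_mean_over(norm, num_ids), _mean_over(norm, den_ids), pseudocount)
        records = [HitRecord(p, float(hs[p]), None, "naive") for p in norm.index]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for rec in records:
        if mode == "naive":
            rec.is_hit = rec.hs_target > threshold
    return records


def call_trimerizers(
    records: list[HitRecord], threshold: float = DEFAULT_THRESHOLD
) -> list[HitRecord]:
    """Flag trimerizer hits: both fold-changes must exceed the threshold.

    Peptides enriched regardless of presenter (hs_target near 1) and
    bead/presenter binders (hs_counter near 1) are thereby excluded.
    """
    for rec in records:
        if rec.mode != "trimerizer":
            raise ValueError("call_trimerizers expects trimerizer-mode records")
        rec.is_hit = rec.hs_target > threshold and (rec.hs_counter or 0) > threshold
    return records


def hits_frame(records: list[HitRecord]) -> pd.DataFrame:
    """Records as a DataFrame sorted by descending hs_target."""
    df = pd.DataFrame(
        {
            "peptide": [r.peptide for r in records],
            "hs_target": [r.hs_target for r in records],
            "hs_counter": [np.nan if r.hs_counter is None else r.hs_counter for r in records],
            "mode": [r.mode for r in records],
            "is_hit": [r.is_hit for r in records],
        }
    )
    return df.sort_values("hs_target", ascending=False).reset_index(drop=True)
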