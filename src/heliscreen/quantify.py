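"""Per-sample peptide tallies and spike-in normalization.

Each screening well is sequenced separately; a constant amount of a
non-library spike-in phage is added to every well before amplification, so
dividing each peptide's raw count by the well's spike-in count removes
depth and amplification differences between wells. Counting is at the
peptide (amino-acid) level, collapsing synonymous DNA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ScreenSample", "CountTable", "read_sample_sheet", "tally", "normalize"]

#: arbitrary normalized-count scale; hit strengths are ratios and do not
#: depend on it
DEFAULT_NORM_SCALE = 1e4


@dataclass(frozen=True)
class ScreenSample:
    """One screening well."""

    sample_id: str
    bead: str  # "target" or "blank"
    target: str | None = None
    target_conc: float | None = None  # uM
    presenter: str | None = None
    presenter_conc: float | None = None  # uM; screens use 10 uM
    replicate: int = 1
    file: str | None = None

    def __post_init__(self) -> None:
        if self.bead not in ("target", "blank"):
            raise ValueError(f"sample {self.sample_id}: bead must be 'target' or 'blank'")
        if self.bead == "blank" and self.target is not None:
            raise ValueError(f"sample {self.sample_id}: blank beads cannot declare a target")
        if self.presenter is not None and not (self.presenter_conc or 0) > 0:
            raise ValueError(f"sample {self.sample_id}: presenter set but presenter_conc not > 0")

    @property
    def has_presenter(self) -> bool:
        return self.presenter is not None


def read_sample_sheet(path: str | Path) -> list[ScreenSample]:
    """Load a sample sheet CSV/TSV.

    Columns: sample_id, file, bead, target, target_conc_uM, presenter,
    presenter_conc_uM, replicate. Empty cells mean 'absent'.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            ScreenSample(
                sample_id=row["sample_id"],
                bead=row["bead"],
                target=row["target"] or None,
                target_conc=float(row["target_conc_uM"]) if row.get("target_conc_uM") else None,
                presenter=row["presenter"] or None,
                presenter_conc=(
                    float(row["presenter_conc_uM"]) if row.get("presenter_conc_uM") else None
                ),
                replicate=int(row["replicate"]) if row.get("replicate") else 1,
                file=row.get("file") or None,
            )
        )
    return samples


@dataclass
class CountTable:
    """Peptide x sample raw counts plus per-sample spike-in counts."""

    raw: pd.DataFrame  # index: peptide, columns: sample_id, integer counts
    spike_raw: pd.Series  # per sample_id
    samples: list[ScreenSample]
    norm_scale: float = DEFAULT_NORM_SCALE

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.raw.columns) != ids or list(self.spike_raw.index) != ids:
            raise ValueError("count matrix columns must match the sample sheet order")
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")
        if self.norm_scale <= 0:
            raise ValueError("norm_scale must be positive")

    @property
    def peptides(self) -> list[str]:
        return list(self.raw.index)

    @property
    def usable(self) -> pd.Series:
        """Samples with a nonzero spike-in count."""
        return self.spike_raw > 0

    def sample(self, sample_id: str) -> ScreenSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def to_tsv(self, path: str | Path) -> None:
        out = self.raw.copy()
        out.loc["#SPIKE"] = self.spike_raw
        out.to_csv(path, sep="\t", index_label="peptide")

    @classmethod
    def from_tsv(
        cls, path: str | Path, samples: list[ScreenSample], norm_scale: float = DEFAULT_NORM_SCALE
    ) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="peptide")
        spike = df.loc["#SPIKE"]
        raw = df.drop(index="#SPIKE").astype(int)
        return cls(raw=raw, spike_raw=spike.astype(int), samples=samples, norm_scale=norm_scale)


def tally(
    peptides_per_sample: Mapping[str, Sequence[str]],
    spike_per_sample: Mapping[str, int],
    samples: list[ScreenSample],
    norm_scale: float = DEFAULT_NORM_SCALE,
) -> CountTable:
    """Tally exact peptide occurrence counts per sample.

    The spike-in is counted separately and never appears among the peptide
    rows. Samples with zero spike-in are kept but flagged unusable (their
    normalized counts are undefined).
    """
    ids = [s.sample_id for s in samples]
    missing = set(peptides_per_sample) - set(ids)
    if missing:
        raise ValueError(f"peptide lists for samples absent from the sheet: {sorted(missing)}")
    counters = {sid: Counter(peptides_per_sample.get(sid, ())) for sid in ids}
    universe = sorted(set().union(*[set(c) for c in counters.values()]) if counters else set())
    raw = pd.DataFrame(
        {sid: [counters[sid].get(p, 0) for p in universe] for sid in ids},
        index=pd.Index(universe, name="peptide"),
        dtype=int,
    )
    spike = pd.Series({sid: int(spike_per_sample.get(sid, 0)) for sid in ids}, dtype=int)[ids]
    return CountTable(raw=raw, spike_raw=spike, samples=samples, norm_scale=norm_scale)


def normalize(table: CountTable) -> pd.DataFrame:
    """Spike-normalized counts: raw / spike_raw x norm_scale.

    Columns with spike_raw == 0 are dropped (with no spike-in reference the
    well's depth is unknowable).
    """
    usable = table.usable
    if not usable.all():
        import warnings

        bad = list(table.spike_raw.index[~usable])
        warnings.warn(f"excluding samples with zero spike-in count: {bad}", stacklevel=2)
    kept = table.raw.loc[:, usable[usable].index]
    return kept / table.spike_raw[usable] * table.norm_scale


def conservation_check(table: CountTable, stats_totals: Mapping[str, int]) -> pd.DataFrame:
    """Reconcile per-sample totals: matched + spike must not exceed reads."""
    rows = []
    for s in table.samples:
        matched = int(table.raw[s.sample_id].sum())
        spike = int(table.spike_raw[s.sample_id])
        total = stats_totals.get(s.sample_id, matched + spike)
        rows.append(
            {
                "sample_id": s.sample_id,
                "matched": matched,
                "spike": spike,
                "rejected": total - matched - spike,
                "total": total,
            }
        )
    return pd.DataFrame(rows)
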