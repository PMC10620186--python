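"""Synthetic screens with planted ground truth.

Emulates a single-round trimerizer phage screen: a large background
library, a constant spike-in, and planted binders that are either
presenter-independent (binary target binders), presenter-dependent
trimerizers (weak binary target affinity, cooperativity alpha >> 1), or
bead binders. Per-well capture weights come from equilibrium occupancy of
the bead-bound target species (TH + ATH from the ternary model, with the
presenter free in solution when present), and read counts are drawn
multinomially at a fixed depth, with the spike-in taking a constant
fraction of each well's input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biophys import TernarySystem, solve_ternary, ternary_signal
from .design import LibraryDesignSpec, naive_design
from .genetics import DEFAULT_CODON_TABLE
from .quantify import DEFAULT_NORM_SCALE, CountTable, ScreenSample

__all__ = [
    "PlantedBinder",
    "SimulationConfig",
    "default_wells",
    "default_planted",
    "simulate_screen",
    "simulate_reads",
    "simulate_dose_response",
    "SPIKE_PEPTIDE_14",
]

#: non-library spike-in insert peptides (contain K/G, so they can never
#: match a design); one per supported insert length
SPIKE_PEPTIDE_14 = "GKGSGKGSGKGSGK"
SPIKE_PEPTIDE_20 = "GKGSGKGSGKGSGKGSGKGS"

#: helicon concentration per unique clone in a screening well (nM); phage
#: clones are individually trace-level, so occupancy is linear in clone
#: abundance and clones do not deplete target or presenter
CLONE_CONC_NM = 1e-3


@dataclass(frozen=True)
class PlantedBinder:
    peptide: str
    k_target: float | None = None  # nM binary target affinity (K_TH)
    k_presenter: float | None = None  # nM presenter affinity (K_AH)
    alpha: float = 1.0
    bead_binder: bool = False

    @property
    def is_trimerizer(self) -> bool:
        return self.alpha > 1.0 and self.k_presenter is not None


@dataclass
class SimulationConfig:
    """Study-scale defaults: ~1e5-member sampled background of the 1e8
    library, 1e6 reads/well, presenter free in solution at 10 uM, target
    titrated on beads with the top concentration at 1 uM."""

    design: LibraryDesignSpec = field(default_factory=naive_design)
    planted: list[PlantedBinder] = field(default_factory=list)
    library_size: int = 100_000
    depth: int = 1_000_000
    spike_fraction: float = 0.02
    baseline_weight: float = 1.0
    capture_scale: float = 100.0
    wells: list[ScreenSample] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 < self.spike_fraction < 1:
            raise ValueError("spike_fraction must lie in (0, 1)")


def default_wells(
    target: str = "TARGET",
    presenter: str = "PRESENTER",
    target_concs: tuple[float, ...] = (0.1, 1.0),
    replicates: int = 2,
) -> list[ScreenSample]:
    """The trimerizer screening plate layout: target wells titrated with
    presenter, target-only wells without presenter (the 'target blanks'),
    and blank beads with and without presenter."""
    wells: list[ScreenSample] = []
    for conc in target_concs:
        for rep in range(1, replicates + 1):
            wells.append(
                ScreenSample(
                    sample_id=f"T{conc:g}_P_r{rep}",
                    bead="target",
                    target=target,
                    target_conc=conc,
                    presenter=presenter,
                    presenter_conc=10.0,
                    replicate=rep,
                )
            )
    top = max(target_concs)
    for rep in range(1, replicates + 1):
        wells.append(
            ScreenSample(
                sample_id=f"T{top:g}_noP_r{rep}",
                bead="target",
                target=target,
                target_conc=top,
                replicate=rep,
            )
        )
    wells.append(
        ScreenSample(
            sample_id="blank_P_r1",
            bead="blank",
            presenter=presenter,
            presenter_conc=10.0,
            replicate=1,
        )
    )
    wells.append(ScreenSample(sample_id="blank_noP_r1", bead="blank", replicate=1))
    return wells


def default_planted(
    design: LibraryDesignSpec, rng: np.random.Generator, n_trimerizers: int = 20, n_binary: int = 20
) -> list[PlantedBinder]:
    """Plant trimerizers (weak binary target affinity, alpha >> 1) and
    presenter-independent binary target binders."""
    peptides = design.sample_peptides(n_trimerizers + n_binary, rng)
    planted = [
        PlantedBinder(p, k_target=1e5, k_presenter=1000.0, alpha=500.0)
        for p in peptides[:n_trimerizers]
    ]
    planted += [
        PlantedBinder(p, k_target=500.0, k_presenter=None, alpha=1.0)
        for p in peptides[n_trimerizers:]
    ]
    return planted


def _capture_weight(binder: PlantedBinder, well: ScreenSample, config: SimulationConfig) -> float:
    """baseline + scale * equilibrium fraction of the clone bound to the
    bead surface (target-bound species; bead binders stick everywhere)."""
    w = config.baseline_weight
    if binder.bead_binder:
        w += config.capture_scale
    t_nm = (well.target_conc or 0.0) * 1e3 if well.bead == "target" else 0.0
    a_nm = (well.presenter_conc or 0.0) * 1e3 if well.has_presenter else 0.0
    if t_nm > 0 and binder.k_target is not None:
        sysm = TernarySystem(
            a_total=a_nm,
            t_total=t_nm,
            h_total=CLONE_CONC_NM,
            k_ah=binder.k_presenter if binder.k_presenter else 1e12,
            k_th=binder.k_target,
            alpha=binder.alpha,
        )
        species = solve_ternary(sysm)
        frac_bound = (species["TH"] + species["ATH"]) / CLONE_CONC_NM
        w += config.capture_scale * frac_bound
    return w


def simulate_screen(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CountTable, list[ScreenSample], pd.DataFrame]:
    """Simulate per-well peptide counts.

    Returns (count table, sample sheet, truth table). The truth table
    records each planted binder's class. Byte-identical for a fixed seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    wells = config.wells or default_wells()
    planted = config.planted

    background = config.design.sample_peptides(config.library_size, rng)
    planted_set = {b.peptide for b in planted}
    background = [p for p in background if p not in planted_set]
    peptides = [b.peptide for b in planted] + background

    base_weights = np.full(len(peptides), config.baseline_weight)
    raw = {}
    spike_raw = {}
    n_spike = int(round(config.depth * config.spike_fraction))
    n_lib = config.depth - n_spike
    for well in wells:
        weights = base_weights.copy()
        for i, binder in enumerate(planted):
            weights[i] = _capture_weight(binder, well, config)
        probs = weights / weights.sum()
        raw[well.sample_id] = rng.multinomial(n_lib, probs)
        spike_raw[well.sample_id] = n_spike
    raw_df = pd.DataFrame(raw, index=pd.Index(peptides, name="peptide"))
    table = CountTable(
        raw=raw_df,
        spike_raw=pd.Series(spike_raw)[[w.sample_id for w in wells]],
        samples=wells,
        norm_scale=DEFAULT_NORM_SCALE,
    )
    truth = pd.DataFrame(
        {
            "peptide": [b.peptide for b in planted],
            "class": [
                "trimerizer" if b.is_trimerizer else ("bead" if b.bead_binder else "binary")
                for b in planted
            ],
            "k_target_nM": [b.k_target for b in planted],
            "k_presenter_nM": [b.k_presenter for b in planted],
            "alpha": [b.alpha for b in planted],
        }
    )
    return table, wells, truth


def spike_dna_for(design: LibraryDesignSpec) -> str:
    """Deterministic spike-in insert DNA for a design's insert length."""
    pep = {14: SPIKE_PEPTIDE_14, 20: SPIKE_PEPTIDE_20}.get(
        design.length, (("GKGS" * design.length)[: design.length])
    )
    return "".join(DEFAULT_CODON_TABLE[a] for a in pep)


def simulate_reads(
    table: CountTable,
    design: LibraryDesignSpec,
    out_dir: str | Path,
    error_rate: float = 0.0,
    qual: int = 35,
    rng: np.random.Generator | None = None,
) -> dict[str, Path]:
    """Write one FASTQ per sample re-encoding the count table as reads.

    Each peptide is reverse-encoded with the design codon rules and
    embedded in the constant flanks; spike counts become spike-in reads.
    With ``error_rate`` 0 the seq_io + quantify pipeline recovers the
    table exactly. Substitution errors are uniform per base; quality
    strings are constant at ``qual``.
    """
    rng = rng or np.random.default_rng(0)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spike_dna = spike_dna_for(design)
    paths: dict[str, Path] = {}
    bases = np.array(list("ACGT"))
    for sample in table.samples:
        sid = sample.sample_id
        path = out_dir / f"{sid}.fastq"
        with open(path, "w") as out:
            n = 0
            inserts = [(spike_dna, int(table.spike_raw[sid]))]
            inserts += [
                (design.encode_peptide(p), int(c))
                for p, c in table.raw[sid].items()
                if c > 0
            ]
            for insert, count in inserts:
                read_dna = design.flank5_dna + insert + design.flank3_dna
                for _ in range(count):
                    dna = read_dna
                    if error_rate > 0:
                        arr = np.array(list(dna))
                        hits = rng.random(len(arr)) < error_rate
                        if hits.any():
                            arr[hits] = bases[rng.integers(0, 4, size=int(hits.sum()))]
                            dna = "".join(arr)
                    n += 1
                    qline = chr(qual + 33) * len(dna)
                    out.write(f"@{sid}_{n}\n{dna}\n+\n{qline}\n")
        paths[sid] = path
    return paths


def write_sample_sheet(samples: list[ScreenSample], path: str | Path,
                       files: dict[str, Path] | None = None) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "file": str(files[s.sample_id]) if files else (s.file or ""),
                "bead": s.bead,
                "target": s.target or "",
                "target_conc_uM": s.target_conc if s.target_conc is not None else "",
                "presenter": s.presenter or "",
                "presenter_conc_uM": s.presenter_conc if s.presenter_conc is not None else "",
                "replicate": s.replicate,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def simulate_dose_response(
    doses: np.ndarray,
    a_total: float,
    t_total: float,
    k_ah: float,
    k_th: float,
    alpha: float,
    noise: float = 0.0,
    scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ternary-complex signal vs Helicon dose, plus Gaussian noise.

    alpha = 1 with strong binary arms reproduces the bell-shaped hook of
    a heterobifunctional chimera; large alpha gives a monotone
    dose-dependent increase over practical ranges.
    """
    doses = np.asarray(doses, dtype=float)
    signal = scale * ternary_signal(doses, a_total, t_total, k_ah, k_th, alpha)
    if noise > 0:
        rng = rng or np.random.default_rng(0)
        signal = signal + rng.normal(0.0, noise, size=signal.shape)
    return pd.DataFrame({"dose_nM": doses, "signal": signal})
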