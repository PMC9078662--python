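"""End-to-end screen processing: chromatograms in, ligand calls out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .chrom_model import Chromatogram, PeakTable, ScreenDesign, read_chromatogram
from .peakproc import (
    DEFAULT_MIN_SNR,
    DEFAULT_WINDOW,
    CompoundPanel,
    PeakAreaTriple,
    detect_peaks,
    match_peaks,
)
from .scoring import LigandCall, ScreenScore, score_screen

__all__ = ["ScreenResult", "process_screen", "load_screen_chromatograms"]


@dataclass(frozen=True)
class ScreenResult:
    """Everything the pipeline produces for one screen."""

    peak_tables: Mapping[str, PeakTable]
    triples: tuple[PeakAreaTriple, ...]
    scores: tuple[ScreenScore, ...]
    calls: tuple[LigandCall, ...]

    def score_of(self, compound_id: str) -> ScreenScore:
        return next(s for s in self.scores if s.compound_id == compound_id)

    def call_of(self, compound_id: str, target: str) -> LigandCall:
        return next(
            c for c in self.calls
            if c.compound_id == compound_id and c.target == target
        )


def process_screen(
    chromatograms: Mapping[str, Chromatogram],
    panel: CompoundPanel,
    design: ScreenDesign,
    min_snr: float = DEFAULT_MIN_SNR,
    window: float = DEFAULT_WINDOW,
) -> ScreenResult:
    """Detect, integrate, match and score a full three-condition screen."""
    tables = {
        run_id: detect_peaks(chrom, min_snr=min_snr, window=window)
        for run_id, chrom in chromatograms.items()
    }
    triples = match_peaks(list(tables.values()), panel, design)
    scores, calls = score_screen(triples, design)
    return ScreenResult(tables, tuple(triples), tuple(scores), tuple(calls))


def load_screen_chromatograms(
    design: ScreenDesign, base_dir: str | Path
) -> dict[str, Chromatogram]:
    """Read every chromatogram the design manifest points at, resolving
    relative paths against ``base_dir``."""
    base_dir = Path(base_dir)
    chroms = {}
    for run_id, group, ctl in design.runs:
        rel = design.chromatogram_paths.get(run_id, f"{run_id}.csv")
        path = Path(rel)
        if not path.is_absolute():
            path = base_dir / path
        chroms[run_id] = read_chromatogram(path, run_id, group, ctl)
    return chroms
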