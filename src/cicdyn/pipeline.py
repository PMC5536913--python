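"""End-to-end orchestration: kymograph -> decomposition -> events ->
Hill fit -> ensemble statistics -> genotype comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import (
    DivisionEvents,
    GenotypeEnsemble,
    align_at_13th_division,
    detect_division_dips,
)
from .compare import ComparisonResult, compare_all
from .config import AnalysisConfig
from .containers import SpaceTimeMatrix
from .hill import DegenerateProfileError, HillFit, fit_hill_anterior
from .separability import RankOneDecomposition, decompose


@dataclass
class EmbryoAnalysis:
    """Everything the tissue-level pipeline computes for one embryo."""

    decomposition: RankOneDecomposition
    events: DivisionEvents
    hill_fit: HillFit | None
    amplitude: np.ndarray  # plateau-scaled, intensity units
    times: np.ndarray
    cycle14_mean_amplitude: float

    def summary(self) -> dict:
        d = self.decomposition
        out = {
            "singular_values": d.singular_values[:10],
            "accuracy_ratio": d.accuracy_ratio,
            "dip_frames": self.events.dip_frames,
            "cycle14_mean_amplitude": self.cycle14_mean_amplitude,
        }
        if self.hill_fit is not None:
            out["lambda"] = self.hill_fit.lambda_half
            out["hill_coeff"] = self.hill_fit.hill_coeff
        return out


def analyze_embryo(
    stm: SpaceTimeMatrix, config: AnalysisConfig | None = None
) -> EmbryoAnalysis:
    """Tissue-level analysis of one kymograph."""
    from .alignment import cycle14_mean_amplitude

    cfg = config or AnalysisConfig()
    dec = decompose(stm)
    amp = dec.plateau_scaled_amplitude
    events = detect_division_dips(
        amp,
        stm.times,
        min_prominence=cfg.dip_prominence,
        smooth_window=cfg.dip_smooth_window,
    )
    try:
        hill_fit = fit_hill_anterior(
            dec.spatial_mode,
            stm.positions,
            lambda_bounds=cfg.lambda_bounds,
            n_bounds=cfg.hill_n_bounds,
        )
    except DegenerateProfileError:
        hill_fit = None
    c14 = cycle14_mean_amplitude(
        amp, stm.times, events, window_start=cfg.cycle14_window_start
    )
    return EmbryoAnalysis(
        decomposition=dec,
        events=events,
        hill_fit=hill_fit,
        amplitude=amp,
        times=stm.times,
        cycle14_mean_amplitude=c14,
    )


def build_genotype_ensemble(
    analyses: list[EmbryoAnalysis],
    genotype: str = "",
    config: AnalysisConfig | None = None,
) -> GenotypeEnsemble:
    """Align a genotype's embryos at the 13th division."""
    cfg = config or AnalysisConfig()
    members = [(a.amplitude, a.events) for a in analyses]
    times = [a.times for a in analyses]
    return align_at_13th_division(
        members,
        times=times,
        grid_step=cfg.grid_step,
        genotype=genotype,
        cycle14_window_start=cfg.cycle14_window_start,
    )


def compare_genotypes(
    analyses_by_genotype: dict[str, list[EmbryoAnalysis]],
    config: AnalysisConfig | None = None,
) -> list[ComparisonResult]:
    """Pairwise comparisons of cycle-14 amplitude and lambda."""
    cfg = config or AnalysisConfig()
    results: list[ComparisonResult] = []
    c14 = {
        g: np.array([a.cycle14_mean_amplitude for a in members])
        for g, members in analyses_by_genotype.items()
    }
    results += compare_all(
        c14, metric="cycle14_mean_amplitude", variance_mode=cfg.variance_mode
    )
    lam = {
        g: np.array(
            [a.hill_fit.lambda_half for a in members if a.hill_fit is not None]
        )
        for g, members in analyses_by_genotype.items()
    }
    if all(v.size >= 2 for v in lam.values()):
        results += compare_all(lam, metric="lambda", variance_mode=cfg.variance_mode)
    return results
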