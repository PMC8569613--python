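"""Scoring of contaminant reports against truth and the simulation benchmark.

Per-population rates (fractions in [0, 1], NaN when the denominator is 0):

``RH``   true hybrids called HP
``RC``   true contaminants (any category) called any contaminant class
``RAC``  true apomictic clones called AC of the correct parent
``RSP``  true selfed progeny called SP of the correct parent
``RCC``  true half-sibs and full contaminants called HSFC

Means over replicate populations give MRH/MRC/MRAC/MRSP/MRCC; populations
lacking a category contribute nothing to that category's mean. The benchmark
sweep reproduces the study design: shared marker universe and parent
quartet, replicate populations of 200 individuals with 1..50 contaminants
split over {AC_P1, SP_P1, HS1, HS2, FC} by random type probabilities, random
marker subsets of fixed sizes, detection with the top-ranked or best-of-three
clustering schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import simulate as sim
from .detect import ContaminantReport, detect_contaminants
from .io_core import TruthLabels

__all__ = ["EvaluationSummary", "score_report", "run_benchmark"]

RATE_COLUMNS = ("RH", "RC", "RAC", "RSP", "RCC")
MEAN_RATE_COLUMNS = ("MRH", "MRC", "MRAC", "MRSP", "MRCC")


def score_report(report: ContaminantReport, truth: TruthLabels) -> dict[str, float]:
    """Per-population identification rates of a report against truth labels."""
    truth_l = truth.labels
    ids = report.calls.index
    if set(ids) != set(truth_l.index):
        raise ValueError("report and truth labels cover different individuals")
    calls = report.calls
    t = truth_l.reindex(ids)

    def rate(mask: pd.Series, correct: pd.Series) -> float:
        n = int(mask.sum())
        return float((mask & correct).sum() / n) if n else float("nan")

    is_hyb = t == "HP"
    is_cont = ~is_hyb
    called_cont = calls != "HP"
    is_ac = t.isin(("AC_P1", "AC_P2"))
    is_sp = t.isin(("SP_P1", "SP_P2"))
    is_cc = t.isin(("HS", "FC"))
    return {
        "RH": rate(is_hyb, calls == "HP"),
        "RC": rate(is_cont, called_cont),
        "RAC": rate(is_ac, calls == t),
        "RSP": rate(is_sp, calls == t),
        "RCC": rate(is_cc, calls == "HSFC"),
    }


@dataclass(frozen=True)
class EvaluationSummary:
    """Benchmark outcome: per-population raw rates plus aggregated means."""

    per_population: pd.DataFrame  # columns: size, population, rank, RH..RCC
    seed: int
    mode: str  # "top1" or "best_of_3"

    def rates(self, mode: str | None = None) -> pd.DataFrame:
        """Mean rates per marker-set size under the given scheme mode."""
        mode = mode or self.mode
        df = self.per_population
        if mode == "top1":
            per_pop = df[df["rank"] == 1].set_index(["size", "population"])[list(RATE_COLUMNS)]
        elif mode == "best_of_3":
            per_pop = df.groupby(["size", "population"])[list(RATE_COLUMNS)].max()
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out = per_pop.groupby(level="size").mean()
        out.columns = list(MEAN_RATE_COLUMNS)
        return out.sort_index(ascending=False)

    @property
    def summary(self) -> pd.DataFrame:
        return self.rates()


def run_benchmark(
    n_populations: int,
    marker_set_sizes: tuple[int, ...],
    mode: str = "top1",
    seed: int = 0,
    ploidy: int = 4,
    population_size: int = 200,
    threshold: float = 0.75,
    n_schemes: int = 3,
    progress: bool = False,
) -> EvaluationSummary:
    """Simulate, detect and score replicate populations per marker-set size.

    One genetic map and parent quartet (made-up default dosage profiles) are
    shared by all populations; each population draws its own composition,
    marker subset, meiosis, errors and missingness. Schemes ranked 1..
    ``n_schemes`` are each scored so both top-1 and best-of-3 aggregation can
    be read from the same run. Fully reproducible from ``seed``.
    """
    if mode not in ("top1", "best_of_3"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    gmap = sim.build_genetic_map(rng)
    if max(marker_set_sizes) > gmap.n_markers:
        raise ValueError(
            f"marker-set size {max(marker_set_sizes)} exceeds the "
            f"{gmap.n_markers} simulated markers"
        )
    parents = {
        pid: sim.simulate_parent(gmap, sim.default_dosage_rates(ploidy, pid), ploidy, rng)
        for pid in ("P1", "P2", "P3", "P4")
    }
    rows = []
    for size in marker_set_sizes:
        for pop in range(n_populations):
            sub_map, sub_parents = sim.subsample_map(gmap, parents, size, rng)
            spec = sim.benchmark_scenario(rng, population_size=population_size)
            matrix, truth = sim.build_population(spec, sub_map, sub_parents, rng)
            reports = detect_contaminants(matrix, threshold=threshold, n_schemes=n_schemes)
            for report in reports:
                rates = score_report(report, truth)
                rows.append({"size": size, "population": pop, "rank": report.scheme.rank, **rates})
        if progress:
            print(f"benchmark: finished {n_populations} populations at {size} markers")
    per_population = pd.DataFrame(rows)
    return EvaluationSummary(per_population=per_population, seed=seed, mode=mode)
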