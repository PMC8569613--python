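"""Simulation of polyploid biparental populations with controlled contamination.

The generator builds a multi-chromosome genetic map, phases parents from
per-dosage frequency profiles, simulates meiosis (random bivalent pairing,
Poisson crossovers under the Haldane model, no interference, no double
reduction), crosses parents, clones them, and injects genotyping error and
per-marker missingness. Contamination categories:

``HP``     true hybrid, P1 x P2
``AC_P1``  apomictic clone of P1 (``AC_P2`` of P2)
``SP_P1``  self-fertilization progeny, P1 x P1 (``SP_P2`` for P2)
``HS1``    half-sibling, P1 x P3 (foreign pollen donor P3)
``HS2``    half-sibling, P1 x P4
``FC``     full contaminant, P3 x P4 (seed admixture, unrelated to the cross)

All randomness flows through a caller-supplied ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import DosageMatrix, TruthLabels

__all__ = [
    "GeneticMap",
    "PhasedParent",
    "ScenarioSpec",
    "build_genetic_map",
    "default_dosage_rates",
    "simulate_parent",
    "make_gamete",
    "cross",
    "clone",
    "inject_errors",
    "inject_missing",
    "build_population",
    "benchmark_scenario",
    "subsample_markers",
    "subsample_map",
]

MIN_SPACING_CM = 0.1


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions (cM) on each chromosome; centromeres are metadata."""

    lengths: tuple[float, ...]  # chromosome lengths in cM
    positions: tuple[np.ndarray, ...]  # sorted marker positions per chromosome
    centromeres: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.positions) or len(self.lengths) != len(self.centromeres):
            raise ValueError("lengths, positions and centromeres must align per chromosome")
        for L, pos in zip(self.lengths, self.positions):
            if pos.size and (pos.min() < 0 or pos.max() > L):
                raise ValueError("marker position outside chromosome")
            if pos.size > 1 and np.diff(pos).min() < MIN_SPACING_CM - 1e-9:
                raise ValueError(f"adjacent markers closer than {MIN_SPACING_CM} cM")

    @property
    def n_chromosomes(self) -> int:
        return len(self.lengths)

    @property
    def n_markers(self) -> int:
        return int(sum(p.size for p in self.positions))

    @property
    def marker_ids(self) -> list[str]:
        return [
            f"c{c + 1:02d}_m{i + 1:04d}"
            for c, pos in enumerate(self.positions)
            for i in range(pos.size)
        ]

    @property
    def chrom_slices(self) -> list[slice]:
        """Column slices of the concatenated marker axis, one per chromosome."""
        out, start = [], 0
        for pos in self.positions:
            out.append(slice(start, start + pos.size))
            start += pos.size
        return out


@dataclass(frozen=True)
class PhasedParent:
    """A parent as ``ploidy`` binary haplotypes over all map markers."""

    haplotypes: np.ndarray  # (ploidy, n_markers) of 0/1

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotypes must be (even ploidy, n_markers)")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be binary")

    @property
    def ploidy(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)


@dataclass(frozen=True)
class ScenarioSpec:
    """Population composition plus the error/missingness model.

    Defaults mirror the study conditions used throughout: 5% uniform dosage
    replacement error and a per-marker missing rate drawn from [1%, 5%].
    """

    counts: dict = field(
        default_factory=lambda: {"HP": 200}
    )  # category -> individuals; categories as in the module docstring
    error_rate: float = 0.05
    missing_range: tuple[float, float] = (0.01, 0.05)

    CATEGORIES = ("HP", "AC_P1", "AC_P2", "SP_P1", "SP_P2", "HS1", "HS2", "FC")

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(self.CATEGORIES)
        if unknown:
            raise ValueError(f"unknown scenario categories: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("scenario counts must be non-negative")
        if self.total < 1:
            raise ValueError("scenario must contain at least one individual")
        if not 0 <= self.error_rate < 1:
            raise ValueError(f"error rate must be in [0, 1), got {self.error_rate}")
        lo, hi = self.missing_range
        if not 0 <= lo <= hi < 1:
            raise ValueError(f"invalid missing range {self.missing_range}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def build_genetic_map(
    rng: np.random.Generator,
    n_chromosomes: int = 8,
    length_range: tuple[float, float] = (90.0, 120.0),
    markers_per_chrom_range: tuple[int, int] = (600, 900),
    centromere_range: tuple[float, float] = (10.0, 50.0),
) -> GeneticMap:
    """Sample a genetic map: chromosome lengths, marker positions, centromeres.

    Positions are drawn without replacement from the 0.1-cM lattice of each
    chromosome, which enforces the minimum adjacent-marker spacing by
    construction.
    """
    lo_m, hi_m = markers_per_chrom_range
    lo_L, hi_L = length_range
    if lo_m > hi_m or lo_L > hi_L or lo_m < 1:
        raise ValueError("empty length or marker-count range")
    if lo_L <= 0:
        raise ValueError("chromosome length must be positive")
    lengths, positions, centromeres = [], [], []
    for _ in range(n_chromosomes):
        L = float(rng.uniform(lo_L, hi_L))
        m = int(rng.integers(lo_m, hi_m + 1))
        lattice = np.arange(0.0, L + 1e-9, MIN_SPACING_CM)
        if m > lattice.size:
            raise ValueError(
                f"{m} markers cannot fit on a {L:.1f} cM chromosome "
                f"at {MIN_SPACING_CM} cM minimum spacing"
            )
        pos = np.sort(rng.choice(lattice, size=m, replace=False))
        lengths.append(L)
        positions.append(pos)
        centromeres.append(float(rng.uniform(*centromere_range)))
    return GeneticMap(tuple(lengths), tuple(positions), tuple(centromeres))


# Made-up per-parent dosage spectra (fraction of markers at dosage 0..ploidy).
# P1/P2 play the crossing parents (one species); P3/P4 play unrelated foreign
# founders of a different species, so their spectra are deliberately and
# clearly distinct — different real genotypes, let alone different species,
# have genuinely different dosage spectra, and that distinctness is what
# makes half-sib families fathered by P3 vs P4 different populations.
# Override freely via simulate_parent(dosage_rates=...).
_TETRA_PRESETS = {
    "P1": (0.32, 0.30, 0.20, 0.12, 0.06),
    "P2": (0.38, 0.28, 0.18, 0.10, 0.06),
    "P3": (0.20, 0.34, 0.24, 0.14, 0.08),
    "P4": (0.42, 0.22, 0.18, 0.11, 0.07),
}
_HEXA_PRESETS = {
    "P1": (0.30, 0.25, 0.17, 0.12, 0.08, 0.05, 0.03),
    "P2": (0.36, 0.24, 0.15, 0.11, 0.07, 0.05, 0.02),
    "P3": (0.20, 0.30, 0.20, 0.14, 0.09, 0.05, 0.02),
    "P4": (0.40, 0.20, 0.16, 0.11, 0.07, 0.04, 0.02),
}


def default_dosage_rates(ploidy: int, parent: str = "P1") -> np.ndarray:
    """Default allele-dosage frequency profile for one of the four parents."""
    presets = {4: _TETRA_PRESETS, 6: _HEXA_PRESETS}.get(ploidy)
    if presets is None:
        raise ValueError(f"no default profiles for ploidy {ploidy}")
    if parent not in presets:
        raise ValueError(f"parent must be one of {sorted(presets)}, got {parent!r}")
    return np.asarray(presets[parent], dtype=float)


def simulate_parent(
    gmap: GeneticMap,
    dosage_rates: np.ndarray,
    ploidy: int,
    rng: np.random.Generator,
) -> PhasedParent:
    """Phase a parent: draw a dosage per marker, place alleles on homologs.

    The per-marker dosage d is drawn from ``dosage_rates`` (a probability
    vector over 0..ploidy); the d alternate alleles are assigned to d
    distinct homologs chosen uniformly.
    """
    rates = np.asarray(dosage_rates, dtype=float)
    if rates.size != ploidy + 1:
        raise ValueError(f"dosage_rates must have length ploidy+1={ploidy + 1}, got {rates.size}")
    if abs(rates.sum() - 1.0) > 1e-9 or (rates < 0).any():
        raise ValueError("dosage_rates must be a probability vector summing to 1")
    m = gmap.n_markers
    dosages = rng.choice(ploidy + 1, size=m, p=rates)
    # place d alleles on d random homologs per marker: rank ploidy uniforms
    ranks = rng.random((ploidy, m)).argsort(axis=0)
    haplo = (ranks < dosages).astype(np.uint8)
    return PhasedParent(haplo)


def make_gamete(parent: PhasedParent, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """Simulate one meiosis: return ``ploidy/2`` recombinant haplotypes.

    Per chromosome, homologs are paired uniformly at random into bivalents.
    The chromatid transmitted from each bivalent follows one homolog and
    switches to the other at the points of a Poisson process of rate 1 per
    Morgan — the Haldane (no-interference) model, so the recombination
    fraction between loci d Morgans apart is (1 - e^(-2d))/2. No double
    reduction.
    """
    p = parent.ploidy
    half = p // 2
    out = np.empty((half, parent.n_markers), dtype=np.uint8)
    for ci, (sl, L) in enumerate(zip(gmap.chrom_slices, gmap.lengths)):
        pos = gmap.positions[ci]
        pairing = rng.permutation(p)
        for b in range(half):
            h_a, h_b = pairing[2 * b], pairing[2 * b + 1]
            n_switch = rng.poisson(L / 100.0)
            current = int(rng.integers(2))
            if n_switch == 0:
                src = h_a if current == 0 else h_b
                out[b, sl] = parent.haplotypes[src, sl]
                continue
            switches = np.sort(rng.uniform(0.0, L, size=n_switch))
            parity = (np.searchsorted(switches, pos, side="right") + current) % 2
            hap_pair = parent.haplotypes[(h_a, h_b), sl]
            out[b, sl] = hap_pair[parity, np.arange(pos.size)]
    return out


def cross(
    p1: PhasedParent,
    p2: PhasedParent,
    n: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    id_prefix: str = "ind",
) -> pd.DataFrame:
    """Cross two parents: n progeny dosage rows (gamete(p1) + gamete(p2))."""
    if p1.ploidy != p2.ploidy:
        raise ValueError("parents must share ploidy")
    if p1.n_markers != p2.n_markers or p1.n_markers != gmap.n_markers:
        raise ValueError("parents and map must cover the same markers")
    rows = np.empty((n, gmap.n_markers), dtype=np.int16)
    for i in range(n):
        rows[i] = make_gamete(p1, gmap, rng).sum(axis=0) + make_gamete(p2, gmap, rng).sum(axis=0)
    ids = [f"{id_prefix}{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(rows, index=ids, columns=gmap.marker_ids, dtype=float)


def clone(parent: PhasedParent) -> np.ndarray:
    """Apomictic clone: an exact copy of the parent's dosage vector."""
    return parent.dosage.astype(float).copy()


def inject_errors(matrix: DosageMatrix, rate: float, rng: np.random.Generator) -> DosageMatrix:
    """Replace each non-missing progeny dosage, with probability ``rate``,
    by one of the other ``ploidy`` valid dosages (uniformly; never its own
    value, never missing). Parent rows are left untouched — they serve as
    error-free references.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"error rate must be in [0, 1), got {rate}")
    if rate == 0:
        return matrix
    df = matrix.data.copy()
    prog = [i for i in matrix.individual_ids if i not in (matrix.parent1, matrix.parent2)]
    vals = df.loc[prog].to_numpy(dtype=float)
    hit = (~np.isnan(vals)) & (rng.random(vals.shape) < rate)
    # uniform over the ploidy other dosages: draw 0..ploidy-1, bump past own value
    draw = rng.integers(0, matrix.ploidy, size=int(hit.sum())).astype(float)
    own = vals[hit]
    vals[hit] = np.where(draw >= own, draw + 1, draw)
    df.loc[prog] = vals
    return matrix.with_data(df)


def inject_missing(
    matrix: DosageMatrix,
    per_marker_range: tuple[float, float],
    rng: np.random.Generator,
) -> DosageMatrix:
    """Per marker, draw u ~ Uniform(lo, hi) and blank ``round(u * n_progeny)``
    progeny cells chosen without replacement. Parents stay fully observed.
    """
    lo, hi = per_marker_range
    if not 0 <= lo <= hi < 1:
        raise ValueError(f"invalid missing range {per_marker_range}")
    if hi == 0:
        return matrix
    df = matrix.data.copy()
    prog = [i for i in matrix.individual_ids if i not in (matrix.parent1, matrix.parent2)]
    vals = df.loc[prog].to_numpy(dtype=float)
    n = len(prog)
    rates = rng.uniform(lo, hi, size=vals.shape[1])
    counts = np.round(rates * n).astype(int)
    for j, k in enumerate(counts):
        if k:
            vals[rng.choice(n, size=k, replace=False), j] = np.nan
    df.loc[prog] = vals
    return matrix.with_data(df)


_CATEGORY_LABEL = {
    "HP": "HP", "AC_P1": "AC_P1", "AC_P2": "AC_P2", "SP_P1": "SP_P1",
    "SP_P2": "SP_P2", "HS1": "HS", "HS2": "HS", "FC": "FC",
}
_CATEGORY_CROSS = {
    "HP": ("P1", "P2"), "SP_P1": ("P1", "P1"), "SP_P2": ("P2", "P2"),
    "HS1": ("P1", "P3"), "HS2": ("P1", "P4"), "FC": ("P3", "P4"),
}


def build_population(
    spec: ScenarioSpec,
    gmap: GeneticMap,
    parents: dict[str, PhasedParent],
    rng: np.random.Generator,
) -> tuple[DosageMatrix, TruthLabels]:
    """Assemble a contaminated biparental population per the scenario.

    ``parents`` maps "P1".."P4" to phased parents (P3/P4 only required when
    half-sib or full-contaminant categories are requested). The emitted
    matrix holds error-free P1 and P2 rows as designated parents; errors and
    missingness are injected into progeny/contaminant rows only.
    """
    for cat, n in spec.counts.items():
        if n == 0:
            continue
        needed = {"AC_P1": ("P1",), "AC_P2": ("P2",)}.get(cat) or _CATEGORY_CROSS[cat]
        for pid in set(needed) | {"P1", "P2"}:
            if pid not in parents:
                raise ValueError(f"scenario requires parent {pid} (category {cat})")
    ploidy = parents["P1"].ploidy
    blocks, ids, labels, origins = [], [], [], []
    for cat in ScenarioSpec.CATEGORIES:
        n = spec.counts.get(cat, 0)
        if n == 0:
            continue
        if cat.startswith("AC"):
            src = parents[cat.split("_")[1]]
            block = np.tile(clone(src), (n, 1))
            origin = f"clone({cat.split('_')[1]})"
        else:
            a, b = _CATEGORY_CROSS[cat]
            block = cross(parents[a], parents[b], n, gmap, rng).to_numpy()
            origin = f"{a}x{b}"
        blocks.append(block)
        ids.extend(f"{cat}_{i + 1:03d}" for i in range(n))
        labels.extend([_CATEGORY_LABEL[cat]] * n)
        origins.extend([origin] * n)
    prog = pd.DataFrame(np.vstack(blocks), index=ids, columns=gmap.marker_ids, dtype=float)
    top = pd.DataFrame(
        np.vstack([parents["P1"].dosage, parents["P2"].dosage]).astype(float),
        index=["P1", "P2"],
        columns=gmap.marker_ids,
    )
    matrix = DosageMatrix(pd.concat([top, prog]), ploidy=ploidy, parent1="P1", parent2="P2")
    matrix = inject_errors(matrix, spec.error_rate, rng)
    matrix = inject_missing(matrix, spec.missing_range, rng)
    truth = TruthLabels(
        pd.Series(labels, index=ids, name="label"),
        pd.Series(origins, index=ids, name="origin"),
    )
    return matrix, truth


def benchmark_scenario(
    rng: np.random.Generator,
    population_size: int = 200,
    contaminant_range: tuple[int, int] = (1, 50),
    type_prob_range: tuple[float, float] = (0.1, 0.8),
) -> ScenarioSpec:
    """Draw one benchmark composition: a uniform contaminant count split over
    {AC_P1, SP_P1, HS1, HS2, FC} by normalized random type probabilities,
    rounded to integers by largest remainder; the rest are true hybrids.
    """
    lo, hi = contaminant_range
    hi = min(hi, population_size // 2)  # small test populations stay viable
    c = int(rng.integers(lo, hi + 1))
    types = ("AC_P1", "SP_P1", "HS1", "HS2", "FC")
    probs = rng.uniform(*type_prob_range, size=len(types))
    shares = probs / probs.sum() * c
    base = np.floor(shares).astype(int)
    short = c - base.sum()
    if short:
        base[np.argsort(shares - base)[::-1][:short]] += 1
    counts = {"HP": population_size - c}
    counts.update({t: int(k) for t, k in zip(types, base) if k > 0})
    return ScenarioSpec(counts=counts)


def subsample_markers(matrix: DosageMatrix, n_markers: int, rng: np.random.Generator) -> DosageMatrix:
    """Uniform sample of markers without replacement; individuals unchanged."""
    if n_markers > matrix.n_markers:
        raise ValueError(f"cannot sample {n_markers} of {matrix.n_markers} markers")
    keep = np.sort(rng.choice(matrix.n_markers, size=n_markers, replace=False))
    return matrix.with_data(matrix.data.iloc[:, keep])


def subsample_map(
    gmap: GeneticMap, parents: dict[str, PhasedParent], n_markers: int, rng: np.random.Generator
) -> tuple[GeneticMap, dict[str, PhasedParent]]:
    """Restrict a map and its phased parents to a uniform marker subsample.

    Simulating meiosis on the restricted map is distributionally identical to
    simulating on the full map and dropping columns afterwards, because a
    gamete's alleles at a marker subset depend only on the positions of that
    subset.
    """
    total = gmap.n_markers
    if n_markers > total:
        raise ValueError(f"cannot sample {n_markers} of {total} markers")
    keep = np.zeros(total, dtype=bool)
    keep[rng.choice(total, size=n_markers, replace=False)] = True
    new_pos = []
    for sl, pos in zip(gmap.chrom_slices, gmap.positions):
        new_pos.append(pos[keep[sl]])
    sub_map = GeneticMap(gmap.lengths, tuple(new_pos), gmap.centromeres)
    sub_parents = {k: PhasedParent(p.haplotypes[:, keep]) for k, p in parents.items()}
    return sub_map, sub_parents
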