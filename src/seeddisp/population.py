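"""Core in-memory containers: study windows, mapped individuals, populations.

Coordinates are metres in a planar, site-local frame.  Genotypes are diploid
multilocus microsatellite profiles; the two alleles of a genotype are
unordered and missing data is encoded as ``-9`` (both allele slots).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

MISSING = -9

#: dbh thresholds (cm) separating the three census cohorts
SMALL_SAPLING_MAX_DBH = 5.0
ADULT_MIN_DBH = 10.0

COHORTS = ("small_sapling", "large_sapling", "adult")
SEXES = ("female", "male", "unknown")


def cohort_from_dbh(dbh: float) -> str:
    """Cohort label from stem diameter: <5 cm small sapling, 5-10 large, >=10 adult."""
    if dbh < SMALL_SAPLING_MAX_DBH:
        return "small_sapling"
    if dbh < ADULT_MIN_DBH:
        return "large_sapling"
    return "adult"


class DegenerateWindowError(ValueError):
    """Raised when a window has no usable area."""


@dataclass(frozen=True)
class StudyWindow:
    """Planar observation window: an outer polygon minus exclusion holes.

    Holes represent surveyed but unsuitable terrain (swamps, rocky outcrops,
    farmland) that must not contribute area to intensity estimates or receive
    simulated points.
    """

    polygon: Polygon

    def __post_init__(self) -> None:
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise DegenerateWindowError("window has zero usable area")

    @classmethod
    def rectangle(cls, width: float, height: float,
                  holes: Sequence[Sequence[tuple[float, float]]] = ()) -> "StudyWindow":
        shell = [(0, 0), (width, 0), (width, height), (0, height)]
        return cls(Polygon(shell, holes=[list(h) for h in holes]))

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised point-in-window test."""
        return shapely.contains_xy(self.polygon, np.asarray(x, float), np.asarray(y, float))

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the window by rejection from the bounding box."""
        if self.area <= 0:
            raise DegenerateWindowError("cannot sample from an empty window")
        xmin, ymin, xmax, ymax = self.bounds
        out = np.empty((0, 2))
        while len(out) < n:
            m = max(64, int(1.5 * (n - len(out)) * (xmax - xmin) * (ymax - ymin)
                            / max(self.area, 1e-12)))
            xs = rng.uniform(xmin, xmax, m)
            ys = rng.uniform(ymin, ymax, m)
            keep = self.contains(xs, ys)
            out = np.vstack([out, np.column_stack([xs[keep], ys[keep]])])
        return out[:n]

    def grid_quadrature(self, step: float) -> tuple[np.ndarray, float]:
        """Centres of grid cells whose centre lies inside the window.

        Returns (centres (m,2), cell_area).  Used for kernel-mass edge
        corrections and intensity integrals.  Cached per step.
        """
        cache = self.__dict__.setdefault("_grid_cache", {})
        if step in cache:
            return cache[step]
        xmin, ymin, xmax, ymax = self.bounds
        xs = np.arange(xmin + step / 2, xmax, step)
        ys = np.arange(ymin + step / 2, ymax, step)
        gx, gy = np.meshgrid(xs, ys)
        gx, gy = gx.ravel(), gy.ravel()
        keep = self.contains(gx, gy)
        out = (np.column_stack([gx[keep], gy[keep]]), step * step)
        cache[step] = out
        return out


@dataclass
class MappedIndividual:
    """One mapped tree, sapling, seed or seedling."""

    id: str
    x: float
    y: float
    cohort: str = "adult"
    sex: str = "unknown"
    dbh: float = float("nan")
    #: locus name -> (allele, allele) integer labels, or None when missing
    genotype: dict[str, tuple[int, int] | None] = field(default_factory=dict)


class Population:
    """Column-oriented container for a set of mapped, genotyped individuals.

    Genotypes are stored as an integer array of shape ``(n, n_loci, 2)`` of
    allele labels with ``-9`` for missing; allele order within an individual
    carries no meaning.
    """

    def __init__(self, ids: Sequence[str], xy: np.ndarray,
                 cohort: Sequence[str], sex: Sequence[str], dbh: Sequence[float],
                 loci: Sequence[str], genotypes: np.ndarray | None = None):
        n = len(ids)
        if len(set(ids)) != n:
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            raise ValueError(f"duplicate individual ids: {dupes}")
        self.ids = list(map(str, ids))
        self.xy = np.asarray(xy, float).reshape(n, 2)
        self.cohort = np.asarray(cohort, object)
        self.sex = np.asarray(sex, object)
        self.dbh = np.asarray(dbh, float)
        self.loci = list(loci)
        if genotypes is None:
            genotypes = np.full((n, len(self.loci), 2), MISSING, int)
        self.genotypes = np.asarray(genotypes, int).reshape(n, len(self.loci), 2)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """(n, n_loci) boolean mask, True where a genotype is missing."""
        return (self.genotypes == MISSING).any(axis=2)

    def subset(self, index: np.ndarray | Sequence[int]) -> "Population":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Population([self.ids[i] for i in idx], self.xy[idx],
                          self.cohort[idx], self.sex[idx], self.dbh[idx],
                          self.loci, self.genotypes[idx])

    def by_cohort(self, cohort: str) -> "Population":
        return self.subset(self.cohort == cohort)

    # -- conversions ---------------------------------------------------------

    @classmethod
    def from_individuals(cls, individuals: Iterable[MappedIndividual],
                         loci: Sequence[str] | None = None) -> "Population":
        inds = list(individuals)
        if loci is None:
            seen: dict[str, None] = {}
            for ind in inds:
                for loc in ind.genotype:
                    seen.setdefault(loc, None)
            loci = list(seen)
        geno = np.full((len(inds), len(loci), 2), MISSING, int)
        for i, ind in enumerate(inds):
            for l, loc in enumerate(loci):
                g = ind.genotype.get(loc)
                if g is not None:
                    geno[i, l] = g
        return cls([i.id for i in inds], np.array([[i.x, i.y] for i in inds]).reshape(len(inds), 2),
                   [i.cohort for i in inds], [i.sex for i in inds],
                   [i.dbh for i in inds], loci, geno)

    def to_individuals(self) -> list[MappedIndividual]:
        out = []
        miss = self.missing_mask()
        for i in range(len(self)):
            geno = {loc: (None if miss[i, l] else (int(self.genotypes[i, l, 0]),
                                                   int(self.genotypes[i, l, 1])))
                    for l, loc in enumerate(self.loci)}
            out.append(MappedIndividual(self.ids[i], float(self.xy[i, 0]), float(self.xy[i, 1]),
                                        str(self.cohort[i]), str(self.sex[i]),
                                        float(self.dbh[i]), geno))
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "x": self.xy[:, 0], "y": self.xy[:, 1],
                           "cohort": self.cohort, "sex": self.sex, "dbh": self.dbh})
        for l, loc in enumerate(self.loci):
            df[loc] = [f"{a}/{b}" for a, b in self.genotypes[:, l, :]]
        return df


def as_population(data: "Population | Iterable[MappedIndividual]") -> Population:
    """Accept either a Population or an iterable of MappedIndividual."""
    if isinstance(data, Population):
        return data
    return Population.from_individuals(data)


@dataclass
class AlleleFrequencyTable:
    """Per-locus reference allele frequencies and gene sample sizes.

    ``freqs[locus]`` maps allele label -> frequency (summing to one);
    ``n_genes[locus]`` is the number of sampled gene copies behind the
    estimate (2x genotyped individuals).
    """

    freqs: dict[str, dict[int, float]]
    n_genes: dict[str, int]

    def __post_init__(self) -> None:
        for locus, f in self.freqs.items():
            total = sum(f.values())
            if not np.isclose(total, 1.0, atol=1e-8):
                raise ValueError(f"frequencies at locus {locus} sum to {total}, not 1")
            if any(v < 0 for v in f.values()):
                raise ValueError(f"negative frequency at locus {locus}")

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    def alleles(self, locus: str) -> np.ndarray:
        return np.array(sorted(self.freqs[locus]))

    def freq_array(self, locus: str) -> np.ndarray:
        al = self.alleles(locus)
        return np.array([self.freqs[locus][a] for a in al])

    def expected_heterozygosity(self, locus: str, unbiased: bool = False) -> float:
        p = self.freq_array(locus)
        he = 1.0 - float(np.sum(p ** 2))
        if unbiased:
            n = self.n_genes[locus]
            if n > 1:
                he *= n / (n - 1)
        return he
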