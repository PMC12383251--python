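"""Reading and writing mapped-genotype datasets.

Population tables are CSV with columns ``id, x, y, cohort, sex, dbh`` plus one
column per microsatellite locus holding ``allele1/allele2`` (missing:
``-9/-9``).  Observation windows are GeoJSON polygons (holes = excluded
terrain).  A GenePop exporter is provided for interoperability with standard
population-genetics software.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .population import (MISSING, AlleleFrequencyTable, Population, StudyWindow,
                         as_population)

METADATA_COLUMNS = ["id", "x", "y", "cohort", "sex", "dbh"]


class PopulationParseError(ValueError):
    pass


def write_population(pop: Population | Sequence, path: str | Path) -> None:
    as_population(pop).to_frame().to_csv(path, index=False)


def read_population(table_path: str | Path,
                    window_path: str | Path | None = None
                    ) -> tuple[Population, StudyWindow | None]:
    """Read a population CSV (and optionally its GeoJSON window).

    Locus columns are all columns beyond the fixed metadata block; malformed
    allele pairs raise a parse error naming the row and locus.  Coordinates
    outside the window are retained with a warning (immigrant true parents may
    legitimately lie outside).
    """
    df = pd.read_csv(table_path, dtype={"id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PopulationParseError(f"missing columns: {missing_cols}")
    loci = [c for c in df.columns if c not in METADATA_COLUMNS]
    if df["id"].duplicated().any():
        raise PopulationParseError(
            f"duplicate ids: {df['id'][df['id'].duplicated()].tolist()}")

    geno = np.full((len(df), len(loci), 2), MISSING, int)
    for l, locus in enumerate(loci):
        for i, cell in enumerate(df[locus].astype(str)):
            parts = cell.strip().split("/")
            try:
                a, b = int(parts[0]), int(parts[1])
            except (ValueError, IndexError):
                raise PopulationParseError(
                    f"malformed allele pair {cell!r} at row {i} (id {df['id'][i]}), "
                    f"locus {locus}") from None
            if a == MISSING or b == MISSING:
                a = b = MISSING
            geno[i, l] = (a, b)

    pop = Population(df["id"].tolist(), df[["x", "y"]].to_numpy(float),
                     df["cohort"].tolist(), df["sex"].tolist(),
                     df["dbh"].to_numpy(float), loci, geno)
    window = None
    if window_path is not None:
        window = read_window(window_path)
        inside = window.contains(pop.xy[:, 0], pop.xy[:, 1])
        if not inside.all():
            warnings.warn(f"{(~inside).sum()} individuals lie outside the window; "
                          "retained", stacklevel=2)
    return pop, window


def write_window(window: StudyWindow, path: str | Path) -> None:
    geo = {"type": "Feature", "properties": {"area_m2": window.area},
           "geometry": mapping(window.polygon)}
    Path(path).write_text(json.dumps(geo))


def read_window(path: str | Path) -> StudyWindow:
    geo = json.loads(Path(path).read_text())
    if geo.get("type") == "Feature":
        geo = geo["geometry"]
    elif geo.get("type") == "FeatureCollection":
        geo = geo["features"][0]["geometry"]
    return StudyWindow(shape(geo))


# ---------------------------------------------------------------------------
# allele frequencies and locus summaries


def estimate_allele_frequencies(individuals, cohort: str | None = None
                                ) -> AlleleFrequencyTable:
    """Allele frequencies by direct counting (missing genotypes excluded).

    ``n_genes`` per locus is the number of non-missing gene copies.  Loci with
    no data are dropped with a warning.
    """
    pop = as_population(individuals)
    if cohort is not None:
        pop = pop.by_cohort(cohort)
    freqs: dict[str, dict[int, float]] = {}
    n_genes: dict[str, int] = {}
    for l, locus in enumerate(pop.loci):
        alleles = pop.genotypes[:, l, :].ravel()
        alleles = alleles[alleles != MISSING]
        if len(alleles) == 0:
            warnings.warn(f"locus {locus} has no data; excluded", stacklevel=2)
            continue
        vals, counts = np.unique(alleles, return_counts=True)
        freqs[locus] = {int(a): float(c) / len(alleles) for a, c in zip(vals, counts)}
        n_genes[locus] = int(len(alleles))
    return AlleleFrequencyTable(freqs, n_genes)


def locus_summary(individuals) -> pd.DataFrame:
    """Per-locus allele count, observed and (unbiased) expected heterozygosity.

    He uses Nei's small-sample correction n/(n-1) with n the number of
    sampled gene copies; monomorphic loci get He = 0 and are flagged.
    """
    pop = as_population(individuals)
    afreq = estimate_allele_frequencies(pop)
    rows = []
    for l, locus in enumerate(pop.loci):
        if locus not in afreq.freqs:
            continue
        g = pop.genotypes[:, l, :]
        ok = (g != MISSING).all(axis=1)
        ho = float((g[ok, 0] != g[ok, 1]).mean()) if ok.any() else np.nan
        he = afreq.expected_heterozygosity(locus, unbiased=True)
        rows.append(dict(locus=locus, n_alleles=len(afreq.freqs[locus]),
                         n_genes=afreq.n_genes[locus], Ho=ho, He=he,
                         monomorphic=len(afreq.freqs[locus]) == 1))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GenePop export


def write_genepop(individuals, path: str | Path, title: str = "seeddisp export",
                  pop_labels: Sequence[str] | None = None) -> None:
    """Write genotypes in GenePop format (3-digit allele codes, 0 = missing).

    ``pop_labels`` optionally splits individuals into GenePop POP blocks; by
    default all individuals form one population.
    """
    pop = as_population(individuals)
    labels = list(pop_labels) if pop_labels is not None else ["pop1"] * len(pop)
    lines = [title]
    lines += pop.loci
    order = sorted(range(len(pop)), key=lambda i: labels[i])
    current = None
    for i in order:
        if labels[i] != current:
            lines.append("POP")
            current = labels[i]
        codes = []
        for l in range(pop.n_loci):
            a, b = pop.genotypes[i, l]
            if a == MISSING or b == MISSING:
                codes.append("000000")
            else:
                codes.append(f"{a:03d}{b:03d}")
        lines.append(f"{pop.ids[i]} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")
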