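"""Genetic diversity statistics for band-coded SSR data.

All statistics are functions of the band-count allele frequency vector
``p`` of a group x locus cell (see
:func:`ssrcore.genotype_io.allele_frequencies`), except observed
heterozygosity, which is read directly off the band sets:

* ``Na``  observed number of alleles, ``#{i : p_i > 0}``
* ``Ne``  effective number of alleles, ``1 / sum(p_i^2)``
* ``I``   Shannon's information index, ``-sum(p_i ln p_i)`` (nats)
* ``Ho``  fraction of non-missing accessions showing >= 2 distinct bands
* ``He``  expected heterozygosity (gene diversity), ``1 - sum(p_i^2)``
* ``PIC`` Botstein's polymorphic information content,
  ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``

Summary tables follow the GenAlEx convention: statistics are computed per
group x locus cell first and then averaged — over groups for the per-locus
table, over loci for the per-group table, and over the full grid for the
collection row.  A cell with no data (all accessions missing) contributes a
zero row to those means rather than being dropped; this matches published
SSR surveys in which mean ``Ne`` can fall below 1 and mean ``Na`` below the
minimum attainable on observed data.  Pass ``undefined="exclude"`` to drop
empty cells from the averages instead.  PIC is computed once per locus on
the frequencies pooled over the whole collection (the PowerMarker
convention), never averaged over groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genotype_io import FrequencyTable, GenotypeDataset, Grouping, allele_frequencies

__all__ = [
    "na",
    "ne",
    "shannon",
    "ho",
    "he",
    "pic",
    "DiversitySummary",
    "diversity_table",
    "high_frequency_alleles",
    "STAT_COLUMNS",
]

STAT_COLUMNS = ["N", "Na", "Ne", "I", "Ho", "He"]


def _as_p(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("undefined frequency vector (no observations)")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("frequencies must be non-negative and sum to 1")
    return p


def na(freqs) -> int:
    """Observed number of alleles (frequency > 0)."""
    return int(np.count_nonzero(_as_p(freqs) > 0))


def ne(freqs) -> float:
    """Effective number of alleles, ``1 / sum(p^2)`` — the allele count of an
    equally-frequent locus with the same homozygosity."""
    p = _as_p(freqs)
    return float(1.0 / np.sum(p**2))


def shannon(freqs) -> float:
    """Shannon's information index in nats, with ``0 ln 0 = 0``."""
    p = _as_p(freqs)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def he(freqs) -> float:
    """Expected heterozygosity (gene diversity), ``1 - sum(p^2)``."""
    p = _as_p(freqs)
    return float(1.0 - np.sum(p**2))


def pic(freqs) -> float:
    """Botstein's polymorphic information content.

    ``PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``; values above 0.5
    conventionally mark a highly polymorphic marker.
    """
    p = _as_p(freqs)
    p2 = p**2
    cross = (np.sum(p2) ** 2 - np.sum(p2**2)) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - np.sum(p2) - 2.0 * cross)


def ho(ds: GenotypeDataset, accessions: Sequence[str], locus: str) -> float:
    """Observed heterozygosity: share of non-missing accessions in the group
    whose band set holds at least two distinct fragment sizes."""
    cells = [ds.band(a, locus) for a in accessions]
    scored = [c for c in cells if c]
    if not scored:
        raise ValueError(f"no scored accessions at locus {locus}")
    return float(sum(len(c) >= 2 for c in scored) / len(scored))


@dataclass
class DiversitySummary:
    """Diversity statistics at every aggregation level.

    ``cells`` is the full (group, locus) grid; ``per_locus`` averages over
    groups and carries the pooled-frequency PIC; ``per_group`` averages over
    loci; ``overall`` is the grand mean over the grid (its PIC is the mean
    of the per-locus PIC column).
    """

    grouping: str
    cells: pd.DataFrame
    per_locus: pd.DataFrame
    per_group: pd.DataFrame
    overall: pd.Series
    n_undefined_cells: int

    def to_locus_table(self) -> pd.DataFrame:
        """Per-locus table with a trailing Mean row (survey-table layout)."""
        table = self.per_locus.copy()
        table.loc["Mean"] = self.overall
        return table


def diversity_table(
    ds: GenotypeDataset,
    grouping: Grouping = "by_species",
    undefined: Literal["zero", "exclude"] = "zero",
) -> DiversitySummary:
    """Compute N, Na, Ne, I, Ho, He on every group x locus cell and average.

    ``undefined`` sets the treatment of cells with no scored accession:
    ``"zero"`` (default, GenAlEx-style) keeps them in the averages as zero
    rows; ``"exclude"`` drops them and records the effective denominator.
    """
    ft = allele_frequencies(ds, grouping)
    groups = ds.groups(grouping)
    rows = []
    n_undef = 0
    for gname, members in groups.items():
        for locus in ds.locus_ids:
            n_scored = ft.n[(gname, locus)]
            if n_scored == 0:
                n_undef += 1
                if undefined == "zero":
                    rows.append((gname, locus, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
                continue
            p = ft.frequencies(gname, locus)
            rows.append(
                (
                    gname,
                    locus,
                    float(n_scored),
                    float(na(p)),
                    ne(p),
                    shannon(p),
                    ho(ds, members, locus),
                    he(p),
                )
            )
    cells = pd.DataFrame(
        rows, columns=["group", "locus"] + STAT_COLUMNS
    ).set_index(["group", "locus"])

    per_locus = cells.groupby(level="locus").mean().reindex(ds.locus_ids)
    per_group = cells.groupby(level="group").mean().reindex(list(groups))

    pooled = allele_frequencies(ds, "overall")
    pic_col = {}
    for locus in ds.locus_ids:
        pic_col[locus] = (
            pic(pooled.frequencies("overall", locus))
            if pooled.defined("overall", locus)
            else np.nan
        )
    per_locus["PIC"] = pd.Series(pic_col)

    overall = cells.mean()
    overall["PIC"] = per_locus["PIC"].mean()
    return DiversitySummary(
        grouping=grouping,
        cells=cells,
        per_locus=per_locus,
        per_group=per_group,
        overall=overall,
        n_undefined_cells=n_undef,
    )


def high_frequency_alleles(
    ft: FrequencyTable, threshold: float = 0.5
) -> pd.DataFrame:
    """High-frequency (dominant) alleles per group x locus.

    Returns every allele whose frequency reaches ``threshold`` plus, in any
    case, the modal allele of the cell (flagged ``below_threshold`` when its
    frequency falls short).  The modal allele is a single deterministic
    representative: the smallest fragment size among frequency ties.
    Ordering is (group, locus, descending frequency, allele size).
    """
    rows = []
    for (group, locus), freqs, n_scored in ft.items():
        if n_scored == 0 or freqs.empty:
            continue
        top = freqs.max()
        modal_allele = min(a for a, f in freqs.items() if f == top)
        for allele, f in freqs.items():
            is_modal = allele == modal_allele
            if f >= threshold or is_modal:
                rows.append((group, locus, int(allele), float(f), is_modal, f < threshold))
    df = pd.DataFrame(
        rows,
        columns=["group", "locus", "allele", "frequency", "modal", "below_threshold"],
    )
    return df.sort_values(
        ["group", "locus", "frequency", "allele"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
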