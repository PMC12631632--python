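"""Reading, writing and validating multi-allelic SSR genotype data.

An SSR (microsatellite) allele is identified by its PCR fragment length in
base pairs.  Each accession carries, at each locus, a *band set*: the set of
distinct fragment sizes observed on the electropherogram.  An empty band set
means the locus failed to amplify (missing data).  Because the study species
are frequently polyploid, more than two bands per locus can occur and no
dosage information is assumed; all downstream statistics therefore work from
band presence/absence.

Three interchangeable on-disk representations are supported:

``long_tsv``
    One row per observed band: ``accession_id  locus_id  allele_size``.
    The canonical format; missing cells are simply absent.
``genalex``
    A GenAlEx-like wide codominant table: ``accession_id  population_id``
    followed by two columns per locus holding allele sizes, ``0`` = missing.
``binary_matrix``
    Accessions x ``locus_allele`` 0/1 presence matrix (CSV); an all-zero
    locus block is read back as missing.

Accession metadata (species group, population, province, coordinates) lives
in a separate TSV keyed by ``accession_id``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "GenotypeDataset",
    "BinaryMatrix",
    "FrequencyTable",
    "ValidationReport",
    "read_genotypes",
    "read_metadata",
    "write_genotypes",
    "write_metadata",
    "to_binary_matrix",
    "from_binary_matrix",
    "allele_frequencies",
    "validate_dataset",
]

META_COLUMNS = [
    "accession_id",
    "species_group",
    "population_id",
    "province",
    "longitude",
    "latitude",
]

Grouping = Literal["by_population", "by_species", "overall"]

#: metadata column backing each grouping mode (``overall`` pools everything)
GROUPING_COLUMN = {"by_population": "population_id", "by_species": "species_group"}


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker.

    The repeat motif and annealing temperature are informational only; they
    play no role in the statistics.
    """

    id: str
    repeat_motif: str = ""
    annealing_temp: float | None = None


class GenotypeDataset:
    """Accessions x loci table of band sets, joined to accession metadata.

    Parameters
    ----------
    calls
        DataFrame indexed by accession id with one column per locus id; each
        cell a ``frozenset`` of positive integer fragment sizes.  An empty
        frozenset marks missing data.
    meta
        DataFrame indexed by accession id with columns ``species_group``,
        ``population_id``, ``province``, ``longitude``, ``latitude``.
    loci
        Optional marker descriptors; defaults to bare :class:`Locus` records
        for each calls column.
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        meta: pd.DataFrame,
        loci: Iterable[Locus] | None = None,
    ):
        if calls.index.has_duplicates:
            dupes = calls.index[calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate accession ids: {dupes}")
        if meta.index.has_duplicates:
            dupes = meta.index[meta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate accession ids in metadata: {dupes}")
        missing_meta = calls.index.difference(meta.index)
        if len(missing_meta):
            raise ValueError(
                f"accessions without metadata: {sorted(missing_meta)[:5]}"
            )
        self.calls = calls.map(frozenset)
        self.calls.index.name = "accession_id"
        self.meta = meta.loc[calls.index]
        self.meta.index.name = "accession_id"
        if loci is None:
            loci = [Locus(str(c)) for c in calls.columns]
        self.loci = list(loci)
        locus_ids = [l.id for l in self.loci]
        if sorted(locus_ids) != sorted(map(str, calls.columns)):
            raise ValueError("locus descriptors do not match calls columns")
        if len(set(locus_ids)) != len(locus_ids):
            raise ValueError("duplicate locus ids")
        bad = (self.meta["longitude"].abs() > 180) | (self.meta["latitude"].abs() > 90)
        if bad.any():
            raise ValueError(
                f"coordinates out of range for {self.meta.index[bad].tolist()}"
            )
        # one population -> one species group
        amb = self.meta.groupby("population_id")["species_group"].nunique()
        if (amb > 1).any():
            raise ValueError(
                f"populations spanning species groups: {amb[amb > 1].index.tolist()}"
            )

    # -- basic accessors ---------------------------------------------------

    @property
    def accession_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_accessions(self) -> int:
        return len(self.calls)

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def band(self, accession: str, locus: str) -> frozenset:
        return self.calls.at[accession, locus]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean accessions x loci frame, True where the cell is missing."""
        return self.calls.map(len) == 0

    def groups(self, grouping: Grouping) -> dict[str, list[str]]:
        """Map group label -> accession ids under the requested grouping."""
        if grouping == "overall":
            return {"overall": self.accession_ids}
        col = GROUPING_COLUMN[grouping]
        out: dict[str, list[str]] = {}
        for acc, label in self.meta[col].items():
            out.setdefault(str(label), []).append(acc)
        return dict(sorted(out.items()))

    def subset(self, accessions: Iterable[str]) -> "GenotypeDataset":
        """Restrict to the given accessions (order preserved as given)."""
        accessions = list(accessions)
        unknown = set(accessions) - set(self.calls.index)
        if unknown:
            raise KeyError(f"unknown accessions: {sorted(unknown)[:5]}")
        return GenotypeDataset(
            self.calls.loc[accessions], self.meta.loc[accessions], self.loci
        )

    def observed_alleles(self, locus: str) -> list[int]:
        """Sorted union of fragment sizes seen at *locus*."""
        sizes: set[int] = set()
        for cell in self.calls[locus]:
            sizes |= cell
        return sorted(sizes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeDataset)
            and self.calls.equals(other.calls)
            and self.meta.equals(other.meta)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeDataset({self.n_accessions} accessions, "
            f"{self.n_loci} loci, "
            f"{self.meta['population_id'].nunique()} populations)"
        )


@dataclass
class BinaryMatrix:
    """0/1 presence/absence recoding of a :class:`GenotypeDataset`.

    ``data`` has one column per observed (locus, allele) pair, MultiIndexed
    as ``(locus_id, allele_size)``; ``missing`` is the accessions x loci
    missing-data mask (a missing cell produces an all-zero locus block).
    """

    data: pd.DataFrame
    missing: pd.DataFrame

    @property
    def accession_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.missing.columns)

    def flat_columns(self) -> list[str]:
        return [f"{loc}_{allele}" for loc, allele in self.data.columns]


@dataclass
class FrequencyTable:
    """Per-group per-locus allele frequency vectors with carrier counts.

    Frequencies use the band-count estimator: each non-missing accession
    contributes its full band set once, and the frequency of allele *a* is
    the number of carriers divided by the total number of band observations
    in the group at that locus.  ``n`` is the number of non-missing
    accessions (the sample size printed as *N* in diversity tables).  A
    group x locus cell with no data is *undefined*: frequency vector empty
    and ``n`` = 0.
    """

    grouping: str
    entries: dict[tuple[str, str], pd.Series]
    n: dict[tuple[str, str], int]
    groups: list[str]
    loci: list[str]

    def frequencies(self, group: str, locus: str) -> pd.Series:
        return self.entries[(group, locus)]

    def defined(self, group: str, locus: str) -> bool:
        return self.n[(group, locus)] > 0

    def items(self):
        for key, freqs in self.entries.items():
            yield key, freqs, self.n[key]


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`; ``issues`` is a list of
    (code, message) pairs and is empty for a clean dataset."""

    issues: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def codes(self) -> list[str]:
        return [c for c, _ in self.issues]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    head = Path(path).read_text().splitlines()[0] if Path(path).stat().st_size else ""
    return "\t" if "\t" in head or "," not in head else ","


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the accession metadata TSV (tab or comma separated)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    for col in ("longitude", "latitude"):
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise ValueError(f"malformed numeric field in column {col}: {exc}") from exc
    if df["accession_id"].duplicated().any():
        dupes = df.loc[df["accession_id"].duplicated(), "accession_id"].tolist()
        raise ValueError(f"duplicate accession ids in metadata: {dupes}")
    return df.set_index("accession_id")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.reset_index().to_csv(path, sep="\t", index=False)


def _read_long(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    if df.empty:
        raise ValueError(f"no records in {path}")
    required = {"accession_id", "locus_id", "allele_size"}
    if not required <= set(df.columns):
        raise ValueError(f"long format requires columns {sorted(required)}")
    try:
        df["allele_size"] = df["allele_size"].astype(int)
    except ValueError:
        bad = df[~df["allele_size"].str.fullmatch(r"\d+")].index[0]
        raise ValueError(f"malformed allele_size at row {bad + 2} of {path}")
    if (df["allele_size"] <= 0).any():
        bad = df.index[df["allele_size"] <= 0][0]
        raise ValueError(f"non-positive allele_size at row {bad + 2} of {path}")
    cells = (
        df.groupby(["accession_id", "locus_id"])["allele_size"]
        .agg(frozenset)
        .unstack(fill_value=frozenset())
    )
    return cells.map(lambda v: v if isinstance(v, frozenset) else frozenset())


def _read_genalex(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    if df.empty:
        raise ValueError(f"no records in {path}")
    cols = list(df.columns)
    if len(cols) < 4 or (len(cols) - 2) % 2:
        raise ValueError(
            "genalex format needs accession_id, population_id then 2 columns per locus"
        )
    locus_pairs = [(cols[i], cols[i + 1]) for i in range(2, len(cols), 2)]
    records: dict[str, dict[str, frozenset]] = {}
    for row_no, row in df.iterrows():
        acc = row[cols[0]]
        if acc in records:
            raise ValueError(f"duplicate accession id {acc!r} at row {row_no + 2}")
        bands = {}
        for c1, c2 in locus_pairs:
            locus = c1  # the first column of each pair names the locus
            sizes = set()
            for raw in (row[c1], row[c2]):
                if pd.isna(raw):
                    continue
                try:
                    val = int(float(raw))
                except ValueError:
                    raise ValueError(
                        f"malformed allele size {raw!r} at row {row_no + 2}, column {c1}"
                    )
                if val > 0:
                    sizes.add(val)
            bands[locus] = frozenset(sizes)
        records[acc] = bands
    return pd.DataFrame.from_dict(records, orient="index")


def _read_binary(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if df.empty:
        raise ValueError(f"no records in {path}")
    cols = []
    for c in df.columns:
        locus, _, allele = str(c).rpartition("_")
        if not locus or not allele.isdigit():
            raise ValueError(f"binary matrix column {c!r} is not locus_allele")
        cols.append((locus, int(allele)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["locus", "allele"])
    missing = pd.DataFrame(
        {
            locus: (df[locus].sum(axis=1) == 0)
            for locus in df.columns.get_level_values(0).unique()
        }
    )
    return from_binary_matrix(BinaryMatrix(df.astype(int), missing))


def read_genotypes(
    path: str | Path,
    format_name: Literal["long_tsv", "genalex", "binary_matrix"] = "long_tsv",
    metadata: str | Path | pd.DataFrame | None = None,
    on_missing_meta: Literal["error", "synthesize"] = "error",
) -> GenotypeDataset:
    """Read a genotype file plus metadata into a validated dataset.

    ``on_missing_meta`` controls what happens when a genotyped accession has
    no metadata row: ``"error"`` raises, ``"synthesize"`` warns and fills a
    placeholder row (unknown population/species, coordinates 0,0).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"long_tsv": _read_long, "genalex": _read_genalex, "binary_matrix": _read_binary}
    if format_name not in readers:
        raise ValueError(f"unknown format {format_name!r}; choose from {sorted(readers)}")
    parsed = readers[format_name](path)
    if isinstance(parsed, GenotypeDataset):
        cells = parsed.calls
    else:
        cells = parsed
    cells = cells.sort_index()
    cells = cells[sorted(cells.columns)]

    if metadata is None:
        meta = pd.DataFrame(
            {
                "species_group": "unknown",
                "population_id": "unknown",
                "province": "unknown",
                "longitude": 0.0,
                "latitude": 0.0,
            },
            index=cells.index,
        )
        meta.index.name = "accession_id"
    else:
        meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
        orphans = cells.index.difference(meta.index)
        if len(orphans):
            if on_missing_meta == "error":
                raise ValueError(
                    f"accessions missing from metadata: {sorted(orphans)[:5]}"
                )
            warnings.warn(
                f"synthesizing placeholder metadata for {len(orphans)} accessions"
            )
            filler = pd.DataFrame(
                {
                    "species_group": "unknown",
                    "population_id": "unknown",
                    "province": "unknown",
                    "longitude": 0.0,
                    "latitude": 0.0,
                },
                index=orphans,
            )
            meta = pd.concat([meta, filler]).sort_index()
    return GenotypeDataset(cells, meta)


def write_genotypes(
    ds: GenotypeDataset,
    path: str | Path,
    format_name: Literal["long_tsv", "binary_matrix"] = "long_tsv",
) -> None:
    """Serialize the band sets; ``long_tsv`` is lossless, ``binary_matrix``
    loses nothing except the distinction between missing cells and cells
    whose alleles were observed nowhere."""
    path = Path(path)
    if format_name == "long_tsv":
        rows = []
        for acc in ds.accession_ids:
            for locus in ds.locus_ids:
                for size in sorted(ds.band(acc, locus)):
                    rows.append((acc, locus, size))
        pd.DataFrame(rows, columns=["accession_id", "locus_id", "allele_size"]).to_csv(
            path, sep="\t", index=False
        )
    elif format_name == "binary_matrix":
        bm = to_binary_matrix(ds)
        out = bm.data.copy()
        out.columns = bm.flat_columns()
        out.index.name = "accession_id"
        out.to_csv(path)
    else:
        raise ValueError(f"unknown format {format_name!r}")


# ---------------------------------------------------------------------------
# representation conversion
# ---------------------------------------------------------------------------


def to_binary_matrix(ds: GenotypeDataset) -> BinaryMatrix:
    """Recode band sets as a 0/1 matrix with one column per observed
    (locus, allele) pair.  Missing cells become all-zero locus blocks and
    are tracked in the ``missing`` mask."""
    columns = []
    blocks = []
    for locus in ds.locus_ids:
        alleles = ds.observed_alleles(locus)
        cells = ds.calls[locus]
        block = np.zeros((ds.n_accessions, len(alleles)), dtype=int)
        for j, a in enumerate(alleles):
            block[:, j] = [a in cell for cell in cells]
        blocks.append(block)
        columns += [(locus, a) for a in alleles]
    data = pd.DataFrame(
        np.hstack(blocks) if blocks else np.empty((ds.n_accessions, 0), dtype=int),
        index=ds.calls.index,
        columns=pd.MultiIndex.from_tuples(columns, names=["locus", "allele"])
        if columns
        else pd.MultiIndex.from_arrays([[], []], names=["locus", "allele"]),
    )
    return BinaryMatrix(data, ds.missing_mask())


def from_binary_matrix(
    bm: BinaryMatrix, meta: pd.DataFrame | None = None
) -> GenotypeDataset:
    """Inverse of :func:`to_binary_matrix` (all-zero locus blocks read back
    as missing)."""
    loci = bm.data.columns.get_level_values(0).unique()
    cells = {}
    for locus in loci:
        block = bm.data[locus]
        alleles = np.array(block.columns)
        cells[locus] = [
            frozenset(alleles[row.to_numpy().astype(bool)]) for _, row in block.iterrows()
        ]
    calls = pd.DataFrame(cells, index=bm.data.index)
    if meta is None:
        meta = pd.DataFrame(
            {
                "species_group": "unknown",
                "population_id": "unknown",
                "province": "unknown",
                "longitude": 0.0,
                "latitude": 0.0,
            },
            index=calls.index,
        )
        meta.index.name = "accession_id"
    return GenotypeDataset(calls, meta)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(ds: GenotypeDataset, grouping: Grouping = "overall") -> FrequencyTable:
    """Band-count allele frequencies per group x locus.

    Each accession contributes every band it carries exactly once; the
    denominator is the total number of band observations in the group at the
    locus, so vectors sum to one.  Cells with zero non-missing accessions
    are recorded as undefined (empty vector, n = 0).
    """
    groups = ds.groups(grouping)
    entries: dict[tuple[str, str], pd.Series] = {}
    ns: dict[tuple[str, str], int] = {}
    for gname, members in groups.items():
        sub = ds.calls.loc[members]
        for locus in ds.locus_ids:
            counts: dict[int, int] = {}
            n_obs = 0
            for cell in sub[locus]:
                if cell:
                    n_obs += 1
                    for a in cell:
                        counts[a] = counts.get(a, 0) + 1
            key = (gname, locus)
            ns[key] = n_obs
            if counts:
                ser = pd.Series(counts, dtype=float).sort_index()
                entries[key] = ser / ser.sum()
            else:
                entries[key] = pd.Series(dtype=float)
    return FrequencyTable(
        grouping=grouping,
        entries=entries,
        n=ns,
        groups=list(groups),
        loci=ds.locus_ids,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_dataset(ds: GenotypeDataset) -> ValidationReport:
    """Non-mutating health check: flags all-missing accessions/loci,
    monomorphic loci and metadata gaps."""
    report = ValidationReport()
    miss = ds.missing_mask()
    for acc in ds.accession_ids:
        if miss.loc[acc].all():
            report.issues.append(
                ("all_missing_accession", f"accession {acc} has no data at any locus")
            )
    for locus in ds.locus_ids:
        if miss[locus].all():
            report.issues.append(
                ("all_missing_locus", f"locus {locus} has no data in any accession")
            )
        else:
            alleles = ds.observed_alleles(locus)
            if len(alleles) == 1:
                report.issues.append(
                    ("monomorphic_locus", f"locus {locus} shows a single allele")
                )
    gaps = ds.meta[ds.meta[["longitude", "latitude"]].isna().any(axis=1)]
    for acc in gaps.index:
        report.issues.append(("metadata_gap", f"accession {acc} lacks coordinates"))
    unk = ds.meta[ds.meta["population_id"].astype(str) == "unknown"]
    for acc in unk.index:
        report.issues.append(
            ("metadata_gap", f"accession {acc} has placeholder metadata")
        )
    return report
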