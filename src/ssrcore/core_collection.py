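"""Least-distance stepwise sampling (LDSS) core-collection construction.

A core collection is a subset of a germplasm bank chosen to keep as much of
the bank's genetic diversity as possible while shedding redundant material.
The LDSS strategy removes redundancy greedily: at every step the pair of
retained accessions with the smallest genetic distance (highest similarity)
is located and one of its members is discarded, until the target size is
reached.  This implementation resolves the one degree of freedom the
strategy leaves open — which member of the closest pair to drop — in favour
of allele retention: the member whose removal forfeits fewer
collection-unique alleles goes first, with deterministic tie-breaking
(higher mean similarity to the remaining set, then larger accession id).

A *ladder* of cores at decreasing sampling ratios is built by continuing
the reduction from the previous step, so the member sets are nested and the
allele retention rate ``Ra`` is monotone non-increasing.  Each rung is
summarized with the same diversity statistics as the full bank, and the
core is selected as the rung maximizing expected heterozygosity (then
Shannon index, then effective allele count).  Validation compares the
per-locus diversity of the chosen core against the original collection
with Welch two-sample t-tests and provides PCoA coordinates and an NJ tree
for visual inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import DiversitySummary, diversity_table
from .genotype_io import GenotypeDataset, Grouping, to_binary_matrix
from .tree_ordination import Ordination, genetic_distance, nj_tree, pcoa, write_newick

__all__ = [
    "LdssConfig",
    "CoreStep",
    "CoreLadder",
    "CoreValidation",
    "ldss_reduce",
    "build_ladder",
    "retention_rate",
    "select_core",
    "validate_core",
    "DEFAULT_RATIOS",
]

DEFAULT_RATIOS = (0.59, 0.45, 0.35, 0.24, 0.13)

VALIDATED_STATS = ["Na", "Ne", "I", "Ho", "He"]


@dataclass(frozen=True)
class LdssConfig:
    """Ladder construction settings.

    ``target_ratios`` must be strictly descending fractions of the bank;
    each implied size is ``floor(ratio * n + 0.5)`` unless ``sizes``
    overrides it explicitly (published core sizes do not always follow one
    rounding rule).  ``grouping`` sets the aggregation used for the
    diversity summaries of every rung.
    """

    target_ratios: tuple[float, ...] = DEFAULT_RATIOS
    sizes: tuple[int, ...] | None = None
    metric: str = "dice"
    grouping: Grouping = "by_species"
    nested: bool = True

    def __post_init__(self):
        ratios = tuple(self.target_ratios)
        if any(not 0 < r <= 1 for r in ratios):
            raise ValueError("ratios must lie in (0, 1]")
        if any(a <= b for a, b in zip(ratios, ratios[1:])):
            raise ValueError("ratios must be strictly descending")
        if self.sizes is not None and len(self.sizes) != len(ratios):
            raise ValueError("sizes override must match target_ratios in length")

    def resolved_sizes(self, n: int) -> list[int]:
        if self.sizes is not None:
            return list(self.sizes)
        return [int(math.floor(r * n + 0.5)) for r in self.target_ratios]


def _unique_allele_counts(ds: GenotypeDataset, retained: list[str]) -> dict[str, int]:
    """Per-accession count of (locus, allele) bands carried by no other
    retained accession."""
    bm = to_binary_matrix(ds.subset(retained))
    X = bm.data.to_numpy()
    col_totals = X.sum(axis=0)
    unique_cols = col_totals == 1
    counts = (X[:, unique_cols] == 1).sum(axis=1)
    return dict(zip(retained, counts.astype(int)))


def ldss_reduce(
    ds: GenotypeDataset,
    distance: pd.DataFrame,
    target_size: int,
) -> list[str]:
    """Reduce the collection to ``target_size`` members by least-distance
    stepwise sampling.

    Fully deterministic: the global minimum-distance pair is found (ties in
    lexicographic pair order); the member losing fewer collection-unique
    alleles is removed; remaining ties fall to the member with the higher
    mean similarity (lower mean distance) to the rest, then to the larger
    accession id.  Returns the retained ids in the dataset's order.
    """
    ids = list(map(str, distance.index))
    if sorted(ids) != sorted(ds.accession_ids):
        raise ValueError("distance matrix labels must match dataset accessions")
    n = len(ids)
    if not 2 <= target_size <= n:
        raise ValueError(f"target_size must lie in [2, {n}]")
    D = distance.loc[ids, ids].to_numpy(dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")

    retained = sorted(ids)
    pos = {a: ids.index(a) for a in ids}
    while len(retained) > target_size:
        # closest pair among retained, lexicographic tie order
        idx = [pos[a] for a in retained]
        sub = D[np.ix_(idx, idx)]
        iu = np.triu_indices(len(retained), k=1)
        vals = sub[iu]
        dmin = vals.min()
        tie_mask = np.isclose(vals, dmin, rtol=0, atol=1e-12)
        pairs = sorted(
            (retained[iu[0][k]], retained[iu[1][k]])
            for k in np.flatnonzero(tie_mask)
        )
        a, b = pairs[0]

        uniq = _unique_allele_counts(ds, retained)
        if uniq[a] != uniq[b]:
            victim = a if uniq[a] < uniq[b] else b
        else:
            rest = [x for x in retained if x not in (a, b)]
            if rest:
                ridx = [pos[x] for x in rest]
                mean_a = D[pos[a], ridx].mean()
                mean_b = D[pos[b], ridx].mean()
            else:
                mean_a = mean_b = 0.0
            if not math.isclose(mean_a, mean_b, rel_tol=0, abs_tol=1e-12):
                # higher similarity to the rest = lower mean distance = redundant
                victim = a if mean_a < mean_b else b
            else:
                victim = max(a, b)
        retained.remove(victim)
    kept = set(retained)
    return [a for a in ds.accession_ids if a in kept]


@dataclass
class CoreStep:
    ratio: float
    size: int
    members: list[str]
    summary: pd.Series  # overall diversity row (N, Na, Ne, I, Ho, He [, PIC])
    ra: float  # allele retention, percent of the original mean Na

    @property
    def name(self) -> str:
        return f"C{self.size}"


@dataclass
class CoreLadder:
    """Nested sequence of LDSS cores with per-rung diversity and allele
    retention; ``original`` is the full-bank baseline rung (Ra = 100)."""

    original: CoreStep
    steps: list[CoreStep] = field(default_factory=list)
    config: LdssConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for step in [self.original, *self.steps]:
            row = {
                "collection": step.name if step is not self.original else "Original",
                "size": step.size,
                "ratio": round(step.ratio * 100.0, 1),
                **{k: step.summary.get(k, math.nan) for k in ["N", "Na", "Ne", "I", "Ho", "He"]},
                "Ra": step.ra,
            }
            rows.append(row)
        return pd.DataFrame(rows).set_index("collection")


def retention_rate(core_na: float, orig_na: float) -> float:
    """Allele retention ``Ra = 100 * core_Na / orig_Na`` (percent, 2 dp),
    where ``Na`` is the collection-mean observed allele count."""
    if not orig_na > 0:
        raise ValueError("original mean allele count must be positive")
    return round(100.0 * core_na / orig_na, 2)


def build_ladder(
    ds: GenotypeDataset,
    cfg: LdssConfig = LdssConfig(),
    distance: pd.DataFrame | None = None,
) -> CoreLadder:
    """Build the core ladder over ``cfg.target_ratios``.

    The genetic distance matrix is computed once on the full bank; each
    rung continues the reduction from the previous rung's members (nested
    mode) or restarts from the full bank when ``cfg.nested`` is False.
    Ratios implying fewer than 2 members are skipped with a warning.
    """
    n = ds.n_accessions
    if distance is None:
        distance = genetic_distance(to_binary_matrix(ds), cfg.metric, undefined="mean")
    summary_full = diversity_table(ds, cfg.grouping)
    orig_na = float(summary_full.overall["Na"])
    original = CoreStep(
        ratio=1.0,
        size=n,
        members=ds.accession_ids,
        summary=summary_full.overall,
        ra=100.0,
    )
    ladder = CoreLadder(original=original, config=cfg)
    current = ds
    current_dist = distance
    for ratio, size in zip(cfg.target_ratios, cfg.resolved_sizes(n)):
        if size < 2:
            import warnings

            warnings.warn(f"ratio {ratio} implies size {size} < 2; step skipped")
            continue
        base = current if cfg.nested else ds
        base_dist = current_dist if cfg.nested else distance
        members = ldss_reduce(base, base_dist, size)
        sub = ds.subset(members)
        summary = diversity_table(sub, cfg.grouping)
        step = CoreStep(
            ratio=ratio,
            size=size,
            members=members,
            summary=summary.overall,
            ra=retention_rate(float(summary.overall["Na"]), orig_na),
        )
        ladder.steps.append(step)
        if cfg.nested:
            current = sub
            current_dist = distance.loc[members, members]
    return ladder


def select_core(ladder: CoreLadder) -> CoreStep:
    """Pick the rung maximizing He, breaking ties by I then Ne.

    Rationale: expected heterozygosity is the primary gene-diversity
    measure; a rung that beats the rest on He (and on the entropy and
    effective-allele-count tie-breakers) packs the most diversity into the
    fewest accessions.
    """
    if not ladder.steps:
        raise ValueError("empty ladder")
    best = max(
        ladder.steps,
        key=lambda s: (
            round(float(s.summary["He"]), 12),
            round(float(s.summary["I"]), 12),
            round(float(s.summary["Ne"]), 12),
        ),
    )
    return best


@dataclass
class CoreValidation:
    """Welch t-tests of per-locus diversity (core vs original), plus PCoA
    overlay coordinates and the Newick NJ tree of the core."""

    tests: pd.DataFrame  # index = statistic, columns = t, p
    pcoa_overlay: Ordination
    membership: pd.Series  # accession -> bool (in core)
    core_tree_newick: str


def validate_core(
    ds: GenotypeDataset,
    core_members: list[str],
    grouping: Grouping = "by_species",
    metric: str = "dice",
    n_axes: int = 2,
) -> CoreValidation:
    """Statistically and visually compare a core against the full bank.

    For each diversity statistic the per-locus values (group-averaged) of
    the core are compared with the original's by Welch's two-sample t-test;
    non-significance (p > 0.05) indicates the core preserves the bank's
    diversity profile.  Also returns the PCoA of the full bank with a core
    membership flag and the NJ tree of the core members.
    """
    if ds.n_loci < 2:
        raise ValueError("validation needs at least 2 loci")
    core = ds.subset(core_members)
    full_locus = diversity_table(ds, grouping).per_locus
    core_locus = diversity_table(core, grouping).per_locus
    rows = {}
    for stat in VALIDATED_STATS:
        x, y = core_locus[stat].to_numpy(), full_locus[stat].to_numpy()
        if np.allclose(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
        rows[stat] = {"t": float(t), "p": float(p)}
    tests = pd.DataFrame(rows).T

    dist_full = genetic_distance(to_binary_matrix(ds), metric, undefined="mean")
    ordination = pcoa(dist_full, n_axes=n_axes)
    membership = pd.Series(
        [a in set(core_members) for a in ds.accession_ids], index=ds.accession_ids
    )
    dist_core = dist_full.loc[core_members, core_members]
    tree = write_newick(nj_tree(dist_core)) if len(core_members) >= 3 else ""
    return CoreValidation(
        tests=tests,
        pcoa_overlay=ordination,
        membership=membership,
        core_tree_newick=tree,
    )
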