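"""Population differentiation: pairwise Phi-Fst, gene flow, AMOVA, Mantel.

Differentiation statistics for band-coded SSR data follow the AMOVA
framework of Excoffier and the GenAlEx binary-data convention: accessions
are recoded as 0/1 allele-presence profiles, squared Euclidean distances
between profiles are partitioned into hierarchical variance components by
equating observed to expected mean squares, and the Phi statistics are
ratios of those components.  For a pair of groups the among-group Phi is
the pairwise ``Fst`` (PhiPT in GenAlEx terms).  Significance is assessed by
permuting labels at the appropriate level; p-values use the standard
``(1 + exceedances) / (1 + n_perm)`` estimator.

Negative variance components (sampling noise) are truncated to zero before
percentages and Phi ratios are formed — the GenAlEx convention; the raw
(untruncated) components are retained in the result table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, to_binary_matrix

__all__ = [
    "AmovaResult",
    "MantelResult",
    "squared_band_distances",
    "pairwise_fst",
    "nm_from_fst",
    "amova",
    "geo_distance_matrix",
    "mantel",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def squared_band_distances(ds: GenotypeDataset) -> pd.DataFrame:
    """Squared Euclidean distances between binary allele profiles.

    Only loci scored in both accessions are compared; the mismatch count is
    rescaled by (total columns / shared columns) so that accessions with
    missing loci remain on the same scale as fully scored ones.  A pair
    sharing no scored locus gets NaN.
    """
    bm = to_binary_matrix(ds)
    X = bm.data.to_numpy(dtype=float)
    scored = (~bm.missing).to_numpy(dtype=float)  # accessions x loci
    locus_of_col = bm.data.columns.get_level_values(0)
    loci = list(bm.missing.columns)
    col_block = np.array([[locus == l for l in loci] for locus in locus_of_col], dtype=float)
    # bands per accession per locus
    bands = X @ col_block  # n x nloci
    cols_per_locus = col_block.sum(axis=0)  # nloci

    a = X @ X.T  # shared presences (missing cells are all-zero)
    s = (bands * scored) @ scored.T  # bands of i over loci scored in both
    shared_cols = (cols_per_locus * scored) @ scored.T
    total_cols = cols_per_locus.sum()

    with np.errstate(divide="ignore", invalid="ignore"):
        mism = s + s.T - 2.0 * a
        d2 = mism * (total_cols / shared_cols)
    d2[shared_cols == 0] = np.nan
    np.fill_diagonal(d2, 0.0)
    return pd.DataFrame(d2, index=bm.accession_ids, columns=bm.accession_ids)


def _fill_undefined(d2: np.ndarray) -> tuple[np.ndarray, int]:
    """Mean-impute undefined (no shared scored locus) pairwise distances.

    Variance partitions need a complete matrix; replacing the few undefined
    pairs by the mean defined off-diagonal distance is neutral with respect
    to the among/within split in expectation.  Returns the filled matrix
    and the number of imputed pairs.
    """
    mask = np.isnan(d2)
    n_bad = int(mask.sum() // 2)
    if n_bad == 0:
        return d2, 0
    off = ~np.eye(len(d2), dtype=bool)
    defined = d2[off & ~mask]
    if defined.size == 0:
        raise ValueError("no defined pairwise distances at all")
    filled = d2.copy()
    filled[mask] = defined.mean()
    np.fill_diagonal(filled, 0.0)
    return filled, n_bad


# ---------------------------------------------------------------------------
# AMOVA machinery
# ---------------------------------------------------------------------------


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_levels: int) -> float:
    """Sum over strata of (pair sums within stratum) / stratum size."""
    total = 0.0
    for g in range(n_levels):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * len(idx))
    return total


def _two_level_phi(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """PhiPT and the (SS, df, variance) pieces for a one-way AMOVA."""
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, codes, n_groups)
    ss_among = ss_total - ss_within
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    g_eff = int(np.count_nonzero(sizes))
    df_among = g_eff - 1
    df_within = n - g_eff
    if df_among < 1 or df_within < 1:
        return math.nan, ss_among, ss_within, ss_total, df_among, df_within, math.nan, math.nan
    ms_within = ss_within / df_within
    ms_among = ss_among / df_among
    nz = sizes[sizes > 0]
    n0 = (n - np.sum(nz**2) / n) / df_among
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    v_a = max(var_among, 0.0)
    denom = v_a + max(var_within, 0.0)
    phi = 0.0 if denom == 0 else v_a / denom
    return phi, ss_among, ss_within, ss_total, df_among, df_within, var_among, var_within


@dataclass
class AmovaResult:
    """Hierarchical AMOVA table plus Phi statistics.

    ``table`` rows are the variance strata with df, SS, MS, the raw
    variance component, and the percent of total after truncating negative
    components to zero.  ``phi`` holds PhiPT (two-level) or PhiCT / PhiSC /
    PhiST (three-level); ``p_values`` the permutation p for each.
    """

    table: pd.DataFrame
    phi: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    seed: int | None


def _amova_two_level(
    d2: np.ndarray, codes: np.ndarray, n_groups: int, labels: tuple[str, str],
    n_perm: int, rng: np.random.Generator | None,
) -> tuple[pd.DataFrame, dict, dict]:
    (phi, ss_a, ss_w, ss_t, df_a, df_w, var_a, var_w) = _two_level_phi(d2, codes, n_groups)
    comp = np.array([max(var_a, 0.0) if not math.isnan(var_a) else math.nan,
                     max(var_w, 0.0) if not math.isnan(var_w) else math.nan])
    total = np.nansum(comp)
    pct = comp / total * 100.0 if total > 0 else np.full(2, math.nan)
    table = pd.DataFrame(
        {
            "df": [df_a, df_w, df_a + df_w],
            "SS": [ss_a, ss_w, ss_t],
            "MS": [ss_a / df_a if df_a else math.nan, ss_w / df_w if df_w else math.nan, math.nan],
            "variance": [var_a, var_w, var_a + var_w],
            "percent": [pct[0], pct[1], 100.0 if total > 0 else math.nan],
        },
        index=[labels[0], labels[1], "total"],
    )
    p = math.nan
    if rng is not None and n_perm > 0 and not math.isnan(phi):
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            phi_p = _two_level_phi(d2, perm, n_groups)[0]
            if not math.isnan(phi_p) and phi_p >= phi:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
    return table, {"PhiPT": phi}, {"PhiPT": p}


def amova(
    ds: GenotypeDataset,
    hierarchy: tuple[str, ...] = ("species_group", "population_id"),
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical analysis of molecular variance on band profiles.

    ``hierarchy`` names the metadata columns defining the strata, outermost
    first.  With one column the partition is among/within groups (PhiPT);
    with two it is among groups / among populations within groups / within
    populations, with PhiCT, PhiSC and PhiST and level-specific permutation
    schemes (populations shuffled among groups for PhiCT; accessions among
    populations within their group for PhiSC; accessions across everything
    for PhiST).
    """
    if len(hierarchy) not in (1, 2):
        raise ValueError("hierarchy must name one or two metadata columns")
    d2, n_imputed = _fill_undefined(squared_band_distances(ds).to_numpy())
    if n_imputed:
        import warnings

        warnings.warn(f"mean-imputed {n_imputed} undefined pairwise distances")
    rng = np.random.default_rng(seed) if n_perm > 0 else None

    if len(hierarchy) == 1:
        labels = ds.meta[hierarchy[0]].astype(str).to_numpy()
        cats = sorted(set(labels))
        if len(cats) < 2:
            raise ValueError("need at least two strata for AMOVA")
        codes = np.array([cats.index(x) for x in labels])
        table, phi, pvals = _amova_two_level(
            d2, codes, len(cats), ("among_groups", "within_groups"), n_perm, rng
        )
        return AmovaResult(table, phi, pvals, n_perm, seed)

    gcol, pcol = hierarchy
    glabels = ds.meta[gcol].astype(str).to_numpy()
    plabels = ds.meta[pcol].astype(str).to_numpy()
    gcats = sorted(set(glabels))
    pcats = sorted(set(plabels))
    if len(gcats) < 2 or len(pcats) <= len(gcats):
        raise ValueError("need >=2 groups and >=2 populations in some group")
    g = np.array([gcats.index(x) for x in glabels])
    p_ = np.array([pcats.index(x) for x in plabels])
    n = len(g)
    G, P = len(gcats), len(pcats)

    def components(g, p_):
        ss_total = d2.sum() / (2.0 * n)
        ss_wp = _ss_within(d2, p_, P)
        ss_wg = _ss_within(d2, g, G)
        ss_ap = ss_wg - ss_wp  # among populations within groups
        ss_ag = ss_total - ss_wg
        df_ag, df_ap, df_wp = G - 1, P - G, n - P
        ms_wp = ss_wp / df_wp
        ms_ap = ss_ap / df_ap
        ms_ag = ss_ag / df_ag
        n_p = np.bincount(p_, minlength=P).astype(float)
        n_g = np.bincount(g, minlength=G).astype(float)
        # population -> group map
        pg = np.zeros(P, dtype=int)
        for j in range(P):
            pg[j] = g[np.flatnonzero(p_ == j)[0]]
        sum_np2_over_ng = sum(
            np.sum(n_p[pg == h] ** 2) / n_g[h] for h in range(G) if n_g[h] > 0
        )
        coef_a = (n - sum_np2_over_ng) / df_ap
        coef_b = (sum_np2_over_ng - np.sum(n_p**2) / n) / df_ag
        coef_c = (n - np.sum(n_g**2) / n) / df_ag
        var_c = ms_wp
        var_b = (ms_ap - var_c) / coef_a
        var_a = (ms_ag - var_c - coef_b * var_b) / coef_c
        return (ss_ag, ss_ap, ss_wp, ss_total, df_ag, df_ap, df_wp, var_a, var_b, var_c)

    (ss_ag, ss_ap, ss_wp, ss_total, df_ag, df_ap, df_wp, var_a, var_b, var_c) = components(g, p_)
    trunc = np.maximum([var_a, var_b, var_c], 0.0)
    total_var = trunc.sum()
    pct = trunc / total_var * 100.0 if total_var > 0 else np.full(3, math.nan)

    def phis(var_a, var_b, var_c):
        ta, tb, tc = max(var_a, 0.0), max(var_b, 0.0), max(var_c, 0.0)
        tot = ta + tb + tc
        phi_ct = ta / tot if tot > 0 else math.nan
        phi_sc = tb / (tb + tc) if (tb + tc) > 0 else math.nan
        phi_st = (ta + tb) / tot if tot > 0 else math.nan
        return phi_ct, phi_sc, phi_st

    phi_ct, phi_sc, phi_st = phis(var_a, var_b, var_c)
    table = pd.DataFrame(
        {
            "df": [df_ag, df_ap, df_wp, n - 1],
            "SS": [ss_ag, ss_ap, ss_wp, ss_total],
            "MS": [ss_ag / df_ag, ss_ap / df_ap, ss_wp / df_wp, math.nan],
            "variance": [var_a, var_b, var_c, var_a + var_b + var_c],
            "percent": [pct[0], pct[1], pct[2], 100.0 if total_var > 0 else math.nan],
        },
        index=[
            "among_groups",
            "among_populations_within_groups",
            "within_populations",
            "total",
        ],
    )

    pvals = {"PhiCT": math.nan, "PhiSC": math.nan, "PhiST": math.nan}
    if rng is not None and n_perm > 0:
        pg = np.zeros(P, dtype=int)
        for j in range(P):
            pg[j] = g[np.flatnonzero(p_ == j)[0]]
        ex_ct = ex_sc = ex_st = 0
        for _ in range(n_perm):
            # PhiCT: shuffle whole populations among groups
            perm_pg = rng.permutation(pg)
            g_ct = perm_pg[p_]
            c = components(g_ct, p_)
            if phis(c[7], c[8], c[9])[0] >= phi_ct:
                ex_ct += 1
            # PhiSC: shuffle accessions among populations within each group
            p_sc = p_.copy()
            for h in range(G):
                idx = np.flatnonzero(g == h)
                p_sc[idx] = p_[idx][rng.permutation(len(idx))]
            c = components(g, p_sc)
            if phis(c[7], c[8], c[9])[1] >= phi_sc:
                ex_sc += 1
            # PhiST: shuffle accessions across everything
            perm = rng.permutation(n)
            c = components(g[perm], p_[perm])
            if phis(c[7], c[8], c[9])[2] >= phi_st:
                ex_st += 1
        pvals = {
            "PhiCT": (1 + ex_ct) / (1 + n_perm),
            "PhiSC": (1 + ex_sc) / (1 + n_perm),
            "PhiST": (1 + ex_st) / (1 + n_perm),
        }
    return AmovaResult(
        table, {"PhiCT": phi_ct, "PhiSC": phi_sc, "PhiST": phi_st}, pvals, n_perm, seed
    )


# ---------------------------------------------------------------------------
# pairwise Fst / Nm
# ---------------------------------------------------------------------------


def pairwise_fst(
    ds: GenotypeDataset,
    level: str = "population",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Phi-based Fst between populations or species groups.

    For every pair of groups a one-way AMOVA on the squared band-profile
    distances gives ``Fst = among-group variance / total variance``
    (truncated at zero).  Returns ``(fst, p)`` as symmetric labelled
    matrices; the permutation p is NaN when either group has a single
    member or permutations are disabled.
    """
    col = {"population": "population_id", "species": "species_group"}.get(level)
    if col is None:
        raise ValueError("level must be 'population' or 'species'")
    groups = sorted(ds.meta[col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    d2_filled, n_imputed = _fill_undefined(squared_band_distances(ds).to_numpy())
    if n_imputed:
        import warnings

        warnings.warn(f"mean-imputed {n_imputed} undefined pairwise distances")
    d2_all = pd.DataFrame(d2_filled, index=ds.accession_ids, columns=ds.accession_ids)
    acc_by_group = {
        gname: list(ds.meta.index[ds.meta[col].astype(str) == gname]) for gname in groups
    }
    rng = np.random.default_rng(seed)
    k = len(groups)
    fst = np.zeros((k, k))
    pmat = np.full((k, k), math.nan)
    np.fill_diagonal(pmat, math.nan)
    for i in range(k):
        for j in range(i + 1, k):
            a_ids, b_ids = acc_by_group[groups[i]], acc_by_group[groups[j]]
            ids = a_ids + b_ids
            d2 = d2_all.loc[ids, ids].to_numpy()
            codes = np.array([0] * len(a_ids) + [1] * len(b_ids))
            phi = _two_level_phi(d2, codes, 2)[0]
            fst[i, j] = fst[j, i] = 0.0 if math.isnan(phi) else phi
            if n_perm > 0 and len(a_ids) >= 2 and len(b_ids) >= 2 and not math.isnan(phi):
                exceed = 0
                for _ in range(n_perm):
                    perm = rng.permutation(codes)
                    phi_p = _two_level_phi(d2, perm, 2)[0]
                    if not math.isnan(phi_p) and phi_p >= phi:
                        exceed += 1
                pmat[i, j] = pmat[j, i] = (1 + exceed) / (1 + n_perm)
    return (
        pd.DataFrame(fst, index=groups, columns=groups),
        pd.DataFrame(pmat, index=groups, columns=groups),
    )


def nm_from_fst(fst):
    """Island-model gene-flow estimate ``Nm = (1 - Fst) / (4 Fst)``.

    Accepts a scalar or array; non-positive Fst maps to ``inf`` (no
    detectable differentiation implies unbounded exchange), Fst above 1 is
    an input error.
    """
    arr = np.asarray(fst, dtype=float)
    if np.nanmax(arr, initial=0.0) > 1.0:
        raise ValueError("Fst cannot exceed 1")
    with np.errstate(divide="ignore"):
        out = np.where(arr > 0, (1.0 - arr) / (4.0 * arr), np.inf)
    out = np.where(np.isnan(arr), np.nan, out)
    if np.isscalar(fst) or np.ndim(fst) == 0:
        return float(out)
    if isinstance(fst, pd.DataFrame):
        return pd.DataFrame(out, index=fst.index, columns=fst.columns)
    return out


# ---------------------------------------------------------------------------
# geography & Mantel
# ---------------------------------------------------------------------------


def geo_distance_matrix(meta: pd.DataFrame, level: str = "population_id") -> pd.DataFrame:
    """Great-circle (haversine) distances in km between population centroids.

    Accession coordinates are averaged per population; populations with any
    missing coordinate are excluded with a warning.
    """
    cent = meta.groupby(level)[["longitude", "latitude"]].mean()
    bad = cent[cent.isna().any(axis=1)]
    if len(bad):
        import warnings

        warnings.warn(f"excluding populations without coordinates: {list(bad.index)}")
        cent = cent.dropna()
    lon = np.radians(cent["longitude"].to_numpy())
    lat = np.radians(cent["latitude"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=cent.index, columns=cent.index)


@dataclass
class MantelResult:
    r: float
    r2: float
    p: float
    n_permutations: int
    seed: int | None


def mantel(
    dist_a: pd.DataFrame,
    dist_b: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test of matrix correlation.

    ``r`` is the Pearson correlation over lower-triangle entries after
    aligning ``dist_b`` to ``dist_a``'s labels; the one-sided p-value
    permutes rows and columns of one matrix jointly and counts permuted
    correlations at least as large as the observed one.
    """
    labels = list(dist_a.index)
    if set(labels) != set(dist_b.index):
        raise ValueError("distance matrices must share labels")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    A = dist_a.to_numpy(dtype=float)
    B = dist_b.loc[labels, labels].to_numpy(dtype=float)
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("distance matrices contain undefined entries")
    n = len(labels)
    il = np.tril_indices(n, k=-1)
    a, b = A[il], B[il]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    az = (a - a.mean()) / a.std()
    r = float(np.mean(az * (b - b.mean()) / b.std()))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B[np.ix_(perm, perm)][il]
        rp = np.mean(az * (bp - bp.mean()) / bp.std())
        if rp >= r:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(r=r, r2=r * r, p=p, n_permutations=n_perm, seed=seed)
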