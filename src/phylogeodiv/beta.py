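"""Beta diversity, geographic/environmental distance, and the decay tests.

Distance matrices are plain labelled DataFrames (symmetric, zero diagonal)
so they can be written as TSV and fed to the Mantel and PERMANOVA tests
without conversion.  Conventions:

* unweighted UniFrac is the fraction of branch length unique to either
  site over the branch length spanned by their union, root-inclusive;
* the "weighted" vs "unweighted" *views* of a community are about which
  strains populate it (all strains vs one per OTU), which is distinct from
  the abundance-weighted UniFrac variant — both are provided;
* permutation p-values use the smoothed ``(1+b)/(1+n)`` estimator; the
  Mantel and PERMANOVA nulls can be enumerated exhaustively for small n.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from ._tree import edge_table

__all__ = [
    "TestResult",
    "unifrac",
    "unifrac_significance",
    "bray_curtis",
    "haversine_matrix",
    "env_distance",
    "mantel",
    "permanova",
    "correlation_table",
]

EARTH_RADIUS_KM = 6371.0088


@dataclasses.dataclass
class TestResult:
    """Outcome of a permutation test, with its provenance."""

    name: str
    statistic: float
    r_squared: float
    p_value: float
    n_perm: int
    seed: int | None = None
    extra: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.update(d.pop("extra"))
        return d


def _as_distance_df(values: np.ndarray, labels, kind: str) -> pd.DataFrame:
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    df.attrs["kind"] = kind
    return df


# ---------------------------------------------------------------------------
# Community dissimilarity

def unifrac(tree: dendropy.Tree, community: pd.DataFrame,
            variant: str = "unweighted") -> pd.DataFrame:
    """Pairwise UniFrac distance between the sites of a community matrix.

    ``unweighted`` compares presence of branches; ``abundance_weighted``
    weights each branch by the absolute difference in the fraction of each
    site's strains found below it, normalized so the distance stays in
    [0, 1].
    """
    if variant not in {"unweighted", "abundance_weighted"}:
        raise ValueError(f"unknown UniFrac variant {variant!r}")
    lengths, incidence, labels = edge_table(tree)
    taxa = [t for t in community.columns]
    missing = set(taxa) - set(labels)
    if missing:
        raise KeyError(f"community taxa not in tree: {sorted(missing)[:5]}")
    if (community.sum(axis=1) == 0).any():
        empty = community.index[community.sum(axis=1) == 0].tolist()
        raise ValueError(f"empty site(s): {empty}")
    col = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(community), len(labels)))
    for j, t in enumerate(taxa):
        counts[:, col[t]] = community[t].values
    # fraction of each site's strains below every edge
    frac = (incidence.astype(float) @ counts.T) / counts.sum(axis=1)
    spanned = frac > 0
    sites = list(community.index)
    n = len(sites)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if variant == "unweighted":
                union = spanned[:, i] | spanned[:, j]
                uniq = spanned[:, i] ^ spanned[:, j]
                denom = lengths[union].sum()
                out[i, j] = out[j, i] = (
                    lengths[uniq].sum() / denom if denom > 0 else 0.0)
            else:
                num = (lengths * np.abs(frac[:, i] - frac[:, j])).sum()
                denom = (lengths * (frac[:, i] + frac[:, j])).sum()
                out[i, j] = out[j, i] = num / denom if denom > 0 else 0.0
    return _as_distance_df(out, sites, f"unifrac_{variant}")


def unifrac_significance(tree: dendropy.Tree, community: pd.DataFrame,
                         variant: str = "unweighted", n_perm: int = 999,
                         seed: int = 0) -> pd.DataFrame:
    """Per-pair p-values for UniFrac under random strain re-assortment.

    Strain records of the two sites are pooled and site labels permuted
    (site totals preserved); p is the one-sided smoothed fraction of
    permuted distances at least as large as the observed one.
    """
    if len(community) < 2:
        raise ValueError("need at least 2 sites")
    obs = unifrac(tree, community, variant)
    rng = np.random.default_rng(seed)
    sites = list(community.index)
    taxa = list(community.columns)
    pvals = pd.DataFrame(np.ones((len(sites), len(sites))),
                         index=sites, columns=sites)
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            pool = np.repeat(
                np.arange(len(taxa)),
                (community.loc[a].values + community.loc[b].values))
            n_a = int(community.loc[a].sum())
            hits = 0
            for _ in range(n_perm):
                rng.shuffle(pool)
                perm = pd.DataFrame(
                    [np.bincount(pool[:n_a], minlength=len(taxa)),
                     np.bincount(pool[n_a:], minlength=len(taxa))],
                    index=[a, b], columns=taxa)
                perm = perm.loc[:, perm.sum(axis=0) > 0]
                d = unifrac(tree, perm, variant).iloc[0, 1]
                hits += d >= obs.at[a, b] - 1e-12
            p = (1 + hits) / (n_perm + 1)
            pvals.at[a, b] = pvals.at[b, a] = p
    return pvals


def bray_curtis(community: pd.DataFrame,
                view: str = "weighted") -> pd.DataFrame:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)`` between sites.

    The ``weighted`` view uses the strain counts as-is; ``unweighted``
    collapses every taxon to presence/absence first (one sequence per OTU).
    """
    if view not in {"weighted", "unweighted"}:
        raise ValueError(f"unknown view {view!r}")
    x = community.values.astype(float)
    if view == "unweighted":
        x = (x > 0).astype(float)
    if (x.sum(axis=1) == 0).any():
        empty = community.index[x.sum(axis=1) == 0].tolist()
        raise ValueError(f"empty site(s): {empty}")
    n = len(community)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = np.abs(x[i] - x[j]).sum()
            den = (x[i] + x[j]).sum()
            out[i, j] = out[j, i] = num / den
    return _as_distance_df(out, community.index, f"braycurtis_{view}")


# ---------------------------------------------------------------------------
# Geographic / environmental distance

def haversine_matrix(sites: pd.DataFrame) -> pd.DataFrame:
    """Great-circle distances (km) between sites from latitude/longitude."""
    lat = np.radians(sites["latitude"].values.astype(float))
    lon = np.radians(sites["longitude"].values.astype(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :]
         * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return _as_distance_df(d, sites.index, "geographic_km")


def env_distance(sites: pd.DataFrame, variables: list[str],
                 standardize: bool = True) -> pd.DataFrame:
    """Euclidean distance on (z-scored) environmental variables.

    Standardization uses the population SD across sites.  A zero-variance
    variable carries no information and is dropped with a warning.
    """
    if not variables:
        raise ValueError("need at least one variable")
    x = sites[variables].astype(float)
    if x.isna().any().any():
        raise ValueError("missing values in environmental variables")
    keep = []
    for v in variables:
        if x[v].std(ddof=0) == 0:
            warnings.warn(f"dropping zero-variance variable {v!r}",
                          stacklevel=2)
        else:
            keep.append(v)
    if not keep:
        raise ValueError("all variables have zero variance")
    z = x[keep].values
    if standardize:
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)
    diff = z[:, None, :] - z[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return _as_distance_df(d, sites.index, "environmental")


# ---------------------------------------------------------------------------
# Tests

def _check_paired(d1: pd.DataFrame, d2: pd.DataFrame) -> None:
    if list(d1.index) != list(d2.index):
        raise ValueError("distance matrices have mismatched labels")


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(d1: pd.DataFrame, d2: pd.DataFrame, n_perm: int = 1000,
           seed: int = 0, exhaustive: bool = False) -> TestResult:
    """Mantel test: Pearson correlation of two distance matrices.

    The statistic is the Pearson r over upper-triangle entries; the
    reported ``r_squared`` is its square (the sign lives in ``statistic``).
    p is one-sided (permuted r >= observed), permuting rows and columns of
    *d2* jointly, smoothed; with ``exhaustive=True`` all n! relabelings are
    enumerated and p is the exact null fraction.
    """
    _check_paired(d1, d2)
    n = len(d1)
    if n < 4:
        raise ValueError("Mantel needs at least 4 observations")
    a = _upper(d1.values.astype(float))
    if np.ptp(a) == 0 or np.ptp(_upper(d2.values.astype(float))) == 0:
        raise ValueError("constant distance matrix")
    m2 = d2.values.astype(float)
    r_obs = _pearson(a, _upper(m2))
    if exhaustive:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            r = _pearson(a, _upper(m2[np.ix_(perm, perm)]))
            hits += r >= r_obs - 1e-12
            total += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            r = _pearson(a, _upper(m2[np.ix_(perm, perm)]))
            hits += r >= r_obs - 1e-12
        p = (1 + hits) / (n_perm + 1)
        n_used = n_perm
    return TestResult("mantel", float(r_obs), float(r_obs ** 2), float(p),
                      n_used, seed, {"n": n})


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / math.sqrt((a @ a) * (b @ b)))


def _design(variable: pd.Series) -> np.ndarray:
    if variable.dtype == object or variable.dtype.name in ("category", "bool"):
        dummies = pd.get_dummies(variable.astype(str), drop_first=True)
        x = dummies.values.astype(float)
        if x.shape[1] == 0:
            raise ValueError("explanatory factor has a single level")
    else:
        x = variable.values.astype(float)[:, None]
        if np.ptp(x) == 0:
            raise ValueError("explanatory variable is constant")
    return np.column_stack([np.ones(len(variable)), x])


def _permanova_stats(gower: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    n = gower.shape[0]
    hat = x @ np.linalg.pinv(x.T @ x) @ x.T
    ss_total = np.trace(gower)
    ss_model = np.trace(hat @ gower @ hat)
    ss_resid = ss_total - ss_model
    df_model = np.linalg.matrix_rank(x) - 1
    if df_model < 1:
        raise ValueError("singular design")
    df_resid = n - df_model - 1
    f = (ss_model / df_model) / (ss_resid / df_resid)
    return f, ss_model / ss_total


def permanova(dist: pd.DataFrame, variable: pd.Series, n_perm: int = 999,
              seed: int = 0, exhaustive: bool = False) -> TestResult:
    """One-variable PERMANOVA (adonis-style) on a distance matrix.

    Partitions the Gower-centered inner-product form of the squared
    distances against a single covariate or factor; the pseudo-F and
    R² = SS_model/SS_total follow the usual sequential sum-of-squares
    decomposition, and p permutes the explanatory variable.
    """
    variable = variable.loc[dist.index]
    x = _design(variable)
    d2 = dist.values.astype(float) ** 2
    n = len(dist)
    j = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * j @ d2 @ j
    f_obs, r2 = _permanova_stats(gower, x)
    raw = x[:, 1:]
    if exhaustive:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            xp = np.column_stack([np.ones(n), raw[list(perm)]])
            f, _ = _permanova_stats(gower, xp)
            hits += f >= f_obs - 1e-12
            total += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            xp = np.column_stack([np.ones(n), raw[rng.permutation(n)]])
            f, _ = _permanova_stats(gower, xp)
            hits += f >= f_obs - 1e-12
        p = (1 + hits) / (n_perm + 1)
        n_used = n_perm
    return TestResult("permanova", float(f_obs), float(r2), float(p),
                      n_used, seed, {"n": n, "variable": variable.name})


def correlation_table(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """All pairwise Pearson correlations among per-site statistics.

    Returns ``{"r": ..., "p": ..., "stars": ...}`` DataFrames; p-values are
    two-sided from the t(n−2) transform.  A constant column has no defined
    correlation and is reported as missing.
    """
    cols = list(table.columns)
    n_sites = len(table)
    if n_sites < 3:
        raise ValueError("need at least 3 sites")
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            x = table[a].astype(float)
            y = table[b].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            rv, pv = stats.pearsonr(x[ok], y[ok])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    stars = p.map(lambda v: "" if pd.isna(v) else
                  "***" if v < 0.001 else "**" if v < 0.01 else
                  "*" if v < 0.05 else "")
    return {"r": r, "p": p, "stars": stars}
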