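"""Diversity indices and paired eDNA-vs-capture assemblage comparisons.

A single eDNA sample is compared against annual electrofishing (TEF)
surveys at the nearest same-reach-type site: species richness, Shannon
diversity H (nats) and Pielou evenness J = H/ln S; rank correlation between
read proportions and catch-per-unit-effort; and an exact sign test for
systematic abundance bias per species across locations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CatchTable",
    "DiversityIndices",
    "diversity",
    "pair_sites",
    "richness_comparison",
    "abundance_bias_test",
    "spearman_site_correlation",
    "richness_trend",
    "trend_free_sites",
]


@dataclass
class CatchTable:
    """Electrofishing catches accumulated over annual surveys.

    ``catches`` is long-format with columns (site, year, species, count);
    ``effort`` maps (site, year) to the effort unit used for CPUE.
    """

    catches: pd.DataFrame
    effort: pd.DataFrame
    km: pd.Series | None = None

    def __post_init__(self) -> None:
        need = {"site", "year", "species", "count"}
        if not need.issubset(self.catches.columns):
            raise ValueError(f"catches needs columns {sorted(need)}")
        if (self.catches["count"] < 0).any():
            raise ValueError("catch counts must be non-negative")
        if not {"site", "year", "effort"}.issubset(self.effort.columns):
            raise ValueError("effort needs columns site, year, effort")

    @property
    def sites(self) -> list:
        return sorted(self.catches["site"].unique())

    def years(self, site) -> list:
        return sorted(self.catches.loc[self.catches["site"] == site, "year"].unique())

    def annual_richness(self, site) -> pd.Series:
        """Species count per survey year at one site."""
        sub = self.catches[(self.catches["site"] == site) & (self.catches["count"] > 0)]
        return sub.groupby("year")["species"].nunique().reindex(self.years(site), fill_value=0)

    def cumulative_richness(self, site) -> int:
        """Species caught at least once over all survey years."""
        sub = self.catches[(self.catches["site"] == site) & (self.catches["count"] > 0)]
        return int(sub["species"].nunique())

    def mean_cpue(self, site) -> pd.Series:
        """Catch per unit effort per year, averaged across years, per species."""
        sub = self.catches[self.catches["site"] == site].merge(
            self.effort, on=["site", "year"], how="left"
        )
        if sub["effort"].isna().any():
            raise ValueError(f"missing effort for some years at site {site!r}")
        sub["cpue"] = sub["count"] / sub["effort"]
        wide = sub.pivot_table(index="year", columns="species", values="cpue", fill_value=0.0)
        return wide.mean(axis=0)

    def proportions(self, site) -> pd.Series:
        cpue = self.mean_cpue(site)
        total = cpue.sum()
        if total == 0:
            raise ValueError(f"no catches at site {site!r}")
        return cpue / total


@dataclass(frozen=True)
class DiversityIndices:
    richness: int
    shannon: float
    evenness: float  # NaN when S == 1 (undefined)


def diversity(abundances) -> DiversityIndices:
    """Richness S, Shannon H = −Σ pᵢ ln pᵢ (nats), evenness J = H / ln S.

    Accepts proportions or raw counts (normalized internally); zero entries
    are ignored.  J is reported as NaN for a single-species assemblage.
    """
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("all-zero abundance vector")
    p = p / p.sum()
    s = int(p.size)
    h = float(-(p * np.log(p)).sum())
    j = h / math.log(s) if s > 1 else float("nan")
    return DiversityIndices(richness=s, shannon=h, evenness=j)


def pair_sites(edna_sites: pd.DataFrame, tef_sites: pd.DataFrame) -> pd.DataFrame:
    """Pair each river section's eDNA and capture sites for local comparison.

    Both inputs need columns (site, section, reach_type, km).  Within each
    section only same-reach-type pairs are eligible; the least distant pair
    (|Δ km| along the river axis) wins, ties broken lexicographically on
    (eDNA site, TEF site).  At most one pair per section; sections with no
    eligible candidate are skipped with a log entry.
    """
    need = {"site", "section", "reach_type", "km"}
    for name, df in (("edna_sites", edna_sites), ("tef_sites", tef_sites)):
        if not need.issubset(df.columns):
            raise ValueError(f"{name} needs columns {sorted(need)}")
    rows = []
    for section in sorted(set(edna_sites["section"]) | set(tef_sites["section"])):
        e = edna_sites[edna_sites["section"] == section]
        t = tef_sites[tef_sites["section"] == section]
        candidates = []
        for _, er in e.iterrows():
            for _, tr in t.iterrows():
                if er["reach_type"] != tr["reach_type"]:
                    continue
                d = abs(float(er["km"]) - float(tr["km"]))
                candidates.append((d, str(er["site"]), str(tr["site"])))
        if not candidates:
            logger.info("section %r: no same-reach-type eDNA/TEF pair; skipped", section)
            continue
        d, es, ts = min(candidates)
        rows.append({"section": section, "edna_site": es, "tef_site": ts, "distance_km": d})
    return pd.DataFrame(rows, columns=["section", "edna_site", "tef_site", "distance_km"])


def richness_comparison(
    annual_richness: dict,
    edna_richness: dict,
    cumulative_richness: dict | None = None,
    min_years: int = 2,
) -> tuple[pd.DataFrame, tuple[float, float] | None]:
    """Compare eDNA richness against annual and cumulative capture richness.

    Per location: one-sample Wilcoxon signed-rank of the annual TEF
    richness values against the paired eDNA richness constant, one-sided
    toward TEF-lower (the direction of interest: a single survey misses
    species an eDNA sample integrates).  Across locations, when
    ``cumulative_richness`` is given: two-sided Wilcoxon signed-rank of the
    cumulative TEF richness against the eDNA richness — testing whether a
    decade of surveys matches one eDNA sample.

    ``annual_richness`` maps location -> iterable of annual richness values;
    ``edna_richness`` maps location -> richness of the paired eDNA sample;
    ``cumulative_richness`` maps location -> species count accumulated over
    all survey years.  Returns (per-location table, (stat, p) of the
    cross-location test or None).
    """
    rows = []
    for loc, annual in annual_richness.items():
        annual = np.asarray(list(annual), dtype=float)
        if loc not in edna_richness:
            continue
        if annual.size < min_years:
            logger.info("location %r has < %d annual samples; excluded", loc, min_years)
            continue
        e = float(edna_richness[loc])
        diffs = annual - e
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(diffs, alternative="less")
        rows.append(
            {
                "location": loc,
                "n_years": int(annual.size),
                "mean_annual_richness": float(annual.mean()),
                "edna_richness": e,
                "wilcoxon_stat": float(stat),
                "p_lower": float(p),
            }
        )
    per_loc = pd.DataFrame(rows)
    cross = None
    if cumulative_richness is not None:
        cross = cumulative_richness_test(cumulative_richness, edna_richness)
    return per_loc, cross


def cumulative_richness_test(
    cumulative_tef: dict, edna_richness: dict
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank of cumulative TEF vs eDNA richness.

    Needs >= 6 paired locations.  Returns (statistic, p); p = 1.0 when all
    paired differences are zero (no evidence of any difference).
    """
    locs = sorted(set(cumulative_tef) & set(edna_richness))
    if len(locs) < 6:
        raise ValueError("need >= 6 paired locations for the cross-location test")
    a = np.array([float(cumulative_tef[l]) for l in locs])
    b = np.array([float(edna_richness[l]) for l in locs])
    diffs = a - b
    if np.all(diffs == 0):
        return 0.0, 1.0
    stat, p = stats.wilcoxon(diffs, alternative="two-sided")
    return float(stat), float(p)


def abundance_bias_test(
    edna_prop: pd.DataFrame,
    catch_prop: pd.DataFrame,
    alpha: float = 0.05,
    min_locations: int = 6,
) -> pd.DataFrame:
    """Exact sign test for systematic per-species abundance bias.

    Inputs are location × species proportion tables from each method.  For
    each species present (either method) in at least ``min_locations``
    locations, the sign of (eDNA − catch) per location enters an exact
    binomial sign test (ties dropped); significance is judged against the
    Bonferroni-corrected threshold alpha / m, m = number of species tested.
    Direction 'edna' marks eDNA-enriched species, 'catch' capture-enriched.
    """
    species = sorted(set(edna_prop.columns) | set(catch_prop.columns))
    locs = sorted(set(edna_prop.index) & set(catch_prop.index))
    e = edna_prop.reindex(index=locs, columns=species, fill_value=0.0)
    c = catch_prop.reindex(index=locs, columns=species, fill_value=0.0)
    rows = []
    for sp in species:
        present = (e[sp] > 0) | (c[sp] > 0)
        if int(present.sum()) < min_locations:
            continue
        d = (e.loc[present, sp] - c.loc[present, sp]).to_numpy()
        d = d[d != 0]
        n = int(d.size)
        n_pos = int((d > 0).sum())
        p = stats.binomtest(n_pos, n, 0.5).pvalue if n > 0 else 1.0
        rows.append(
            {
                "species": sp,
                "n_locations": n,
                "n_edna_higher": n_pos,
                "p": float(p),
                "direction": "edna" if n_pos > n - n_pos else ("catch" if n_pos < n - n_pos else "none"),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        m = len(out)
        out["p_threshold"] = alpha / m
        out["significant"] = out["p"] < alpha / m
    return out


def spearman_site_correlation(edna: pd.Series, catch: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation between read counts and catches at one site.

    Species absent from both methods are excluded; mid-rank ties.  Requires
    at least 5 species with a value in either method; a constant vector
    yields (nan, nan).
    """
    species = sorted(set(edna.index) | set(catch.index))
    e = edna.reindex(species, fill_value=0.0).astype(float)
    c = catch.reindex(species, fill_value=0.0).astype(float)
    mask = (e > 0) | (c > 0)
    e, c = e[mask], c[mask]
    if len(e) < 5:
        raise ValueError("need >= 5 species present in either method")
    if e.nunique() == 1 or c.nunique() == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(e, c)
    return float(rho), float(p)


def richness_trend(years, richness) -> tuple[float, float]:
    """Poisson-GLM slope of annual richness on year and its p-value.

    Used to verify that a site's richness shows no consistent temporal
    trend before its annual surveys are pooled.  Needs >= 5 annual values.
    """
    years = np.asarray(years, dtype=float)
    richness = np.asarray(richness, dtype=float)
    if years.size < 5:
        raise ValueError("need >= 5 annual values")
    X = sm.add_constant(years - years.mean())
    res = sm.GLM(richness, X, family=sm.families.Poisson()).fit()
    slope = float(res.params[1])
    p = float(res.pvalues[1])
    if np.isnan(p):  # constant series: zero slope, no evidence of trend
        slope, p = 0.0, 1.0
    return slope, p


def trend_free_sites(annual_richness: dict, alpha: float = 0.05) -> list:
    """Sites whose annual richness shows no significant temporal trend."""
    keep = []
    for site, series in annual_richness.items():
        series = pd.Series(series)
        years = np.asarray(series.index, dtype=float)
        _, p = richness_trend(years, series.to_numpy())
        if p > alpha:
            keep.append(site)
        else:
            logger.info("site %r shows a richness trend (p=%.3g); excluded", site, p)
    return keep
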