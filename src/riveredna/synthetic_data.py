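"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure a river-scale eDNA
metabarcoding survey assumes, so every pipeline stage is testable offline:

* a longitudinal species-turnover gradient from Gaussian niche-response
  curves along the river axis;
* optional downstream mixing of the eDNA signal — each site receives
  first-order-decayed contributions from all upstream sites, the mechanism
  by which transported eDNA lengthens spatial autocorrelation;
* multinomial read sampling at site-specific sequencing depths;
* PCR-replicate detections following the logit-linear model in log read
  count that the detection GLM fits;
* bank-biased, overdispersed (negative binomial) electrofishing catches
  across annual surveys.

Defaults mirror the motivating survey: ~40 sites over a 500-km river,
24 PCR replicates, a rarefaction-scale sequencing depth floor of 163,121
reads, ten annual capture surveys, and detection-curve parameters
(a, b) = (−6.0, 1.2).  Every generator is a pure function of
(scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .assemblage import CatchTable
from .readtable import MOTUReadTable

__all__ = [
    "SyntheticScenario",
    "kilometre_points",
    "true_assemblage",
    "apply_transport",
    "simulate_reads",
    "simulate_pcr",
    "simulate_catches",
    "simulate_survey",
    "simulate_detection_records",
]


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic survey.

    ``niche_optima`` (km), ``niche_breadth`` (km), ``max_abundance`` and
    ``catchability_bias`` may be scalars (broadcast) or per-species arrays;
    unset optima default to even spacing along the river.
    ``transport_sp_km`` is the e-folding mixing length of downstream eDNA
    transport (0 = no mixing).  ``overdispersion`` is the negative-binomial
    size of the catch counts (larger = closer to Poisson).
    """

    n_sites: int = 40
    river_length_km: float = 500.0
    n_species: int = 30
    niche_optima: np.ndarray | None = None
    niche_breadth: float | np.ndarray = 50.0
    max_abundance: float | np.ndarray = 1.0
    read_depth_range: tuple[int, int] = (163_121, 400_000)
    glm_intercept: float = -6.0
    glm_slope: float = 1.2
    pcr_replicates: int = 24
    transport_sp_km: float = 0.0
    catchability_bias: float | np.ndarray = 1.0
    overdispersion: float = 5.0
    n_years: int = 10
    effort: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2 or self.n_species < 1:
            raise ValueError("need >= 2 sites and >= 1 species")
        if self.river_length_km <= 0:
            raise ValueError("river_length_km must be positive")
        if self.niche_optima is None:
            self.niche_optima = np.linspace(0.0, self.river_length_km, self.n_species)
        self.niche_optima = np.asarray(self.niche_optima, dtype=float)
        if self.niche_optima.size != self.n_species:
            raise ValueError("niche_optima length must equal n_species")
        if (self.niche_optima < 0).any() or (self.niche_optima > self.river_length_km).any():
            raise ValueError("niche optima must lie within [0, river_length_km]")
        self.niche_breadth = np.broadcast_to(
            np.asarray(self.niche_breadth, dtype=float), (self.n_species,)
        ).copy()
        self.max_abundance = np.broadcast_to(
            np.asarray(self.max_abundance, dtype=float), (self.n_species,)
        ).copy()
        self.catchability_bias = np.broadcast_to(
            np.asarray(self.catchability_bias, dtype=float), (self.n_species,)
        ).copy()
        if (self.niche_breadth <= 0).any() or (self.max_abundance <= 0).any():
            raise ValueError("niche breadth and max abundance must be positive")
        lo, hi = self.read_depth_range
        if not 0 < lo <= hi:
            raise ValueError("read_depth_range must satisfy 0 < min <= max")
        if self.transport_sp_km < 0:
            raise ValueError("transport_sp_km must be >= 0")

    @property
    def species(self) -> list[str]:
        return [f"sp{i + 1:03d}" for i in range(self.n_species)]

    @property
    def sites(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_sites)]


def kilometre_points(scenario: SyntheticScenario) -> pd.Series:
    """Evenly spaced site positions along the river (km downstream)."""
    return pd.Series(
        np.linspace(0.0, scenario.river_length_km, scenario.n_sites),
        index=scenario.sites,
        name="km",
    )


def true_assemblage(scenario: SyntheticScenario) -> pd.DataFrame:
    """Site × species relative abundances from Gaussian niche responses.

    abundance(s, i) ∝ max_abundanceᵢ · exp(−(KPₛ − optᵢ)² / (2·breadthᵢ²)),
    rows normalized to 1.  Deterministic (no randomness).
    """
    km = kilometre_points(scenario).to_numpy()[:, None]
    opt = scenario.niche_optima[None, :]
    br = scenario.niche_breadth[None, :]
    resp = scenario.max_abundance[None, :] * np.exp(-((km - opt) ** 2) / (2 * br**2))
    resp = resp / resp.sum(axis=1, keepdims=True)
    return pd.DataFrame(resp, index=scenario.sites, columns=scenario.species)


def apply_transport(
    assemblage: pd.DataFrame, km: pd.Series, sp_km: float
) -> pd.DataFrame:
    """Mix downstream sites with exponentially decayed upstream signal.

    signal(s) ∝ local(s) + Σ_{u upstream of s} local(u)·exp(−Δkm/sp_km),
    rows renormalized.  ``sp_km = 0`` returns the input unchanged.  Sites
    must be ordered downstream (non-decreasing km).
    """
    pos = km.reindex(assemblage.index).to_numpy(dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("sites must be ordered downstream (non-decreasing km)")
    if sp_km == 0:
        return assemblage.copy()
    if sp_km < 0:
        raise ValueError("sp_km must be >= 0")
    local = assemblage.to_numpy(dtype=float)
    delta = pos[:, None] - pos[None, :]  # km downstream from u to s
    weights = np.where(delta >= 0, np.exp(-delta / sp_km), 0.0)
    mixed = weights @ local
    mixed = mixed / mixed.sum(axis=1, keepdims=True)
    return pd.DataFrame(mixed, index=assemblage.index, columns=assemblage.columns)


def simulate_reads(
    mixed_assemblage: pd.DataFrame, scenario: SyntheticScenario, seed: int | None = None
) -> MOTUReadTable:
    """Multinomial read counts at a uniformly drawn site-specific depth.

    Positive-PCR counts are initialized to zero; :func:`simulate_pcr`
    fills them conditional on the realized reads.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    props = mixed_assemblage.to_numpy(dtype=float)
    if not np.allclose(props.sum(axis=1), 1.0):
        raise ValueError("assemblage rows must sum to 1")
    lo, hi = scenario.read_depth_range
    depths = rng.integers(lo, hi + 1, size=props.shape[0])
    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, props)])
    reads = pd.DataFrame(
        counts, index=mixed_assemblage.index, columns=mixed_assemblage.columns
    )
    km = kilometre_points(scenario).reindex(mixed_assemblage.index)
    return MOTUReadTable(
        reads=reads,
        pcr_positive=pd.DataFrame(0, index=reads.index, columns=reads.columns),
        km=km,
        pcr_replicates=scenario.pcr_replicates,
    )


def simulate_pcr(
    table: MOTUReadTable, scenario: SyntheticScenario, seed: int | None = None
) -> MOTUReadTable:
    """Draw k ~ Binomial(R, logistic(a + b·ln reads)) per cell with reads > 0.

    Conditions on realized reads (the covariate the detection GLM uses),
    not on the underlying true abundance.  Zero-read cells get k = 0.
    """
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    reads = table.reads.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        eta = scenario.glm_intercept + scenario.glm_slope * np.log(
            np.where(reads > 0, reads, 1.0)
        )
    p = np.where(reads > 0, expit(eta), 0.0)
    k = rng.binomial(scenario.pcr_replicates, p)
    return MOTUReadTable(
        reads=table.reads.copy(),
        pcr_positive=pd.DataFrame(k, index=table.reads.index, columns=table.reads.columns),
        km=table.km.copy(),
        pcr_replicates=table.pcr_replicates,
    )


def simulate_catches(
    assemblage: pd.DataFrame, scenario: SyntheticScenario, seed: int | None = None
) -> CatchTable:
    """Negative-binomial annual catch counts with per-species catchability bias.

    count(site, year, species) ~ NB(mean = effort·abundance·biasᵢ,
    size = overdispersion), independent across the ``n_years`` surveys.
    Catches sample the *local* (unmixed) assemblage: fish are caught where
    they live, unlike eDNA which integrates upstream signal.
    """
    rng = np.random.default_rng(scenario.seed + 2 if seed is None else seed)
    ab = assemblage.to_numpy(dtype=float)
    mean = scenario.effort * ab * scenario.catchability_bias[None, :]
    size = scenario.overdispersion
    rows = []
    for y in range(scenario.n_years):
        # NB via gamma-Poisson mixture; mean 0 stays 0
        lam = rng.gamma(shape=size, scale=np.where(mean > 0, mean / size, 0.0))
        counts = rng.poisson(lam)
        for si, site in enumerate(assemblage.index):
            for pi, spp in enumerate(assemblage.columns):
                c = int(counts[si, pi])
                if c > 0:
                    rows.append({"site": site, "year": 2000 + y, "species": spp, "count": c})
    catches = pd.DataFrame(rows, columns=["site", "year", "species", "count"])
    effort = pd.DataFrame(
        [
            {"site": site, "year": 2000 + y, "effort": scenario.effort}
            for site in assemblage.index
            for y in range(scenario.n_years)
        ]
    )
    km = None
    return CatchTable(catches=catches, effort=effort, km=km)


def simulate_survey(
    scenario: SyntheticScenario, seed: int | None = None
) -> dict:
    """End-to-end synthetic survey: assemblage, mixed signal, reads+PCR, catches.

    Returns a dict with keys ``assemblage``, ``mixed``, ``reads`` (a
    :class:`MOTUReadTable` with PCR counts filled), ``catches``, ``km``.
    Sub-seeds are derived deterministically from the master seed.
    """
    master = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(master).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    km = kilometre_points(scenario)
    local = true_assemblage(scenario)
    mixed = apply_transport(local, km, scenario.transport_sp_km)
    reads = simulate_reads(mixed, scenario, seed=sub[0])
    reads = simulate_pcr(reads, scenario, seed=sub[1])
    catches = simulate_catches(local, scenario, seed=sub[2])
    return {"assemblage": local, "mixed": mixed, "reads": reads, "catches": catches, "km": km}


def simulate_detection_records(
    n_records: int,
    intercept: float = -6.0,
    slope: float = 1.2,
    pcr_replicates: int = 24,
    log_reads_range: tuple[float, float] = (np.log(30.0), np.log(20_000.0)),
    seed: int | None = None,
) -> pd.DataFrame:
    """Standalone detection records for parameter-recovery studies.

    log read counts are uniform over ``log_reads_range`` (spanning the
    rising part of the logistic curve) and k ~ Binomial(R, logistic(a+b·x)).
    Returns the long-format record frame the detection GLM consumes.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(*log_reads_range, size=n_records)
    p = expit(intercept + slope * x)
    k = rng.binomial(pcr_replicates, p)
    return pd.DataFrame(
        {
            "motu": ["synthetic"] * n_records,
            "site": [f"rec{i}" for i in range(n_records)],
            "log_reads": x,
            "k": k,
            "R": pcr_replicates,
        }
    )
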