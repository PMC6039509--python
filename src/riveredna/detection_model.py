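"""Binomial-logit models of PCR detection rate versus log standardized reads.

For a MOTU at relative abundance p, the chance that any one of the R PCR
replicates run on a site's sample amplifies it rises with the amount of its
template DNA, which the standardized (rarefied) read count proxies.  The
model is a grouped-binomial GLM::

    k ~ Binomial(R, pi),    logit(pi) = a + b * ln(reads)

optionally with MOTU-identity intercept offsets and per-MOTU slope
interactions.  Explained deviance 1 - D_resid/D_null summarizes fit quality;
nested fits partition the deviance across terms.  Inverting the fitted curve
converts a target detection rate into the relative abundance at which it is
reached — the calibration that lets read proportions be read as abundance.

Cells with zero standardized reads have no defined covariate and are
excluded from fitting (their count is logged); a cell may legitimately have
positive PCRs with zero reads because reads come from sequencing the pooled
PCR products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .readtable import MOTUReadTable

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionRecord",
    "DetectionGLMFit",
    "build_detection_records",
    "select_modelable_motus",
    "fit_detection_glm",
    "fit_separate_motus",
    "deviance_partition",
    "invert_abundance_at_rate",
]

MODEL_FORMS = ("pooled", "per_motu", "identity_interaction")


@dataclass(frozen=True)
class DetectionRecord:
    """One (site, MOTU) observation entering the detection GLM."""

    motu: str
    site: str
    log_reads: float
    k: int
    R: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_reads):
            raise ValueError("log_reads must be finite (zero-read cells are excluded)")
        if not 0 <= self.k <= self.R:
            raise ValueError("k must lie in [0, R]")


def build_detection_records(
    table: MOTUReadTable, motus: Sequence[str] | None = None
) -> pd.DataFrame:
    """Long-format records (motu, site, log_reads, k, R) from a standardized table.

    Only cells with reads > 0 are kept.  Cells with reads = 0 but positive
    PCRs are counted and logged — they exist because sequencing reads derive
    from pooled PCR products and can miss a weak amplicon.
    """
    motus = list(motus) if motus is not None else table.motus
    rows = []
    n_orphan = 0
    for m in motus:
        for s in table.sites:
            reads = int(table.reads.at[s, m])
            k = int(table.pcr_positive.at[s, m])
            if reads > 0:
                rows.append((m, s, float(np.log(reads)), k, table.pcr_replicates))
            elif k > 0:
                n_orphan += 1
    if n_orphan:
        logger.info("excluded %d zero-read cells with positive PCRs", n_orphan)
    return pd.DataFrame(rows, columns=["motu", "site", "log_reads", "k", "R"])


def select_modelable_motus(
    table: MOTUReadTable, min_sites: int = 10, k_min: int = 3, k_max: int = 23
) -> list[str]:
    """MOTUs informative enough for detection modelling.

    A MOTU qualifies when it is present (reads > 0) in more than
    ``min_sites`` sites and its observed positive-PCR counts span the
    detection range: some site at or below ``k_min`` positives and some site
    at or above ``k_max``, so the logistic curve is constrained at both ends.
    """
    if not 0 <= k_min <= table.pcr_replicates or not 0 <= k_max <= table.pcr_replicates:
        raise ValueError("k thresholds must lie within [0, R]")
    out = []
    for m in table.motus:
        present = table.reads[m] > 0
        if int(present.sum()) <= min_sites:
            continue
        ks = table.pcr_positive.loc[present, m]
        if len(ks) and ks.min() <= k_min and ks.max() >= k_max:
            out.append(m)
    return out


def _design_matrix(records: pd.DataFrame, model_form: str) -> pd.DataFrame:
    """Dense design matrix for the requested nested model form.

    pooled:               1 + log_reads
    per_motu:             1 + log_reads + MOTU intercept offsets
    identity_interaction: per_motu + per-MOTU slope offsets
    Reference MOTU = first in sorted order; offsets are relative to it.
    """
    X = pd.DataFrame({"Intercept": 1.0, "log_reads": records["log_reads"].to_numpy()})
    if model_form == "pooled":
        return X
    levels = sorted(records["motu"].unique())
    if len(levels) < 2:
        raise ValueError(f"model form {model_form!r} needs >= 2 MOTUs")
    for lev in levels[1:]:
        ind = (records["motu"] == lev).astype(float).to_numpy()
        X[f"motu[{lev}]"] = ind
        if model_form == "identity_interaction":
            X[f"motu[{lev}]:log_reads"] = ind * records["log_reads"].to_numpy()
    if model_form == "identity_interaction":
        # keep blocks ordered: intercept offsets then interactions
        cols = ["Intercept", "log_reads"]
        cols += [f"motu[{l}]" for l in levels[1:]]
        cols += [f"motu[{l}]:log_reads" for l in levels[1:]]
        X = X[cols]
    return X


@dataclass
class DetectionGLMFit:
    """Fitted binomial-logit detection model.

    ``coefficients`` holds the intercept, the common log-reads slope, and —
    for the richer forms — MOTU offsets relative to the reference MOTU
    (first in sorted order).  ``explained_deviance`` is
    1 − residual/null deviance.
    """

    model_form: str
    coefficients: pd.Series
    standard_errors: pd.Series
    null_deviance: float
    residual_deviance: float
    df_model: int
    nobs: int
    motus: tuple = ()
    converged: bool = True
    cov_params: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.residual_deviance > self.null_deviance + 1e-6:
            raise ValueError("residual deviance exceeds null deviance")

    @property
    def explained_deviance(self) -> float:
        if self.null_deviance == 0:
            return 0.0
        return 1.0 - self.residual_deviance / self.null_deviance

    def intercept_slope(self, motu: str | None = None) -> tuple[float, float]:
        """Resolve (a, b) for one MOTU (or the pooled/reference curve)."""
        a = float(self.coefficients["Intercept"])
        b = float(self.coefficients["log_reads"])
        if motu is not None and self.model_form != "pooled":
            a += float(self.coefficients.get(f"motu[{motu}]", 0.0))
            b += float(self.coefficients.get(f"motu[{motu}]:log_reads", 0.0))
        return a, b

    def predict_rate(self, log_reads, motu: str | None = None) -> np.ndarray:
        a, b = self.intercept_slope(motu)
        return expit(a + b * np.asarray(log_reads, dtype=float))


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.reset_index(drop=True)
    return pd.DataFrame(
        [(r.motu, r.site, r.log_reads, r.k, r.R) for r in records],
        columns=["motu", "site", "log_reads", "k", "R"],
    )


def fit_detection_glm(records, model_form: str = "pooled") -> DetectionGLMFit:
    """Maximum-likelihood binomial-logit fit of k-of-R detections on log reads.

    The response is grouped-binomial (k successes, R−k failures) per record,
    fitted by IRLS.  Perfect separation yields a converged-with-warning fit;
    coefficients are still returned.
    """
    df = _as_frame(records)
    if model_form not in MODEL_FORMS:
        raise ValueError(f"model_form must be one of {MODEL_FORMS}")
    if df["log_reads"].nunique() < 2:
        raise ValueError("need >= 2 distinct log_reads values")
    X = _design_matrix(df, model_form)
    endog = np.column_stack([df["k"].to_numpy(), (df["R"] - df["k"]).to_numpy()])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    converged = True
    try:
        res = model.fit(maxiter=100, tol=1e-8)
        converged = bool(res.converged)
    except Exception:  # pragma: no cover - separation edge
        res = model.fit(maxiter=100, tol=1e-8, method="lbfgs")
        converged = False
    if not converged:
        logger.warning("detection GLM (%s) did not fully converge", model_form)
    return DetectionGLMFit(
        model_form=model_form,
        coefficients=pd.Series(res.params, index=X.columns),
        standard_errors=pd.Series(res.bse, index=X.columns),
        null_deviance=float(res.null_deviance),
        residual_deviance=float(res.deviance),
        df_model=int(res.df_model),
        nobs=int(res.nobs),
        motus=tuple(sorted(df["motu"].unique())),
        converged=converged,
        cov_params=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
    )


def fit_separate_motus(records) -> dict[str, DetectionGLMFit]:
    """Independent pooled-form fits, one per MOTU (the per-taxon curves)."""
    df = _as_frame(records)
    return {
        m: fit_detection_glm(sub, "pooled")
        for m, sub in df.groupby("motu")
        if sub["log_reads"].nunique() >= 2
    }


def deviance_partition(
    base: DetectionGLMFit,
    with_identity: DetectionGLMFit,
    with_interaction: DetectionGLMFit,
) -> pd.DataFrame:
    """Added explained-deviance fractions and LR tests for nested fits.

    The three fits must come from identical records (checked via nobs and
    null deviance).  For each added term the fraction of *total* (null)
    deviance it explains beyond the previous model is reported, with a
    chi-square likelihood-ratio test on the deviance drop.
    """
    from scipy.stats import chi2

    fits = [base, with_identity, with_interaction]
    if len({f.nobs for f in fits}) != 1 or any(
        abs(f.null_deviance - base.null_deviance) > 1e-6 * max(1.0, base.null_deviance)
        for f in fits
    ):
        raise ValueError("fits are not nested on identical records")
    rows = []
    rows.append(
        {
            "term": "log_reads",
            "explained_fraction": base.explained_deviance,
            "added_fraction": base.explained_deviance,
            "lr_stat": base.null_deviance - base.residual_deviance,
            "df": base.df_model,
            "p": float(
                chi2.sf(base.null_deviance - base.residual_deviance, max(base.df_model, 1))
            ),
        }
    )
    for term, prev, cur in (
        ("identity", base, with_identity),
        ("interaction", with_identity, with_interaction),
    ):
        lr = prev.residual_deviance - cur.residual_deviance
        ddf = cur.df_model - prev.df_model
        p = float(chi2.sf(lr, ddf)) if ddf > 0 else 1.0
        rows.append(
            {
                "term": term,
                "explained_fraction": cur.explained_deviance,
                "added_fraction": cur.explained_deviance - prev.explained_deviance,
                "lr_stat": lr,
                "df": ddf,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def invert_abundance_at_rate(
    fit: DetectionGLMFit, target_rate: float, depth: int
):
    """Relative abundance at which the fitted curve reaches ``target_rate``.

    Solves logit(r) = a + b ln(reads*) for reads*, then divides by the
    rarefaction depth.  At r = 0.5 this is exp(−a/b)/depth exactly.  For
    MOTU-specific forms a Series of per-MOTU abundances is returned.
    Requires a strictly positive slope (a decaying curve cannot be inverted
    to an abundance).
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must lie strictly between 0 and 1")

    def _one(a: float, b: float) -> float:
        if b <= 0:
            raise ValueError("non-positive slope: inversion not identifiable")
        return float(np.exp((logit(target_rate) - a) / b)) / depth

    if fit.model_form == "pooled":
        return _one(*fit.intercept_slope())
    return pd.Series(
        {m: _one(*fit.intercept_slope(m)) for m in fit.motus}, name=f"abundance@{target_rate}"
    )
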