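"""Site × MOTU read-count tables: ingestion, filtering, and read standardization.

An eDNA metabarcoding survey yields, per sampling site, an integer read
count for every MOTU (metabarcoding operational taxonomic unit) together
with the number of positive PCR amplifications among the R replicates run
on the site's sample.  Because sequencing depth varies between sites, read
counts are only comparable as relative abundances after rarefaction: every
site is subsampled *without replacement* to a common depth (a multivariate
hypergeometric draw), conventionally the smallest site total.

The :class:`MOTUReadTable` container couples the read matrix, the positive
PCR count matrix, the per-site kilometre points along the river axis, and R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MOTUReadTable",
    "FilterPolicy",
    "filter_taxa",
    "rarefy",
    "relative_abundance",
    "detection_rate",
    "read_motu_table",
    "write_motu_table",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Rules for discarding MOTUs before analysis.

    Parameters
    ----------
    excluded_taxa
        MOTU identifiers dropped as implausible detections (e.g. marine
        species upstream of any saltwater influence, farmed species whose
        DNA enters with effluents).
    min_reads_threshold
        A MOTU whose maximum read count across all sites falls below this
        copy-number threshold is discarded table-wide.
    """

    excluded_taxa: tuple = ()
    min_reads_threshold: int = 10

    def __post_init__(self) -> None:
        if self.min_reads_threshold < 0:
            raise ValueError("min_reads_threshold must be >= 0")
        object.__setattr__(self, "excluded_taxa", tuple(self.excluded_taxa))


@dataclass
class MOTUReadTable:
    """Read counts and PCR detections for one survey.

    Attributes
    ----------
    reads
        Site × MOTU integer read counts; the index is the ordered site
        identifiers, columns are MOTU identifiers.
    pcr_positive
        Same shape as ``reads``: number of positive PCR amplifications for
        that (site, MOTU) cell, each out of ``pcr_replicates``.
    km
        Kilometre point of each site, measured downstream from the river
        origin; indexed like ``reads``.
    pcr_replicates
        Total PCR replicates R run per site (24 in the motivating survey).
    """

    reads: pd.DataFrame
    pcr_positive: pd.DataFrame
    km: pd.Series
    pcr_replicates: int = 24

    def __post_init__(self) -> None:
        self.reads = self.reads.astype(np.int64)
        if self.reads.index.has_duplicates:
            raise ValueError("site identifiers must be unique")
        if (self.reads.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.pcr_replicates <= 0:
            raise ValueError("pcr_replicates must be positive")
        self.pcr_positive = (
            self.pcr_positive.reindex(index=self.reads.index, columns=self.reads.columns)
            .fillna(0)
            .astype(np.int64)
        )
        k = self.pcr_positive.to_numpy()
        if (k < 0).any() or (k > self.pcr_replicates).any():
            raise ValueError("pcr_positive must lie in [0, pcr_replicates]")
        self.km = self.km.reindex(self.reads.index).astype(float)
        if self.km.isna().any():
            missing = self.km.index[self.km.isna()].tolist()
            raise ValueError(f"missing kilometre point for sites {missing}")
        if (self.km < 0).any():
            raise ValueError("kilometre points must be non-negative")

    @property
    def sites(self) -> list:
        return list(self.reads.index)

    @property
    def motus(self) -> list:
        return list(self.reads.columns)

    @property
    def site_totals(self) -> pd.Series:
        """Total reads per site."""
        return self.reads.sum(axis=1)

    def subset_motus(self, motus: Sequence) -> "MOTUReadTable":
        return MOTUReadTable(
            reads=self.reads[list(motus)].copy(),
            pcr_positive=self.pcr_positive[list(motus)].copy(),
            km=self.km.copy(),
            pcr_replicates=self.pcr_replicates,
        )


def filter_taxa(table: MOTUReadTable, policy: FilterPolicy) -> MOTUReadTable:
    """Apply an exclusion list and a table-wide minimum copy threshold.

    Excluded taxa are removed by name; any remaining MOTU whose maximum
    read count over all sites is below ``policy.min_reads_threshold`` is
    also dropped.  The site set is never changed.  Unknown names in the
    exclusion list are logged as warnings, not errors.
    """
    unknown = [t for t in policy.excluded_taxa if t not in table.reads.columns]
    for t in unknown:
        logger.warning("exclusion list names unknown MOTU %r; ignored", t)
    keep = [m for m in table.motus if m not in set(policy.excluded_taxa)]
    sub = table.reads[keep]
    max_counts = sub.max(axis=0)
    keep = [m for m in keep if max_counts[m] >= policy.min_reads_threshold]
    dropped = set(table.motus) - set(keep)
    if dropped:
        logger.info("filter_taxa dropped %d MOTUs: %s", len(dropped), sorted(dropped))
    return table.subset_motus(keep)


def rarefy(table: MOTUReadTable, depth: int | None = None, *, seed: int) -> MOTUReadTable:
    """Standardize read counts by subsampling each site without replacement.

    Each site's counts are replaced by a multivariate hypergeometric draw
    of ``depth`` reads from that site's observed reads (uniform subsample
    without replacement), so every site total equals ``depth`` exactly.
    Deterministic given ``seed``.  PCR detection counts are untouched:
    they describe the amplifications run on the physical sample, not the
    sequenced reads.

    Parameters
    ----------
    depth
        Target reads per site.  Defaults to the smallest observed site
        total, the convention that discards no site.
    seed
        Mandatory RNG seed (reproducibility contract: same seed, same
        build, identical output).
    """
    totals = table.site_totals
    if depth is None:
        depth = int(totals.min())
    depth = int(depth)
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if (totals < depth).any():
        offending = totals.index[totals < depth].tolist()
        raise ValueError(
            f"rarefaction depth {depth} exceeds the total reads at sites {offending}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.reads.to_numpy())
    for i, (_, row) in enumerate(table.reads.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    reads = pd.DataFrame(out, index=table.reads.index, columns=table.reads.columns)
    return MOTUReadTable(
        reads=reads,
        pcr_positive=table.pcr_positive.copy(),
        km=table.km.copy(),
        pcr_replicates=table.pcr_replicates,
    )


def relative_abundance(table: MOTUReadTable) -> pd.DataFrame:
    """Row proportions reads / site total; rows sum to 1.

    Raises on any zero-total site (its proportions are undefined).
    """
    totals = table.site_totals
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"sites with zero total reads: {bad}")
    return table.reads.div(totals, axis=0)


def detection_rate(table: MOTUReadTable) -> pd.DataFrame:
    """Proportion of positive PCR amplifications, pcr_positive / R."""
    return table.pcr_positive / float(table.pcr_replicates)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def read_motu_table(
    reads_path: str | Path,
    pcr_path: str | Path | None = None,
    pcr_replicates: int = 24,
) -> MOTUReadTable:
    """Load a read table (and optional companion PCR table) from delimited text.

    Layout: first column site id, second column kilometre point, remaining
    columns MOTU read counts.  The PCR file has identical shape holding
    positive-amplification counts; when absent, PCR counts default to zero
    (sufficient for stages that only use reads).
    """
    df = _read_delimited(reads_path)
    site_col, km_col = df.columns[:2]
    df = df.set_index(site_col)
    km = df[km_col].astype(float)
    reads = df.drop(columns=[km_col])
    if pcr_path is not None:
        pdf = _read_delimited(pcr_path).set_index(site_col)
        pcr = pdf.drop(columns=[km_col], errors="ignore")
    else:
        logger.warning("no PCR table given; positive-PCR counts set to zero")
        pcr = pd.DataFrame(0, index=reads.index, columns=reads.columns)
    return MOTUReadTable(reads=reads, pcr_positive=pcr, km=km, pcr_replicates=pcr_replicates)


def write_motu_table(
    table: MOTUReadTable, reads_path: str | Path, pcr_path: str | Path | None = None
) -> None:
    """Write the table (and optionally its PCR companion) as TSV."""
    def _dump(df: pd.DataFrame, path: str | Path) -> None:
        out = df.copy()
        out.insert(0, "km", table.km)
        out.index.name = "site"
        out.to_csv(path, sep="\t")

    _dump(table.reads, reads_path)
    if pcr_path is not None:
        _dump(table.pcr_positive, pcr_path)
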