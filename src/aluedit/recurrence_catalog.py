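"""The recurrent-site editing matrix: build, filter, and coverage exclusion.

The matrix holds per-sample editing frequencies at a fixed site panel
(rows: sites, columns: samples).  A cell is computed straight from pileup
counts — zero when the site is covered but unedited, missing (NaN) when
RNA depth at the site falls below the coverage threshold — so a panel can
be re-extracted in an independent cohort without re-running the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .rdd_detection import pileup_frame

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import IntervalSet


@dataclass(frozen=True)
class Site:
    """One panel site: position, coding strand and a display label."""

    contig: str
    pos: int  # 0-based
    strand: str  # '+'/'-': strand carrying the edited adenosine
    label: str = ""

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos + 1}"


@dataclass
class EditingMatrix:
    """Site x sample editing frequencies with explicit missingness.

    ``freq`` is NaN exactly where ``depth`` (edited + unedited reads) is
    below the construction-time coverage threshold; ``edited`` carries the
    raw edited-read counts used for edited-cell decisions.
    """

    sites: list[Site]
    samples: list[str]
    freq: pd.DataFrame  # index: site keys, columns: samples
    depth: pd.DataFrame
    edited: pd.DataFrame
    min_cov: int = 10
    n_absent: int = field(default=0)  # panel sites absent from the pileup entirely

    def __post_init__(self) -> None:
        keys = [s.key for s in self.sites]
        for df in (self.freq, self.depth, self.edited):
            if list(df.index) != keys or list(df.columns) != self.samples:
                raise ValueError("matrix dimensions inconsistent with site/sample lists")
        low = self.depth.to_numpy() < self.min_cov
        miss = self.freq.isna().to_numpy()
        if not (miss == low).all():
            raise ValueError("missing cells must coincide with depth below threshold")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.sites), len(self.samples)

    def site_labels(self) -> list[str]:
        return [s.label or s.key for s in self.sites]

    def subset_samples(self, samples: list[str]) -> "EditingMatrix":
        return replace(
            self,
            samples=list(samples),
            freq=self.freq[samples],
            depth=self.depth[samples],
            edited=self.edited[samples],
        )

    def subset_sites(self, keys: list[str]) -> "EditingMatrix":
        keep = [s for s in self.sites if s.key in set(keys)]
        kk = [s.key for s in keep]
        return replace(
            self,
            sites=keep,
            freq=self.freq.loc[kk],
            depth=self.depth.loc[kk],
            edited=self.edited.loc[kk],
        )

    def edited_cells(self, min_freq: float = 0.01, min_reads: int = 2) -> pd.DataFrame:
        """Boolean frame: non-missing cells with evidence of editing."""
        return (
            self.freq.notna()
            & (self.freq >= min_freq)
            & (self.edited >= min_reads)
        )

    def to_tsv(self, path) -> None:
        out = self.freq.copy()
        out.insert(0, "label", self.site_labels())
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g", index_label="site")


def build_matrix(
    rna,
    panel: list[Site],
    min_cov: int = 10,
) -> EditingMatrix:
    """Build the editing matrix from a multi-sample RNA pileup at a site panel.

    Frequencies are strand-adjusted: edited reads are G at reference-A
    positions for '+' sites and C at reference-T positions for '-' sites;
    the denominator is edited + unedited reads.  Panel sites absent from a
    sample's pileup are missing and tallied in ``n_absent``.
    """
    rna_df = pileup_frame(rna)
    rna_df = rna_df[rna_df["modality"] == "RNA"]
    samples = sorted(rna_df["sample"].unique())
    keys = [s.key for s in panel]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate sites in panel")
    site_df = pd.DataFrame(
        {
            "contig": [s.contig for s in panel],
            "pos": [s.pos for s in panel],
            "strand": [s.strand for s in panel],
            "key": keys,
        }
    )
    merged = site_df.merge(rna_df, on=["contig", "pos"], how="left")
    plus = merged["strand"].to_numpy() == "+"
    merged["edited_reads"] = np.where(plus, merged["nG"], merged["nC"])
    merged["unedited_reads"] = np.where(plus, merged["nA"], merged["nT"])
    merged["cell_depth"] = merged["edited_reads"] + merged["unedited_reads"]

    def _pivot(col: str) -> pd.DataFrame:
        p = merged.pivot_table(index="key", columns="sample", values=col, aggfunc="first")
        return p.reindex(index=keys, columns=samples)

    depth = _pivot("cell_depth")
    edited = _pivot("edited_reads")
    n_absent = int(depth.isna().to_numpy().sum())
    depth = depth.fillna(0).astype(int)
    edited = edited.fillna(0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = edited / depth.where(depth > 0)
    freq = freq.where(depth >= min_cov)
    freq.columns.name = depth.columns.name = edited.columns.name = None
    return EditingMatrix(
        sites=list(panel),
        samples=samples,
        freq=freq,
        depth=depth,
        edited=edited,
        min_cov=min_cov,
        n_absent=n_absent,
    )


def recurrent_sites(
    matrix: EditingMatrix,
    k: int = 5,
    min_freq: float = 0.01,
    min_reads: int = 2,
) -> list[Site]:
    """Sites edited in at least ``k`` samples (non-missing, above thresholds)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    edited = matrix.edited_cells(min_freq=min_freq, min_reads=min_reads)
    n_edited = edited.sum(axis=1)
    keep = set(n_edited.index[n_edited >= k])
    return [s for s in matrix.sites if s.key in keep]


def exclude_low_coverage_sites(
    matrix: EditingMatrix,
    max_missing_frac: float = 0.5,
) -> tuple[EditingMatrix, list[Site]]:
    """Drop sites missing in more than ``max_missing_frac`` of samples.

    Mirrors low-coverage gene exclusion in validation-cohort extraction.
    Raises when every site would be excluded.
    """
    if not 0 < max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in (0, 1]")
    missing_frac = matrix.freq.isna().mean(axis=1)
    keep_keys = [s.key for s in matrix.sites if missing_frac[s.key] <= max_missing_frac]
    excluded = [s for s in matrix.sites if missing_frac[s.key] > max_missing_frac]
    if not keep_keys:
        raise ValueError(
            "all sites excluded by coverage rule; lower max_missing_frac or min_cov"
        )
    return matrix.subset_sites(keep_keys), excluded
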