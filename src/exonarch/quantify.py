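"""Per-sample transcript abundances and exon usage.

Counts come straight from cluster membership; percentages are per-sample
column percentages; exon usage divides the summed counts of transcripts
containing an exon by the sample's total gene expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import TranscriptCluster
from .io import SampleSheet

__all__ = ["CountMatrix", "build_matrix", "core_and_specific", "exon_usage",
           "major_isoforms"]


@dataclass
class CountMatrix:
    """Transcripts x samples integer counts with derived percentages."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def transcripts(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def percentages(self) -> pd.DataFrame:
        # a zero-read sample yields 0/0 -> NA for the whole column
        totals = self.counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return 100.0 * self.counts / totals


def build_matrix(clusters: list[TranscriptCluster],
                 sheet: SampleSheet | list[str]) -> CountMatrix:
    """Counts from per-sample cluster membership; transcripts ordered by
    global abundance (the cluster naming order)."""
    samples = sheet.sample_ids if isinstance(sheet, SampleSheet) else list(sheet)
    data = {s: [cl.per_sample_counts.get(s, 0) for cl in clusters]
            for s in samples}
    counts = pd.DataFrame(data, index=[cl.name for cl in clusters], dtype=int)
    empty = [s for s in samples if counts[s].sum() == 0]
    if empty:
        warnings.warn(f"samples with zero reads: {empty}; percentages are NA",
                      stacklevel=2)
    return CountMatrix(counts)


def core_and_specific(matrix: CountMatrix, grouping: dict[str, str],
                      min_count: int = 1
                      ) -> tuple[set[str], dict[str, set[str]], set[str]]:
    """Partition transcripts into a common core (detected in every tissue),
    tissue-specific sets, and the shared-partial remainder.

    ``grouping`` maps sample_id -> tissue; detection in a tissue means the
    summed count over its samples reaches ``min_count``.
    """
    tissues = sorted(set(grouping.values()))
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    by_tissue = pd.DataFrame({
        t: matrix.counts[[s for s in matrix.samples if grouping[s] == t]].sum(axis=1)
        for t in tissues})
    detected = by_tissue >= min_count
    n_detected = detected.sum(axis=1)
    core = set(detected.index[n_detected == len(tissues)])
    specific: dict[str, set[str]] = {t: set() for t in tissues}
    for t in tissues:
        only_t = detected[t] & (n_detected == 1)
        specific[t] = set(detected.index[only_t])
    partial = set(detected.index) - core - set().union(*specific.values())
    return core, specific, partial


def exon_usage(matrix: CountMatrix, clusters: list[TranscriptCluster],
               exon_names: list[str]) -> pd.DataFrame:
    """usage(e, s) = sum of counts over transcripts containing exon e,
    normalized by the sample's total gene expression; values in [0, 1]."""
    membership = {cl.name: set(cl.barcode.exon_names) for cl in clusters}
    totals = matrix.counts.sum(axis=0)
    rows = {}
    for e in exon_names:
        with_e = [t for t in matrix.transcripts if e in membership[t]]
        rows[e] = matrix.counts.loc[with_e].sum(axis=0) / totals.where(totals > 0)
    return pd.DataFrame(rows).T[matrix.samples]


def major_isoforms(matrix: CountMatrix) -> dict[str, dict]:
    """Per sample: the most abundant transcript and its percentage share."""
    out = {}
    pct = matrix.percentages
    for s in matrix.samples:
        col = pct[s]
        if col.isna().all():
            out[s] = {"transcript": None, "share_pct": None}
        else:
            t = col.idxmax()
            out[s] = {"transcript": t, "share_pct": float(col[t])}
    return out
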