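"""Windowed gene-class density over a genome annotation, with cluster
calling — the scan used to show that the male-sterility interval coincides
with one of the genome's densest pentatricopeptide-repeat (PPR) clusters.

Genes are binned into non-overlapping windows (default 1 Mb) tiling each
chromosome.  A gene belongs to the window containing its start coordinate
(configurable to midpoint); internally windows are half-open
``[k·w, (k+1)·w)`` in 0-based coordinates, so no gene is double counted at a
boundary.  The final partial window is retained with its density scaled by
its true span, and window counts always sum to the total number of genes of
the class.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

from .model import ModelError

__all__ = [
    "GeneRecord",
    "WindowDensity",
    "read_gff3_genes",
    "window_counts",
    "interval_count",
    "call_clusters",
    "GeneCluster",
    "GeneClassWindowScan",
]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene with 1-based inclusive coordinates and free-form
    class labels (e.g. "PPR", a gene-family id, "mitochondrial-targeted")."""

    chromosome: str
    start: int
    end: int
    strand: str
    gene_id: str
    classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelError(f"gene {self.gene_id}: start > end")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_gff3_genes(
    path,
    class_key: str = "gene_class",
    feature_type: str = "gene",
) -> list[GeneRecord]:
    """Read gene records from GFF3; class labels are taken from the
    attribute ``class_key`` (comma-separated)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        labels: list[str] = []
        for value in feat.attributes.get(class_key, []):
            labels.extend(v.strip() for v in value.split(",") if v.strip())
        genes.append(
            GeneRecord(
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
                gene_id=feat.id,
                classes=frozenset(labels),
            )
        )
    return genes


@dataclass(frozen=True)
class WindowDensity:
    chromosome: str
    index: int
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    count: int
    density_per_mb: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _of_class(genes: Iterable[GeneRecord], label: str | None) -> list[GeneRecord]:
    if label is None:
        return list(genes)
    return [g for g in genes if label in g.classes]


def window_counts(
    genes: Sequence[GeneRecord],
    class_label: str | None,
    assembly: Mapping[str, int],
    window_size: int = 1_000_000,
    assign_by: str = "start",
) -> list[WindowDensity]:
    """Counts and densities of class genes in non-overlapping windows tiling
    every assembly chromosome.  Genes on chromosomes missing from the
    assembly table raise an error listing the offenders."""
    if window_size <= 0:
        raise ModelError("window size must be positive")
    if assign_by not in ("start", "midpoint"):
        raise ModelError("assign_by must be 'start' or 'midpoint'")
    selected = _of_class(genes, class_label)
    unknown = sorted(
        {g.chromosome for g in selected if g.chromosome not in assembly}
    )
    if unknown:
        raise ModelError(f"genes on chromosome(s) absent from assembly: {unknown}")
    counts: dict[tuple[str, int], int] = {}
    for g in selected:
        anchor = g.start if assign_by == "start" else g.midpoint
        idx = (anchor - 1) // window_size  # to 0-based, half-open windows
        counts[(g.chromosome, idx)] = counts.get((g.chromosome, idx), 0) + 1
    out = []
    for chrom, length in assembly.items():
        n_windows = max(1, -(-length // window_size))
        for idx in range(n_windows):
            start = idx * window_size + 1
            end = min((idx + 1) * window_size, length)
            count = counts.get((chrom, idx), 0)
            span = end - start + 1
            out.append(
                WindowDensity(
                    chromosome=chrom,
                    index=idx,
                    start=start,
                    end=end,
                    count=count,
                    density_per_mb=count / (span / 1e6),
                )
            )
    return out


def interval_count(
    genes: Sequence[GeneRecord],
    class_label: str | None,
    chromosome: str,
    start: int,
    end: int,
    assign_by: str = "start",
) -> int:
    """Number of class genes whose start (or midpoint) lies in the 1-based
    inclusive interval [start, end]."""
    if start > end:
        raise ModelError("interval start must not exceed end")
    selected = _of_class(genes, class_label)
    n = 0
    for g in selected:
        if g.chromosome != chromosome:
            continue
        anchor = g.start if assign_by == "start" else g.midpoint
        if start <= anchor <= end:
            n += 1
    return n


@dataclass(frozen=True)
class GeneCluster:
    chromosome: str
    start: int
    end: int
    peak_count: int
    total_count: int
    n_windows: int


def call_clusters(
    densities: Sequence[WindowDensity], threshold: float
) -> list[GeneCluster]:
    """Maximal runs of adjacent windows with density ≥ threshold (per Mb),
    ranked by peak window count, then total count, then coordinates."""
    if threshold <= 0:
        raise ModelError("cluster threshold must be positive")
    by_chrom: dict[str, list[WindowDensity]] = {}
    for w in densities:
        by_chrom.setdefault(w.chromosome, []).append(w)
    clusters = []
    for chrom, wins in by_chrom.items():
        wins = sorted(wins, key=lambda w: w.index)
        run: list[WindowDensity] = []
        for w in wins + [None]:  # type: ignore[list-item]
            if w is not None and w.density_per_mb >= threshold:
                run.append(w)
                continue
            if run:
                clusters.append(
                    GeneCluster(
                        chromosome=chrom,
                        start=run[0].start,
                        end=run[-1].end,
                        peak_count=max(x.count for x in run),
                        total_count=sum(x.count for x in run),
                        n_windows=len(run),
                    )
                )
                run = []
    clusters.sort(
        key=lambda c: (-c.peak_count, -c.total_count, c.chromosome, c.start)
    )
    return clusters


class GeneClassWindowScan(BaseEstimator):
    """Estimator: windowed density scan for one gene class.

    ``fit(genes, assembly)`` computes ``windows_`` (a DataFrame),
    ``clusters_`` (ranked :class:`GeneCluster` list when
    ``cluster_threshold`` is set) and ``mean_density_``, the genome-wide
    mean class density per Mb.
    """

    def __init__(
        self,
        class_label: str | None = "PPR",
        window_size: int = 1_000_000,
        assign_by: str = "start",
        cluster_threshold: float | None = None,
    ):
        self.class_label = class_label
        self.window_size = window_size
        self.assign_by = assign_by
        self.cluster_threshold = cluster_threshold

    def fit(
        self, genes: Sequence[GeneRecord], assembly: Mapping[str, int]
    ) -> "GeneClassWindowScan":
        wins = window_counts(
            genes, self.class_label, assembly, self.window_size, self.assign_by
        )
        self.windows_ = pd.DataFrame(
            {
                "chromosome": [w.chromosome for w in wins],
                "index": [w.index for w in wins],
                "start": [w.start for w in wins],
                "end": [w.end for w in wins],
                "count": [w.count for w in wins],
                "density_per_mb": [w.density_per_mb for w in wins],
            }
        )
        total_genes = sum(w.count for w in wins)
        total_mb = sum(assembly.values()) / 1e6
        self.mean_density_ = total_genes / total_mb
        self.clusters_ = (
            call_clusters(wins, self.cluster_threshold)
            if self.cluster_threshold is not None
            else []
        )
        self._window_list_ = wins
        return self

    def transform(self, genes: Sequence[GeneRecord]) -> pd.DataFrame:
        if not hasattr(self, "windows_"):
            raise ModelError("estimator is not fitted")
        return self.windows_
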