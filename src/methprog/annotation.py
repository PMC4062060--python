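"""Probe-to-feature annotation, gene-level aggregation of probe calls, and
gene-list overlap statistics.

A probe is annotated as *promoter* when it overlaps the strand-aware window
from 2,000 bp upstream to 500 bp downstream of a gene's transcription start
site, else *gene_body* when it overlaps the gene span, else *downstream*
within 2 kb past the gene end, else *unknown*. Promoter takes precedence over
gene body over downstream; ties between genes go to the nearest TSS.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import GenomicInterval

__all__ = [
    "ProbeRecord",
    "GeneCallSet",
    "assign_feature",
    "annotate_probes",
    "aggregate_genes",
    "compare_gene_lists",
    "FEATURES",
]

FEATURES = ("promoter", "gene_body", "downstream", "unknown")

PROMOTER_UP = 2000
PROMOTER_DOWN = 500
DOWNSTREAM_WINDOW = 2000


@dataclass
class ProbeRecord:
    """One array probe: location, regulatory feature and gene assignment."""

    probe_id: str
    interval: GenomicInterval
    feature: str = "unknown"
    gene_id: str | None = None
    is_negative_control: bool = False
    cgi_id: str | None = None

    def __post_init__(self) -> None:
        if self.feature == "promoter" and self.gene_id is None:
            raise ValueError("promoter probes must carry a gene id")


def _promoter_window(gene) -> tuple[int, int]:
    if gene.strand == "+":
        return max(0, gene.tss - PROMOTER_UP), gene.tss + PROMOTER_DOWN + 1
    return max(0, gene.tss - PROMOTER_DOWN), gene.tss + PROMOTER_UP + 1


def _downstream_window(gene) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.span.end, gene.span.end + DOWNSTREAM_WINDOW
    return max(0, gene.span.start - DOWNSTREAM_WINDOW), gene.span.start


def assign_feature(
    probe: GenomicInterval, genes: Sequence
) -> tuple[str, str | None]:
    """Classify one probe against a list of gene models.

    Returns ``(feature, gene_id)``; feature assignment is a total function with
    ``("unknown", None)`` as the fallback, and multi-gene ties are resolved by
    nearest TSS.
    """
    mid = (probe.start + probe.end) // 2
    best: dict[str, tuple[int, str]] = {}
    for gene in genes:
        if gene.chrom != probe.chrom:
            continue
        dist = abs(gene.tss - mid)
        ps, pe = _promoter_window(gene)
        if probe.start < pe and ps < probe.end:
            cat = "promoter"
        elif probe.overlaps(gene.span):
            cat = "gene_body"
        else:
            ds, de = _downstream_window(gene)
            if de > ds and probe.start < de and ds < probe.end:
                cat = "downstream"
            else:
                continue
        if cat not in best or dist < best[cat][0]:
            best[cat] = (dist, gene.gene_id)
    for cat in ("promoter", "gene_body", "downstream"):
        if cat in best:
            return cat, best[cat][1]
    return "unknown", None


def annotate_probes(
    probes: Iterable[ProbeRecord], genes: Sequence
) -> pd.DataFrame:
    """Assign a feature/gene to every probe in place; returns a summary frame.

    Negative-control probes stay ``unknown`` with no gene, mirroring their
    off-island design.
    """
    rows = []
    for rec in probes:
        if rec.is_negative_control:
            rec.feature, rec.gene_id = "unknown", None
        else:
            rec.feature, rec.gene_id = assign_feature(rec.interval, genes)
        rows.append(
            {
                "probe_id": rec.probe_id,
                "chrom": rec.interval.chrom,
                "start": rec.interval.start,
                "end": rec.interval.end,
                "feature": rec.feature,
                "gene_id": rec.gene_id,
                "cgi_id": rec.cgi_id,
                "is_negative_control": rec.is_negative_control,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GeneCallSet:
    """Per-gene probe-support counts and stringency-filtered call flags."""

    table: pd.DataFrame  # gene_id, n_hyper, n_hypo, called_hyper, called_hypo
    min_probes: int

    def called(self, direction: str = "hyper") -> set:
        col = f"called_{direction}"
        return set(self.table.loc[self.table[col], "gene_id"])


def aggregate_genes(
    hyper_ids: set,
    hypo_ids: set,
    probes: Sequence[ProbeRecord],
    min_probes: int = 1,
) -> GeneCallSet:
    """Aggregate probe-level calls to genes (or CGI ids for unannotated probes).

    A gene is called in a direction iff at least ``min_probes`` of its probes
    are in that direction's call set; probes without a gene aggregate under
    their CGI id so 'genes or other genomic locations' are counted jointly.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    known = {p.probe_id for p in probes}
    missing = (set(hyper_ids) | set(hypo_ids)) - known
    if missing:
        raise KeyError(f"DMP ids absent from the probe table: {sorted(missing)[:10]}")
    counts: dict[str, list[int]] = {}
    for p in probes:
        key = p.gene_id or p.cgi_id
        if key is None:
            continue
        entry = counts.setdefault(key, [0, 0])
        if p.probe_id in hyper_ids:
            entry[0] += 1
        if p.probe_id in hypo_ids:
            entry[1] += 1
    rows = [
        {
            "gene_id": key,
            "n_hyper": h,
            "n_hypo": l,
            "called_hyper": h >= min_probes,
            "called_hypo": l >= min_probes,
        }
        for key, (h, l) in sorted(counts.items())
    ]
    return GeneCallSet(pd.DataFrame(rows), min_probes)


def _norm_symbols(symbols: Iterable[str]) -> set:
    return {str(s).strip().casefold() for s in symbols if str(s).strip()}


def compare_gene_lists(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str] | None = None,
) -> dict:
    """Overlap between two gene lists with optional hypergeometric enrichment.

    Matching is case-insensitive after whitespace stripping. When a gene
    universe is supplied the enrichment p is the upper hypergeometric tail of
    drawing |A ∩ B| or more of A's genes in a |B|-sized draw from the universe.
    """
    a, b = _norm_symbols(set_a), _norm_symbols(set_b)
    common = a & b
    out = {
        "n_a": len(a),
        "n_b": len(b),
        "n_common": len(common),
        "common": sorted(common),
        "ratio": len(common) / len(b) if b else float("nan"),
        "p": None,
    }
    if universe is not None:
        uni = _norm_symbols(universe)
        if not uni:
            raise ValueError("empty gene universe")
        n_uni, n_a, n_b = len(uni), len(a & uni), len(b & uni)
        k = len(common & uni)
        out["p"] = float(stats.hypergeom.sf(k - 1, n_uni, n_a, n_b))
    return out
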