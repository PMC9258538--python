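"""QTL intervals from significant SNPs: definition, merging, consensus and
gene annotation.

A QTL is an interval around a significant SNP whose half-width reflects the
panel's LD decay (so that the causal polymorphism is likely inside).
Intervals are merged when overlapping or book-ended (coordinates are 1-based
inclusive throughout, the VCF/GFF3 convention, so [100, 200] and [201, 300]
are adjacent and merge), within a chosen scope.  A merged interval found by
at least two association methods for the same response variable is deemed
*reliable*.  Gene models from a GFF3 overlap a QTL if they share at least
one base pair.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "QTLInterval",
    "define_intervals",
    "merge_overlapping",
    "consensus",
    "annotate",
    "read_gff3_genes",
    "intervals_to_dataframe",
    "intervals_to_bed",
]

DEFAULT_HALF_WIDTH = 50_000


@dataclasses.dataclass
class QTLInterval:
    """Genomic interval (1-based inclusive) around significant SNPs."""

    chromosome: str
    start: int
    end: int
    peak_snps: list[str] = dataclasses.field(default_factory=list)
    response_variable: str = ""
    methods: set = dataclasses.field(default_factory=set)
    snp_sets: set = dataclasses.field(default_factory=set)
    genes: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must not exceed end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def define_intervals(
    significant_snps: pd.DataFrame,
    half_width: int = DEFAULT_HALF_WIDTH,
    response_variable: str = "",
    method: str | None = None,
    snp_set: str | None = None,
) -> list[QTLInterval]:
    """One interval of ±``half_width`` bp per significant SNP.

    ``significant_snps`` needs columns ``id``, ``chrom``, ``pos`` and may
    carry ``method``/``response``/``snp_set`` columns overriding the keyword
    labels.  The left edge is clamped at 1; a SNP at position pos yields
    [max(1, pos - hw), pos + hw] (length 2*hw + 1 away from the edge).
    """
    out: list[QTLInterval] = []
    for _, r in significant_snps.iterrows():
        m = str(r["method"]) if "method" in r else (method or "unknown")
        rv = str(r["response"]) if "response" in r else response_variable
        ss = str(r["snp_set"]) if "snp_set" in r else (snp_set or "default")
        pos = int(r["pos"])
        out.append(QTLInterval(
            chromosome=str(r["chrom"]),
            start=max(1, pos - half_width),
            end=pos + half_width,
            peak_snps=[str(r["id"])],
            response_variable=rv,
            methods={m},
            snp_sets={ss},
        ))
    return out


def _merge_group(group: list[QTLInterval]) -> list[QTLInterval]:
    group = sorted(group, key=lambda iv: (iv.start, iv.end))
    merged: list[QTLInterval] = []
    for iv in group:
        if merged and iv.start <= merged[-1].end + 1:  # book-ended merges
            last = merged[-1]
            last.end = max(last.end, iv.end)
            last.peak_snps = sorted(set(last.peak_snps) | set(iv.peak_snps))
            last.methods |= iv.methods
            last.snp_sets |= iv.snp_sets
            if last.response_variable != iv.response_variable:
                parts = set(last.response_variable.split("+")) | {iv.response_variable}
                last.response_variable = "+".join(sorted(p for p in parts if p))
        else:
            merged.append(dataclasses.replace(
                iv,
                peak_snps=list(iv.peak_snps),
                methods=set(iv.methods),
                snp_sets=set(iv.snp_sets),
                genes=list(iv.genes),
            ))
    return merged


def merge_overlapping(
    intervals: list[QTLInterval], scope: str = "per-variable"
) -> list[QTLInterval]:
    """Union overlapping (or adjacent) intervals on the same chromosome.

    ``scope`` controls which intervals are allowed to merge: ``per-method``
    keeps (response, method, snp_set) runs separate, ``per-variable`` merges
    across methods and SNP sets within a response variable, ``global``
    merges everything.  Merged intervals inherit the union of peak SNPs,
    methods, SNP sets and (for the global scope) response labels.
    Idempotent and order-invariant.
    """
    if scope not in {"per-method", "per-variable", "global"}:
        raise ValueError(f"unknown scope {scope!r}")

    def key(iv: QTLInterval):
        if scope == "per-method":
            return (iv.chromosome, iv.response_variable,
                    tuple(sorted(iv.methods)), tuple(sorted(iv.snp_sets)))
        if scope == "per-variable":
            return (iv.chromosome, iv.response_variable)
        return (iv.chromosome,)

    groups: dict = {}
    for iv in intervals:
        groups.setdefault(key(iv), []).append(iv)
    out: list[QTLInterval] = []
    for g in groups.values():
        out.extend(_merge_group(g))
    out.sort(key=lambda iv: (iv.chromosome, iv.start, iv.end, iv.response_variable))
    return out


def consensus(
    intervals: list[QTLInterval], min_methods: int = 2
) -> list[QTLInterval]:
    """Reliable QTLs: merged intervals supported by >= ``min_methods``.

    Intervals (from any method and SNP set) are overlap-merged per response
    variable; merged intervals whose method set has cardinality at least
    ``min_methods`` are kept.
    """
    merged = merge_overlapping(intervals, scope="per-variable")
    return [iv for iv in merged if len(iv.methods) >= min_methods]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene features (id, chrom, start, end) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = [
        (f.id, f.seqid, f.start, f.end)
        for f in db.features_of_type("gene")
    ]
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end"])


def annotate(
    intervals: list[QTLInterval], gff3: str | Path | pd.DataFrame
) -> list[QTLInterval]:
    """Attach overlapping gene-model ids to each interval.

    A gene overlaps a QTL iff their 1-based inclusive spans share at least
    one base pair.  A complete chromosome-name mismatch between QTLs and
    the annotation produces zero overlaps plus a warning listing the
    unmatched names.
    """
    genes = gff3 if isinstance(gff3, pd.DataFrame) else read_gff3_genes(gff3)
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        t = IntervalTree()
        for _, g in sub.iterrows():
            t.addi(int(g["start"]), int(g["end"]) + 1, str(g["id"]))  # half-open
        trees[str(chrom)] = t
    qtl_chroms = {iv.chromosome for iv in intervals}
    unmatched = qtl_chroms - set(trees)
    if intervals and unmatched == qtl_chroms:
        warnings.warn(
            "no QTL chromosome matches the annotation; unmatched names: "
            + ", ".join(sorted(unmatched))
        )
    out = []
    for iv in intervals:
        hits = trees.get(iv.chromosome, IntervalTree()).overlap(iv.start, iv.end + 1)
        iv2 = dataclasses.replace(iv, genes=sorted({h.data for h in hits}))
        out.append(iv2)
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def intervals_to_dataframe(intervals: list[QTLInterval]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chrom": iv.chromosome,
            "start": iv.start,
            "end": iv.end,
            "length": iv.length,
            "response": iv.response_variable,
            "methods": ",".join(sorted(iv.methods)),
            "n_methods": len(iv.methods),
            "snp_sets": ",".join(sorted(iv.snp_sets)),
            "peak_snps": ",".join(iv.peak_snps),
            "genes": ",".join(iv.genes),
        }
        for iv in intervals
    ])


def intervals_to_bed(intervals: list[QTLInterval], path: str | Path) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = f"{iv.response_variable or 'qtl'}|{','.join(sorted(iv.methods))}"
            fh.write(f"{iv.chromosome}\t{iv.start - 1}\t{iv.end}\t{name}\n")
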