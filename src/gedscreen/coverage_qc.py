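"""Per-region sequencing-depth QC for the amplicon panel.

Coverage of each targeted exon/amplicon is summarized as the arithmetic
mean of per-base depth (positions absent from the depth table count as 0),
and compared against strict thresholds: a region "passes" at threshold t
iff mean depth > t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import depth_frame
from .types import DepthRecord, GedscreenError, TargetRegion

DEFAULT_THRESHOLDS = (50, 20, 10)


@dataclass
class ExonCoverage:
    region: TargetRegion
    mean_depth: float
    passes: dict[int, bool] = field(default_factory=dict)


def round_half_up(x: float, digits: int) -> float:
    """Decimal half-up rounding (Python's round() is banker's)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_depth(
    regions: Sequence[TargetRegion],
    depths: Iterable[DepthRecord],
    sample: str,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    stat: str = "mean",
) -> list[ExonCoverage]:
    """Mean (or median) per-base depth of each region for one sample."""
    df = depth_frame(depths)
    df = df[df["sample"] == sample]
    if df.empty:
        raise GedscreenError(f"no depth records for sample {sample!r} (sample-id mismatch?)")
    lookup = {(c, p): d for c, p, d in zip(df["chrom"], df["pos"], df["depth"])}
    out = []
    for region in regions:
        per_base = np.array([lookup.get((region.chrom, p), 0) for p in region.positions()])
        value = float(np.median(per_base) if stat == "median" else per_base.mean())
        out.append(
            ExonCoverage(region, value, {t: value > t for t in thresholds})
        )
    return out


def mean_coverage_across_samples(
    regions: Sequence[TargetRegion],
    depths: Iterable[DepthRecord],
    samples: Sequence[str],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> list[ExonCoverage]:
    """Per-region depth averaged over samples as well as bases."""
    per_sample = [summarize_depth(regions, depths, s, thresholds) for s in samples]
    out = []
    for i, region in enumerate(regions):
        value = float(np.mean([cov[i].mean_depth for cov in per_sample]))
        out.append(ExonCoverage(region, value, {t: value > t for t in thresholds}))
    return out


def pass_fraction(coverages: Sequence[ExonCoverage], threshold: int) -> tuple[int, float]:
    """(count, fraction) of regions whose mean depth strictly exceeds threshold."""
    if not coverages:
        raise GedscreenError("pass_fraction: empty coverage list")
    count = sum(1 for c in coverages if c.mean_depth > threshold)
    return count, count / len(coverages)


def coverage_report(
    coverages: Sequence[ExonCoverage], thresholds: Sequence[int] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    rows = [
        {
            "region": c.region.name,
            "chrom": c.region.chrom,
            "start": c.region.start,
            "end": c.region.end,
            "mean_depth": round_half_up(c.mean_depth, 2),
            **{f"pass_gt{t}": c.passes.get(t, c.mean_depth > t) for t in thresholds},
        }
        for c in coverages
    ]
    return pd.DataFrame(rows)


def coverage_summary(
    coverages: Sequence[ExonCoverage], thresholds: Sequence[int] = DEFAULT_THRESHOLDS
) -> dict[str, object]:
    """Summary block: pass counts and half-up 1-decimal percentages."""
    summary: dict[str, object] = {"regions": len(coverages)}
    for t in thresholds:
        count, frac = pass_fraction(coverages, t)
        summary[f"pass_gt{t}"] = count
        summary[f"pct_gt{t}"] = round_half_up(100.0 * frac, 1)
    return summary


def write_coverage_report(coverages: Sequence[ExonCoverage], path: str | Path) -> Path:
    coverage_report(coverages).to_csv(path, sep="\t", index=False)
    return Path(path)
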