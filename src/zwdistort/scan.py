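"""Sex-linked segregation-distortion scan.

For every single-parent-informative marker the offspring genotype
distribution is tested against offspring sex with a two-sided exact
conditional test (null hypothesis: genotypes occur with the same relative
frequency in both sexes).  P-values are Bonferroni-corrected separately
within the maternal and the paternal marker group, using as multiplier the
number of markers in the group with a defined p-value.

Under ZW sex determination, maternal markers linked to the sex-determination
locus co-segregate with sex; paternal markers are distorted between the sexes
only when a sex-limited process — here, a lethal maternal-paternal haplotype
combination at a linked sex-ratio-distorter locus — removes a genotype class
from one sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exact import exact_conditional_p
from .genotypes import MISSING, GenotypeTable, classify_markers
from .markers import UNKNOWN_CHROMOSOME

__all__ = [
    "SexSegregationScan",
    "SegregationScanResults",
    "sex_segregation_scan",
    "summarize_by_region",
    "RegionSummary",
]

_GT_NAMES = {0: "AA", 1: "AB", 2: "BB"}


class SexSegregationScan:
    """Exact-test scan of marker genotype distributions against offspring sex.

    Parameters
    ----------
    table
        Genotype table with sex labels; apply :func:`zwdistort.qc_filter`
        beforehand if a completeness filter is wanted.
    alpha
        Group-wise significance level applied to Bonferroni-corrected
        p-values (default 0.05).

    Markers classified ``both`` or ``uninformative`` are excluded: the scan
    concerns the two pseudo-testcross groups.
    """

    def __init__(self, table: GenotypeTable, alpha: float = 0.05):
        if not (0 < alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not set(table.sex).intersection({"F", "M"}):
            raise ValueError("no sexed offspring in table")
        self.table = table
        self.alpha = alpha

    def fit(self) -> "SegregationScanResults":
        table = self.table
        cls = classify_markers(table)
        sex = table.sex.to_numpy()
        is_f, is_m = sex == "F", sex == "M"
        calls = table.calls.to_numpy()
        mm = table.markers.df

        rows = []
        for i, mid in enumerate(table.markers.marker_ids):
            group = cls.iloc[i]
            if group not in ("maternal", "paternal"):
                continue
            row = calls[i]
            counts = np.zeros((2, 3), dtype=np.int64)
            for g in (0, 1, 2):
                counts[0, g] = np.count_nonzero(is_f & (row == g))
                counts[1, g] = np.count_nonzero(is_m & (row == g))
            p = exact_conditional_p(counts)
            rows.append(
                {
                    "marker_id": mid,
                    "chromosome": mm["chromosome"].iloc[i],
                    "position_cM": mm["position_cM"].iloc[i],
                    "group": group,
                    **{f"n_{s}_{_GT_NAMES[g]}": counts[r, g]
                       for r, s in enumerate("FM") for g in (0, 1, 2)},
                    "p_raw": p,
                }
            )
        res = pd.DataFrame(rows).set_index("marker_id") if rows else pd.DataFrame(
            columns=["chromosome", "position_cM", "group", "p_raw"])

        res["p_corrected"] = np.nan
        res["significant"] = False
        for group in ("maternal", "paternal"):
            in_group = res["group"] == group
            defined = in_group & res["p_raw"].notna()
            multiplier = int(defined.sum())
            res.loc[defined, "p_corrected"] = np.minimum(
                1.0, res.loc[defined, "p_raw"] * multiplier)
            res.loc[defined, "significant"] = res.loc[defined, "p_corrected"] < self.alpha
        return SegregationScanResults(frame=res, alpha=self.alpha)


@dataclass(frozen=True)
class SegregationScanResults:
    """Per-marker scan results.

    ``frame`` has one row per tested marker: chromosome, position, group,
    the sex x genotype contingency counts, raw and Bonferroni-corrected
    p-values and the significance call at ``alpha``.
    """

    frame: pd.DataFrame = field(repr=False)
    alpha: float = 0.05

    def significant_markers(self, group: str | None = None) -> pd.Index:
        sub = self.frame[self.frame["significant"]]
        if group is not None:
            sub = sub[sub["group"] == group]
        return sub.index

    def region_summary(self, focal_chromosome: str) -> "RegionSummary":
        return summarize_by_region(self.frame, focal_chromosome)

    def summary(self) -> str:
        lines = [f"Sex-segregation scan (alpha = {self.alpha})", "=" * 44]
        for group in ("maternal", "paternal"):
            sub = self.frame[self.frame["group"] == group]
            n_def = int(sub["p_raw"].notna().sum())
            n_sig = int(sub["significant"].sum())
            lines.append(f"{group:>8} markers: {len(sub)} tested "
                         f"({n_def} with defined p), {n_sig} significant")
            top = sub[sub["significant"]].nsmallest(5, "p_corrected")
            for mid, r in top.iterrows():
                lines.append(f"          {mid}  {r['chromosome']}:{r['position_cM']:.1f} cM"
                             f"  p_corr = {r['p_corrected']:.3g}")
        return "\n".join(lines)


def sex_segregation_scan(table: GenotypeTable, alpha: float = 0.05) -> SegregationScanResults:
    """Functional wrapper: ``SexSegregationScan(table, alpha).fit()``."""
    return SexSegregationScan(table, alpha).fit()


@dataclass(frozen=True)
class RegionSummary:
    """Counts of significant markers by genomic region bucket.

    ``frame`` is indexed by marker group with integer columns ``focal``,
    ``unknown``, ``other`` and ``total``; ``focal_percent`` holds the
    percentage of a group's significant markers on the focal chromosome
    (integer-truncated, as printed in the study's summary table), or NA for
    an empty group.
    """

    frame: pd.DataFrame
    focal_chromosome: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"Significant markers by region (focal = {self.focal_chromosome})\n"
                + self.frame.to_string())


def summarize_by_region(scan_frame: pd.DataFrame, focal_chromosome: str) -> RegionSummary:
    """Bucket significant markers into {focal chromosome, unknown, other}.

    ``scan_frame`` needs columns ``group``, ``chromosome`` and
    ``significant`` (a :class:`SegregationScanResults` frame works as is).
    """
    rows = {}
    for group in ("maternal", "paternal"):
        sub = scan_frame[(scan_frame["group"] == group) & scan_frame["significant"]]
        chrom = sub["chromosome"].fillna(UNKNOWN_CHROMOSOME)
        focal = int((chrom == focal_chromosome).sum())
        unknown = int((chrom == UNKNOWN_CHROMOSOME).sum())
        total = len(sub)
        other = total - focal - unknown
        pct = (100 * focal) // total if total else pd.NA
        rows[group] = {"focal": focal, "unknown": unknown, "other": other,
                       "total": total, "focal_percent": pct}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "group"
    return RegionSummary(frame=frame, focal_chromosome=focal_chromosome)
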