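"""Genotype tables for two-parent outbred crosses.

Calls are biallelic and stored as allele-B dosages: ``0 = AA``, ``1 = AB``,
``2 = BB`` and ``-1 = missing``.  Allele ``A`` is, by convention, the
reference parent allele at each marker; the string codes used in files are
``AA/AB/BB/--``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import MarkerMap

MISSING = -1
CODE_TO_STR = {0: "AA", 1: "AB", 2: "BB", MISSING: "--"}
STR_TO_CODE = {v: k for k, v in CODE_TO_STR.items()}

SEXES = ("F", "M", "U")


@dataclass(frozen=True)
class GenotypeTable:
    """Offspring x marker genotype calls plus parental genotypes and sex.

    Attributes
    ----------
    markers
        The marker map; row order of ``calls`` follows it.
    calls
        int8 frame of dosages, indexed by marker id, one column per offspring.
    parents
        int8 frame indexed by marker id with columns ``mother`` and ``father``.
    sex
        Series mapping offspring id to ``"F"``, ``"M"`` or ``"U"``.
    """

    markers: MarkerMap
    calls: pd.DataFrame = field(repr=False)
    parents: pd.DataFrame = field(repr=False)
    sex: pd.Series = field(repr=False)
    mother_id: str = "mother"
    father_id: str = "father"

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.markers.marker_ids):
            raise ValueError("calls index must match the marker map")
        if not self.parents.index.equals(self.markers.marker_ids):
            raise ValueError("parents index must match the marker map")
        if set(self.parents.columns) != {"mother", "father"}:
            raise ValueError("parents must have columns 'mother' and 'father'")
        if not self.sex.index.equals(self.calls.columns):
            raise ValueError("sex index must match offspring columns")
        bad = set(np.unique(self.calls.to_numpy())) - {0, 1, 2, MISSING}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if not set(self.sex).issubset(SEXES):
            raise ValueError("sex labels must be F, M or U")

    @property
    def offspring_ids(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_offspring(self) -> int:
        return self.calls.shape[1]

    def completeness(self) -> pd.Series:
        """Per-marker fraction of non-missing offspring calls."""
        return (self.calls != MISSING).mean(axis=1)

    def subset_markers(self, marker_ids) -> "GenotypeTable":
        return replace(
            self,
            markers=self.markers.subset(marker_ids),
            calls=self.calls.loc[marker_ids],
            parents=self.parents.loc[marker_ids],
        )


def classify_markers(table: GenotypeTable) -> pd.Series:
    """Classify markers by parental informativeness from parent genotypes.

    ``maternal``: mother heterozygous, father homozygous; ``paternal``: the
    converse; ``both``: both heterozygous; ``uninformative``: both homozygous
    or any parental genotype missing.
    """
    mo = table.parents["mother"].to_numpy()
    fa = table.parents["father"].to_numpy()
    mo_het, fa_het = mo == 1, fa == 1
    mo_ok, fa_ok = mo != MISSING, fa != MISSING
    out = np.full(len(mo), "uninformative", dtype=object)
    out[mo_het & fa_ok & ~fa_het] = "maternal"
    out[fa_het & mo_ok & ~mo_het] = "paternal"
    out[mo_het & fa_het] = "both"
    return pd.Series(out, index=table.markers.marker_ids, name="informativeness")


def qc_filter(table: GenotypeTable, min_completeness: float = 0.7) -> GenotypeTable:
    """Drop markers whose non-missing call fraction is below the threshold.

    The default mirrors a 70% per-site completeness filter typical for
    GBS-derived genotype matrices.  An empty result is allowed (a warning is
    emitted), since downstream code treats empty tables explicitly.
    """
    keep = table.completeness() >= min_completeness
    if not keep.any():
        import warnings

        warnings.warn("qc_filter removed every marker", stacklevel=2)
    return table.subset_markers(table.markers.marker_ids[keep])


def inheritance_indicators(table: GenotypeTable, group: str) -> pd.DataFrame:
    """Per-offspring indicators of which segregating-parent allele was received.

    For a marker informative in one parent only (pseudo-testcross marker), the
    offspring call minus the homozygous parent's allele contribution reveals
    the allele transmitted by the heterozygous parent.  Returns an
    offspring x marker int8 frame with entries 0 (allele A), 1 (allele B) or
    -1 (missing or Mendelian-inconsistent call).

    Parameters
    ----------
    group
        ``"maternal"`` or ``"paternal"``: which parent's markers to use.
    """
    if group not in ("maternal", "paternal"):
        raise ValueError("group must be 'maternal' or 'paternal'")
    cls = classify_markers(table)
    ids = cls.index[cls == group]
    hom_parent = "father" if group == "maternal" else "mother"
    hom = table.parents.loc[ids, hom_parent].to_numpy()  # 0 or 2
    calls = table.calls.loc[ids].to_numpy()
    ind = calls - (hom[:, None] // 2)
    ind[(calls == MISSING) | (ind < 0) | (ind > 1)] = MISSING
    return pd.DataFrame(
        ind.T.astype(np.int8), index=table.offspring_ids, columns=ids
    )
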