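"""Marker maps and map functions.

A :class:`MarkerMap` is the ordered list of genetic markers used throughout the
package: each marker has an identifier, a chromosome (linkage group) label, a
map position in centimorgan and an informativeness class describing which
parent of an outbred two-parent cross is heterozygous at the marker
(``maternal``, ``paternal`` or ``both``).  In a pseudo-testcross the
single-parent-informative classes are the ones that reveal that parent's
gamete haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INFORMATIVENESS_CLASSES = ("maternal", "paternal", "both")

#: chromosome label used for markers without a known genomic position
UNKNOWN_CHROMOSOME = "unknown"


class ConfigurationError(ValueError):
    """Raised for invalid simulation or map configurations."""


def haldane_r(d_cM: float) -> float:
    """Recombination fraction for a map distance under the Haldane function.

    No crossover interference: ``r = (1 - exp(-2d)) / 2`` with *d* in Morgan.
    """
    d = np.asarray(d_cM, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def kosambi_r(d_cM: float) -> float:
    """Recombination fraction under the Kosambi function, ``r = tanh(2d)/2``."""
    d = np.asarray(d_cM, dtype=float) / 100.0
    return 0.5 * np.tanh(2.0 * d)


MAP_FUNCTIONS = {"haldane": haldane_r, "kosambi": kosambi_r}


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker definitions with map positions.

    Parameters
    ----------
    df
        Frame indexed by unique marker id with columns ``chromosome``,
        ``position_cM`` and ``informativeness``.  Markers must be sorted by
        non-decreasing position within each chromosome.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"chromosome", "position_cM", "informativeness"}
        missing = required - set(self.df.columns)
        if missing:
            raise ConfigurationError(f"marker map missing columns: {sorted(missing)}")
        if not self.df.index.is_unique:
            raise ConfigurationError("marker ids must be unique")
        if (self.df["position_cM"] < 0).any():
            raise ConfigurationError("map positions must be non-negative")
        bad = set(self.df["informativeness"]) - set(INFORMATIVENESS_CLASSES) - {"uninformative"}
        if bad:
            raise ConfigurationError(f"unknown informativeness classes: {sorted(bad)}")
        for _, sub in self.df.groupby("chromosome", sort=False):
            if (np.diff(sub["position_cM"].to_numpy()) < 0).any():
                raise ConfigurationError("positions must be non-decreasing within a chromosome")

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> pd.Index:
        return self.df.index

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.df["chromosome"]:
            seen.setdefault(c, None)
        return list(seen)

    def positions(self) -> np.ndarray:
        return self.df["position_cM"].to_numpy(dtype=float)

    def subset(self, marker_ids) -> "MarkerMap":
        return MarkerMap(self.df.loc[marker_ids])

    def region(self, chromosome: str, start_cM: float | None = None,
               end_cM: float | None = None) -> "MarkerMap":
        """Markers on one chromosome, optionally restricted to a cM interval."""
        sub = self.df[self.df["chromosome"] == chromosome]
        if start_cM is not None:
            sub = sub[sub["position_cM"] >= start_cM]
        if end_cM is not None:
            sub = sub[sub["position_cM"] <= end_cM]
        return MarkerMap(sub)

    def span_cM(self, chromosome: str) -> tuple[float, float]:
        pos = self.df.loc[self.df["chromosome"] == chromosome, "position_cM"]
        if pos.empty:
            raise KeyError(f"no markers on chromosome {chromosome!r}")
        return float(pos.min()), float(pos.max())


def make_marker_map(
    n_markers: int,
    chromosome_lengths_cM,
    class_mix=None,
    seed: int = 0,
    chromosome_names=None,
) -> MarkerMap:
    """Place markers uniformly at random on chromosomes of given lengths.

    Markers are assigned to chromosomes with probability proportional to
    chromosome length (uniformly if every length is zero), positioned
    uniformly along each chromosome and sorted by position.  Informativeness
    classes are drawn from ``class_mix``, a mapping over
    ``{"maternal", "paternal", "both"}`` whose proportions sum to one
    (default: equal thirds).  Deterministic for a given ``seed``.
    """
    if n_markers < 2:
        raise ConfigurationError("need at least two markers")
    lengths = np.asarray(chromosome_lengths_cM, dtype=float)
    if lengths.ndim != 1 or len(lengths) == 0:
        raise ConfigurationError("chromosome_lengths_cM must be a non-empty sequence")
    if (lengths < 0).any():
        raise ConfigurationError("chromosome lengths must be non-negative")
    if class_mix is None:
        class_mix = {c: 1.0 / 3.0 for c in INFORMATIVENESS_CLASSES}
    probs = np.array([float(class_mix.get(c, 0.0)) for c in INFORMATIVENESS_CLASSES])
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigurationError("class_mix proportions must be non-negative and sum to 1")
    if chromosome_names is None:
        chromosome_names = [f"chr{i + 1:02d}" for i in range(len(lengths))]
    if len(chromosome_names) != len(lengths):
        raise ConfigurationError("one name per chromosome required")

    rng = np.random.default_rng(seed)
    weights = lengths / lengths.sum() if lengths.sum() > 0 else np.full(len(lengths), 1.0 / len(lengths))
    chrom_idx = rng.choice(len(lengths), size=n_markers, p=weights)
    pos = rng.uniform(0.0, 1.0, size=n_markers) * lengths[chrom_idx]
    classes = rng.choice(INFORMATIVENESS_CLASSES, size=n_markers, p=probs)

    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos, classes = chrom_idx[order], pos[order], classes[order]
    df = pd.DataFrame(
        {
            "chromosome": [chromosome_names[i] for i in chrom_idx],
            "position_cM": pos,
            "informativeness": classes,
        },
        index=pd.Index([f"m{i + 1:04d}" for i in range(n_markers)], name="marker_id"),
    )
    return MarkerMap(df)
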