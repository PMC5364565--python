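"""Synthetic two-parent ZW cross populations.

Simulates offspring of an outbred cross between a W/Z mother and a Z/Z
father.  Sex is female heterogametic: an offspring is female iff the maternal
gamete carries the W gametolog at the sex-determination (SD) locus.  A linked
sex-ratio-distorter (SR) locus may carry a lethal combination of one maternal
and one paternal haplotype; zygotes with a lethal combination are discarded
(post-zygotic rejection — the surviving-genotype distribution is identical
under pre-zygotic elimination, which marker data cannot distinguish).

Two presets emulate the study crosses:

``S5``
    271 surviving offspring; the maternal Z (``Z3``) is lethal in combination
    with one paternal haplotype (``Z1``), removing half the expected males and
    producing a 2:1 female-biased sex ratio.
``S3``
    516 surviving offspring, same father, a different mother with no lethal
    combination: an even sex ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable
from .markers import (
    MAP_FUNCTIONS,
    ConfigurationError,
    MarkerMap,
)

__all__ = [
    "CrossSpec",
    "TruthSet",
    "CrossExpectation",
    "preset_cross",
    "simulate_gamete",
    "simulate_population",
    "simulate_cross",
    "apply_noise",
    "expected_offspring_classes",
]


@dataclass(frozen=True)
class CrossSpec:
    """Full specification of a simulated cross.

    ``maternal_haplotypes`` and ``paternal_haplotypes`` are (2, n_markers)
    0/1 allele arrays; row order matches ``maternal_labels`` /
    ``paternal_labels``.  By convention the first maternal label is the
    W gametolog (its carrier offspring are female).  ``lethal_pairs`` is a set
    of ``(maternal_label, paternal_label)`` combinations lethal at the SR
    locus.
    """

    marker_map: MarkerMap
    maternal_haplotypes: np.ndarray = field(repr=False)
    paternal_haplotypes: np.ndarray = field(repr=False)
    sd_chromosome: str = "chr15"
    sd_position_cM: float = 60.7
    sr_chromosome: str = "chr15"
    sr_position_cM: float = 60.7
    lethal_pairs: frozenset = frozenset()
    n_offspring_surviving: int = 271
    missing_rate: float = 0.1
    error_rate: float = 0.005
    map_function: str = "haldane"
    seed: int = 0
    maternal_labels: tuple = ("W", "Z3")
    paternal_labels: tuple = ("Z1", "Z2")
    mother_id: str = "mother"
    father_id: str = "father"

    def __post_init__(self) -> None:
        m = self.marker_map.n_markers
        for name in ("maternal_haplotypes", "paternal_haplotypes"):
            h = np.asarray(getattr(self, name), dtype=np.int8)
            if h.shape != (2, m):
                raise ConfigurationError(f"{name} must have shape (2, n_markers)")
            object.__setattr__(self, name, h)
        object.__setattr__(self, "lethal_pairs", frozenset(self.lethal_pairs))
        labels = set(self.maternal_labels) | set(self.paternal_labels)
        for mat, pat in self.lethal_pairs:
            if mat not in labels or pat not in labels:
                raise ConfigurationError(f"lethal pair ({mat}, {pat}) uses undeclared labels")
        if self.map_function not in MAP_FUNCTIONS:
            raise ConfigurationError(f"unknown map function {self.map_function!r}")
        if not (0 <= self.missing_rate <= 1 and 0 <= self.error_rate <= 1):
            raise ConfigurationError("noise rates must lie in [0, 1]")
        if self.n_offspring_surviving <= 0:
            raise ConfigurationError("n_offspring_surviving must be positive")
        for chrom, pos, what in (
            (self.sd_chromosome, self.sd_position_cM, "SD"),
            (self.sr_chromosome, self.sr_position_cM, "SR"),
        ):
            lo, hi = self.marker_map.span_cM(chrom)
            if not (lo <= pos <= hi):
                raise ConfigurationError(f"{what} locus at {pos} cM outside map span [{lo}, {hi}]")


@dataclass(frozen=True)
class TruthSet:
    """Ground-truth inheritance for a simulated population.

    Label matrices hold the parental-haplotype index (0/1, row order of the
    spec's haplotype arrays) each offspring received at each marker.
    Breakpoints are per-offspring lists of flanking marker-index pairs
    ``(i, i + 1)``; chromosome boundaries are not breakpoints.
    """

    maternal_labels: pd.DataFrame = field(repr=False)
    paternal_labels: pd.DataFrame = field(repr=False)
    maternal_breakpoints: dict = field(repr=False)
    paternal_breakpoints: dict = field(repr=False)
    sd_maternal_label: pd.Series = field(repr=False)
    sr_labels: pd.DataFrame = field(repr=False)
    sex: pd.Series = field(repr=False)
    viable: pd.Series = field(repr=False)
    maternal_label_names: tuple = ("W", "Z3")
    paternal_label_names: tuple = ("Z1", "Z2")
    n_zygotes: int = 0


def _locus_layout(spec: CrossSpec):
    """Merge markers with the SD and SR loci into one ordered locus list.

    Returns (chrom codes, positions, marker_slot, sd_index, sr_index) where
    ``marker_slot[j]`` is the marker-map row a locus corresponds to, or -1
    for the virtual SD/SR loci.
    """
    mm = spec.marker_map.df
    chrom_order = {c: i for i, c in enumerate(spec.marker_map.chromosomes)}
    chroms = np.array([chrom_order[c] for c in mm["chromosome"]])
    pos = mm["position_cM"].to_numpy(dtype=float)
    slots = np.arange(len(mm))

    extra = [
        (chrom_order[spec.sd_chromosome], spec.sd_position_cM, -2),
        (chrom_order[spec.sr_chromosome], spec.sr_position_cM, -3),
    ]
    chroms = np.concatenate([chroms, [e[0] for e in extra]])
    pos = np.concatenate([pos, [e[1] for e in extra]])
    slots = np.concatenate([slots, [e[2] for e in extra]])
    order = np.lexsort((slots == -2, pos, chroms))  # stable; SD after ties
    chroms, pos, slots = chroms[order], pos[order], slots[order]
    sd_index = int(np.flatnonzero(slots == -2)[0])
    sr_index = int(np.flatnonzero(slots == -3)[0])
    return chroms, pos, slots, sd_index, sr_index


def _draw_labels(chroms, pos, map_function, n, rng):
    """Draw n gamete origin-label vectors (0/1 per locus) without interference.

    Chromosomes segregate independently; a crossover falls between adjacent
    loci with the recombination fraction implied by their cM gap under the
    chosen map function.  Returns (labels, crossover indicator matrix over
    intra-chromosome intervals).
    """
    rfun = MAP_FUNCTIONS[map_function]
    gaps = np.diff(pos)
    same = np.diff(chroms) == 0
    r = np.where(same, rfun(np.abs(gaps)), 0.0)
    switch = rng.random((n, len(gaps))) < r[None, :]
    # independent start label per chromosome
    starts = rng.integers(0, 2, size=(n, int(chroms.max()) + 1))
    start_per_locus = starts[:, chroms]
    cum = np.concatenate([np.zeros((n, 1), dtype=int), np.cumsum(switch, axis=1)], axis=1)
    # reset the crossover count at each chromosome start
    first_of_chrom = np.concatenate([[True], ~same])
    base = np.maximum.accumulate(np.where(first_of_chrom, np.arange(len(pos)), 0))
    labels = (start_per_locus + cum - cum[:, base]) % 2
    return labels.astype(np.int8), switch & same[None, :]


def simulate_gamete(haplotype_pair, marker_map: MarkerMap, map_function: str = "haldane",
                    random_stream=None):
    """Simulate one gamete from a pair of parental haplotypes.

    Returns ``(gamete alleles, origin labels, breakpoints)`` where breakpoints
    are flanking marker-index pairs at which the origin label switches.
    """
    rng = random_stream if isinstance(random_stream, np.random.Generator) \
        else np.random.default_rng(random_stream)
    hap = np.asarray(haplotype_pair, dtype=np.int8)
    if hap.shape != (2, marker_map.n_markers):
        raise ValueError("haplotype pair must have shape (2, n_markers)")
    chrom_order = {c: i for i, c in enumerate(marker_map.chromosomes)}
    chroms = np.array([chrom_order[c] for c in marker_map.df["chromosome"]])
    labels, _ = _draw_labels(chroms, marker_map.positions(), map_function, 1, rng)
    labels = labels[0]
    gamete = hap[labels, np.arange(marker_map.n_markers)]
    flips = np.flatnonzero((np.diff(labels) != 0) & (np.diff(chroms) == 0))
    breakpoints = [(int(i), int(i) + 1) for i in flips]
    return gamete, labels, breakpoints


def simulate_population(spec: CrossSpec, seed: int | None = None):
    """Simulate surviving offspring of a cross (noise-free calls).

    Zygotes are formed from one maternal and one paternal gamete; sex is
    female iff the maternal gamete carries the first maternal haplotype (W)
    at the SD locus; zygotes whose (maternal, paternal) haplotype pair at the
    SR locus is lethal are discarded; sampling continues until
    ``spec.n_offspring_surviving`` survivors are collected.

    Returns ``(GenotypeTable, TruthSet)``.
    """
    if len(spec.lethal_pairs) >= 4:
        raise ConfigurationError("every zygote class is lethal; the cross is unsatisfiable")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    chroms, pos, slots, sd_index, sr_index = _locus_layout(spec)
    marker_loci = slots >= 0
    marker_slots = slots[marker_loci]

    mat_names, pat_names = spec.maternal_labels, spec.paternal_labels
    lethal = np.zeros((2, 2), dtype=bool)
    for m_lab, p_lab in spec.lethal_pairs:
        lethal[mat_names.index(m_lab), pat_names.index(p_lab)] = True

    n_target = spec.n_offspring_surviving
    expect_viable = max(1.0 - lethal.mean(), 0.25)
    kept: list[dict] = []
    n_zygotes = 0
    for _attempt in range(1000):
        short = n_target - sum(k["sex"].size for k in kept)
        if short <= 0:
            break
        batch = int(np.ceil(short / expect_viable * 1.2)) + 8
        mat_lab, _ = _draw_labels(chroms, pos, spec.map_function, batch, rng)
        pat_lab, _ = _draw_labels(chroms, pos, spec.map_function, batch, rng)
        n_zygotes += batch
        viable = ~lethal[mat_lab[:, sr_index], pat_lab[:, sr_index]]
        kept.append(
            {
                "mat": mat_lab[viable],
                "pat": pat_lab[viable],
                "sex": np.where(mat_lab[viable, sd_index] == 0, "F", "M"),
            }
        )
    else:  # pragma: no cover - requires pathological rejection rates
        raise ConfigurationError("could not collect survivors within the attempt bound")

    mat = np.concatenate([k["mat"] for k in kept])[:n_target]
    pat = np.concatenate([k["pat"] for k in kept])[:n_target]
    sex = np.concatenate([k["sex"] for k in kept])[:n_target]

    ids = pd.Index([f"o{i + 1:04d}" for i in range(n_target)], name="offspring_id")
    marker_ids = spec.marker_map.marker_ids

    mat_alleles = spec.maternal_haplotypes[mat[:, marker_loci], marker_slots]
    pat_alleles = spec.paternal_haplotypes[pat[:, marker_loci], marker_slots]
    calls = pd.DataFrame((mat_alleles + pat_alleles).T.astype(np.int8),
                         index=marker_ids, columns=ids)
    parents = pd.DataFrame(
        {
            "mother": spec.maternal_haplotypes.sum(axis=0).astype(np.int8),
            "father": spec.paternal_haplotypes.sum(axis=0).astype(np.int8),
        },
        index=marker_ids,
    )
    table = GenotypeTable(
        markers=spec.marker_map,
        calls=calls,
        parents=parents,
        sex=pd.Series(sex, index=ids, name="sex"),
        mother_id=spec.mother_id,
        father_id=spec.father_id,
    )

    # marker-level breakpoints recomputed from labels at marker loci, so a
    # crossover landing between a marker and a virtual locus collapses onto
    # the flanking marker interval
    def _label_breakpoints(lab_rows):
        lab_m = lab_rows[:, marker_loci]
        chrom_m = chroms[marker_loci]
        same = np.diff(chrom_m) == 0
        out = {}
        for oid, row in zip(ids, lab_m):
            flips = np.flatnonzero((np.diff(row) != 0) & same)
            out[oid] = [(int(i), int(i) + 1) for i in flips]
        return out

    truth = TruthSet(
        maternal_labels=pd.DataFrame(mat[:, marker_loci], index=ids, columns=marker_ids),
        paternal_labels=pd.DataFrame(pat[:, marker_loci], index=ids, columns=marker_ids),
        maternal_breakpoints=_label_breakpoints(mat),
        paternal_breakpoints=_label_breakpoints(pat),
        sd_maternal_label=pd.Series([mat_names[i] for i in mat[:, sd_index]], index=ids),
        sr_labels=pd.DataFrame(
            {
                "maternal": [mat_names[i] for i in mat[:, sr_index]],
                "paternal": [pat_names[i] for i in pat[:, sr_index]],
            },
            index=ids,
        ),
        sex=table.sex,
        viable=pd.Series(True, index=ids),
        maternal_label_names=mat_names,
        paternal_label_names=pat_names,
        n_zygotes=n_zygotes,
    )
    return table, truth


def apply_noise(table: GenotypeTable, missing_rate: float, error_rate: float,
                seed: int = 0) -> GenotypeTable:
    """Return a copy with calls dropped to missing and/or miscalled.

    Each call is independently set to missing with ``missing_rate``; each
    surviving non-missing call is replaced by one of the two other genotype
    codes (uniformly) with ``error_rate``.  The input table is not modified.
    """
    if not (0 <= missing_rate <= 1 and 0 <= error_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = table.calls.to_numpy().copy()
    present = calls != MISSING
    drop = present & (rng.random(calls.shape) < missing_rate)
    calls[drop] = MISSING
    present = calls != MISSING
    err = present & (rng.random(calls.shape) < error_rate)
    shift = rng.integers(1, 3, size=calls.shape)
    calls[err] = (calls[err] + shift[err]) % 3
    return replace(table, calls=pd.DataFrame(calls, index=table.calls.index,
                                             columns=table.calls.columns))


def simulate_cross(spec: CrossSpec, seed: int | None = None):
    """Simulate a population and apply the spec's genotyping noise."""
    table, truth = simulate_population(spec, seed=seed)
    base = spec.seed if seed is None else seed
    noisy = apply_noise(table, spec.missing_rate, spec.error_rate, seed=base + 1)
    return noisy, truth


@dataclass(frozen=True)
class CrossExpectation:
    """Deterministic expected genotype-class distribution of a cross.

    Computed from the four equally likely (maternal x paternal) SR-locus
    haplotype combinations under complete SD-SR linkage, with lethal
    combinations removed and the remainder renormalized.
    """

    classes: pd.DataFrame  # maternal, paternal, sex, probability

    def female_fraction(self) -> float:
        return float(self.classes.loc[self.classes["sex"] == "F", "probability"].sum())

    def female_male_ratio(self) -> float:
        f = self.female_fraction()
        return f / (1.0 - f)

    def paternal_share(self, sex: str) -> pd.Series:
        """Distribution of paternal SR haplotypes within one sex."""
        sub = self.classes[self.classes["sex"] == sex]
        share = sub.groupby("paternal")["probability"].sum()
        return share / share.sum()


def expected_offspring_classes(spec: CrossSpec) -> CrossExpectation:
    """Closed-form survivor class distribution for a cross specification."""
    rows = []
    for i, m_lab in enumerate(spec.maternal_labels):
        for p_lab in spec.paternal_labels:
            if (m_lab, p_lab) in spec.lethal_pairs:
                continue
            rows.append({"maternal": m_lab, "paternal": p_lab,
                         "sex": "F" if i == 0 else "M", "probability": 0.25})
    if not rows:
        raise ConfigurationError("every zygote class is lethal")
    df = pd.DataFrame(rows)
    df["probability"] /= df["probability"].sum()
    return CrossExpectation(classes=df)


def _preset_map(seed: int = 15) -> tuple[MarkerMap, np.ndarray, np.ndarray, np.ndarray]:
    """Marker map shared by the S5/S3 presets, plus per-marker het assignment.

    Chromosome 15 carries the focal region (54.5-75.8 cM) with 40 maternally
    and 16 paternally informative markers (the counts used for haplotype
    inference in the emulated cross) plus a few biparental ones; one maternal
    and one paternal marker sit exactly at the 60.7 cM SD/SR position.  A
    second chromosome and an "unknown" group provide unlinked null markers.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(chrom, n, cls, lo, hi, prefix):
        p = np.sort(rng.uniform(lo, hi, size=n))
        for k, x in enumerate(p):
            rows.append((f"{prefix}{k + 1:03d}", chrom, float(x), cls))

    add("chr15", 39, "maternal", 54.5, 75.8, "c15M")
    rows.append(("c15M040", "chr15", 60.7, "maternal"))
    add("chr15", 15, "paternal", 54.5, 75.8, "c15P")
    rows.append(("c15P016", "chr15", 60.7, "paternal"))
    add("chr15", 4, "both", 54.5, 75.8, "c15B")
    add("chr01", 6, "maternal", 0.0, 60.0, "c01M")
    add("chr01", 6, "paternal", 0.0, 60.0, "c01P")
    add("chr01", 2, "both", 0.0, 60.0, "c01B")
    add("unknown", 3, "maternal", 0.0, 50.0, "unkM")
    add("unknown", 3, "paternal", 0.0, 50.0, "unkP")

    df = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_cM",
                                     "informativeness"]).set_index("marker_id")
    df = df.sort_values(["chromosome", "position_cM"],
                        key=lambda s: s.map({"chr01": 0, "chr15": 1, "unknown": 2})
                        if s.name == "chromosome" else s)
    mm = MarkerMap(df)

    m = mm.n_markers
    cls = df["informativeness"].to_numpy()
    # which haplotype of the heterozygous parent carries the B allele
    mat_carrier = rng.integers(0, 2, size=m)
    pat_carrier = rng.integers(0, 2, size=m)
    return mm, cls, mat_carrier, pat_carrier


def _haplotypes_from_carriers(cls, carrier, parent_is_het):
    hap = np.zeros((2, len(cls)), dtype=np.int8)
    for j, c in enumerate(cls):
        if parent_is_het(c):
            hap[carrier[j], j] = 1
    return hap


def preset_cross(name: str) -> CrossSpec:
    """Cross specifications emulating the S5 and S3 study populations."""
    if name not in ("S5", "S3"):
        raise ConfigurationError(f"unknown preset {name!r}; expected 'S5' or 'S3'")
    mm, cls, mat_carrier, pat_carrier = _preset_map()
    pat_hap = _haplotypes_from_carriers(cls, pat_carrier, lambda c: c in ("paternal", "both"))
    if name == "S5":
        mat_hap = _haplotypes_from_carriers(cls, mat_carrier, lambda c: c in ("maternal", "both"))
        return CrossSpec(
            marker_map=mm,
            maternal_haplotypes=mat_hap,
            paternal_haplotypes=pat_hap,
            lethal_pairs=frozenset({("Z3", "Z1")}),
            n_offspring_surviving=271,
            mother_id="78021",
            father_id="81084",
        )
    # S3: same father, a different mother with compatible SR alleles
    rng = np.random.default_rng(3)
    mat_carrier_s3 = rng.integers(0, 2, size=mm.n_markers)
    mat_hap = _haplotypes_from_carriers(cls, mat_carrier_s3, lambda c: c in ("maternal", "both"))
    return CrossSpec(
        marker_map=mm,
        maternal_haplotypes=mat_hap,
        paternal_haplotypes=pat_hap,
        lethal_pairs=frozenset(),
        n_offspring_surviving=516,
        maternal_labels=("W", "Zm"),
        mother_id="78195",
        father_id="81084",
    )
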