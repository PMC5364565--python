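"""Deterministic balancing-selection models for a Z-linked incompatibility locus.

Infinite-population, random-mating recurrences for the two genetic
architectures that can maintain a sex-ratio-distorting incompatibility next
to a ZW sex-determination locus:

multiallelic overdominance
    A single locus with K alleles where every homozygous combination is
    inviable.  With allele frequencies ``p``, the surviving zygote mass is
    ``S = 1 - sum(p_i^2)`` and allele frequencies are perfectly preserved at
    the symmetric equilibrium.

multilocus pseudooverdominance
    L tightly linked biallelic loci carrying recessive lethals in repulsion;
    a haplotype is a bit vector of lethal alleles, and a genotype is viable
    iff no locus is homozygous for a lethal (the bitwise intersection of its
    two haplotypes is empty).  Rare recombination (rate ``r`` per adjacent
    interval) eventually assembles a lethal-free haplotype, which erodes the
    balanced system.

Each model comes in a sex-neutral version (incompatibility alleles on both
W and Z gametologs, behaving autosomally, sexes unaffected) and a
sex-dependent version (lethals confined to the Z gametolog; hemizygous W/Z
females are always viable, so only male zygotes are filtered).  In the
sex-dependent version the female fraction among survivors is
``1 / (1 + S)`` with ``S`` the male-zygote survivor mass — e.g. 2/3 (67%)
for two alleles at equal frequencies and 1/1.9 (53%) for ten.

All recurrences are exact and deterministic; no randomness enters anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "PopulationState",
    "Trajectory",
    "ExtinctionError",
    "viability",
    "step_overdominance",
    "step_pseudooverdominance",
    "recombine_gamete_distribution",
    "run_trajectory",
    "closed_form_recessive_lethal",
    "OverdominanceModel",
    "PseudoOverdominanceModel",
    "load_scenarios",
    "run_scenario",
]

_SIMPLEX_TOL = 1e-12


class ExtinctionError(RuntimeError):
    """Raised when the viable zygote mass reaches zero."""

    def __init__(self, message: str, generation: int | None = None):
        super().__init__(message)
        self.generation = generation


def _parse_haplotype(h) -> int:
    """Bit-vector haplotype ('0110', iterable of bits, or int mask) -> mask."""
    if isinstance(h, (int, np.integer)):
        return int(h)
    bits = [int(b) for b in h]
    if any(b not in (0, 1) for b in bits):
        raise ValueError(f"haplotype {h!r} is not a 0/1 vector")
    return sum(b << i for i, b in enumerate(bits))


def viability(genotype_pair, model: str = "overdominance") -> bool:
    """Viability of an unordered pair of alleles (or lethal-locus haplotypes).

    Overdominance: viable iff the two alleles differ.  Pseudooverdominance:
    viable iff no locus carries the lethal on both haplotypes (empty bitwise
    intersection).  Hemizygous W-carrying females in the sex-dependent model
    versions are always viable and never reach this test.
    """
    a, b = genotype_pair
    if model == "overdominance":
        return a != b
    if model == "pseudooverdominance":
        return (_parse_haplotype(a) & _parse_haplotype(b)) == 0
    raise ValueError(f"unknown model {model!r}")


def closed_form_recessive_lethal(q0: float, t: int) -> float:
    """Frequency of a single recessive lethal after t generations: q0/(1+t*q0)."""
    return q0 / (1.0 + t * q0)


@dataclass(frozen=True)
class PopulationState:
    """Allele/haplotype frequencies of one generation of breeding adults.

    ``alleles`` labels the support (allele names or haplotype bit-strings).
    ``maternal_Z_frequencies`` is the distribution of the single Z gametolog
    of breeding females; ``paternal_Z_frequencies`` the male gamete pool; for
    the sex-neutral versions both equal the single autosomal-style pool.
    ``combined_Z_frequencies`` is the reporting convention with the
    W gametolog discounted: every female contributes her one Z and every male
    his two, weighted by the classes' relative frequencies.
    ``survivor_fraction`` is the viable mass of the zygotes that formed this
    generation (male zygotes only in sex-dependent mode).
    """

    alleles: tuple
    maternal_Z_frequencies: np.ndarray = field(repr=False)
    paternal_Z_frequencies: np.ndarray = field(repr=False)
    combined_Z_frequencies: np.ndarray = field(repr=False)
    male_perZ_frequencies: np.ndarray = field(repr=False)
    survivor_fraction: float = 1.0
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("maternal_Z_frequencies", "paternal_Z_frequencies",
                     "combined_Z_frequencies", "male_perZ_frequencies"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            # remove accumulated rounding drift so long runs stay on the simplex
            object.__setattr__(self, name, v / v.sum())

    @property
    def female_percent(self) -> int:
        """Female fraction as the rounded integer percentage."""
        return int(round(100.0 * self.female_fraction))


def _initial_state(alleles, init, sex_mode, model, r=0.0) -> PopulationState:
    init = np.asarray(init, dtype=float)
    if init.min() < 0 or abs(init.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError("initial frequencies must be a simplex vector (sum 1)")
    if sex_mode == "neutral":
        S = _survivor_mass(init, init, alleles, model)
        return PopulationState(tuple(alleles), init, init, init, init,
                               survivor_fraction=S, female_fraction=0.5)
    S = _survivor_mass(init, init, alleles, model)
    if S <= 0:
        raise ExtinctionError("no viable male zygote class at initialization", 0)
    return PopulationState(tuple(alleles), init, init, init, init,
                           survivor_fraction=S, female_fraction=1.0 / (1.0 + S))


def _viability_matrix(alleles, model) -> np.ndarray:
    if model == "overdominance":
        k = len(alleles)
        return ~np.eye(k, dtype=bool)
    masks = np.array([_parse_haplotype(a) for a in alleles])
    return (masks[:, None] & masks[None, :]) == 0


def _survivor_mass(mu, phi, alleles, model) -> float:
    V = _viability_matrix(alleles, model)
    return float(np.einsum("i,j,ij->", mu, phi, V))


def step_overdominance(state: PopulationState, sex_mode: str = "dependent",
                       n_alleles: int | None = None) -> PopulationState:
    """One generation of the multiallelic overdominance recurrence.

    Sex-neutral: ``p' = p (1 - p) / S`` with ``S = 1 - sum(p^2)``.
    Sex-dependent: daughters take their Z from the male gamete pool
    (``mu' = phi``); sons (maternal allele i, paternal allele j) survive iff
    ``i != j``, giving ``S = 1 - sum(mu * phi)`` and
    ``phi' = (mu (1 - phi) + phi (1 - mu)) / (2 S)``.
    """
    k = len(state.alleles)
    if n_alleles is not None and n_alleles != k:
        raise ValueError("n_alleles does not match the state support")
    if sex_mode == "neutral":
        p = state.maternal_Z_frequencies
        S = 1.0 - float(p @ p)
        if S <= 0:
            raise ExtinctionError("all zygotes homozygous: population extinct")
        p1 = p * (1.0 - p) / S
        return PopulationState(state.alleles, p1, p1, p1, p1,
                               survivor_fraction=S, female_fraction=0.5)
    if sex_mode != "dependent":
        raise ValueError(f"unknown sex_mode {sex_mode!r}")
    mu, phi = state.maternal_Z_frequencies, state.paternal_Z_frequencies
    S = 1.0 - float(mu @ phi)
    if S <= 0:
        raise ExtinctionError("all male zygotes inviable: population extinct")
    phi1 = (mu * (1.0 - phi) + phi * (1.0 - mu)) / (2.0 * S)
    mu1 = phi.copy()
    # complete linkage: a male transmits each of his two Z's equally, so the
    # per-Z distribution among males equals the gamete pool
    combined = (0.5 * mu1 + S * phi1) / (0.5 + S)
    return PopulationState(state.alleles, mu1, phi1, combined, phi1,
                           survivor_fraction=S, female_fraction=1.0 / (1.0 + S))


@lru_cache(maxsize=None)
def _pair_gametes(h1: int, h2: int, r: float, n_loci: int):
    """Gamete distribution of one genotype under left-to-right meiosis.

    The gamete copies from one parental haplotype and switches template with
    probability r at each of the ``n_loci - 1`` intervals (no interference).
    Returns (masks tuple, probabilities tuple).
    """
    if h1 == h2 or r == 0.0 or n_loci <= 1:
        if h1 == h2:
            return (h1,), (1.0,)
        return (h1, h2), (0.5, 0.5)
    states = {(h1 & 1, 0): 0.5, (h2 & 1, 1): 0.5}
    acc = {}
    for (pfx, src), p in list(states.items()):
        acc[(pfx, src)] = acc.get((pfx, src), 0.0) + p
    states = acc
    for i in range(1, n_loci):
        nxt: dict = {}
        for (pfx, src), p in states.items():
            for new_src, q in ((src, 1.0 - r), (1 - src, r)):
                bit = (h1 if new_src == 0 else h2) >> i & 1
                key = (pfx | (bit << i), new_src)
                nxt[key] = nxt.get(key, 0.0) + p * q
        states = nxt
    out: dict[int, float] = {}
    for (mask, _src), p in states.items():
        out[mask] = out.get(mask, 0.0) + p
    masks = tuple(sorted(out))
    return masks, tuple(out[m] for m in masks)


def recombine_gamete_distribution(genotype_distribution, r: float, n_loci: int) -> dict:
    """Gamete haplotype distribution from a genotype distribution.

    ``genotype_distribution`` maps unordered haplotype pairs (each haplotype
    a bit-string or int mask) to probabilities.  ``r`` is the per-interval
    recombination rate; ``r = 0`` transmits the two intact parental
    haplotypes with equal weight.
    """
    if not (0.0 <= r <= 0.5):
        raise ValueError("recombination rate must lie in [0, 0.5]")
    if n_loci > 16:
        raise ValueError("haplotype space enumerable only up to 16 loci")
    out: dict[int, float] = {}
    for (a, b), p in genotype_distribution.items():
        masks, probs = _pair_gametes(_parse_haplotype(a), _parse_haplotype(b),
                                     float(r), n_loci)
        for m_, q in zip(masks, probs):
            out[m_] = out.get(m_, 0.0) + p * q
    return out


class _PseudoEngine:
    """Vectorized transmission over the subset lattice of lethal loci.

    The reachable haplotype space is the set of subsets of the union of the
    initial haplotypes' lethal bits; for the default layouts this lattice is
    small (2^9 = 512 for the ten-haplotype scenario) and the full viable-pair
    transmission matrix is precomputed once per (lattice, r).
    """

    _cache: dict = {}

    def __new__(cls, union_mask: int, r: float, n_loci: int):
        key = (union_mask, r, n_loci)
        if key in cls._cache:
            return cls._cache[key]
        self = super().__new__(cls)
        self._build(union_mask, r, n_loci)
        cls._cache[key] = self
        return self

    def _build(self, union_mask: int, r: float, n_loci: int):
        bits = [i for i in range(n_loci) if union_mask >> i & 1]
        if len(bits) > 12:
            raise ValueError("recombining pseudooverdominance dynamics supported "
                             "for at most 12 segregating lethal loci")
        masks = []
        for sub in range(1 << len(bits)):
            m = 0
            for j, b in enumerate(bits):
                if sub >> j & 1:
                    m |= 1 << b
            masks.append(m)
        self.masks = np.array(sorted(masks))
        self.index = {m: i for i, m in enumerate(self.masks)}
        n = len(self.masks)
        self.viable = (self.masks[:, None] & self.masks[None, :]) == 0
        pairs_i, pairs_j = np.nonzero(np.triu(self.viable))
        self.pairs_i, self.pairs_j = pairs_i, pairs_j
        from scipy.sparse import csr_matrix

        data, indices, indptr = [], [], [0]
        for i, j in zip(pairs_i, pairs_j):
            gmasks, gprobs = _pair_gametes(int(self.masks[i]), int(self.masks[j]),
                                           float(r), n_loci)
            indices.extend(self.index[g] for g in gmasks)
            data.extend(gprobs)
            indptr.append(len(data))
        self.transmission = csr_matrix(
            (np.array(data), np.array(indices), np.array(indptr)),
            shape=(len(pairs_i), n))

    def expand(self, alleles, freqs) -> np.ndarray:
        full = np.zeros(len(self.masks))
        for a, f in zip(alleles, freqs):
            full[self.index[_parse_haplotype(a)]] += f
        return full

    def step(self, mu_full, phi_full):
        """Viable zygote mass, per-Z male distribution and male gamete pool."""
        i, j = self.pairs_i, self.pairs_j
        w = mu_full[i] * phi_full[j] + np.where(i != j, mu_full[j] * phi_full[i], 0.0)
        S = float(w.sum())
        if S <= 0:
            raise ExtinctionError("all zygotes inviable")
        P = w / S
        perZ = np.zeros_like(mu_full)
        np.add.at(perZ, i, 0.5 * P)
        np.add.at(perZ, j, 0.5 * P)
        pool = self.transmission.T @ P
        return S, perZ, np.asarray(pool).ravel()


def _mask_labels(masks, n_loci) -> tuple:
    return tuple("".join(str(m >> i & 1) for i in range(n_loci)) for m in masks)


def step_pseudooverdominance(state: PopulationState, sex_mode: str,
                             r: float, n_loci: int) -> PopulationState:
    """One generation of the multilocus pseudooverdominance recurrence.

    Zygotes are formed from the parental pools, inviable genotypes (sharing a
    homozygous lethal locus) are removed, and the next-generation gamete
    pools follow meiosis with per-interval recombination rate ``r``.  The
    haplotype support grows as recombination creates new haplotypes (full
    subset-lattice enumeration, no truncation).
    """
    masks = [_parse_haplotype(a) for a in state.alleles]
    union = 0
    for m in masks:
        union |= m
    eng = _PseudoEngine(union, float(r), n_loci)
    labels = _mask_labels(eng.masks, n_loci)
    if sex_mode == "neutral":
        p = eng.expand(state.alleles, state.maternal_Z_frequencies)
        S, _perZ, pool = eng.step(p, p)
        return PopulationState(labels, pool, pool, pool, pool,
                               survivor_fraction=S, female_fraction=0.5)
    if sex_mode != "dependent":
        raise ValueError(f"unknown sex_mode {sex_mode!r}")
    mu = eng.expand(state.alleles, state.maternal_Z_frequencies)
    phi = eng.expand(state.alleles, state.paternal_Z_frequencies)
    S, perZ, pool = eng.step(mu, phi)
    mu1 = phi
    combined = (0.5 * mu1 + S * perZ) / (0.5 + S)
    return PopulationState(labels, mu1, pool, combined, perZ,
                           survivor_fraction=S, female_fraction=1.0 / (1.0 + S))


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of a model run.

    For ``model="overdominance"`` give ``n_alleles``; for
    ``"pseudooverdominance"`` give ``haplotypes`` (bit-strings over the
    lethal loci, at most one all-zero harmless haplotype) and the
    per-interval ``recombination_rate``.  ``initial_frequencies`` defaults to
    the uniform simplex over the support.
    """

    model: str = "overdominance"
    sex_mode: str = "dependent"
    n_alleles: int | None = None
    haplotypes: tuple | None = None
    initial_frequencies: tuple | None = None
    recombination_rate: float = 0.01
    generations: int = 100

    def __post_init__(self) -> None:
        if self.model not in ("overdominance", "pseudooverdominance"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.sex_mode not in ("neutral", "dependent"):
            raise ValueError(f"unknown sex_mode {self.sex_mode!r}")
        if self.generations < 1:
            raise ValueError("generations must be positive")
        if self.model == "overdominance":
            if not self.n_alleles or self.n_alleles < 2:
                raise ValueError("overdominance needs n_alleles >= 2")
        else:
            if not self.haplotypes or len(self.haplotypes) < 2:
                raise ValueError("pseudooverdominance needs >= 2 haplotypes")
            hl = {len(str(h)) for h in self.haplotypes}
            if len(hl) != 1:
                raise ValueError("haplotype bit-vectors must share one length")
            masks = [_parse_haplotype(h) for h in self.haplotypes]
            if len(set(masks)) != len(masks):
                raise ValueError("duplicate haplotypes are not allowed")
            if not (0 <= self.recombination_rate <= 0.5):
                raise ValueError("recombination_rate must lie in [0, 0.5]")
        if self.initial_frequencies is not None:
            init = np.asarray(self.initial_frequencies, dtype=float)
            if len(init) != self.support_size:
                raise ValueError("one initial frequency per allele/haplotype required")
            if init.min() < 0 or abs(init.sum() - 1.0) > _SIMPLEX_TOL:
                raise ValueError("initial frequencies must sum to 1")
            object.__setattr__(self, "initial_frequencies", tuple(init))

    @property
    def support_size(self) -> int:
        return self.n_alleles if self.model == "overdominance" else len(self.haplotypes)

    @property
    def n_loci(self) -> int:
        return len(str(self.haplotypes[0])) if self.haplotypes else 0

    def labels(self) -> tuple:
        if self.model == "overdominance":
            return tuple(f"A{i + 1}" for i in range(self.n_alleles))
        return tuple(str(h) for h in self.haplotypes)

    def init(self) -> np.ndarray:
        if self.initial_frequencies is not None:
            return np.asarray(self.initial_frequencies, dtype=float)
        return np.full(self.support_size, 1.0 / self.support_size)


@dataclass(frozen=True)
class Trajectory:
    """Per-generation population states, t = 0..T."""

    spec: ModelSpec
    states: tuple = field(repr=False)

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, t) -> PopulationState:
        return self.states[t]

    def female_fractions(self) -> np.ndarray:
        return np.array([s.female_fraction for s in self.states])

    def survivor_fractions(self) -> np.ndarray:
        return np.array([s.survivor_fraction for s in self.states])

    def combined_frequency(self, label) -> np.ndarray:
        """Trajectory of one allele/haplotype's combined Z frequency."""
        out = np.zeros(len(self.states))
        for t, s in enumerate(self.states):
            if label in s.alleles:
                out[t] = s.combined_Z_frequencies[s.alleles.index(label)]
        return out

    def stable_female_percent(self) -> int:
        """Rounded female percentage of the final generation."""
        return self.states[-1].female_percent

    def to_frame(self) -> pd.DataFrame:
        """Wide per-generation frame over the final support."""
        support = self.states[-1].alleles
        rows = []
        for t, s in enumerate(self.states):
            row = {"t": t, "survivor_fraction": s.survivor_fraction,
                   "female_fraction": s.female_fraction,
                   "female_percent": s.female_percent}
            freq = dict(zip(s.alleles, s.combined_Z_frequencies))
            for lab in support:
                row[f"freq_{lab}"] = freq.get(lab, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def run_trajectory(spec: ModelSpec) -> Trajectory:
    """Iterate the model recurrence for ``spec.generations`` generations."""
    labels = spec.labels()
    state = _initial_state(labels, spec.init(), spec.sex_mode,
                           spec.model, spec.recombination_rate)
    states = [state]
    for t in range(spec.generations):
        try:
            if spec.model == "overdominance":
                state = step_overdominance(state, spec.sex_mode)
            else:
                state = step_pseudooverdominance(state, spec.sex_mode,
                                                 spec.recombination_rate, spec.n_loci)
        except ExtinctionError as err:
            raise ExtinctionError(f"extinct at generation {t + 1}: {err}", t + 1) from err
        states.append(state)
    return Trajectory(spec=spec, states=tuple(states))


class OverdominanceModel:
    """Multiallelic overdominance model (every homozygote inviable)."""

    def __init__(self, n_alleles: int, sex_mode: str = "dependent",
                 initial_frequencies=None, generations: int = 100):
        self.spec = ModelSpec(model="overdominance", sex_mode=sex_mode,
                              n_alleles=n_alleles,
                              initial_frequencies=None if initial_frequencies is None
                              else tuple(initial_frequencies),
                              generations=generations)

    def run(self, generations: int | None = None) -> Trajectory:
        spec = self.spec if generations is None else \
            ModelSpec(**{**self.spec.__dict__, "generations": generations})
        return run_trajectory(spec)


class PseudoOverdominanceModel:
    """Multilocus recessive-lethal (pseudooverdominance) model.

    ``default_haplotypes(k)`` builds the standard layout: k - 1 haplotypes
    carrying one lethal each at distinct loci plus one harmless haplotype.
    """

    def __init__(self, haplotypes, sex_mode: str = "dependent",
                 initial_frequencies=None, recombination_rate: float = 0.01,
                 generations: int = 100):
        self.spec = ModelSpec(model="pseudooverdominance", sex_mode=sex_mode,
                              haplotypes=tuple(str(h) for h in haplotypes),
                              initial_frequencies=None if initial_frequencies is None
                              else tuple(initial_frequencies),
                              recombination_rate=recombination_rate,
                              generations=generations)

    @staticmethod
    def default_haplotypes(n_haplotypes: int) -> tuple:
        L = n_haplotypes - 1
        haps = ["".join("1" if j == i else "0" for j in range(L)) for i in range(L)]
        haps.append("0" * L)
        return tuple(haps)

    def run(self, generations: int | None = None) -> Trajectory:
        spec = self.spec if generations is None else \
            ModelSpec(**{**self.spec.__dict__, "generations": generations})
        return run_trajectory(spec)


def load_scenarios() -> dict:
    """Named model scenarios (the three simulation panels) from package data."""
    import importlib.resources

    import yaml

    text = importlib.resources.files("zwdistort").joinpath("scenarios.yaml").read_text()
    return yaml.safe_load(text)


def run_scenario(name: str, generations: int | None = None) -> dict[str, Trajectory]:
    """Run every curve of a named scenario; returns {curve name: Trajectory}."""
    scenarios = load_scenarios()
    if name not in scenarios:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(scenarios)}")
    cfg = scenarios[name]
    T = generations if generations is not None else cfg.get("generations", 100)
    out = {}
    for curve, params in cfg["curves"].items():
        params = dict(params)
        init = params.pop("initial_frequencies", None)
        normalize = params.pop("normalize_initial", False)
        if init is not None and normalize:
            init = list(np.asarray(init, dtype=float) / np.sum(init))
        if "haplotypes" in params:
            params["haplotypes"] = tuple(str(h) for h in params["haplotypes"])
        spec = ModelSpec(generations=T,
                         initial_frequencies=None if init is None else tuple(init),
                         **params)
        out[curve] = run_trajectory(spec)
    return out
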