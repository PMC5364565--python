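"""Pseudo-testcross haplotype phasing and genotype-class analysis.

Markers informative in one parent reveal, per offspring, which of that
parent's two alleles was transmitted — but the phase (which allele sits on
which parental haplotype) is unknown per marker.  Phasing chooses one
orientation bit per marker so that the total number of inheritance-state
changes between adjacent markers, summed over the whole population, is
minimal; adjacency is per offspring between nearest non-missing markers.

The minimization is solved exactly by a sliding-window dynamic programme
over marker orientations: the objective decomposes over the (marker, marker)
adjacency edges, and only markers with pending edges to the right need to be
kept in the DP frontier.  With complete data the frontier has width one and
the DP reduces to chaining pairwise majority votes; missing data widens the
frontier by at most the longest per-offspring gap.  The global H1/H2 label
swap is an accepted symmetry, fixed by orienting the first informative
marker of each connected component.

Downstream of phasing: breakpoint calling and recombinant classification,
the (maternal x paternal x sex) genotype-class census that detects missing
classes such as the absent Z1/Z3 males, and the single-recombinant grouping
scan used to probe linkage between the sex-determination and sex-ratio
distorter loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .exact import exact_conditional_p
from .genotypes import MISSING, GenotypeTable, inheritance_indicators

__all__ = [
    "MinRecombinationPhaser",
    "PhaseResults",
    "phase_by_min_recombination",
    "call_breakpoints",
    "resolve_locus_states",
    "genotype_class_census",
    "GenotypeClassTable",
    "sd_sr_linkage_scan",
    "phase_cross",
    "CrossPhasing",
]


def _adjacency_edges(X: np.ndarray):
    """Aggregate per-offspring nearest-non-missing adjacencies into edges.

    Returns a dict mapping marker-index pairs (a, b), a < b, to
    ``[n_same, n_diff]``: the number of offspring whose indicators at a and b
    agree / disagree.
    """
    edges: dict[tuple[int, int], list[int]] = {}
    for row in X:
        idx = np.flatnonzero(row != MISSING)
        if idx.size < 2:
            continue
        a, b = idx[:-1], idx[1:]
        diff = row[a] != row[b]
        for aa, bb, d in zip(a, b, diff):
            e = edges.setdefault((int(aa), int(bb)), [0, 0])
            e[1 if d else 0] += 1
    return edges


def _solve_orientations(edges, n_markers: int, forced: dict[int, int] | None = None):
    """Exact minimum-recombination orientation via frontier DP.

    ``forced`` pins orientations of selected markers (used for gauge fixing
    and for tie probing).  Returns (orientations array, optimal objective,
    has_edges boolean mask).
    """
    forced = dict(forced or {})
    edges_to: dict[int, list] = {}
    last_target = {}
    has_edges = np.zeros(n_markers, dtype=bool)
    for (a, b), (n_same, n_diff) in edges.items():
        edges_to.setdefault(b, []).append((a, n_same, n_diff))
        last_target[a] = max(last_target.get(a, -1), b)
        has_edges[a] = has_edges[b] = True

    active: list[int] = []
    # states: key = orientation bits of active markers -> (cost, assignment dict)
    states: dict[tuple, tuple[int, dict]] = {(): (0, {})}
    for m in range(n_markers):
        if not has_edges[m]:
            continue
        incoming = edges_to.get(m, [])
        if m in forced:
            bits = (forced[m],)
        elif not active:
            bits = (0,)  # gauge: first marker of a component
        else:
            bits = (0, 1)
        new_states: dict[tuple, tuple[int, dict]] = {}
        pos_of = {a: i for i, a in enumerate(active)}
        for key in sorted(states):
            cost, assign = states[key]
            for bit in bits:
                c = cost
                for a, n_same, n_diff in incoming:
                    # transition iff orientation-adjusted states disagree:
                    # o_a ^ o_b == 0 leaves disagreements, == 1 flips them
                    c += n_diff if (bit ^ key[pos_of[a]]) == 0 else n_same
                nk = key + (bit,)
                na = dict(assign)
                na[m] = bit
                old = new_states.get(nk)
                if old is None or c < old[0]:
                    new_states[nk] = (c, na)
        active.append(m)
        # retire markers with no pending edges to the right
        retire = [a for a in active if last_target.get(a, -1) <= m]
        if retire:
            keep_pos = [i for i, a in enumerate(active) if a not in retire]
            merged: dict[tuple, tuple[int, dict]] = {}
            for key in sorted(new_states):
                cost, assign = new_states[key]
                nk = tuple(key[i] for i in keep_pos)
                old = merged.get(nk)
                if old is None or cost < old[0]:
                    merged[nk] = (cost, assign)
            active = [a for a in active if a not in retire]
            states = merged
        else:
            states = new_states

    (_, (best_cost, best_assign)), = states.items() if len(states) == 1 else [
        min(states.items(), key=lambda kv: kv[1][0])]
    orient = np.zeros(n_markers, dtype=np.int8)
    for m, bit in best_assign.items():
        orient[m] = bit
    for m, bit in forced.items():
        orient[m] = bit
    return orient, int(best_cost), has_edges


@dataclass(frozen=True)
class PhaseResults:
    """Phased inheritance states for one parental marker group.

    ``states`` is offspring x markers with values 0 (haplotype H1), 1 (H2)
    or -1 (missing/uninformative); ``orientation`` records which observed
    allele was mapped to H1 at each marker.  ``undetermined`` flags markers
    with no non-missing adjacency to any neighbour; ``ambiguous`` flags
    markers whose orientation can be flipped without changing the optimal
    objective (exact ties).  ``objective`` is the minimized population-wide
    recombination count.
    """

    states: pd.DataFrame = field(repr=False)
    orientation: np.ndarray = field(repr=False)
    undetermined: np.ndarray = field(repr=False)
    ambiguous: np.ndarray = field(repr=False)
    objective: int = 0

    @property
    def marker_ids(self) -> pd.Index:
        return self.states.columns

    @property
    def offspring_ids(self) -> pd.Index:
        return self.states.index

    def breakpoints(self) -> pd.DataFrame:
        return call_breakpoints(self.states)

    def summary(self) -> str:
        bp = self.breakpoints()
        counts = bp["rec_class"].value_counts()
        lines = [
            f"Min-recombination phasing: {self.states.shape[1]} markers, "
            f"{self.states.shape[0]} offspring",
            f"objective (total recombination events): {self.objective}",
            f"undetermined markers: {int(self.undetermined.sum())}, "
            f"tied orientations: {int(self.ambiguous.sum())}",
        ]
        for cls in ("non-recombinant", "single-recombinant", "multi-recombinant", "unknown"):
            lines.append(f"  {cls}: {int(counts.get(cls, 0))}")
        return "\n".join(lines)


class MinRecombinationPhaser:
    """Population-wide minimum-recombination phaser for ordered markers.

    Parameters
    ----------
    indicators
        Offspring x ordered-marker frame of transmitted-allele indicators
        (0/1, -1 missing), e.g. from
        :func:`zwdistort.genotypes.inheritance_indicators`.
    flag_ties
        When true (default), markers whose orientation is not uniquely
        optimal are flagged by re-solving with the orientation pinned to the
        opposite value; disable for bulk simulation work.
    """

    def __init__(self, indicators: pd.DataFrame, flag_ties: bool = True):
        self.indicators = indicators
        self.flag_ties = flag_ties

    def fit(self) -> PhaseResults:
        X = self.indicators.to_numpy()
        n_off, n_markers = X.shape
        edges = _adjacency_edges(X)
        orient, cost, has_edges = _solve_orientations(edges, n_markers)

        ambiguous = np.zeros(n_markers, dtype=bool)
        if self.flag_ties and edges:
            # gauge markers (one per component) carry the global-swap symmetry
            gauges = _component_gauges(edges, n_markers)
            pins = {g: int(orient[g]) for g in gauges}
            for m in range(n_markers):
                if not has_edges[m] or m in pins:
                    continue
                forced = dict(pins)
                forced[m] = 1 - int(orient[m])
                _, alt_cost, _ = _solve_orientations(edges, n_markers, forced=forced)
                if alt_cost == cost:
                    ambiguous[m] = True

        states = np.where(X == MISSING, MISSING, X ^ orient[None, :]).astype(np.int8)
        states[:, ~has_edges] = np.where(X[:, ~has_edges] == MISSING, MISSING,
                                         X[:, ~has_edges])
        return PhaseResults(
            states=pd.DataFrame(states, index=self.indicators.index,
                                columns=self.indicators.columns),
            orientation=orient,
            undetermined=~has_edges,
            ambiguous=ambiguous,
            objective=cost,
        )


def _component_gauges(edges, n_markers: int) -> list[int]:
    """First marker of each connected component of the adjacency graph."""
    parent = list(range(n_markers))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    roots: dict[int, int] = {}
    involved = sorted({m for e in edges for m in e})
    for m in involved:
        roots.setdefault(find(m), m)
    return sorted(roots.values())


def phase_by_min_recombination(indicators: pd.DataFrame, flag_ties: bool = True) -> PhaseResults:
    """Functional wrapper: ``MinRecombinationPhaser(indicators).fit()``."""
    return MinRecombinationPhaser(indicators, flag_ties=flag_ties).fit()


def call_breakpoints(states: pd.DataFrame) -> pd.DataFrame:
    """Count state transitions and classify recombinants per offspring.

    Transitions are counted between consecutive non-missing states; each
    breakpoint interval is the (last marker of the previous state, first
    marker of the next state) index pair.  Offspring with fewer than one
    non-missing state are classified ``unknown``.
    """
    X = states.to_numpy()
    rows = []
    for row in X:
        idx = np.flatnonzero(row != MISSING)
        if idx.size == 0:
            rows.append((0, "unknown", []))
            continue
        flips = np.flatnonzero(np.diff(row[idx]) != 0)
        intervals = [(int(idx[j]), int(idx[j + 1])) for j in flips]
        n = len(intervals)
        cls = ("non-recombinant" if n == 0
               else "single-recombinant" if n == 1 else "multi-recombinant")
        rows.append((n, cls, intervals))
    return pd.DataFrame(rows, index=states.index,
                        columns=["n_transitions", "rec_class", "intervals"])


def resolve_locus_states(states: pd.DataFrame, positions_cM, query_cM: float) -> pd.Series:
    """Inheritance state at an arbitrary map position per offspring.

    Uses the nearest non-missing flanking markers; if both flanks exist and
    agree the state is returned, if only one flank exists its state is used,
    and if the flanks disagree (a breakpoint spans the position) the
    offspring is unresolved (-1).
    """
    pos = np.asarray(positions_cM, dtype=float)
    X = states.to_numpy()
    out = np.full(X.shape[0], MISSING, dtype=np.int8)
    for i, row in enumerate(X):
        idx = np.flatnonzero(row != MISSING)
        if idx.size == 0:
            continue
        p = pos[idx]
        left = idx[p <= query_cM]
        right = idx[p >= query_cM]
        sl = row[left[-1]] if left.size else None
        sr = row[right[0]] if right.size else None
        if sl is None:
            out[i] = sr
        elif sr is None or sl == sr:
            out[i] = sl
    return pd.Series(out, index=states.index)


@dataclass(frozen=True)
class GenotypeClassTable:
    """Census of (maternal x paternal x sex) genotype classes at a locus.

    ``frame`` has one row per class with the observed count, the Mendelian
    expectation (half of the (maternal, sex) stratum, i.e. the 1:1 paternal
    split conditioned on observed stratum totals), an exact binomial p-value
    for that split, and a flag for classes that are absent despite a positive
    expectation.
    """

    frame: pd.DataFrame = field(repr=False)

    def missing_classes(self) -> list[tuple[str, str, str]]:
        sub = self.frame[self.frame["missing_class"]]
        return [tuple(r) for r in sub[["maternal", "paternal", "sex"]].to_numpy()]

    def count(self, maternal: str, paternal: str, sex: str) -> int:
        f = self.frame
        row = f[(f["maternal"] == maternal) & (f["paternal"] == paternal) & (f["sex"] == sex)]
        return int(row["count"].iloc[0])

    def summary(self) -> str:
        lines = ["Genotype-class census (maternal x paternal x sex)", "-" * 50]
        for _, r in self.frame.iterrows():
            flag = "  << MISSING CLASS" if r["missing_class"] else ""
            lines.append(f"{r['maternal']:>4} / {r['paternal']:<4} {r['sex']}: "
                         f"n = {int(r['count']):4d}  (expected {r['expected']:6.1f}, "
                         f"binomial p = {r['p_binomial']:.3g}){flag}")
        return "\n".join(lines)


def genotype_class_census(
    maternal_states: pd.Series,
    paternal_states: pd.Series,
    sex: pd.Series,
    maternal_names: tuple = ("H1", "H2"),
    paternal_names: tuple = ("H1", "H2"),
) -> GenotypeClassTable:
    """Count (maternal haplotype x paternal haplotype x sex) classes.

    Inputs are per-offspring locus states (0/1, -1 unresolved) for each
    parental set plus sex labels; only offspring resolved on both sides with
    known sex contribute.  The Mendelian expectation for each cell is half of
    its (maternal, sex) stratum — under ZW inheritance the maternal gametolog
    determines sex, so the 1:1 paternal split is the only testable dimension —
    and each cell gets the exact two-sided binomial p-value of that split.
    """
    df = pd.DataFrame({"mat": maternal_states, "pat": paternal_states, "sex": sex})
    df = df[(df["mat"] != MISSING) & (df["pat"] != MISSING) & df["sex"].isin(["F", "M"])]
    if df.empty:
        raise ValueError("no offspring resolved at the queried locus")
    rows = []
    for sx in ("F", "M"):
        for mi, m_name in enumerate(maternal_names):
            stratum = df[(df["sex"] == sx) & (df["mat"] == mi)]
            n = len(stratum)
            for pi, p_name in enumerate(paternal_names):
                k = int((stratum["pat"] == pi).sum())
                expected = n / 2.0
                p = binomtest(k, n, 0.5).pvalue if n > 0 else np.nan
                rows.append({
                    "maternal": m_name, "paternal": p_name, "sex": sx,
                    "count": k, "expected": expected, "p_binomial": p,
                    "missing_class": k == 0 and expected > 0,
                })
    return GenotypeClassTable(frame=pd.DataFrame(rows))


def sd_sr_linkage_scan(
    single_recombinants: pd.DataFrame,
    paternal_labels: pd.Series,
    n_markers: int,
    alpha: float = 0.05,
    membership: str = "exact",
) -> pd.DataFrame:
    """Grouping test for recombination between the SD and SR loci.

    ``single_recombinants`` holds one row per single-recombinant female with
    integer columns ``left`` and ``right``: the 0-based flanking marker
    indices of her maternal breakpoint.  ``paternal_labels`` gives the
    paternal SR-locus haplotype (0/1) for every genotyped female (the
    comparison set); unresolved females must be dropped beforehand.

    Groups are indexed by 1-based (n, m): females carrying one maternal
    haplotype on markers 1..n and the other on markers m..``n_markers``.
    With ``membership="exact"`` (default) each female belongs to the single
    group given by her observed breakpoint flanks — grouping by recombination
    point; ``membership="nested"`` instead includes her in every compatible
    (n <= left+1, m >= right+1) group.  Each group's paternal-haplotype counts
    are tested against all remaining females with a two-sided exact test,
    uncorrected for multiple testing.

    Returns one row per group with >= 1 member (empty frame if there are no
    single recombinants).
    """
    if membership not in ("exact", "nested"):
        raise ValueError("membership must be 'exact' or 'nested'")
    cols = ["n", "m", "size", "in_h1", "in_h2", "out_h1", "out_h2", "p", "significant"]
    if single_recombinants.empty:
        return pd.DataFrame(columns=cols)
    rec = single_recombinants[single_recombinants.index.isin(paternal_labels.index)]
    labels = paternal_labels.astype(int)
    total_h1 = int((labels == 0).sum())
    total_h2 = int((labels == 1).sum())

    groups: dict[tuple[int, int], list] = {}
    if membership == "exact":
        for fid, row in rec.iterrows():
            groups.setdefault((int(row["left"]) + 1, int(row["right"]) + 1), []).append(fid)
    else:
        lefts = rec["left"].to_numpy(int)
        rights = rec["right"].to_numpy(int)
        for n in range(1, int(lefts.max()) + 2):
            for m in range(int(rights.min()) + 1, n_markers + 1):
                if m <= n:
                    continue
                members = rec.index[(lefts >= n - 1) & (rights <= m - 1)].tolist()
                if members:
                    groups[(n, m)] = members

    # deduplicate identical membership sets so each distinct group is tested once
    p_cache: dict[frozenset, tuple] = {}
    rows = []
    for (n, m), members in sorted(groups.items()):
        key = frozenset(members)
        if key not in p_cache:
            in_h1 = int((labels.loc[members] == 0).sum())
            in_h2 = int((labels.loc[members] == 1).sum())
            table = [[in_h1, in_h2], [total_h1 - in_h1, total_h2 - in_h2]]
            p_cache[key] = (in_h1, in_h2, exact_conditional_p(table))
        in_h1, in_h2, p = p_cache[key]
        rows.append({
            "n": n, "m": m, "size": len(members),
            "in_h1": in_h1, "in_h2": in_h2,
            "out_h1": total_h1 - in_h1, "out_h2": total_h2 - in_h2,
            "p": p, "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class CrossPhasing:
    """Phased maternal and paternal marker sets for one cross region."""

    maternal: PhaseResults
    paternal: PhaseResults
    maternal_positions: np.ndarray = field(repr=False)
    paternal_positions: np.ndarray = field(repr=False)
    sex: pd.Series = field(repr=False)

    def _locus_states(self, which: str, position_cM: float,
                      exclude_multirecombinant: bool = True) -> pd.Series:
        phase = getattr(self, which)
        pos = getattr(self, f"{which}_positions")
        states = resolve_locus_states(phase.states, pos, position_cM)
        if exclude_multirecombinant:
            multi = phase.breakpoints()["rec_class"] == "multi-recombinant"
            states = states.mask(multi, MISSING).astype(np.int8)
        return states

    def census_at(self, position_cM: float,
                  exclude_multirecombinant: bool = True) -> GenotypeClassTable:
        """Genotype-class census at a map position, with W assigned by sex.

        The maternal haplotype carried by the majority of females at the
        locus is labelled ``W`` (female heterogamety), the other ``Z``;
        paternal haplotypes keep the neutral phasing labels ``P1``/``P2``.
        Offspring classified multi-recombinant in either parental set are
        treated as unresolved by default, which shields the census against
        isolated genotyping errors (an erroneous interior call shows up as a
        double transition).
        """
        mat = self._locus_states("maternal", position_cM, exclude_multirecombinant)
        pat = self._locus_states("paternal", position_cM, exclude_multirecombinant)
        females = mat[(self.sex == "F") & (mat != MISSING)]
        if len(females) and (females == 1).mean() > 0.5:
            mat = mat.mask(mat != MISSING, 1 - mat).astype(np.int8)
        return genotype_class_census(mat, pat, self.sex,
                                     maternal_names=("W", "Z"),
                                     paternal_names=("P1", "P2"))

    def linkage_scan(self, position_cM: float, alpha: float = 0.05,
                     membership: str = "exact") -> pd.DataFrame:
        """Single-recombinant grouping scan for SD-SR recombination.

        Uses maternal single-recombinant females and the paternal haplotype
        at ``position_cM`` of every resolved female as the comparison set.
        """
        bp = self.maternal.breakpoints()
        is_female = self.sex == "F"
        singles = bp[(bp["rec_class"] == "single-recombinant") & is_female]
        sr = pd.DataFrame(
            {
                "left": [iv[0][0] for iv in singles["intervals"]],
                "right": [iv[0][1] for iv in singles["intervals"]],
            },
            index=singles.index,
        )
        pat = self._locus_states("paternal", position_cM)
        pat_females = pat[is_female & (pat != MISSING)]
        return sd_sr_linkage_scan(sr, pat_females,
                                  n_markers=self.maternal.states.shape[1],
                                  alpha=alpha, membership=membership)


def phase_cross(table: GenotypeTable, chromosome: str | None = None,
                start_cM: float | None = None, end_cM: float | None = None,
                flag_ties: bool = True) -> CrossPhasing:
    """Phase the maternal and paternal pseudo-testcross markers of a region.

    Markers are restricted to one chromosome (required when the map has
    several) and optionally to a cM window, ordered by map position.
    """
    mm = table.markers.df
    if chromosome is None:
        if len(set(mm["chromosome"])) > 1:
            raise ValueError("specify the chromosome to phase on a multi-chromosome map")
        chromosome = mm["chromosome"].iloc[0]
    region = table.markers.region(chromosome, start_cM, end_cM)

    results = {}
    positions = {}
    for group in ("maternal", "paternal"):
        ind = inheritance_indicators(table, group)
        ids = [m for m in region.marker_ids if m in ind.columns]
        results[group] = MinRecombinationPhaser(ind[ids], flag_ties=flag_ties).fit()
        positions[group] = region.df.loc[ids, "position_cM"].to_numpy(dtype=float)
    return CrossPhasing(
        maternal=results["maternal"],
        paternal=results["paternal"],
        maternal_positions=positions["maternal"],
        paternal_positions=positions["paternal"],
        sex=table.sex,
    )
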