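"""Population-level analyses downstream of typing.

Allele/carrier frequencies, addressed-allele coverage, a Monte-Carlo exact
Hardy-Weinberg test, chord genetic distances, neighbor-joining dendrograms,
principal-coordinates ordination, allele aliasing, and exact contingency
tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "PopulationFrequencies",
    "DistanceMatrix",
    "HweResult",
    "PcoaResult",
    "allele_frequencies",
    "carrier_frequencies",
    "coverage",
    "cumulative_coverage_curve",
    "hwe_test",
    "cavalli_sforza_distance",
    "distance_matrix",
    "nj_tree",
    "pcoa",
    "alias_alleles",
    "load_default_aliases",
    "fisher_exact_2x2",
    "fisher_freeman_halton",
]

FreqTable = Mapping[str, Mapping[str, float]]  # locus -> allele -> frequency


@dataclass
class PopulationFrequencies:
    name: str
    freqs: dict[str, dict[str, float]]
    sample_size_2n: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, table in self.freqs.items():
            if any(f < 0 for f in table.values()):
                raise ValueError(f"{self.name}/{locus}: negative frequency")
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}/{locus}: frequencies sum to {total}, not 1"
                )

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)


@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match names")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("distance matrix has negative entries")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])


# ---------------------------------------------------------------------------
# Frequencies and coverage
# ---------------------------------------------------------------------------


def _complete_rows(table: pd.DataFrame) -> pd.DataFrame:
    ok = table["allele_1"].notna() & table["allele_2"].notna()
    ok &= (table["allele_1"].astype(str).str.len() > 0)
    ok &= (table["allele_2"].astype(str).str.len() > 0)
    dropped = table[~ok]
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} half-missing genotype row(s): "
            + ", ".join(f"{r.sample_id}/{r.locus}" for r in dropped.itertuples()),
            stacklevel=3,
        )
    return table[ok]


def allele_frequencies(
    genotype_table: pd.DataFrame, name: str = "population"
) -> PopulationFrequencies:
    """Direct-counting allele frequencies from a sample x locus genotype table.

    Expects columns ``sample_id, locus, allele_1, allele_2``; each complete row
    contributes two allele copies.
    """
    if len(genotype_table) == 0:
        raise ValueError("empty genotype table")
    table = _complete_rows(genotype_table)
    if len(table) == 0:
        raise ValueError("no complete genotype rows")
    freqs: dict[str, dict[str, float]] = {}
    two_n: dict[str, int] = {}
    for locus, grp in table.groupby("locus", sort=True):
        copies = pd.concat([grp["allele_1"], grp["allele_2"]])
        counts = copies.value_counts().sort_index()
        two_n[locus] = int(len(copies))
        freqs[locus] = {a: c / len(copies) for a, c in counts.items()}
    return PopulationFrequencies(name, freqs, two_n)


def carrier_frequencies(genotype_table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Fraction of samples carrying >=1 copy of each allele, per locus."""
    table = _complete_rows(genotype_table)
    out: dict[str, dict[str, float]] = {}
    for locus, grp in table.groupby("locus", sort=True):
        n = len(grp)
        carriers: dict[str, int] = {}
        for a1, a2 in zip(grp["allele_1"], grp["allele_2"]):
            for a in {a1, a2}:
                carriers[a] = carriers.get(a, 0) + 1
        out[locus] = {a: c / n for a, c in sorted(carriers.items())}
    return out


def coverage(freqs: Mapping[str, float], addressed: Iterable[str]) -> float:
    """Summed frequency of the addressed alleles (absent alleles contribute 0)."""
    return float(sum(freqs.get(a, 0.0) for a in addressed))


def cumulative_coverage_curve(freqs: Mapping[str, float]) -> list[tuple[str, float]]:
    """Alleles in descending-frequency order (ties lexicographic) with running sums."""
    ordered = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    running = 0.0
    for allele, f in ordered:
        running += f
        out.append((allele, running))
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------


@dataclass
class HweResult:
    p_value: float
    n_samples: int
    n_alleles: int
    n_permutations: int


def _genotype_log_prob(counts: Mapping[tuple[str, str], int]) -> float:
    # conditional probability of the genotype table given its allele counts
    # under random union of gametes (used as the test's ordering statistic)
    n = sum(counts.values())
    allele_counts: dict[str, int] = {}
    het = 0
    for (a, b), c in counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
        if a != b:
            het += c
    logp = math.lgamma(n + 1) - math.lgamma(2 * n + 1) + het * math.log(2)
    logp += sum(math.lgamma(c + 1) for c in allele_counts.values())
    logp -= sum(math.lgamma(c + 1) for c in counts.values())
    return logp


def hwe_test(
    genotype_counts: Mapping[tuple[str, str], int],
    n_permutations: int = 10000,
    seed: int | None = None,
) -> HweResult:
    """Monte-Carlo exact Hardy-Weinberg test.

    The 2n allele copies are repeatedly shuffled and re-paired; the p-value is
    the fraction of resampled tables whose conditional probability does not
    exceed the observed table's (with the usual +1 correction).
    """
    if n_permutations < 1000:
        raise ValueError("n_permutations must be >= 1000")
    counts = { (min(a, b), max(a, b)): int(c)
               for (a, b), c in genotype_counts.items() if c }
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty genotype counts")
    copies: list[str] = []
    for (a, b), c in counts.items():
        copies.extend([a] * c)
        copies.extend([b] * c)
    alleles = sorted(set(copies))
    if len(alleles) < 2:
        return HweResult(1.0, n, len(alleles), 0)
    obs = _genotype_log_prob(counts)
    rng = np.random.default_rng(seed)
    pool = np.array(copies)
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(pool)
        sim: dict[tuple[str, str], int] = {}
        for i in range(0, 2 * n, 2):
            a, b = pool[i], pool[i + 1]
            g = (a, b) if a <= b else (b, a)
            sim[g] = sim.get(g, 0) + 1
        if _genotype_log_prob(sim) <= obs + 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return HweResult(min(p, 1.0), n, len(alleles), n_permutations)


# ---------------------------------------------------------------------------
# Genetic distance, trees, ordination
# ---------------------------------------------------------------------------


def _freq_tables(pop: PopulationFrequencies | FreqTable) -> FreqTable:
    return pop.freqs if isinstance(pop, PopulationFrequencies) else pop


def cavalli_sforza_distance(
    freqs_1: PopulationFrequencies | FreqTable,
    freqs_2: PopulationFrequencies | FreqTable,
    loci: Sequence[str] | None = None,
) -> float:
    """Chord distance D between two populations over shared loci.

    D^2 = 4 * sum_l (1 - sum_a sqrt(p1a * p2a)) / sum_l (a_l - 1), where a_l
    counts alleles present in either population at locus l.
    """
    t1, t2 = _freq_tables(freqs_1), _freq_tables(freqs_2)
    shared = [l for l in (loci if loci is not None else t1) if l in t1 and l in t2]
    if not shared:
        raise ValueError("populations share no loci")
    num = 0.0
    denom = 0
    for locus in shared:
        p1, p2 = t1[locus], t2[locus]
        union = {a for a, f in p1.items() if f > 0} | {a for a, f in p2.items() if f > 0}
        overlap = sum(math.sqrt(p1.get(a, 0.0) * p2.get(a, 0.0)) for a in union)
        num += 4.0 * (1.0 - min(overlap, 1.0))
        denom += max(len(union) - 1, 0)
    if denom == 0:
        return 0.0
    return math.sqrt(max(num / denom, 0.0))


def distance_matrix(
    populations: Sequence[PopulationFrequencies],
    loci: Sequence[str] | None = None,
) -> DistanceMatrix:
    names = [p.name for p in populations]
    n = len(populations)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = cavalli_sforza_distance(populations[i], populations[j], loci)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(names, values)


def _fmt_len(x: float) -> str:
    return f"{x:.6g}"


def nj_tree(dist: DistanceMatrix) -> str:
    """Neighbor-joining dendrogram as an unrooted Newick string.

    Ties in the Q criterion break on the smallest (i, j) pair index; negative
    branch lengths are clamped to zero with a warning.
    """
    names = list(dist.names)
    if len(names) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dist.values.astype(float).copy()
    labels = [str(x) for x in names]  # grows into newick sub-strings

    def clamp(x: float, context: str) -> float:
        if x < 0:
            warnings.warn(f"negative branch length {x:.6g} at {context}; clamped to 0",
                          stacklevel=3)
            return 0.0
        return x

    while len(labels) > 3:
        n = len(labels)
        totals = d.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - totals[i] - totals[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        vi = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (n - 2))
        vj = d[i, j] - vi
        vi = clamp(vi, labels[i])
        vj = clamp(vj, labels[j])
        new_label = f"({labels[i]}:{_fmt_len(vi)},{labels[j]}:{_fmt_len(vj)})"
        new_row = np.array([
            0.5 * (d[i, k] + d[j, k] - d[i, j])
            for k in range(n) if k not in (i, j)
        ])
        keep = [k for k in range(n) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        labels = [labels[k] for k in keep]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        labels.append(new_label)

    va = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]), labels[0])
    vb = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]), labels[1])
    vc = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]), labels[2])
    return (
        f"({labels[0]}:{_fmt_len(va)},{labels[1]}:{_fmt_len(vb)},"
        f"{labels[2]}:{_fmt_len(vc)});"
    )


@dataclass
class PcoaResult:
    names: list[str]
    coordinates: np.ndarray  # (n_points, n_axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending (incl. negatives)
    variance_fractions: np.ndarray  # per retained axis, of positive-eigenvalue mass


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, scales eigenvectors by the square
    roots of positive eigenvalues, and fixes each axis's sign so its
    largest-magnitude loading is positive.  Negative eigenvalues are reported
    but yield no coordinates.
    """
    d2 = dist.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-9 if len(evals) else 0.0
    positive = evals > tol
    k = int(positive.sum())
    if n_axes is not None:
        k = min(k, n_axes)
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for axis in range(k):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    pos_sum = evals[positive].sum()
    fractions = evals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return PcoaResult(list(dist.names), coords, evals, fractions)


# ---------------------------------------------------------------------------
# Allele aliasing
# ---------------------------------------------------------------------------


def load_default_aliases() -> dict[str, str]:
    """Packaged allele alias map (synonymy + not-distinguished group labels)."""
    path = Path(str(resources.files("hlassp").joinpath("data", "allele_aliases.tsv")))
    out: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        src, dst = line.split("\t")
        out[src] = dst
    return out


def _resolve_alias(allele: str, alias_map: Mapping[str, str]) -> str:
    seen = {allele}
    cur = allele
    while cur in alias_map:
        cur = alias_map[cur]
        if cur in seen:
            raise ValueError(f"alias cycle involving {allele!r}")
        seen.add(cur)
    return cur


def alias_alleles(
    freqs: PopulationFrequencies, alias_map: Mapping[str, str]
) -> PopulationFrequencies:
    """Merge aliased alleles into their group labels; total mass is conserved."""
    merged: dict[str, dict[str, float]] = {}
    for locus, table in freqs.freqs.items():
        out: dict[str, float] = {}
        for allele, f in table.items():
            target = _resolve_alias(allele, alias_map)
            out[target] = out.get(target, 0.0) + f
        merged[locus] = dict(sorted(out.items()))
    return PopulationFrequencies(freqs.name, merged, dict(freqs.sample_size_2n))


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities <= observed's."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    n = t.sum()
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    rv = hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(t[0, 0])
    return float(min(pmf[pmf <= p_obs * (1 + 1e-9)].sum(), 1.0))


def _table_log_prob(t: np.ndarray) -> float:
    # generalized hypergeometric probability of an r x c table given margins
    logp = sum(math.lgamma(x + 1) for x in t.sum(axis=1))
    logp += sum(math.lgamma(x + 1) for x in t.sum(axis=0))
    logp -= math.lgamma(t.sum() + 1)
    logp -= sum(math.lgamma(x + 1) for x in t.ravel())
    return logp


def fisher_freeman_halton(
    table: Sequence[Sequence[int]],
    n_permutations: int = 10000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo Freeman-Halton test for r x c tables (exact for 2x2)."""
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    if t.shape == (2, 2):
        return fisher_exact_2x2(t)
    rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
    cols = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))
    if len(rows) == 0:
        return 1.0
    obs = _table_log_prob(t)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(cols)
        sim = np.zeros_like(t)
        np.add.at(sim, (rows, cols), 1)
        if _table_log_prob(sim) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
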