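"""Gene-set overlap inference for multi-protein target comparisons.

Target gene lists from different experiments (and species) are harmonised
to uppercase symbols, restricted to a finite common background, partitioned
into the seven exclusive regions of a three-set Venn diagram, and tested
two ways:

* pairwise enrichment by the one-sided Fisher exact test, i.e. the upper
  tail of the hypergeometric distribution
  ``P(X >= k) = sum_j C(K,j) C(N-K, n-j) / C(N,n)``, computed in log space
  so p-values down to ~1e-300 are representable;
* a Monte-Carlo permutation null for the exclusive Venn regions: three sets
  of the observed sizes drawn independently and uniformly without
  replacement from the background, region counts recorded per replicate,
  and empirical one-tailed p-values reported as ``r / n_perm`` where ``r``
  counts replicates whose region count exceeds the observed count (a
  reported p of 0 therefore means "a larger overlap was never drawn";
  counting ties as extreme is available via a flag).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

REGION_KEYS = ("a_only", "b_only", "c_only", "ab_only", "ac_only", "bc_only", "abc")
TESTED_REGIONS = ("ab_only", "ac_only", "bc_only", "abc")


# ---------------------------------------------------------------------------
# gene universes and sets
# ---------------------------------------------------------------------------

class GeneUniverse:
    """A finite background of unique uppercase gene symbols.

    Symbols whose uppercase forms collide in the raw input (e.g. ``Abc``
    and ``ABC``) are recorded in ``collisions`` so that background
    construction can exclude many-to-one symbol relationships.
    """

    def __init__(self, symbols: Iterable[str]):
        raw = [s.strip() for s in symbols if s and s.strip()]
        folded = [s.upper() for s in raw]
        counts = Counter(folded)
        self.collisions: frozenset[str] = frozenset(
            s for s, c in counts.items() if c > 1
        )
        self.symbols: frozenset[str] = frozenset(folded)

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return self.size

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    @classmethod
    def from_file(cls, path: str) -> "GeneUniverse":
        with open(path) as fh:
            return cls(line.split("\t")[0] for line in fh if not line.startswith("#"))


@dataclass
class GeneSet:
    """A labelled set of uppercase gene symbols."""

    label: str
    symbols: frozenset[str] = frozenset()

    def __init__(self, label: str, symbols: Iterable[str] = ()):  # fold on entry
        self.label = label
        self.symbols = frozenset(
            s.strip().upper() for s in symbols if s and s.strip()
        )

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def from_file(cls, path: str, label: Optional[str] = None) -> "GeneSet":
        with open(path) as fh:
            symbols = [line.split("\t")[0] for line in fh if not line.startswith("#")]
        return cls(label or str(path), symbols)


def build_common_background(
    universe_a: Iterable[str] | GeneUniverse, universe_b: Iterable[str] | GeneUniverse
) -> GeneUniverse:
    """Intersect two symbol universes after uppercasing.

    Cross-species symbol comparison matches symbols case-insensitively (the
    conventions differ mainly in capitalisation).  Symbols that appear more
    than once within either universe after folding are excluded — they
    represent many-to-one relationships that cannot be assessed.
    """
    ua = universe_a if isinstance(universe_a, GeneUniverse) else GeneUniverse(universe_a)
    ub = universe_b if isinstance(universe_b, GeneUniverse) else GeneUniverse(universe_b)
    shared = (ua.symbols & ub.symbols) - ua.collisions - ub.collisions
    return GeneUniverse(shared)


def restrict_to_background(gene_set: GeneSet, universe: GeneUniverse) -> GeneSet:
    """Drop symbols not present in the background universe."""
    return GeneSet(gene_set.label, gene_set.symbols & universe.symbols)


# ---------------------------------------------------------------------------
# identifier resolution
# ---------------------------------------------------------------------------

class IdMappingTable:
    """Mapping between Ensembl IDs, Entrez IDs, symbols and RefSeq IDs.

    Backed by a DataFrame with columns ``ensembl``, ``entrez``, ``symbol``,
    ``refseq`` and ``gene_type`` (``mRNA`` / ``miRNA`` / ``other``); one
    row per (key, Entrez) relation, so multi-valued matches are preserved.
    """

    COLUMNS = ("ensembl", "entrez", "symbol", "refseq", "gene_type")

    def __init__(self, frame: pd.DataFrame):
        if frame.empty:
            raise ValueError("empty ID-mapping table")
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"mapping table missing columns: {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)
        self._by_ensembl = self._index("ensembl")
        self._by_symbol = self._index("symbol")
        self._by_refseq = self._index("refseq")
        counts = self.frame.groupby("entrez")["ensembl"].nunique()
        self._ensembls_per_entrez = counts.to_dict()

    @classmethod
    def from_tsv(cls, path: str) -> "IdMappingTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str).fillna(""))

    def _index(self, column: str) -> dict[str, list[int]]:
        index: dict[str, list[int]] = {}
        for i, key in enumerate(self.frame[column]):
            if key:
                index.setdefault(str(key), []).append(i)
        return index

    def candidates(self, column: str, key: str) -> pd.DataFrame:
        index = {"ensembl": self._by_ensembl, "symbol": self._by_symbol,
                 "refseq": self._by_refseq}[column]
        rows = index.get(str(key), [])
        return self.frame.iloc[rows]


def resolve_ids(
    records: Sequence[Mapping[str, str]] | pd.DataFrame,
    table: IdMappingTable,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Resolve gene records to unique Entrez IDs with audited precedence.

    Per record: (1) a one-to-one Ensembl<->Entrez match wins; (2) else a
    unique match via the gene symbol; (3) else a unique match via the
    RefSeq ID; (4) else, among multiple Entrez candidates for the Ensembl
    ID, candidates typed ``miRNA`` are discarded and the record resolves if
    exactly one ``mRNA``-typed candidate remains; (5) otherwise the record
    is dropped.  Records explicitly assigned to two different genes are
    removed, and the output is deduplicated on Entrez ID.  The audit dict
    counts resolutions at each step.
    """
    if isinstance(records, pd.DataFrame):
        records = records.fillna("").to_dict("records")
    audit = {
        "ensembl_1to1": 0,
        "symbol_unique": 0,
        "refseq_unique": 0,
        "mrna_filter": 0,
        "unresolved": 0,
        "duplicate_entrez_dropped": 0,
    }
    resolved: list[dict] = []
    for rec in records:
        entrez, step = _resolve_one(rec, table)
        if entrez is None:
            audit["unresolved"] += 1
        else:
            audit[step] += 1
            resolved.append({**rec, "entrez": entrez, "resolved_by": step})
    frame = pd.DataFrame(resolved, columns=list(resolved[0]) if resolved else
                         ["entrez", "resolved_by"])
    if not frame.empty:
        before = len(frame)
        frame = frame.drop_duplicates(subset="entrez", keep="first").reset_index(drop=True)
        audit["duplicate_entrez_dropped"] = before - len(frame)
    return frame, audit


def _resolve_one(rec: Mapping[str, str], table: IdMappingTable):
    ensembl = str(rec.get("ensembl", "") or "")
    symbol = str(rec.get("symbol", "") or "")
    refseq = str(rec.get("refseq", "") or "")

    ens_hits = table.candidates("ensembl", ensembl) if ensembl else None
    if ens_hits is not None and len(ens_hits):
        entrez_ids = sorted(set(ens_hits["entrez"]))
        if len(entrez_ids) == 1 and table._ensembls_per_entrez.get(entrez_ids[0], 0) == 1:
            return entrez_ids[0], "ensembl_1to1"

    for column, key, step in (("symbol", symbol, "symbol_unique"),
                              ("refseq", refseq, "refseq_unique")):
        if not key:
            continue
        hits = table.candidates(column, key)
        entrez_ids = sorted(set(hits["entrez"]))
        if len(entrez_ids) == 1:
            return entrez_ids[0], step

    if ens_hits is not None and len(ens_hits):
        mrna = ens_hits[ens_hits["gene_type"] == "mRNA"]
        mrna_ids = sorted(set(mrna["entrez"]))
        if len(mrna_ids) == 1:
            return mrna_ids[0], "mrna_filter"
    return None, None


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VennPartition:
    """Counts of the seven exclusive regions of three sets.

    ``ab_only`` counts members of A and B but not C, etc.; ``abc`` counts
    the triple intersection.  Pairwise totals (``ab = ab_only + abc`` and
    cyclic variants) are derived properties.
    """

    a_only: int
    b_only: int
    c_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int
    members: Optional[dict[str, frozenset[str]]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for key in REGION_KEYS:
            if getattr(self, key) < 0:
                raise ValueError(f"negative Venn region count for {key}")

    @property
    def ab(self) -> int:
        return self.ab_only + self.abc

    @property
    def ac(self) -> int:
        return self.ac_only + self.abc

    @property
    def bc(self) -> int:
        return self.bc_only + self.abc

    @property
    def size_a(self) -> int:
        return self.a_only + self.ab_only + self.ac_only + self.abc

    @property
    def size_b(self) -> int:
        return self.b_only + self.ab_only + self.bc_only + self.abc

    @property
    def size_c(self) -> int:
        return self.c_only + self.ac_only + self.bc_only + self.abc

    @property
    def union_size(self) -> int:
        return sum(getattr(self, key) for key in REGION_KEYS)

    def region_counts(self) -> dict[str, int]:
        return {key: getattr(self, key) for key in REGION_KEYS}


def venn_partition(a: GeneSet, b: GeneSet, c: GeneSet) -> VennPartition:
    """Exact counts (and memberships) of the seven exclusive Venn regions."""
    sa, sb, sc = a.symbols, b.symbols, c.symbols
    members = {
        "a_only": frozenset(sa - sb - sc),
        "b_only": frozenset(sb - sa - sc),
        "c_only": frozenset(sc - sa - sb),
        "ab_only": frozenset((sa & sb) - sc),
        "ac_only": frozenset((sa & sc) - sb),
        "bc_only": frozenset((sb & sc) - sa),
        "abc": frozenset(sa & sb & sc),
    }
    part = VennPartition(
        **{key: len(val) for key, val in members.items()}, members=members
    )
    assert part.ab == len(sa & sb) and part.ac == len(sa & sc) and part.bc == len(sb & sc)
    assert part.union_size == len(sa | sb | sc)
    return part


# ---------------------------------------------------------------------------
# Fisher exact (hypergeometric upper tail)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapTestResult:
    """One-sided Fisher enrichment test for the overlap of two gene sets."""

    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    p_value: float
    log10_p: float
    expected: float


def _log_hypergeom_pmf(N: int, K: int, n: int, j: np.ndarray) -> np.ndarray:
    # log [ C(K,j) C(N-K, n-j) / C(N,n) ] via log-gamma
    j = np.asarray(j, dtype=float)
    return (
        _log_comb(K, j)
        + _log_comb(N - K, n - j)
        - _log_comb(N, np.asarray(float(n)))
    )


def _log_comb(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_overlap(N: int, K: int, n: int, k: int) -> OverlapTestResult:
    """Upper-tail hypergeometric probability of an overlap >= ``k``.

    ``N`` is the background size, ``K`` and ``n`` the two set sizes, ``k``
    the observed overlap.  Equivalent to the one-sided Fisher exact test
    for enrichment.  The tail sum runs in log space so that extreme
    significance (down to ~1e-300) is representable; the analytic expected
    overlap ``K * n / N`` is reported alongside.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"set sizes must satisfy 0 <= K, n <= N (K={K}, n={n}, N={N})")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K, n)={min(K, n)}]")
    lo = max(k, max(0, K + n - N))
    hi = min(K, n)
    if k <= max(0, K + n - N):
        log_p = 0.0  # tail from the minimal achievable overlap covers everything
    else:
        j = np.arange(lo, hi + 1)
        log_p = float(logsumexp(_log_hypergeom_pmf(N, K, n, j)))
        log_p = min(log_p, 0.0)  # guard against rounding slightly above 1
    expected = K * n / N if N else 0.0
    return OverlapTestResult(
        universe_size=N,
        size_a=K,
        size_b=n,
        overlap=k,
        p_value=float(np.exp(log_p)),
        log10_p=log_p / np.log(10.0),
        expected=expected,
    )


# ---------------------------------------------------------------------------
# permutation null for the Venn regions
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Monte-Carlo null for the exclusive Venn regions.

    ``null_exceed_counts[region]`` is the number of replicates ``r`` whose
    region count was more extreme than the observed count (strictly
    greater by default, >= with ``include_ties``); ``empirical_p`` is
    exactly ``r / n_perm`` (or ``(r+1)/(n_perm+1)`` under the add-one
    convention).  Reporting ``r`` and ``n_perm`` alongside p keeps
    "p = 0" unambiguous.
    """

    n_perm: int
    seed: int
    generator: str
    observed: VennPartition
    null_exceed_counts: dict[str, int]
    empirical_p: dict[str, float]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    add_one: bool = False
    include_ties: bool = False


def permutation_overlap(
    N: int,
    sizes: tuple[int, int, int],
    observed: VennPartition,
    n_perm: int = 50_000,
    seed: int = 0,
    add_one: bool = False,
    include_ties: bool = False,
) -> PermutationResult:
    """Permutation null for three-set Venn region counts.

    Each replicate draws three sets of the given sizes independently and
    uniformly without replacement from an ``N``-element universe and counts
    the four tested exclusive regions (AB-only, AC-only, BC-only, ABC).
    The empirical one-tailed p-value per region is ``r / n_perm`` where
    ``r`` counts replicates whose region count strictly exceeds the
    observed count, so p = 0 states that a larger overlap was never drawn;
    ``include_ties`` switches to the at-least-as-extreme (>=) convention.
    Identical seeds reproduce identical results (NumPy PCG64).
    """
    ka, kb, kc = sizes
    for size in sizes:
        if not 0 <= size <= N:
            raise ValueError(f"set size {size} outside [0, N={N}]")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty((n_perm, 4), dtype=np.int64)
    # By exchangeability of the universe, fix A = {0..ka-1} and randomise
    # only B and C; the joint law of the overlap counts is unchanged.
    for rep in range(n_perm):
        mask_b = np.zeros(N, dtype=bool)
        mask_b[rng.choice(N, kb, replace=False)] = True
        idx_c = rng.choice(N, kc, replace=False)
        ab = int(mask_b[:ka].sum())
        in_a_c = idx_c < ka
        in_b_c = mask_b[idx_c]
        abc = int((in_a_c & in_b_c).sum())
        ac = int(in_a_c.sum())
        bc = int(in_b_c.sum())
        counts[rep] = (ab - abc, ac - abc, bc - abc, abc)

    observed_counts = np.array([getattr(observed, key) for key in TESTED_REGIONS])
    if include_ties:
        exceed = (counts >= observed_counts).sum(axis=0)
    else:
        exceed = (counts > observed_counts).sum(axis=0)
    if add_one:
        pvals = (exceed + 1) / (n_perm + 1)
    else:
        pvals = exceed / n_perm
    return PermutationResult(
        n_perm=n_perm,
        seed=seed,
        generator="numpy.random.Generator(PCG64)",
        observed=observed,
        null_exceed_counts={k: int(r) for k, r in zip(TESTED_REGIONS, exceed)},
        empirical_p={k: float(p) for k, p in zip(TESTED_REGIONS, pvals)},
        null_mean={k: float(m) for k, m in zip(TESTED_REGIONS, counts.mean(axis=0))},
        null_sd={k: float(s) for k, s in zip(TESTED_REGIONS, counts.std(axis=0, ddof=1))},
        add_one=add_one,
        include_ties=include_ties,
    )


def expected_overlaps(N: int, sizes: tuple[int, int, int]) -> dict[str, float]:
    """Analytic expectations of the Venn overlaps under independent draws.

    ``E[|A∩B|] = K_a K_b / N``, ``E[|A∩B∩C|] = K_a K_b K_c / N^2``, and the
    exclusive-region expectations follow by subtraction.  Used to
    sanity-check permutation null means.
    """
    ka, kb, kc = sizes
    for size in sizes:
        if size > N:
            raise ValueError(f"set size {size} exceeds N={N}")
    if N == 0:
        return {key: 0.0 for key in ("ab", "ac", "bc", "abc",
                                     "ab_only", "ac_only", "bc_only")}
    ab = ka * kb / N
    ac = ka * kc / N
    bc = kb * kc / N
    abc = ka * kb * kc / N**2
    return {
        "ab": ab, "ac": ac, "bc": bc, "abc": abc,
        "ab_only": ab - abc, "ac_only": ac - abc, "bc_only": bc - abc,
    }
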