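"""Single-cell VH somatic-hypermutation analysis.

Calls mutations in single-cell VH amplicon sequences against the parental
reference by deterministic global alignment, deduplicates sequences by exact
mutation-spectrum equality, builds mutant genealogies by subset order on
mutation sets, tabulates substitution spectra and per-sequence mutation-load
distributions with a chi-square comparison against a reference population,
and estimates surface-IgM loss frequencies from staining intensities.

Coordinates are 1-based on the reference, numbered from the first base of
the first codon.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Mutation",
    "MutationSet",
    "SpectrumMatrix",
    "LoadDistribution",
    "Genealogy",
    "align_and_call",
    "call_mutations",
    "dedupe_spectra",
    "build_genealogy",
    "spectrum_matrix",
    "load_distribution",
    "chi2_vs_reference",
    "sigm_loss_frequency",
    "FailedAmpliconError",
]

BASES = "ACGT"


class FailedAmpliconError(ValueError):
    """Read too short (or otherwise unusable) to be a valid VH amplicon."""


@dataclass(frozen=True, order=True)
class Mutation:
    """One called mutation in reference coordinates.

    ``kind`` is ``substitution``, ``deletion`` or ``insertion``.  For a
    substitution ``ref`` and ``alt`` are single differing bases; a deletion
    has empty ``alt``; an insertion has empty ``ref`` and ``position`` is the
    reference base after which the bases are inserted.
    """

    kind: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion", "insertion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based reference coordinate)")
        if self.kind == "substitution" and (
            len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt
        ):
            raise ValueError("substitution must have single differing ref/alt bases")
        if self.kind == "deletion" and (not self.ref or self.alt):
            raise ValueError("deletion must have non-empty ref and empty alt")
        if self.kind == "insertion" and (self.ref or not self.alt):
            raise ValueError("insertion must have empty ref and non-empty alt")


@dataclass(frozen=True)
class MutationSet:
    """The mutations called in one cell's VH amplicon.

    Two sequences have the *same spectrum* iff their mutation sets are equal;
    set equality ignores ``cell_id``.
    """

    cell_id: str
    mutations: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.mutations)

    def key(self) -> tuple:
        """Canonical sortable serialization of the mutation set."""
        return tuple(sorted(self.mutations))

    def same_spectrum(self, other: "MutationSet") -> bool:
        return self.mutations == other.mutations


def _make_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _check_dna(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    return seq


def align_and_call(read: str, reference: str, cell_id: str = "") -> MutationSet:
    """Globally align a read to the reference and read off its mutations.

    Scoring: match +1, mismatch -1, linear gap -2.  Among co-optimal
    alignments the aligner's deterministic enumeration order decides, so
    identical inputs always give identical calls.  A read shorter than half
    the reference raises :class:`FailedAmpliconError`.
    """
    read = _check_dna(read, "read")
    reference = _check_dna(reference, "reference")
    if len(read) < 0.5 * len(reference):
        raise FailedAmpliconError(
            f"read length {len(read)} is under 50% of the reference ({len(reference)})"
        )
    if read == reference:
        return MutationSet(cell_id)
    aln = _make_aligner().align(reference, read)[0]
    muts = set()
    ref_aln, read_aln = aln[0], aln[1]
    ref_pos = 0  # 1-based position of the last consumed reference base
    pending_ins: list[str] = []
    ins_anchor = 0
    for rb, qb in zip(ref_aln, read_aln):
        if rb != "-" and pending_ins:
            muts.add(Mutation("insertion", max(ins_anchor, 1), "", "".join(pending_ins)))
            pending_ins = []
        if rb == "-":
            if not pending_ins:
                ins_anchor = ref_pos
            pending_ins.append(qb)
            continue
        ref_pos += 1
        if qb == "-":
            muts.add(Mutation("deletion", ref_pos, rb, ""))
        elif qb != rb:
            muts.add(Mutation("substitution", ref_pos, rb, qb))
    if pending_ins:
        muts.add(Mutation("insertion", max(ins_anchor, 1), "", "".join(pending_ins)))
    # merge runs of adjacent single-base deletions into one deletion event
    muts = _merge_adjacent_deletions(muts)
    return MutationSet(cell_id, frozenset(muts))


def _merge_adjacent_deletions(muts: set) -> set:
    dels = sorted(m for m in muts if m.kind == "deletion")
    merged, run = [], []
    for d in dels:
        if run and d.position == run[0].position + sum(len(x.ref) for x in run):
            run.append(d)
        else:
            if run:
                merged.append(run)
            run = [d]
    if run:
        merged.append(run)
    out = {m for m in muts if m.kind != "deletion"}
    for run in merged:
        out.add(Mutation("deletion", run[0].position, "".join(d.ref for d in run), ""))
    return out


def call_mutations(reads: dict, reference: str) -> tuple[list, int]:
    """Call mutation sets for many reads; skip failed amplicons with a log.

    ``reads`` maps cell id to sequence.  Returns (list of MutationSet,
    number of failed amplicons).
    """
    out, n_failed = [], 0
    for cell_id, seq in reads.items():
        try:
            out.append(align_and_call(seq, reference, cell_id=cell_id))
        except FailedAmpliconError as exc:
            n_failed += 1
            logger.warning("failed amplicon %s: %s", cell_id, exc)
    return out, n_failed


def dedupe_spectra(sets: list) -> list:
    """Group sequences with identical mutation spectra.

    Returns ``[(representative MutationSet, multiplicity), ...]`` with one
    representative (the first seen) per distinct spectrum, ordered canonically
    by (set size, serialized set) so the output is independent of input order.
    """
    groups: dict = {}
    for ms in sets:
        groups.setdefault(ms.mutations, []).append(ms)
    items = [(members[0], len(members)) for members in groups.values()]
    items.sort(key=lambda item: (len(item[0]), item[0].key()))
    return items


@dataclass
class Genealogy:
    """Forest of mutant lineages rooted at the germline (empty) set.

    ``parent`` maps each node's serialized mutation set to its parent's
    (``()`` is the germline root); ``ambiguous`` flags nodes whose parent was
    chosen among several equal-cardinality subset candidates.
    """

    nodes: list
    parent: dict
    ambiguous: set

    def edges(self) -> list:
        return sorted((p, c) for c, p in self.parent.items())

    def children(self, key: tuple) -> list:
        return sorted(c for c, p in self.parent.items() if p == key)

    def to_newick(self) -> str:
        label = lambda k: "germline" if k == () else "+".join(
            f"{m.ref or '-'}{m.position}{m.alt or '-'}" for m in k
        )

        def rec(k: tuple) -> str:
            kids = self.children(k)
            if not kids:
                return label(k)
            return "(" + ",".join(rec(c) for c in kids) + ")" + label(k)

        return rec(()) + ";"


def build_genealogy(unique_sets: list) -> Genealogy:
    """Arrange distinct mutation sets into lineages by subset order.

    Each set's parent is a maximal-cardinality observed proper subset of it,
    or the germline root when none is observed.  Among equal-cardinality
    candidates the one with the lexicographically smallest serialization is
    chosen and the node is flagged ambiguous.  Input may be the output of
    :func:`dedupe_spectra` or a plain list of MutationSets (must be distinct).
    """
    sets = [item[0] if isinstance(item, tuple) else item for item in unique_sets]
    keys = [ms.key() for ms in sets]
    if len(set(keys)) != len(keys):
        raise ValueError("build_genealogy requires deduplicated (distinct) mutation sets")
    by_key = dict(zip(keys, sets))
    parent: dict = {}
    ambiguous: set = set()
    for key, ms in by_key.items():
        if key == ():
            continue
        candidates = [
            k for k, other in by_key.items() if other.mutations < ms.mutations
        ]
        if not candidates:
            parent[key] = ()
            continue
        max_card = max(len(k) for k in candidates)
        best = sorted(k for k in candidates if len(k) == max_card)
        parent[key] = best[0]
        if len(best) > 1:
            ambiguous.add(key)
    return Genealogy(nodes=sorted(by_key), parent=parent, ambiguous=ambiguous)


@dataclass(frozen=True)
class SpectrumMatrix:
    """Counts and percentages of the 12 substitution classes.

    Percentages are of all point mutations; indels are tallied separately and
    excluded from the denominators.  ``marginal_percent`` gives the fraction
    of all point mutations occurring at each reference base.
    """

    counts: dict
    n_point: int
    n_deletions: int
    n_insertions: int

    @property
    def percent(self) -> dict:
        if self.n_point == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.n_point for k, v in self.counts.items()}

    @property
    def marginal_percent(self) -> dict:
        out = {b: 0.0 for b in BASES}
        for (ref, _alt), pct in self.percent.items():
            out[ref] += pct
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ref": r, "alt": a, "count": self.counts[(r, a)], "percent": self.percent[(r, a)]}
            for r in BASES
            for a in BASES
            if r != a
        ]
        return pd.DataFrame(rows)


def spectrum_matrix(sets: list) -> SpectrumMatrix:
    """Tabulate the substitution spectrum of a collection of mutation sets."""
    counts = Counter()
    n_del = n_ins = 0
    for ms in sets:
        for m in ms.mutations:
            if m.kind == "substitution":
                counts[(m.ref, m.alt)] += 1
            elif m.kind == "deletion":
                n_del += 1
            else:
                n_ins += 1
    full = {(r, a): counts.get((r, a), 0) for r in BASES for a in BASES if r != a}
    n_point = sum(full.values())
    if n_point == 0:
        logger.warning("no point mutations: spectrum matrix is empty")
    return SpectrumMatrix(counts=full, n_point=n_point, n_deletions=n_del, n_insertions=n_ins)


@dataclass(frozen=True)
class LoadDistribution:
    """Counts of sequences carrying 0, 1, 2, 3, 4 or >=5 mutations."""

    counts: dict
    n_sequences: int

    @property
    def proportions(self) -> dict:
        return {k: v / self.n_sequences for k, v in self.counts.items()}


def load_distribution(sets: list, top_bin: int = 5) -> LoadDistribution:
    """Bin per-sequence mutation counts, with an open top bin (>= top_bin)."""
    counts = {k: 0 for k in range(top_bin + 1)}
    for ms in sets:
        counts[min(len(ms), top_bin)] += 1
    return LoadDistribution(counts=counts, n_sequences=len(sets))


def chi2_vs_reference(
    observed: LoadDistribution, reference: LoadDistribution, min_expected: float = 5.0
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of an observed load distribution against the
    proportions of a reference population.

    Expected counts are the reference proportions scaled to the observed total.
    Adjacent bins are pooled from the top downward until every expected count
    reaches ``min_expected``; df = (bins after pooling) - 1.
    """
    bins = sorted(observed.counts)
    obs = np.array([observed.counts[k] for k in bins], dtype=float)
    ref_props = np.array([reference.proportions.get(k, 0.0) for k in bins])
    exp = ref_props * obs.sum()
    while len(exp) > 1 and exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp, obs = exp[:-1], obs[:-1]
    if len(exp) < 2:
        raise ValueError("reference distribution too sparse: pooling left a single bin")
    if (exp <= 0).any():
        raise ValueError("reference proportions must be strictly positive after pooling")
    chi2, p = stats.chisquare(obs, exp)
    return float(chi2), len(exp) - 1, float(p)


def sigm_loss_frequency(
    intensities,
    threshold: float | None = None,
    control=None,
    control_quantile: float = 0.005,
) -> float:
    """Percentage of cells with surface-IgM staining below a negativity gate.

    The gate is either a fixed ``threshold`` or a low quantile of a stained
    (sIgM-positive) ``control`` population.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty intensity list")
    if threshold is None:
        if control is None:
            raise ValueError("provide either a fixed threshold or a stained control")
        threshold = float(np.quantile(np.asarray(control, dtype=float), control_quantile))
    return float(100.0 * np.mean(x < threshold))
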