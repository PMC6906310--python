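"""Transitions-only sequence divergence, barcoding gap, diversity, NJ.

The assay separates elephantid species on transition differences alone
(A<->G, C<->T): over this fragment transitions carry the diagnostic
signal, and the published distance matrices were computed with the
transitions-only setting of both the p-distance and the Kimura
two-parameter (K2P) model.  With P the proportion of transition
differences and Q of transversion differences per compared site
(pairwise deletion: positions with an ambiguous base or gap in either
sequence are excluded), the transitions-only distances are

    p   = P
    K2P = -1/2 ln(1 - 2P - Q) + 1/4 ln(1 - 2Q)

which reduces to -1/2 ln(1 - 2P) when Q = 0.  Nucleotide diversity (pi)
follows the DnaSP convention instead and counts all substitution types.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .errors import (
    AlignmentError,
    GapUndefinedError,
    InsufficientDataError,
    SaturationError,
    UndefinedDistanceError,
    ValidationError,
)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_CONCRETE = frozenset("ACGT")

OVERALL = "overall"


@dataclass(frozen=True)
class PairwiseComparison:
    """Per-pair substitution counts under pairwise deletion."""

    compared_sites: int
    ts_diffs: int
    tv_diffs: int

    @property
    def P(self) -> float:
        return self.ts_diffs / self.compared_sites

    @property
    def Q(self) -> float:
        return self.tv_diffs / self.compared_sites


def compare_pair(a: str, b: str) -> PairwiseComparison:
    """Count transition and transversion differences between two aligned
    sequences, excluding positions where either base is not concrete."""
    if len(a) != len(b):
        raise AlignmentError(
            f"sequence lengths differ: {len(a)} vs {len(b)}"
        )
    compared = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _CONCRETE or y not in _CONCRETE:
            continue
        compared += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return PairwiseComparison(compared, ts, tv)


def p_distance_ts(c: PairwiseComparison) -> float:
    """Transition differences per compared site."""
    if c.compared_sites == 0:
        raise UndefinedDistanceError("no comparable sites")
    return c.P


def k2p_ts(c: PairwiseComparison) -> float:
    """Transitions-only K2P distance."""
    if c.compared_sites == 0:
        raise UndefinedDistanceError("no comparable sites")
    arg_ts = 1.0 - 2.0 * c.P - c.Q
    arg_tv = 1.0 - 2.0 * c.Q
    if arg_ts <= 0 or arg_tv <= 0:
        raise SaturationError(
            f"saturated pair (P={c.P:.4f}, Q={c.Q:.4f})"
        )
    return -0.5 * math.log(arg_ts) + 0.25 * math.log(arg_tv)

_MODELS = {"p": p_distance_ts, "k2p": k2p_ts}


def pairwise_distance(a: str, b: str, model: str = "k2p") -> float:
    return _MODELS[model](compare_pair(a, b))


def distance_matrix(seqs: list[str], labels: list[str],
                    model: str = "k2p") -> pd.DataFrame:
    """Symmetric matrix of pairwise distances with labelled axes.

    ``labels`` here are per-sequence identifiers (must be unique).
    """
    if len(labels) != len(set(labels)):
        raise ValidationError("sequence identifiers must be unique")
    n = len(seqs)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = pairwise_distance(seqs[i], seqs[j], model)
    return pd.DataFrame(m, index=labels, columns=labels)


@dataclass
class DistanceSummary:
    """Intra-/inter-class range statistics over all unordered pairs.

    ``intra`` has one row per class plus ``overall``; ``inter`` one row
    per unordered class pair (index "A|B", labels sorted) plus
    ``overall``.  Columns: n_pairs, min, max, mean, sd.  Distances are
    fractions (multiply by 100 for the conventional percentage form).
    """

    model: str
    intra: pd.DataFrame
    inter: pd.DataFrame


def _summarise(values: dict[str, list[float]]) -> pd.DataFrame:
    rows = {}
    pooled: list[float] = []
    for key in sorted(values):
        v = values[key]
        pooled.extend(v)
        rows[key] = _stats_row(v)
    rows[OVERALL] = _stats_row(pooled)
    return pd.DataFrame.from_dict(rows, orient="index")


def _stats_row(v: list[float]) -> dict[str, float]:
    if not v:
        return {"n_pairs": 0, "min": np.nan, "max": np.nan,
                "mean": np.nan, "sd": np.nan}
    arr = np.asarray(v)
    return {
        "n_pairs": len(v), "min": float(arr.min()),
        "max": float(arr.max()), "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(v) > 1 else 0.0,
    }


def distance_summary(seqs: list[str], labels: list[str],
                     model: str = "k2p") -> DistanceSummary:
    """Range statistics for within- and between-class pairs.

    ``labels`` are class labels (species/clade); a class with a single
    sequence contributes no intra pairs but is still reported with the
    degenerate 0-0 range (absence-of-variation convention, matching how
    published matrices print invariant species).
    """
    if len(seqs) != len(labels):
        raise ValidationError("seqs and labels differ in length")
    if len(seqs) < 2:
        raise InsufficientDataError("need at least two sequences")
    intra: dict[str, list[float]] = {lab: [] for lab in labels}
    inter: dict[str, list[float]] = {}
    for i, j in itertools.combinations(range(len(seqs)), 2):
        d = pairwise_distance(seqs[i], seqs[j], model)
        if labels[i] == labels[j]:
            intra[labels[i]].append(d)
        else:
            key = "|".join(sorted((labels[i], labels[j])))
            inter.setdefault(key, []).append(d)
    intra_frame = _summarise(intra)
    singletons = [lab for lab in set(labels) if labels.count(lab) == 1]
    for lab in singletons:
        intra_frame.loc[lab, ["min", "max", "mean", "sd"]] = 0.0
    return DistanceSummary(model=model, intra=intra_frame,
                           inter=_summarise(inter))


@dataclass(frozen=True)
class GapSummary:
    """Barcoding gap: separation between the distance classes.

    A negative ``gap_width`` (overlap between intra- and interspecific
    distances) is reported as-is, never clamped.
    """

    upper_intra: float
    lower_inter: float

    @property
    def gap_width(self) -> float:
        return self.lower_inter - self.upper_intra


def barcoding_gap(summary: DistanceSummary) -> GapSummary:
    """Gap between the largest intra- and smallest inter-class distance."""
    upper = summary.intra.loc[OVERALL, "max"]
    lower = summary.inter.loc[OVERALL, "min"]
    if math.isnan(upper) or math.isnan(lower):
        raise GapUndefinedError(
            "need at least one intra-class and one inter-class pair"
        )
    return GapSummary(upper_intra=float(upper), lower_inter=float(lower))


@dataclass(frozen=True)
class DiversitySummary:
    pi: float
    n_sequences: int
    n_segregating_sites: int


def nucleotide_diversity(seqs: list[str]) -> DiversitySummary:
    """Average pairwise proportion of differing sites (all substitution
    types), with pairwise deletion of non-concrete positions."""
    if len(seqs) < 2:
        raise InsufficientDataError("need at least two sequences")
    total = 0.0
    npairs = 0
    for a, b in itertools.combinations(seqs, 2):
        c = compare_pair(a, b)
        if c.compared_sites == 0:
            raise UndefinedDistanceError("no comparable sites in a pair")
        total += (c.ts_diffs + c.tv_diffs) / c.compared_sites
        npairs += 1
    seg = 0
    for column in zip(*(s.upper() for s in seqs)):
        states = {ch for ch in column if ch in _CONCRETE}
        if len(states) > 1:
            seg += 1
    return DiversitySummary(pi=total / npairs, n_sequences=len(seqs),
                            n_segregating_sites=seg)


# --- neighbour joining and monophyly ---------------------------------------


def nj_tree(matrix: pd.DataFrame) -> str:
    """Neighbour-joining tree (Newick) from a labelled distance matrix.

    Agglomeration is delegated to scikit-bio's NJ implementation; the
    matrix is pre-sorted by label so the output is invariant under input
    permutation.
    """
    if matrix.shape[0] < 3:
        raise ValidationError("NJ needs at least 3 taxa")
    arr = matrix.to_numpy(dtype=float)
    if np.any(np.diag(arr) != 0):
        raise ValidationError("distance matrix diagonal must be zero")
    if not np.allclose(arr, arr.T):
        raise ValidationError("distance matrix must be symmetric")
    order = sorted(matrix.index)
    matrix = matrix.loc[order, order]
    dm = skbio.DistanceMatrix(matrix.to_numpy(dtype=float),
                              ids=list(matrix.index))
    tree = skbio.tree.nj(dm)
    return str(tree).strip()


def check_monophyly(newick: str, label_map: dict[str, str]
                    ) -> dict[str, bool]:
    """Per-label monophyly on an (implicitly unrooted) tree.

    A label is monophyletic when some edge bipartition isolates exactly
    its leaves; terminal edges make singleton labels trivially
    monophyletic.
    """
    import io

    tree = skbio.TreeNode.read(io.StringIO(newick))
    leaves = {t.name for t in tree.tips()}
    missing = leaves - set(label_map)
    if missing:
        raise ValidationError(f"unlabelled leaves: {sorted(missing)}")
    splits: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) \
            if not node.is_tip() else frozenset({node.name})
        splits.add(side)
        splits.add(frozenset(leaves - side))
    result = {}
    for label in set(label_map.values()):
        members = frozenset(k for k, v in label_map.items() if v == label)
        result[label] = members in splits
    return result


def bootstrap_support(seqs: list[str], ids: list[str],
                      model: str = "k2p", replicates: int = 100,
                      seed: int | None = None) -> dict[frozenset, float]:
    """Site-resampling bootstrap support for the NJ tree's bipartitions.

    Returns support (fraction of replicates containing the split) for
    each non-trivial bipartition of the NJ tree built on the original
    alignment.  Supports are reported for inspection only; they are not
    comparable to likelihood- or Bayesian-based supports.
    """
    rng = np.random.default_rng(seed)
    ref_tree = nj_tree(distance_matrix(seqs, ids, model))
    ref_splits = _nontrivial_splits(ref_tree)
    counts = {s: 0 for s in ref_splits}
    length = len(seqs[0])
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = ["".join(s[c] for c in cols) for s in seqs]
        try:
            rep_tree = nj_tree(distance_matrix(resampled, ids, model))
        except (SaturationError, UndefinedDistanceError):
            continue
        rep_splits = _nontrivial_splits(rep_tree)
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    return {s: c / replicates for s, c in counts.items()}


def _nontrivial_splits(newick: str) -> set[frozenset[str]]:
    import io

    tree = skbio.TreeNode.read(io.StringIO(newick))
    leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            splits.add(min(side, leaves - side, key=sorted))
    return splits
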