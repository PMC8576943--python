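"""Trees over tumor regions: exact maximum parsimony and CCF ordering.

Regions are taxa; each somatic variant is a binary character (present /
absent, with the matched normal as an all-zero outgroup).  Maximum
parsimony trees are found exactly by branch-and-bound over unrooted
topologies (stepwise leaf addition; a partial tree's Fitch score is an
admissible lower bound because adding leaves never lowers it).  All
co-optimal topologies are returned in canonical (lexicographic) order.

CCF-based lineage constraints complement the presence/absence trees:
cluster X may be ancestral to Y only if its CCF dominates Y's in every
sample (within a tolerance), and X, Y may be siblings under Z only if
their CCFs sum to at most Z's everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from multiregion.errors import ValidationError
from multiregion.variants import VariantTable

OUTGROUP = "Normal"
MAX_EXACT_SAMPLES = 12

#: nested-tuple topology over sample names; the outgroup is implicit at
#: the root, so a topology is either a leaf (str) or a pair of topologies.
Topology = object


@dataclass
class BinaryMatrix:
    """Weighted unique presence patterns over samples (outgroup implicit)."""

    samples: list[str]
    patterns: dict[tuple, float]  # pattern (0/1 per sample) -> weight
    variant_patterns: dict[str, tuple] = field(default_factory=dict)

    def restricted(self, k: int) -> dict[tuple, float]:
        """Patterns projected onto the first k samples, weights merged."""
        out: dict[tuple, float] = {}
        for pat, w in self.patterns.items():
            sub = pat[:k]
            if any(sub):
                out[sub] = out.get(sub, 0.0) + w
        return out


def build_matrix(table_or_presence) -> BinaryMatrix:
    """Binary variants x samples matrix from post-recovery presence.

    Duplicate variant patterns are collapsed with multiplicity weights;
    all-zero rows are dropped; the all-zero outgroup is implicit.
    """
    if isinstance(table_or_presence, VariantTable):
        presence = table_or_presence.presence_matrix(effect_class=None)
    else:
        presence = pd.DataFrame(table_or_presence).astype(bool)
    samples = list(presence.columns)
    if len(samples) < 3:
        raise ValidationError("need >= 3 samples for an informative topology")
    patterns: dict[tuple, float] = {}
    variant_patterns: dict[str, tuple] = {}
    for vid, row in zip(presence.index, presence.to_numpy(dtype=bool)):
        pat = tuple(int(x) for x in row)
        if not any(pat):
            continue
        patterns[pat] = patterns.get(pat, 0.0) + 1.0
        variant_patterns[str(vid)] = pat
    return BinaryMatrix(samples=samples, patterns=patterns,
                        variant_patterns=variant_patterns)


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------

def _leaves(topology) -> list[str]:
    if isinstance(topology, str):
        return [topology]
    return _leaves(topology[0]) + _leaves(topology[1])


def _fitch_pattern(topology, state: Mapping[str, int]) -> int:
    """Changes for one binary character, outgroup fixed at state 0."""

    def rec(node):
        if isinstance(node, str):
            return 1 << state[node], 0
        ls, lc = rec(node[0])
        rs, rc = rec(node[1])
        inter = ls & rs
        if inter:
            return inter, lc + rc
        return ls | rs, lc + rc + 1

    root_set, changes = rec(topology)
    if not root_set & 1:  # 0 not in root set -> one change on the trunk
        changes += 1
    return changes


def fitch_score(topology, matrix: BinaryMatrix,
                patterns: dict[tuple, float] | None = None) -> float:
    """Weighted parsimony length of ``topology`` (outgroup state 0)."""
    leaves = _leaves(topology)
    if patterns is None:
        if set(leaves) != set(matrix.samples):
            raise ValidationError("topology leaves do not match matrix samples")
        patterns = matrix.patterns
        index = {s: i for i, s in enumerate(matrix.samples)}
    else:
        index = {s: i for i, s in enumerate(matrix.samples)}
    total = 0.0
    for pat, w in patterns.items():
        state = {leaf: pat[index[leaf]] for leaf in leaves}
        total += w * _fitch_pattern(topology, state)
    return total


# ---------------------------------------------------------------------------
# Branch and bound over unrooted topologies
# ---------------------------------------------------------------------------

def _attachments(topology, leaf):
    """All topologies obtained by attaching ``leaf`` on any edge."""
    yield (topology, leaf)  # attach on the trunk (edge to the outgroup)
    if not isinstance(topology, str):
        left, right = topology
        for sub in _attachments(left, leaf):
            yield (sub, right)
        for sub in _attachments(right, leaf):
            yield (left, sub)


def _canonical(topology):
    if isinstance(topology, str):
        return topology
    a, b = _canonical(topology[0]), _canonical(topology[1])
    return (a, b) if _canon_key(a) <= _canon_key(b) else (b, a)


def _canon_key(topology) -> str:
    return topology if isinstance(topology, str) else f"({_canon_key(topology[0])},{_canon_key(topology[1])})"


@dataclass
class SampleTree:
    """A reconstructed region tree with branch-assigned variants."""

    samples: list[str]
    topology: Topology
    score: float
    branch_variants: dict[frozenset, list[str]] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)

    def newick(self) -> str:
        def fmt(node):
            if isinstance(node, str):
                clade = frozenset([node])
            else:
                clade = frozenset(_leaves(node))
            count = len(self.branch_variants.get(clade, []))
            if isinstance(node, str):
                return f"{node}:{count}"
            return f"({fmt(node[0])},{fmt(node[1])}):{count}"

        return f"({fmt(self.topology)},{OUTGROUP}:0);"


def enumerate_topologies(samples: Sequence[str]):
    """All unrooted topologies over samples + outgroup (nested-tuple form)."""
    samples = list(samples)
    trees = [samples[0]]
    for leaf in samples[1:]:
        trees = [t for base in trees for t in _attachments(base, leaf)]
    return trees


def max_parsimony(matrix: BinaryMatrix, exhaustive: bool = False) -> list[SampleTree]:
    """All minimum-parsimony-length topologies, canonically ordered.

    Exact branch-and-bound: leaves are added stepwise and partial trees
    whose (restricted-pattern) Fitch score exceeds the incumbent optimum
    are pruned.  ``exhaustive=True`` disables pruning (testing hook).
    """
    samples = matrix.samples
    if len(samples) > MAX_EXACT_SAMPLES:
        raise ValidationError(
            f"{len(samples)} samples exceed the exact-search bound of "
            f"{MAX_EXACT_SAMPLES}; no heuristic mode is provided"
        )
    restricted = [matrix.restricted(k) for k in range(len(samples) + 1)]
    best = [float("inf")]
    complete: list[tuple[float, object]] = []

    def recurse(tree, k):
        score = fitch_score(tree, matrix, patterns=restricted[k])
        if not exhaustive and score > best[0]:
            return
        if k == len(samples):
            if score < best[0]:
                best[0] = score
            complete.append((score, tree))
            return
        for nxt in _attachments(tree, samples[k]):
            recurse(nxt, k + 1)

    recurse(samples[0], 1)
    optimal = [t for s, t in complete if s == best[0]]
    trees = sorted((_canonical(t) for t in optimal), key=_canon_key)
    return [
        _with_branch_assignments(SampleTree(samples=list(samples), topology=t,
                                            score=best[0]), matrix)
        for t in trees
    ]


def _with_branch_assignments(tree: SampleTree, matrix: BinaryMatrix) -> SampleTree:
    """Assign each variant to the branch above the clade it defines.

    A variant whose support set matches no clade of the topology needs
    more than one state change (homoplasy) and is reported as unresolved
    rather than forced onto a branch.
    """
    clades = set()

    def collect(node):
        clade = frozenset(_leaves(node)) if not isinstance(node, str) else frozenset([node])
        clades.add(clade)
        if not isinstance(node, str):
            collect(node[0])
            collect(node[1])

    collect(tree.topology)
    for vid, pat in matrix.variant_patterns.items():
        support = frozenset(s for s, x in zip(matrix.samples, pat) if x)
        if support in clades:
            tree.branch_variants.setdefault(support, []).append(vid)
        else:
            tree.unresolved.append(vid)
    return tree


def write_newick(tree: SampleTree, path) -> None:
    """Write the outgroup-rooted newick (branch lengths = variant counts)."""
    text = tree.newick()
    # round-trip through dendropy validates the generated string
    dendropy.Tree.get(data=text, schema="newick")
    with open(path, "w") as fh:
        fh.write(text + "\n")


# ---------------------------------------------------------------------------
# CCF ordering constraints
# ---------------------------------------------------------------------------

def ccf_order_check(ccf: pd.DataFrame, epsilon: float = 0.1) -> dict:
    """Admissible lineage relations between CCF clusters.

    ``ccf``: clusters x samples matrix of cancer cell fractions.  X may be
    ancestral to Y iff CCF_X >= CCF_Y - epsilon in every sample; X and Y
    may be siblings under Z iff CCF_X + CCF_Y <= CCF_Z + epsilon in every
    sample.  Cluster pairs admissible in neither direction are reported
    as crossing (they cannot lie on one lineage).
    """
    ccf = pd.DataFrame(ccf).astype(float)
    if ccf.empty or ccf.isna().all(axis=1).any():
        raise ValidationError("every cluster needs at least one CCF value")
    names = list(ccf.index)
    vals = ccf.to_numpy()

    def dominates(i, j):
        return bool(np.all(vals[i] >= vals[j] - epsilon))

    ancestral = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(len(names))
        if i != j and dominates(i, j)
    ]
    crossing = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if not dominates(i, j) and not dominates(j, i)
    ]
    siblings = [
        (names[i], names[j], names[k])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        for k in range(len(names))
        if k not in (i, j) and bool(np.all(vals[i] + vals[j] <= vals[k] + epsilon))
    ]
    return {"ancestral": ancestral, "siblings": siblings, "crossing": crossing,
            "epsilon": epsilon}
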