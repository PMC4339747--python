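"""Performance measures for recovered restriction graphs.

Four scores compare an inferred graph F with the true graph T:

* **Diff** — the number of directed edges present in exactly one of the two
  cover-adjacency matrices, built over the union of node sets with Root
  included (the squared Frobenius norm of the adjacency difference for 0/1
  matrices).
* **PFD** — proportion of false discoveries, FP / (TP + FP).
* **PND** — proportion of negative discoveries, FN / (TP + FN).
* **FPF** — false positive fraction, FP / (FP + TN).

The relation-level confusion counts use "relations": the transitive
closure of the cover relations with Root excluded, over a universe of all
ordered pairs of distinct non-Root nodes from the union of the two gene
sets (so selected passengers and missed drivers both count against the
inference).  Empty denominators (no discoveries / empty universe side)
score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graphs import ROOT, RestrictionGraph


@dataclass(frozen=True)
class PerformanceScores:
    diff: int
    pfd: float
    pnd: float
    fpf: float
    tp: int
    fp: int
    fn: int
    tn: int
    universe_size: int

    def as_dict(self) -> dict:
        return {
            "Diff": self.diff,
            "PFD": self.pfd,
            "PND": self.pnd,
            "FPF": self.fpf,
        }


def diff_score(true: RestrictionGraph, inferred: RestrictionGraph) -> int:
    """Symmetric difference of cover edge sets over the union of nodes,
    Root included.  Symmetric in its arguments."""
    return len(set(true.edges) ^ set(inferred.edges))


def relation_confusion(
    true: RestrictionGraph, inferred: RestrictionGraph
) -> tuple[int, int, int, int, int]:
    """(tp, fp, fn, tn, universe_size) over ordered non-Root gene pairs."""
    rel_t = true.relations()
    rel_f = inferred.relations()
    genes = set(true.drivers) | set(inferred.drivers)
    universe = len(genes) * (len(genes) - 1)
    tp = len(rel_t & rel_f)
    fp = len(rel_f - rel_t)
    fn = len(rel_t - rel_f)
    tn = universe - tp - fp - fn
    return tp, fp, fn, tn, universe


def scores(
    true: RestrictionGraph, inferred: RestrictionGraph
) -> PerformanceScores:
    tp, fp, fn, tn, universe = relation_confusion(true, inferred)
    pfd = fp / (tp + fp) if (tp + fp) else 0.0
    pnd = fn / (tp + fn) if (tp + fn) else 0.0
    fpf = fp / (fp + tn) if (fp + tn) else 0.0
    return PerformanceScores(
        diff=diff_score(true, inferred),
        pfd=pfd,
        pnd=pnd,
        fpf=fpf,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        universe_size=universe,
    )
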