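"""Truth-based evaluation of subgenome assignment and contig ordering.

Cluster labels are arbitrary, so assignment accuracy is computed after an
optimal one-to-one cluster-to-subgenome matching (Hungarian algorithm on the
base-weighted confusion matrix).  Ordering is scored per chromosome by
Kendall tau after choosing the direction (as-is vs reversed-with-flips) that
maximises tau, reflecting the intrinsic reversal symmetry of a scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import kendalltau

from .errors import ContractError


@dataclass
class AssignmentEval:
    base_weighted_accuracy: float
    count_weighted_accuracy: float
    purity: dict[int, float]
    unassigned_rate: float        # fraction of bases unassigned
    assigned_base_fraction: float
    label_map: dict[int, int]     # cluster label -> matched true subgenome


@dataclass
class OrderEval:
    per_chromosome_tau: dict[str, float]
    adjacency_accuracy: float
    orientation_accuracy: float
    anchoring_rate: float         # placed bases / total contig bases
    missing_chromosomes: list[str] = field(default_factory=list)


def evaluate_assignment(assignment: pd.DataFrame, truth: pd.DataFrame) -> AssignmentEval:
    """Score a subgenome assignment against simulator truth."""
    t = truth.set_index("contig")
    a = assignment.set_index("contig")
    if set(a.index) != set(t.index):
        raise ContractError("assignment and truth cover different contig sets")
    a = a.loc[t.index]
    lengths = (t["end"] - t["start"]).to_numpy(dtype=float)
    pred = a["label"].to_numpy(dtype=int)
    true = t["subgenome"].to_numpy(dtype=int)
    clusters = sorted(set(pred) - {0})
    sgs = sorted(set(true))
    conf = np.zeros((len(clusters), len(sgs)))
    for ci, c in enumerate(clusters):
        for si, s in enumerate(sgs):
            conf[ci, si] = lengths[(pred == c) & (true == s)].sum()
    if conf.size:
        ri, cj = linear_sum_assignment(-conf)
        label_map = {clusters[i]: sgs[j] for i, j in zip(ri, cj)}
    else:
        label_map = {}
    mapped = np.array([label_map.get(p, -1) for p in pred])
    assigned = pred != 0
    correct = assigned & (mapped == true)
    base_acc = lengths[correct].sum() / max(lengths[assigned].sum(), 1e-300)
    count_acc = correct.sum() / max(assigned.sum(), 1)
    purity = {}
    for ci, c in enumerate(clusters):
        tot = conf[ci].sum()
        purity[c] = float(conf[ci].max() / tot) if tot else 0.0
    unassigned_rate = lengths[~assigned].sum() / lengths.sum()
    return AssignmentEval(
        base_weighted_accuracy=float(base_acc),
        count_weighted_accuracy=float(count_acc),
        purity=purity,
        unassigned_rate=float(unassigned_rate),
        assigned_base_fraction=float(1.0 - unassigned_rate),
        label_map=label_map,
    )


def _directed_scores(entries: list[tuple[str, str]], t: pd.DataFrame):
    """Tau/adjacency/orientation for one direction of a recovered group."""
    names = [c for c, _ in entries]
    orients = [o for _, o in entries]
    true_order = t.loc[names, "order_index"].to_numpy()
    if len(names) < 2:
        tau = 1.0
    else:
        tau = kendalltau(np.arange(len(names)), true_order).statistic
        if np.isnan(tau):
            tau = 0.0
    true_orient = t.loc[names, "orientation"].to_numpy()
    orient_acc = float(np.mean([o == to for o, to in zip(orients, true_orient)]))
    # adjacency: fraction of true-adjacent pairs recovered adjacent
    pos_of = {int(oi): k for k, oi in enumerate(true_order)}
    true_adj = [
        (i, i + 1) for i in sorted(pos_of) if i + 1 in pos_of
    ]
    if true_adj:
        hits = sum(1 for i, j in true_adj if abs(pos_of[i] - pos_of[j]) == 1)
        adj_acc = hits / len(true_adj)
    else:
        adj_acc = 1.0
    return float(tau), adj_acc, orient_acc


def evaluate_order(build, truth: pd.DataFrame) -> OrderEval:
    """Score a ChromosomeBuild's per-group order and orientation vs truth.

    Each group is compared against its dominant true chromosome; the
    direction (as-is or reversed with all orientations flipped) maximising
    Kendall tau is used for all three scores.
    """
    t = truth.set_index("contig")
    missing_placed = [c for c in build.placed_contigs() if c not in t.index]
    if missing_placed:
        raise ContractError(f"placed contigs absent from truth: {missing_placed[:5]}")
    taus: dict[str, float] = {}
    adj_parts: list[tuple[float, int]] = []
    ori_parts: list[tuple[float, int]] = []
    placed_bases = 0
    seen_chroms: set[str] = set()
    for (sg, group), entries in sorted(build.groups.items()):
        names = [c for c, _, _ in entries]
        placed_bases += int((t.loc[names, "end"] - t.loc[names, "start"]).sum())
        chrom = t.loc[names, "chromosome"].mode().iloc[0]
        seen_chroms.add(chrom)
        on_chrom = [(c, o) for c, o, _ in entries if t.at[c, "chromosome"] == chrom]
        fwd = _directed_scores(on_chrom, t)
        rev_entries = [(c, "-" if o == "+" else "+") for c, o in reversed(on_chrom)]
        rev = _directed_scores(rev_entries, t)
        best = fwd if fwd[0] >= rev[0] else rev
        key = f"{chrom}"
        if key in taus:  # two groups mapping to one chromosome: keep larger group
            key = f"{chrom}/sg{sg}_{group}"
        taus[key] = best[0]
        adj_parts.append((best[1], max(len(on_chrom) - 1, 1)))
        ori_parts.append((best[2], len(on_chrom)))
    total_bases = int((truth["end"] - truth["start"]).sum())
    missing = sorted(set(truth["chromosome"]) - seen_chroms)

    def wmean(parts):
        tot = sum(w for _, w in parts)
        return sum(v * w for v, w in parts) / tot if tot else float("nan")

    return OrderEval(
        per_chromosome_tau=taus,
        adjacency_accuracy=float(wmean(adj_parts)),
        orientation_accuracy=float(wmean(ori_parts)),
        anchoring_rate=placed_bases / total_bases if total_bases else 0.0,
        missing_chromosomes=missing,
    )
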