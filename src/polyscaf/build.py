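"""Chromosome building: diploid-anchor pre-assignment of chromosome groups,
contact-driven ordering and orientation within each group, and AGP/FASTA
emission.

Each subgenome's contigs are anchored to the diploid reference through
k-mers unique in the reference; the majority chromosome vote pre-assigns a
group and the median reference offset provides a positional prior.  Within
a group, the initial order follows those offsets (contacts place anchorless
contigs), orientations come from anchor strand votes or, failing that, from
the end-resolved contact cells, and a deterministic 2-opt/relocation
refinement accepts only moves that strictly increase the adjacency
objective — the sum over adjacent pairs of contacts joining their abutting
ends.  A reversal-symmetric solution is canonicalised by putting the
smallest-offset contig in '+' context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmers import canonical_kmers, reverse_complement
from .contacts import ContactMap, HEAD, TAIL
from .errors import ContractError, ParameterError

log = logging.getLogger(__name__)


# -------------------------------------------------------------- anchor hits

@dataclass
class AnchorHits:
    """Per-contig diploid anchor evidence."""

    contig: str
    n_hits: int
    chromosome: str | None        # majority reference chromosome
    vote_fraction: float
    median_offset: float          # median reference offset of majority hits
    orientation: str | None       # majority relative orientation of majority hits
    orient_votes: int             # hits supporting the majority orientation


def _reference_anchor_index(reference: dict[str, str], anchor_k: int):
    """Canonical anchor_k-mers unique across the whole reference, with
    (chromosome idx, offset, fwd-is-canonical)."""
    codes_l, chrom_l, off_l, fwd_l = [], [], [], []
    names = list(reference)
    for ci, name in enumerate(names):
        canon, fwd, valid = canonical_kmers(reference[name], anchor_k, exact=True)
        v = np.flatnonzero(valid)
        codes_l.append(canon[v])
        chrom_l.append(np.full(v.size, ci, dtype=np.int32))
        off_l.append(v.astype(np.int64))
        fwd_l.append(fwd[v])
    codes = np.concatenate(codes_l) if codes_l else np.zeros(0, np.uint64)
    if codes.size == 0:
        return list(reference), codes, np.zeros(0, np.int32), np.zeros(0, np.int64), np.zeros(0, bool)
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    uniq_mask = np.concatenate(([True], codes[1:] != codes[:-1])) & np.concatenate(
        (codes[:-1] != codes[1:], [True])
    )
    keep = order[uniq_mask]
    return (
        names,
        codes[uniq_mask],
        np.concatenate(chrom_l)[keep],
        np.concatenate(off_l)[keep],
        np.concatenate(fwd_l)[keep],
    )


def preassign_chromosome_groups(
    contigs: dict[str, str],
    reference: dict[str, str],
    anchor_k: int = 21,
    min_vote: float = 0.6,
) -> tuple[dict[str, AnchorHits], dict[str, str]]:
    """Anchor one subgenome's contigs to diploid chromosomes.

    Returns (per-contig AnchorHits, group map contig -> chromosome for
    contigs whose majority vote fraction reaches ``min_vote``); contigs with
    no anchors or a weak vote stay ungrouped, to be placed by contacts.
    """
    names, ref_codes, ref_chrom, ref_off, ref_fwd = _reference_anchor_index(
        reference, anchor_k
    )
    hits: dict[str, AnchorHits] = {}
    groups: dict[str, str] = {}
    for cid, seq in contigs.items():
        canon, fwd, valid = canonical_kmers(seq, anchor_k, exact=True)
        v = np.flatnonzero(valid)
        canon, fwd = canon[v], fwd[v]
        pos = np.searchsorted(ref_codes, canon)
        pos[pos == ref_codes.size] = 0
        m = ref_codes[pos] == canon
        if not m.any():
            hits[cid] = AnchorHits(cid, 0, None, 0.0, np.nan, None, 0)
            continue
        h_chrom = ref_chrom[pos[m]]
        h_off = ref_off[pos[m]]
        h_same = ref_fwd[pos[m]] == fwd[m]
        counts = np.bincount(h_chrom, minlength=len(names))
        maj = int(counts.argmax())
        vote = counts[maj] / counts.sum()
        on_maj = h_chrom == maj
        med = float(np.median(h_off[on_maj]))
        n_plus = int(h_same[on_maj].sum())
        n_maj = int(on_maj.sum())
        orient = "+" if n_plus * 2 >= n_maj else "-"
        hits[cid] = AnchorHits(
            cid, int(m.sum()), names[maj], float(vote), med, orient,
            max(n_plus, n_maj - n_plus),
        )
        if vote >= min_vote:
            groups[cid] = names[maj]
    n_ungrouped = len(contigs) - len(groups)
    if n_ungrouped:
        log.info("%d/%d contigs ungrouped by anchors", n_ungrouped, len(contigs))
    return hits, groups


# ------------------------------------------------------- order and orient

def _right_end(orient: str) -> int:
    return TAIL if orient == "+" else HEAD


def _left_end(orient: str) -> int:
    return HEAD if orient == "+" else TAIL


def _adjacency_term(cmap: ContactMap, i: int, oi: str, j: int, oj: str) -> float:
    """Density of contacts joining the abutting ends of an adjacent pair.

    The raw end-cell count is normalised by the product of the two
    end-window lengths (contacts per Mb^2): raw counts grow with contig
    length, and an un-normalised objective rewards evicting short contigs
    from between long neighbours.
    """
    count = cmap.cell(i, _right_end(oi), j, _left_end(oj))
    wi = max(cmap.lengths[i] / 2, 1.0)
    wj = max(cmap.lengths[j] / 2, 1.0)
    return count / (wi * wj / 1e12)


def _objective(cmap: ContactMap, order: list[int], orients: list[str]) -> float:
    return sum(
        _adjacency_term(cmap, order[t], orients[t], order[t + 1], orients[t + 1])
        for t in range(len(order) - 1)
    )


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def order_and_orient(
    group_contigs: list[str],
    cmap: ContactMap,
    hits: dict[str, AnchorHits],
    refine_passes: int = 3,
    min_orient_anchors: int = 3,
) -> list[tuple[str, str, str]]:
    """Order and orient one chromosome group's contigs.

    Returns ``[(contig, orientation, confidence)]`` where confidence is
    'high' for anchor-oriented contigs and 'low' for contact-only ones.
    """
    if not group_contigs:
        raise ParameterError("empty chromosome group")
    if len(group_contigs) == 1:
        c = group_contigs[0]
        return [(c, "+", "high" if _anchored(hits.get(c), min_orient_anchors) else "low")]
    anchored = [c for c in group_contigs
                if hits.get(c) is not None and hits[c].n_hits > 0
                and not np.isnan(hits[c].median_offset)]
    unanchored = [c for c in group_contigs if c not in set(anchored)]
    has_contacts = any(
        cmap.pair_total(cmap.index[a], cmap.index[b])
        for ai, a in enumerate(group_contigs) for b in group_contigs[ai + 1:]
        if a in cmap.index and b in cmap.index
    )
    if not anchored and not has_contacts:
        raise ParameterError("group has neither anchors nor contacts; unorderable")

    idx = cmap.index
    # initial order: ascending median reference offset, ties by id
    order_ids = sorted(anchored, key=lambda c: (hits[c].median_offset, c))
    # contacts-only greedy insertion for anchorless contigs, strongest first
    def total_link(c):
        return cmap.contig_total(idx[c]) if c in idx else 0
    for c in sorted(unanchored, key=lambda c: (-total_link(c), c)):
        if not order_ids:
            order_ids.append(c)
            continue
        # cheapest insertion: links gained to the new neighbours minus the
        # link severed between them
        best_slot, best_score = 0, -np.inf
        for slot in range(len(order_ids) + 1):
            score = 0.0
            left = order_ids[slot - 1] if slot > 0 else None
            right = order_ids[slot] if slot < len(order_ids) else None
            if left is not None and c in idx and left in idx:
                score += cmap.density[idx[c], idx[left]]
            if right is not None and c in idx and right in idx:
                score += cmap.density[idx[c], idx[right]]
            if left is not None and right is not None and left in idx and right in idx:
                score -= cmap.density[idx[left], idx[right]]
            if score > best_score:
                best_slot, best_score = slot, score
        order_ids.insert(best_slot, c)

    order = [idx.get(c, -1) for c in order_ids]
    # orientation: anchor strand votes where confident, else contact cells
    orients: list[str] = []
    anchor_oriented: list[bool] = []
    for c in order_ids:
        h = hits.get(c)
        if _anchored(h, min_orient_anchors):
            orients.append(h.orientation)
            anchor_oriented.append(True)
        else:
            orients.append("+")
            anchor_oriented.append(False)
    # greedy orientation of non-anchored contigs by consistent end cells
    for t, c in enumerate(order_ids):
        if anchor_oriented[t] or order[t] < 0:
            continue
        score = {"+": 0, "-": 0}
        for o in ("+", "-"):
            if t > 0 and order[t - 1] >= 0:
                score[o] += _adjacency_term(cmap, order[t - 1], orients[t - 1], order[t], o)
            if t + 1 < len(order) and order[t + 1] >= 0:
                score[o] += _adjacency_term(cmap, order[t], o, order[t + 1], orients[t + 1])
        if score["-"] > score["+"]:
            orients[t] = "-"
    # flip refinement for contact-oriented contigs (strict improvement only)
    improved = True
    while improved:
        improved = False
        for t in range(len(order_ids)):
            if anchor_oriented[t] or order[t] < 0:
                continue
            base = _local_objective(cmap, order, orients, t)
            orients[t] = _flip(orients[t])
            if _local_objective(cmap, order, orients, t) > base:
                improved = True
            else:
                orients[t] = _flip(orients[t])

    # 2-opt segment reversals and single-contig relocations.  Anchor order
    # is independent evidence and is never contradicted: a reversal may span
    # at most one anchor-placed contig and anchor-placed contigs are not
    # relocated, so contact refinement acts only where anchors are silent.
    anchored_set = set(anchored)
    n = len(order_ids)
    for _ in range(max(0, refine_passes)):
        changed = False
        # segment reversal [i, j]: only the two boundary adjacencies change
        for i in range(n - 1):
            for j in range(i + 1, n):
                if sum(1 for c in order_ids[i:j + 1] if c in anchored_set) > 1:
                    continue
                delta = _reversal_delta(cmap, order, orients, i, j)
                if delta > 0:
                    order[i:j + 1] = order[i:j + 1][::-1]
                    order_ids[i:j + 1] = order_ids[i:j + 1][::-1]
                    orients[i:j + 1] = [_flip(o) for o in orients[i:j + 1]][::-1]
                    anchor_oriented[i:j + 1] = anchor_oriented[i:j + 1][::-1]
                    changed = True
        # single-contig relocation (anchorless contigs only)
        for i in range(n):
            if order_ids[i] in anchored_set:
                continue
            cur = _objective(cmap, order, orients)
            best_gain, best_slot = 0, None
            for slot in range(n):
                if slot == i:
                    continue
                o2 = order[:i] + order[i + 1:]
                oi2 = orients[:i] + orients[i + 1:]
                o2.insert(slot, order[i])
                oi2.insert(slot, orients[i])
                gain = _objective(cmap, o2, oi2) - cur
                if gain > best_gain:
                    best_gain, best_slot = gain, slot
            if best_slot is not None:
                v, ov, av, cv = order[i], orients[i], anchor_oriented[i], order_ids[i]
                del order[i], orients[i], anchor_oriented[i], order_ids[i]
                order.insert(best_slot, v)
                orients.insert(best_slot, ov)
                anchor_oriented.insert(best_slot, av)
                order_ids.insert(best_slot, cv)
                changed = True
        if not changed:
            break

    # canonicalisation: smallest-median-offset contig in '+' context;
    # fall back to lexicographically smallest id when no anchors
    if anchored:
        pivot = min(anchored, key=lambda c: (hits[c].median_offset, c))
    else:
        pivot = min(order_ids)
    t = order_ids.index(pivot)
    if orients[t] == "-":
        order_ids.reverse()
        order.reverse()
        anchor_oriented.reverse()
        orients = [_flip(o) for o in reversed(orients)]

    return [
        (c, o, "high" if a else "low")
        for c, o, a in zip(order_ids, orients, anchor_oriented)
    ]


def _anchored(h: AnchorHits | None, min_orient_anchors: int) -> bool:
    return (h is not None and h.orientation is not None
            and h.orient_votes >= min_orient_anchors)


def _local_objective(cmap, order, orients, t) -> int:
    s = 0
    if t > 0 and order[t - 1] >= 0 and order[t] >= 0:
        s += _adjacency_term(cmap, order[t - 1], orients[t - 1], order[t], orients[t])
    if t + 1 < len(order) and order[t] >= 0 and order[t + 1] >= 0:
        s += _adjacency_term(cmap, order[t], orients[t], order[t + 1], orients[t + 1])
    return s


def _reversal_delta(cmap, order, orients, i, j) -> int:
    """Objective change from reversing segment [i, j] (with orientation flips);
    internal adjacencies are invariant, only the two boundaries change."""
    old = new = 0
    if i > 0:
        old += _adjacency_term(cmap, order[i - 1], orients[i - 1], order[i], orients[i])
        new += _adjacency_term(cmap, order[i - 1], orients[i - 1],
                               order[j], _flip(orients[j]))
    if j + 1 < len(order):
        old += _adjacency_term(cmap, order[j], orients[j], order[j + 1], orients[j + 1])
        new += _adjacency_term(cmap, order[i], _flip(orients[i]),
                               order[j + 1], orients[j + 1])
    return new - old


# ----------------------------------------------------------- whole assembly

@dataclass
class ChromosomeBuild:
    """Ordered, oriented contigs per (subgenome, chromosome group)."""

    groups: dict[tuple[int, str], list[tuple[str, str, str]]] = field(default_factory=dict)
    unplaced: list[str] = field(default_factory=list)
    gap_size: int = 100

    def placed_contigs(self) -> list[str]:
        return [c for g in self.groups.values() for c, _, _ in g]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sg, chrom), entries in sorted(self.groups.items()):
            for k, (c, o, conf) in enumerate(entries):
                rows.append({"subgenome": sg, "group": chrom, "contig": c,
                             "order": k, "orientation": o, "confidence": conf})
        return pd.DataFrame(
            rows, columns=["subgenome", "group", "contig", "order",
                           "orientation", "confidence"])


def build_chromosomes(
    contigs: dict[str, str],
    assignment: pd.DataFrame,
    reference: dict[str, str],
    pairs: pd.DataFrame,
    config,
) -> ChromosomeBuild:
    """Run pre-assignment and ordering for every subgenome cluster."""
    from .contacts import contig_contact_matrix

    build = ChromosomeBuild(gap_size=config.gap_size)
    labelled = assignment[assignment["label"] != 0]
    cmap_all = contig_contact_matrix(pairs, contigs)
    for sg in sorted(labelled["label"].unique()):
        sub_ids = sorted(labelled.loc[labelled["label"] == sg, "contig"])
        sub_contigs = {c: contigs[c] for c in sub_ids}
        hits, groups = preassign_chromosome_groups(
            sub_contigs, reference, config.anchor_k, config.min_vote
        )
        # ungrouped contigs join the group they link to most strongly
        by_group: dict[str, list[str]] = {}
        for c, g in groups.items():
            by_group.setdefault(g, []).append(c)
        ungrouped = [c for c in sub_ids if c not in groups]
        for c in sorted(ungrouped):
            if not by_group:
                break
            best_g, best_d = None, 0.0
            ci = cmap_all.index.get(c)
            for g, members in sorted(by_group.items()):
                if ci is None:
                    break
                d = float(np.mean([cmap_all.density[ci, cmap_all.index[m]]
                                   for m in members if m in cmap_all.index] or [0.0]))
                if d > best_d:
                    best_g, best_d = g, d
            if best_g is not None:
                by_group[best_g].append(c)
            else:
                build.unplaced.append(c)
        for g, members in sorted(by_group.items()):
            try:
                placed = order_and_orient(
                    sorted(members), cmap_all, hits,
                    config.refine_passes, config.min_orient_anchors,
                )
            except ParameterError as exc:
                log.warning("group sg%d/%s unorderable: %s", sg, g, exc)
                build.unplaced.extend(sorted(members))
                continue
            build.groups[(int(sg), g)] = placed
    build.unplaced.extend(sorted(
        set(assignment.loc[assignment["label"] == 0, "contig"])
    ))
    return build


# ------------------------------------------------------------------- AGP out

def build_agp(
    build: ChromosomeBuild,
    contigs: dict[str, str],
    gap_size: int | None = None,
) -> tuple[list[tuple], dict[str, str]]:
    """Emit AGP v2.1 rows (1-based inclusive) and scaffold sequences.

    Scaffolds are named ``sg{subgenome}_{group}``; component rows are type W,
    gaps type N with evidence 'proximity_ligation'.  Splitting a scaffold on
    its N-gaps recovers every oriented contig byte-exactly.
    """
    if gap_size is None:
        gap_size = build.gap_size
    rows: list[tuple] = []
    scaffolds: dict[str, str] = {}
    for (sg, chrom), entries in sorted(build.groups.items()):
        if not entries:
            log.warning("empty group sg%d/%s: no AGP object emitted", sg, chrom)
            continue
        obj = f"sg{sg}_{chrom}"
        parts: list[str] = []
        pos = 0  # 0-based cursor
        part_no = 0
        for k, (cid, orient, _conf) in enumerate(entries):
            if cid not in contigs:
                raise ContractError(f"placed contig {cid} missing from contig set")
            seq = contigs[cid]
            if orient == "-":
                seq = reverse_complement(seq)
            if k > 0 and gap_size > 0:
                part_no += 1
                rows.append((obj, pos + 1, pos + gap_size, part_no, "N",
                             gap_size, "scaffold", "yes", "proximity_ligation"))
                parts.append("N" * gap_size)
                pos += gap_size
            part_no += 1
            rows.append((obj, pos + 1, pos + len(seq), part_no, "W",
                         cid, 1, len(contigs[cid]), orient))
            parts.append(seq)
            pos += len(seq)
        scaffolds[obj] = "".join(parts)
    return rows, scaffolds


def split_scaffold_on_gaps(scaffold: str) -> list[str]:
    """Inverse of gap-joined concatenation: maximal runs without N."""
    out, cur = [], []
    for ch in scaffold:
        if ch == "N":
            if cur:
                out.append("".join(cur))
                cur = []
        else:
            cur.append(ch)
    if cur:
        out.append("".join(cur))
    return out
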