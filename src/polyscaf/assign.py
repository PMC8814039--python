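"""Subgenome distinguishing: diploid k-mer depth clustering, allelic-contig
correction, and Hi-C link-density correction.

The pipeline mirrors the three-signal design for polyploid phasing: contigs
are first clustered on their diploid k-mer match fraction (homoeologous
copies sit at distinct divergences from the diploid relative, so their
100-mer survival fractions form separated bands), conflicts between allelic
(homoeologous) contigs — which can never share a subgenome — are then
repaired, and finally Hi-C link densities re-home contigs whose depth signal
was ambiguous, over multiple rounds with early stopping.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._kmers import canonical_kmers, valid_canonical
from .contacts import ContactMap, contig_contact_matrix
from .errors import ContractError, ParameterError
from .params import PipelineConfig

log = logging.getLogger(__name__)

UNASSIGNED = 0
LOG_FLOOR = 1e-4  # added to match fractions before log10

ASSIGN_COLS = ["contig", "label", "confidence", "provenance"]


# ------------------------------------------------------------- depth profile

@dataclass
class DepthProfile:
    """Per-contig diploid k-mer match fractions (one column per reference)."""

    contig_ids: list[str]
    values: np.ndarray        # (n_contigs, n_references), in [0, 1]
    lengths: np.ndarray
    k: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            columns=[f"ref{r}" for r in range(self.values.shape[1])],
        )
        df.insert(0, "contig", self.contig_ids)
        df["length"] = self.lengths
        return df


def kmer_depth_profile(
    contigs: dict[str, str],
    references: list[dict[str, str]],
    k_depth: int = 100,
) -> DepthProfile:
    """Fraction of each contig's k-mer start positions whose canonical
    k-mer occurs in each diploid reference.

    Contigs shorter than ``k_depth`` get fraction 0 with a warning.
    """
    if not references:
        raise ParameterError("at least one diploid reference is required")
    ref_sets = []
    for ref in references:
        hashes = [valid_canonical(seq, k_depth) for seq in ref.values()]
        ref_sets.append(np.unique(np.concatenate(hashes)) if hashes else np.zeros(0, np.uint64))
    ids = list(contigs)
    n, R = len(ids), len(ref_sets)
    values = np.zeros((n, R))
    lengths = np.zeros(n, dtype=np.int64)
    for i, cid in enumerate(ids):
        seq = contigs[cid]
        lengths[i] = len(seq)
        if len(seq) < k_depth:
            log.warning("contig %s shorter than k_depth=%d; depth set to 0", cid, k_depth)
            continue
        canon, _, valid = canonical_kmers(seq, k_depth)
        kv = canon[valid]
        denom = canon.size  # all start positions, invalid count as non-matching
        for r, refset in enumerate(ref_sets):
            if refset.size and kv.size:
                pos = np.searchsorted(refset, kv)
                pos[pos == refset.size] = 0
                values[i, r] = np.count_nonzero(refset[pos] == kv) / denom
    return DepthProfile(ids, values, lengths, k_depth)


# ------------------------------------------------------------ depth clusters

def cluster_by_depth(
    profile: DepthProfile,
    K: int,
    ambiguity_margin: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Preliminary K-cluster assignment of log10 depth profiles.

    A full-covariance Gaussian mixture is initialised at quantile-spaced
    means (deterministic); a contig whose top posterior responsibility falls
    below ``0.5 + ambiguity_margin`` stays unassigned.  Cluster labels are
    ordered by decreasing mean match fraction (cluster 1 = least diverged
    from the first diploid reference).
    """
    if K < 1:
        raise ParameterError("K must be >= 1")
    n = len(profile.contig_ids)
    if n < K:
        raise ParameterError(f"cannot form {K} clusters from {n} contigs")
    X = np.log10(profile.values + LOG_FLOOR)
    if K == 1:
        return pd.DataFrame({
            "contig": profile.contig_ids, "label": 1,
            "confidence": 1.0, "provenance": "depth",
        })
    qs = (np.arange(K) + 0.5) / K
    means_init = np.quantile(X, qs, axis=0)
    gm = GaussianMixture(
        n_components=K, covariance_type="full",
        means_init=means_init, random_state=seed, n_init=1,
    ).fit(X)
    resp = gm.predict_proba(X)
    # relabel components so cluster 1 has the highest mean depth signal
    order = np.argsort(-gm.means_[:, 0], kind="stable")
    resp = resp[:, order]
    top = resp.argmax(axis=1)
    conf = resp[np.arange(n), top]
    labels = np.where(conf < 0.5 + ambiguity_margin, UNASSIGNED, top + 1)
    return pd.DataFrame({
        "contig": profile.contig_ids, "label": labels,
        "confidence": conf, "provenance": "depth",
    })


def posterior_to_label(posterior: np.ndarray, ambiguity_margin: float) -> int:
    """Ambiguity rule: label = argmax+1 unless the top responsibility is
    below 0.5 + margin, in which case unassigned (0)."""
    top = int(np.argmax(posterior))
    if posterior[top] < 0.5 + ambiguity_margin:
        return UNASSIGNED
    return top + 1


# ------------------------------------------------------------------ allelism

@dataclass
class AllelismGraph:
    """Homoeologous contig pairs that must not share a subgenome label."""

    edges: pd.DataFrame  # contig_i, contig_j (i < j), shared_anchors, chain_length

    def neighbors(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {}
        for u, v in zip(self.edges["contig_i"], self.edges["contig_j"]):
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        return adj

    def __len__(self) -> int:
        return len(self.edges)


def _lis_length(seq: np.ndarray) -> int:
    """Longest strictly increasing subsequence (patience sorting)."""
    tails: list[int] = []
    for x in seq:
        i = bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def _self_repeat_mask(canon: np.ndarray, flank: int) -> np.ndarray:
    """True at positions NOT within ``flank`` bp of a k-mer duplicated
    inside the same contig (tandem-repeat shadow)."""
    if canon.size == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(canon, kind="stable")
    s = canon[order]
    dup_sorted = np.concatenate(([False], s[1:] == s[:-1]))
    dup_sorted |= np.concatenate((s[:-1] == s[1:], [False]))
    dup = np.zeros(canon.size, dtype=bool)
    dup[order] = dup_sorted
    if not dup.any():
        return np.ones(canon.size, dtype=bool)
    hits = np.flatnonzero(dup)
    bad = np.zeros(canon.size + 1, dtype=np.int32)
    lo = np.maximum(hits - flank, 0)
    hi = np.minimum(hits + flank + 1, canon.size)
    np.add.at(bad, lo, 1)
    np.add.at(bad, hi, -1)
    return np.cumsum(bad[:-1]) == 0


def detect_allelic_pairs(
    contigs: dict[str, str],
    anchor_k: int = 21,
    min_anchors: int = 8,
    max_anchor_occurrences: int = 3,
    max_anchors_per_pair: int = 2000,
) -> AllelismGraph:
    """Build the allelism graph from shared low-copy anchor k-mers.

    Anchors are canonical ``anchor_k``-mers occurring at most
    ``max_anchor_occurrences`` times in the whole contig set.  A pair of
    contigs sharing at least ``min_anchors`` anchors that form a collinear
    chain (monotone offsets under either relative orientation; longest chain
    by patience sorting) receives an edge.

    Tandem arrays (centromeric repeats) would otherwise link same-subgenome
    contigs straddling an array: positions whose k-mer recurs within the
    same contig, plus a flank, are masked before anchoring.
    """
    ids = list(contigs)
    mask_flank = 10 * anchor_k
    codes_l, cidx_l, pos_l, fwd_l = [], [], [], []
    for i, cid in enumerate(ids):
        canon, fwd, valid = canonical_kmers(contigs[cid], anchor_k, exact=True)
        valid = valid & _self_repeat_mask(canon, mask_flank)
        v = np.flatnonzero(valid)
        codes_l.append(canon[v])
        cidx_l.append(np.full(v.size, i, dtype=np.int64))
        pos_l.append(v.astype(np.int64))
        fwd_l.append(fwd[v])
    codes = np.concatenate(codes_l) if codes_l else np.zeros(0, np.uint64)
    if codes.size == 0:
        return AllelismGraph(pd.DataFrame(
            columns=["contig_i", "contig_j", "shared_anchors", "chain_length"]))
    cidx = np.concatenate(cidx_l)
    pos = np.concatenate(pos_l)
    fwd = np.concatenate(fwd_l)
    order = np.argsort(codes, kind="stable")
    codes, cidx, pos, fwd = codes[order], cidx[order], pos[order], fwd[order]
    # group boundaries per anchor code
    starts = np.flatnonzero(np.concatenate(([True], codes[1:] != codes[:-1])))
    counts = np.diff(np.concatenate((starts, [codes.size])))
    # emit all intra-group index pairs for groups of size 2..max_occ
    pair_a, pair_b = [], []
    for g in range(2, max_anchor_occurrences + 1):
        sel = starts[counts == g]
        if sel.size == 0:
            continue
        tmpl = [(a, b) for a in range(g) for b in range(a + 1, g)]
        for a, b in tmpl:
            pair_a.append(sel + a)
            pair_b.append(sel + b)
    if not pair_a:
        return AllelismGraph(pd.DataFrame(
            columns=["contig_i", "contig_j", "shared_anchors", "chain_length"]))
    ia = np.concatenate(pair_a)
    ib = np.concatenate(pair_b)
    ci, cj = cidx[ia], cidx[ib]
    pi, pj = pos[ia], pos[ib]
    same = fwd[ia] == fwd[ib]
    cross = ci != cj  # no self-loops
    ci, cj, pi, pj, same = ci[cross], cj[cross], pi[cross], pj[cross], same[cross]
    flip = ci > cj
    ci2 = np.where(flip, cj, ci)
    cj2 = np.where(flip, ci, cj)
    pi2 = np.where(flip, pj, pi)
    pj2 = np.where(flip, pi, pj)
    order = np.lexsort((pj2, pi2, cj2, ci2))
    ci2, cj2, pi2, pj2, same = ci2[order], cj2[order], pi2[order], pj2[order], same[order]
    key = ci2 * len(ids) + cj2
    gstarts = np.flatnonzero(np.concatenate(([True], key[1:] != key[:-1])))
    gcounts = np.diff(np.concatenate((gstarts, [key.size])))
    rows = []
    for s, c in zip(gstarts, gcounts):
        if c < min_anchors:
            continue
        sl = slice(s, s + c)
        a_pi, a_pj, a_same = pi2[sl], pj2[sl], same[sl]
        if c > max_anchors_per_pair:
            take = np.unique(np.linspace(0, c - 1, max_anchors_per_pair).astype(int))
            a_pi, a_pj, a_same = a_pi[take], a_pj[take], a_same[take]
        chain = 0
        for orient in (True, False):
            m = a_same == orient
            if m.sum() < 2:
                chain = max(chain, int(m.sum()))
                continue
            target = a_pj[m] if orient else -a_pj[m]
            chain = max(chain, _lis_length(target))
        if chain >= min_anchors:
            rows.append({
                "contig_i": ids[int(ci2[s])], "contig_j": ids[int(cj2[s])],
                "shared_anchors": int(c), "chain_length": int(chain),
            })
    return AllelismGraph(pd.DataFrame(
        rows, columns=["contig_i", "contig_j", "shared_anchors", "chain_length"]))


def count_intra_cluster_edges(assignment: pd.DataFrame, graph: AllelismGraph) -> int:
    """Number of allelic edges whose endpoints share a (non-unassigned) label."""
    lab = dict(zip(assignment["contig"], assignment["label"]))
    return sum(
        1 for u, v in zip(graph.edges["contig_i"], graph.edges["contig_j"])
        if lab.get(u, UNASSIGNED) == lab.get(v, UNASSIGNED) != UNASSIGNED
    )


def correct_with_allelism(
    assignment: pd.DataFrame,
    graph: AllelismGraph,
    K: int,
    max_passes: int = 10,
) -> pd.DataFrame:
    """Greedy repair of label conflicts along allelic edges.

    Edges are visited in descending chain-length order; when both endpoints
    share a label, the lower-confidence endpoint is relabelled to the label
    minimising its conflict count (ties leave it unassigned).  Each relabel
    moves to a minimum-conflict label, so the intra-cluster allelic edge
    count never increases; passes repeat until a fixed point (a relabel can
    expose an earlier edge whose endpoints now agree) or ``max_passes``.
    Afterwards an unassigned contig whose allelic partners occupy K-1
    distinct labels receives the remaining one.
    """
    known = set(assignment["contig"])
    for col in ("contig_i", "contig_j"):
        missing = set(graph.edges[col]) - known
        if missing:
            raise ContractError(f"allelism graph names unknown contigs: {sorted(missing)[:5]}")
    out = assignment.set_index("contig", drop=False).copy()
    adj = graph.neighbors()
    edges = graph.edges.sort_values(
        ["chain_length", "contig_i", "contig_j"], ascending=[False, True, True]
    )

    def conflicts(contig: str, label: int) -> int:
        return sum(1 for nb in adj.get(contig, []) if out.at[nb, "label"] == label)

    n_relabelled = 0
    for _ in range(max_passes):
        changed = False
        for u, v in zip(edges["contig_i"], edges["contig_j"]):
            lu, lv = out.at[u, "label"], out.at[v, "label"]
            if lu != lv or lu == UNASSIGNED:
                continue
            cu, cv = out.at[u, "confidence"], out.at[v, "confidence"]
            # relabel the lower-confidence endpoint; on a tie, the later id.
            # If that endpoint's minimum-conflict label is its current one
            # (moving it cannot help), try the other endpoint instead.
            if cu == cv:
                first, second = max(u, v), min(u, v)
            else:
                first, second = (u, v) if cu < cv else (v, u)
            for w in (first, second):
                counts = {l: conflicts(w, l) for l in range(1, K + 1)}
                best = min(counts.values())
                winners = [l for l, c in counts.items() if c == best]
                if winners == [out.at[w, "label"]]:
                    continue  # already optimal for w; move the other endpoint
                new = winners[0] if len(winners) == 1 else UNASSIGNED
                out.at[w, "label"] = new
                out.at[w, "provenance"] = "allelism"
                n_relabelled += 1
                changed = True
                break
        if not changed:
            break
    # rescue: partners occupy exactly K-1 labels -> the remaining label
    n_rescued = 0
    for contig in sorted(out.index[out["label"] == UNASSIGNED]):
        partner_labels = {
            out.at[nb, "label"] for nb in adj.get(contig, [])
        } - {UNASSIGNED}
        if len(partner_labels) == K - 1 and K >= 2:
            (remaining,) = set(range(1, K + 1)) - partner_labels
            out.at[contig, "label"] = remaining
            out.at[contig, "confidence"] = 0.5
            out.at[contig, "provenance"] = "allelism"
            n_rescued += 1
    if n_relabelled or n_rescued:
        log.info("allelism correction: %d relabelled, %d rescued", n_relabelled, n_rescued)
    return out.reset_index(drop=True)


# ------------------------------------------------------------ Hi-C correction

def correct_with_contacts(
    assignment: pd.DataFrame,
    cmap: ContactMap,
    K: int,
    max_rounds: int = 5,
    reassign_margin: float = 2.0,
    reassign_unassigned: bool = True,
) -> pd.DataFrame:
    """Iterative relabelling by Hi-C link density.

    Affinity of a contig to a cluster is the mean normalised link density to
    the cluster's labelled members.  A labelled contig moves when its best
    cluster's affinity exceeds ``reassign_margin`` times its current one and
    the move strictly increases total within-cluster density; an unassigned
    contig adopts its best cluster when that affinity exceeds the margin
    times the second best.  Stops at the first round with no changes.
    """
    out = assignment.set_index("contig", drop=False).copy()
    order = sorted(out.index)
    D = cmap.density
    idx_of = cmap.index
    labels = {c: int(out.at[c, "label"]) for c in order}

    def cluster_members(label: int) -> list[int]:
        return [idx_of[c] for c in order if labels[c] == label and c in idx_of]

    for l in range(1, K + 1):
        if not cluster_members(l):
            log.warning("cluster %d has no labelled contig; skipped in Hi-C round", l)

    for rnd in range(max_rounds):
        changed = 0
        members = {l: np.array(cluster_members(l), dtype=int) for l in range(1, K + 1)}
        for contig in order:
            if contig not in idx_of:
                continue
            ci = idx_of[contig]
            cur = labels[contig]
            aff = np.full(K + 1, -np.inf)
            sums = np.zeros(K + 1)
            for l in range(1, K + 1):
                mem = members[l]
                mem = mem[mem != ci]
                if mem.size:
                    sums[l] = D[ci, mem].sum()
                    aff[l] = sums[l] / mem.size
            ranked = np.argsort(-aff[1:], kind="stable") + 1
            best = int(ranked[0])
            if aff[best] == -np.inf:
                continue
            if cur == UNASSIGNED:
                if not reassign_unassigned:
                    continue
                second = aff[int(ranked[1])] if K > 1 else 0.0
                second = max(second, 0.0)
                if aff[best] > reassign_margin * second and aff[best] > 0:
                    labels[contig] = best
                    out.at[contig, "label"] = best
                    out.at[contig, "provenance"] = "hic"
                    out.at[contig, "confidence"] = 0.5
                    changed += 1
                    members = {l: np.array(cluster_members(l), dtype=int)
                               for l in range(1, K + 1)}
            elif best != cur:
                cur_aff = max(aff[cur], 0.0) if aff[cur] != -np.inf else 0.0
                if aff[best] > reassign_margin * cur_aff and sums[best] > sums[cur]:
                    labels[contig] = best
                    out.at[contig, "label"] = best
                    out.at[contig, "provenance"] = "hic"
                    changed += 1
                    members = {l: np.array(cluster_members(l), dtype=int)
                               for l in range(1, K + 1)}
        log.info("Hi-C correction round %d: %d changes", rnd + 1, changed)
        if changed == 0:
            break
    return out.reset_index(drop=True)


# ----------------------------------------------------------------- composite

def assign_subgenomes(
    contigs: dict[str, str],
    references: list[dict[str, str]],
    pairs: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict]:
    """Full subgenome-distinguishing stage: depth -> allelism -> Hi-C.

    Returns the final assignment table and a dict of intermediates
    (profile, graph, contact map, per-stage change counts).
    """
    K = config.n_subgenomes
    profile = kmer_depth_profile(contigs, references, config.k_depth)
    a0 = cluster_by_depth(profile, K, config.ambiguity_margin, seed=config.seed)
    graph = detect_allelic_pairs(
        contigs, config.anchor_k, config.min_anchors,
        config.max_anchor_occurrences, config.max_anchors_per_pair,
    )
    a1 = correct_with_allelism(a0, graph, K)
    cmap = contig_contact_matrix(pairs, contigs)
    a2 = correct_with_contacts(
        a1, cmap, K, config.max_rounds, config.reassign_margin,
        config.reassign_unassigned,
    )
    changes = {
        "allelism": int((a0.set_index("contig")["label"]
                         != a1.set_index("contig")["label"]).sum()),
        "hic": int((a1.set_index("contig")["label"]
                    != a2.set_index("contig")["label"]).sum()),
    }
    log.info("stage change counts: %s", changes)
    extras = {"profile": profile, "graph": graph, "contact_map": cmap,
              "changes": changes, "preliminary": a0, "after_allelism": a1}
    return a2, extras
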