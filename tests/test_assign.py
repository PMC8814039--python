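"""Subgenome distinguishing: depth law, depth clustering, allelism graph and
its corrections, Hi-C correction, and the end-resolved contact map."""

import numpy as np
import pandas as pd
import pytest

from polyscaf import assign as A
from polyscaf.contacts import ContactMap, HEAD, TAIL, contig_contact_matrix
from polyscaf.errors import ContractError, FormatError, ParameterError


# ----------------------------------------------------------------- depth law

def test_depth_profile_follows_survival_law(small_sim, small_assignment):
    """Mean 100-mer match fraction per subgenome tracks ((1-d0)(1-d_s))^k."""
    _, extras = small_assignment
    prof = extras["profile"]
    df = prof.to_frame().merge(small_sim.truth[["contig", "subgenome"]], on="contig")
    p = small_sim.params
    k = prof.k
    for s in range(1, p.n_subgenomes + 1):
        expected = ((1 - p.diploid_divergence) * (1 - p.subgenome_divergences[s - 1])) ** k
        obs = df.loc[df["subgenome"] == s, "ref0"].mean()
        assert abs(obs - expected) < 0.03


def test_depth_profile_identical_sequences_match_fully():
    seq = "ACGT" * 100
    prof = A.kmer_depth_profile({"c1": seq}, [{"r": seq}], k_depth=100)
    assert prof.values[0, 0] == pytest.approx(1.0)


def test_depth_profile_short_contig_gets_zero():
    prof = A.kmer_depth_profile({"tiny": "ACGTACGT"}, [{"r": "ACGT" * 200}], k_depth=100)
    assert prof.values[0, 0] == 0.0


def test_depth_profile_requires_reference():
    with pytest.raises(ParameterError):
        A.kmer_depth_profile({"c": "ACGT" * 50}, [])


# ------------------------------------------------------------ depth clusters

def test_cluster_by_depth_separates_clear_bands(rng):
    """On well-separated depth bands the mixture recovers the partition
    exactly, with cluster 1 the highest-fraction band."""
    levels = [0.6, 0.05, 0.002]
    vals, true = [], []
    for li, lv in enumerate(levels):
        x = lv * np.exp(rng.normal(0, 0.15, size=30))
        vals.append(np.clip(x, 0, 1))
        true.append(np.full(30, li + 1))
    prof = A.DepthProfile(
        [f"c{i}" for i in range(90)],
        np.concatenate(vals)[:, None],
        np.full(90, 10_000), 100)
    out = A.cluster_by_depth(prof, K=3, seed=0)
    labelled = out[out["label"] != A.UNASSIGNED]
    agree = (labelled["label"].to_numpy()
             == np.concatenate(true)[labelled.index]).mean()
    assert agree == 1.0
    assert (out["label"] != A.UNASSIGNED).mean() > 0.9


def test_preliminary_depth_clusters_capture_least_diverged(small_sim, small_assignment):
    """Cluster 1 (highest diploid match fraction) is dominated by the least
    diverged subgenome even before allelism/Hi-C correction."""
    _, extras = small_assignment
    a0 = extras["preliminary"]
    merged = a0.merge(small_sim.truth[["contig", "subgenome"]], on="contig")
    c1 = merged[merged["label"] == 1]
    assert len(c1) > 0
    assert (c1["subgenome"] == 1).mean() > 0.9


def test_ambiguity_rule():
    assert A.posterior_to_label(np.array([0.9, 0.05, 0.05]), 0.1) == 1
    assert A.posterior_to_label(np.array([0.55, 0.40, 0.05]), 0.1) == A.UNASSIGNED
    assert A.posterior_to_label(np.array([0.2, 0.2, 0.61]), 0.1) == 3


def test_cluster_needs_enough_contigs():
    prof = A.DepthProfile(["a", "b"], np.array([[0.5], [0.4]]), np.array([10, 10]), 100)
    with pytest.raises(ParameterError):
        A.cluster_by_depth(prof, K=3)


# -------------------------------------------------------------- allelism

def test_allelic_pairs_are_homoeologous(small_sim, small_assignment):
    """Detected edges overwhelmingly join contigs from the same ancestral
    interval of different subgenomes, never the same subgenome."""
    _, extras = small_assignment
    graph = extras["graph"]
    assert len(graph) > 0
    t = small_sim.truth.set_index("contig")
    for u, v in zip(graph.edges["contig_i"], graph.edges["contig_j"]):
        assert t.at[u, "subgenome"] != t.at[v, "subgenome"]
        # ancestral coordinates must overlap for a collinear chain
        assert min(t.at[u, "end"], t.at[v, "end"]) > max(t.at[u, "start"], t.at[v, "start"]) - 50_000


def test_allelism_detects_synthetic_homoeologs(rng):
    base = "".join(rng.choice(list("ACGT"), size=4000))
    codes = np.frombuffer(base.encode(), np.uint8).copy()
    hits = rng.random(codes.size) < 0.03
    sub = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=int(hits.sum()))
    codes[hits] = sub
    mut = codes.tobytes().decode()
    unrelated = "".join(rng.choice(list("ACGT"), size=4000))
    g = A.detect_allelic_pairs({"a": base, "b": mut, "c": unrelated})
    pairs = set(map(tuple, g.edges[["contig_i", "contig_j"]].to_numpy()))
    assert pairs == {("a", "b")}


def test_allelism_chain_measures_collinearity(rng):
    """Scrambling shared blocks collapses the collinear chain: the chain
    length of a block-shuffled partner is far below the shared-anchor count,
    while a truly collinear partner chains nearly all shared anchors."""
    blocks = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(60)]
    a = "".join(blocks)
    perm = rng.permutation(len(blocks))
    b = "".join(blocks[i] for i in perm)
    g = A.detect_allelic_pairs({"a": a, "b": b}, min_anchors=8)
    assert len(g) == 1
    e = g.edges.iloc[0]
    assert e["chain_length"] < 0.5 * e["shared_anchors"]
    g2 = A.detect_allelic_pairs({"a": a, "b2": a}, min_anchors=8,
                                max_anchors_per_pair=10_000)
    e2 = g2.edges.iloc[0]
    assert e2["chain_length"] > 0.95 * e2["shared_anchors"]


def test_allelism_reverse_complement_chain(rng):
    from polyscaf._kmers import reverse_complement

    base = "".join(rng.choice(list("ACGT"), size=3000))
    g = A.detect_allelic_pairs({"a": base, "b": reverse_complement(base)})
    assert len(g) == 1


def test_correction_zeroes_intra_cluster_edges(small_assignment):
    assignment, extras = small_assignment
    graph = extras["graph"]
    after = extras["after_allelism"]
    assert A.count_intra_cluster_edges(after, graph) == 0
    assert A.count_intra_cluster_edges(assignment, graph) == 0


def test_correction_never_increases_conflicts(rng):
    """Property: on random labelings of a random conflict graph, the
    intra-cluster edge count never increases."""
    for trial in range(10):
        ids = [f"c{i}" for i in range(12)]
        rows = []
        seen = set()
        for _ in range(15):
            i, j = sorted(rng.choice(12, size=2, replace=False))
            if (i, j) in seen:
                continue
            seen.add((i, j))
            rows.append({"contig_i": ids[i], "contig_j": ids[j],
                         "shared_anchors": 10, "chain_length": int(rng.integers(8, 30))})
        graph = A.AllelismGraph(pd.DataFrame(rows))
        assignment = pd.DataFrame({
            "contig": ids,
            "label": rng.integers(0, 4, size=12),
            "confidence": rng.random(12),
            "provenance": "depth",
        })
        before = A.count_intra_cluster_edges(assignment, graph)
        out = A.correct_with_allelism(assignment, graph, K=3)
        assert A.count_intra_cluster_edges(out, graph) <= before


def test_correction_rescues_unassigned_by_elimination():
    graph = A.AllelismGraph(pd.DataFrame([
        {"contig_i": "u", "contig_j": "p1", "shared_anchors": 10, "chain_length": 10},
        {"contig_i": "u", "contig_j": "p2", "shared_anchors": 10, "chain_length": 10},
    ]))
    assignment = pd.DataFrame({
        "contig": ["u", "p1", "p2"],
        "label": [0, 1, 2],
        "confidence": [0.4, 0.9, 0.9],
        "provenance": "depth",
    })
    out = A.correct_with_allelism(assignment, graph, K=3).set_index("contig")
    assert out.at["u", "label"] == 3
    assert out.at["u", "provenance"] == "allelism"


def test_correction_rejects_unknown_contigs():
    graph = A.AllelismGraph(pd.DataFrame([
        {"contig_i": "x", "contig_j": "y", "shared_anchors": 10, "chain_length": 10}]))
    assignment = pd.DataFrame({"contig": ["x"], "label": [1],
                               "confidence": [1.0], "provenance": ["depth"]})
    with pytest.raises(ContractError):
        A.correct_with_allelism(assignment, graph, K=2)


# ------------------------------------------------------------- contact map

def test_contact_map_cells_and_symmetry():
    contigs = {"a": "A" * 100, "b": "C" * 200}
    pairs = pd.DataFrame({
        "contig1": ["a", "a", "a", "b"],
        "pos1":    [10,   90,  10, 190],
        "contig2": ["b", "b", "a", "b"],
        "pos2":    [150,  20,  80,  10],
    })
    cmap = contig_contact_matrix(pairs, contigs)
    i, j = cmap.index["a"], cmap.index["b"]
    assert cmap.cell(i, HEAD, j, TAIL) == 1     # (10, 150)
    assert cmap.cell(j, TAIL, i, HEAD) == 1     # symmetric access
    assert cmap.cell(i, TAIL, j, HEAD) == 1     # (90, 20)
    assert cmap.cell(i, HEAD, i, TAIL) == 1     # self-pair (10, 80)
    assert cmap.cell(j, HEAD, j, TAIL) == 1     # (190, 10) canonicalised
    assert cmap.pair_total(i, j) == 2
    # conservation: total records = sum over unordered pairs
    assert cmap.n_records == 4
    assert cmap.density[i, j] == pytest.approx(2 / (100 * 200 / 1e12))


def test_contact_map_rejects_bad_records_beyond_threshold():
    contigs = {"a": "A" * 100}
    bad = pd.DataFrame({"contig1": ["a", "zz"], "pos1": [5, 1],
                        "contig2": ["a", "a"], "pos2": [500, 2]})
    with pytest.raises(FormatError):
        contig_contact_matrix(bad, contigs)


def test_contact_map_conserves_records(clean_sim):
    cmap = contig_contact_matrix(clean_sim.pairs, clean_sim.contigs)
    total = sum(int(v.sum()) for v in cmap._cells.values())
    assert total == cmap.n_records == len(clean_sim.pairs)


# ---------------------------------------------------------- Hi-C correction

def test_hic_correction_adopts_unassigned_and_fixes_mislabels():
    """Two 3-contig cliques with dense internal links: a mislabelled and an
    unassigned contig are pulled to their clique's label."""
    ids = [f"c{i}" for i in range(6)]
    contigs = {c: "A" * 1000 for c in ids}
    rows = []
    for grp in ([0, 1, 2], [3, 4, 5]):
        for x in grp:
            for y in grp:
                if x < y:
                    rows += [{"contig1": ids[x], "pos1": 10,
                              "contig2": ids[y], "pos2": 10}] * 50
    rows += [{"contig1": ids[2], "pos1": 5, "contig2": ids[3], "pos2": 5}] * 2
    cmap = contig_contact_matrix(pd.DataFrame(rows), contigs)
    assignment = pd.DataFrame({
        "contig": ids,
        "label":      [1, 1, 2, 2, 2, 0],   # c2 mislabelled, c5 unassigned
        "confidence": [0.9] * 6,
        "provenance": "depth",
    })
    out = A.correct_with_contacts(assignment, cmap, K=2).set_index("contig")
    assert out.at["c2", "label"] == 1
    assert out.at["c5", "label"] == 2
    assert out.at["c2", "provenance"] == "hic"


def test_hic_correction_fixed_point_is_stable(small_assignment, small_sim):
    """Re-running the Hi-C correction on its own output changes nothing."""
    assignment, extras = small_assignment
    cmap = extras["contact_map"]
    again = A.correct_with_contacts(assignment, cmap, K=3)
    assert (again.set_index("contig")["label"]
            == assignment.set_index("contig")["label"]).all()


# ----------------------------------------------------------------- composite

def test_full_assignment_matches_truth(small_sim, small_assignment):
    from polyscaf.evaluate import evaluate_assignment

    assignment, _ = small_assignment
    ev = evaluate_assignment(assignment, small_sim.truth)
    assert ev.base_weighted_accuracy >= 0.95
    assert ev.assigned_base_fraction >= 0.9


def test_assignment_is_deterministic(small_sim, pipeline_cfg, small_assignment):
    assignment, _ = small_assignment
    again, _ = A.assign_subgenomes(
        small_sim.contigs, [small_sim.diploid], small_sim.pairs, pipeline_cfg)
    pd.testing.assert_frame_equal(assignment, again)


def test_label_permutation_equivariance(small_sim, small_assignment):
    """Swapping true subgenome identities cannot change the evaluated
    accuracy: scoring is invariant to cluster labelling."""
    from polyscaf.evaluate import evaluate_assignment

    assignment, _ = small_assignment
    ev1 = evaluate_assignment(assignment, small_sim.truth)
    swapped = small_sim.truth.copy()
    swapped["subgenome"] = swapped["subgenome"].map({1: 2, 2: 1, 3: 3})
    ev2 = evaluate_assignment(assignment, swapped)
    assert ev1.base_weighted_accuracy == pytest.approx(ev2.base_weighted_accuracy)
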