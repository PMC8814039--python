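"""Generator contracts: composition, divergence statistics, fragmentation
partitioning, contact counts and determinism."""

import numpy as np
import pandas as pd
import pytest

from polyscaf import simdata
from polyscaf._kmers import reverse_complement
from polyscaf.errors import ParameterError
from polyscaf.params import SimParams


def _mismatch_fraction(a: str, b: str) -> float:
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((aa != bb).mean())


def test_ancestor_base_composition(small_params):
    anc = simdata.simulate_ancestor(small_params)
    assert len(anc) == small_params.n_chromosomes_per_subgenome
    seq = "".join(anc.values())
    n = len(seq)
    gc = (seq.count("G") + seq.count("C")) / n
    p = small_params.gc_fraction
    # 3-sigma binomial band around the target GC fraction
    assert abs(gc - p) < 3 * np.sqrt(p * (1 - p) / n)
    assert set(seq) <= set("ACGT")


def test_divergence_matches_requested_rates(small_params):
    anc = simdata.simulate_ancestor(small_params)
    diploid, poly, chrom_truth = simdata.derive_subgenomes(anc, small_params)
    anc_cat = "".join(anc.values())
    # diploid at d0
    d_obs = _mismatch_fraction(anc_cat, "".join(diploid.values()))
    d0 = small_params.diploid_divergence
    n = len(anc_cat)
    assert abs(d_obs - d0) < 3 * np.sqrt(d0 * (1 - d0) / n)
    # each subgenome at its own d[s]
    for s in range(1, small_params.n_subgenomes + 1):
        d = small_params.subgenome_divergences[s - 1]
        sg_cat = "".join(
            poly[f"sg{s}_chr{c}"]
            for c in range(1, small_params.n_chromosomes_per_subgenome + 1)
        )
        obs = _mismatch_fraction(anc_cat, sg_cat)
        assert abs(obs - d) < 3 * np.sqrt(d * (1 - d) / n)


def test_zero_divergence_is_identity():
    p = SimParams(chromosome_length=20_000, diploid_divergence=0.0,
                  mean_contig_length=5_000, min_contig_length=1_000, seed=4)
    anc = simdata.simulate_ancestor(p)
    diploid, _, _ = simdata.derive_subgenomes(anc, p)
    assert list(diploid.values()) == list(anc.values())


def test_decoration_adds_telomeres_and_centromere(small_params):
    anc = simdata.simulate_ancestor(small_params)
    _, poly, _ = simdata.derive_subgenomes(anc, small_params)
    decorated, feats = simdata.decorate_features(poly, small_params)
    tel = "AAACCCT" * small_params.telomere_copies
    for name, seq in decorated.items():
        base = poly[name]
        assert seq.startswith(reverse_complement(tel))
        assert seq.endswith(tel)
        assert len(seq) == (len(base) + 2 * len(tel)
                            + small_params.centromere_unit * small_params.centromere_copies)
        rows = feats[feats["chromosome"] == name]
        assert set(rows["feature"]) == {"telomere5", "telomere3", "centromere"}
        cen = rows[rows["feature"] == "centromere"].iloc[0]
        # the recorded interval really holds the tandem array
        assert cen["end"] - cen["start"] == (
            small_params.centromere_unit * small_params.centromere_copies)
        seg = seq[cen["start"]:cen["end"]]
        unit = small_params.centromere_unit
        a = np.frombuffer(seg.encode(), dtype=np.uint8)
        ident = (a[:-unit] == a[unit:]).mean()
        assert ident > 0.85  # 5% per-copy mutation leaves high periodic identity


def test_fragmentation_partitions_each_chromosome(small_sim):
    """Kept + discarded intervals tile each chromosome exactly, and each
    contig sequence equals its oriented truth interval."""
    truth = small_sim.truth
    for name, seq in small_sim.polyploid.items():
        kept = truth[truth["chromosome"] == name][["start", "end"]]
        disc = small_sim.discarded[small_sim.discarded["chromosome"] == name][["start", "end"]]
        ivals = sorted(map(tuple, pd.concat([kept, disc]).to_numpy()))
        assert ivals[0][0] == 0 and ivals[-1][1] == len(seq)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            assert e1 == s2  # contiguous, non-overlapping
    for row in truth.itertuples():
        frag = small_sim.polyploid[row.chromosome][row.start:row.end]
        if row.orientation == "-":
            frag = reverse_complement(frag)
        assert small_sim.contigs[row.contig] == frag
        assert row.end - row.start >= small_sim.params.min_contig_length


def test_order_index_is_positional(small_sim):
    for _, grp in small_sim.truth.groupby("chromosome"):
        grp = grp.sort_values("start")
        assert list(grp["order_index"]) == list(range(len(grp)))


def test_contact_count_and_coordinate_ranges(small_sim):
    pairs = small_sim.pairs
    assert len(pairs) == small_sim.params.n_contact_pairs
    lengths = {c: len(s) for c, s in small_sim.contigs.items()}
    for side in (1, 2):
        l = pairs[f"contig{side}"].map(lengths)
        assert l.notna().all()
        assert (pairs[f"pos{side}"] >= 0).all()
        assert (pairs[f"pos{side}"] < l).all()
    assert (pairs["contig1"] <= pairs["contig2"]).all()


def test_clean_contacts_stay_within_subgenome(clean_sim):
    """With mis-mapping and background off, every pair joins two contigs of
    one chromosome."""
    chrom_of = dict(zip(clean_sim.truth["contig"], clean_sim.truth["chromosome"]))
    c1 = clean_sim.pairs["contig1"].map(chrom_of)
    c2 = clean_sim.pairs["contig2"].map(chrom_of)
    assert (c1 == c2).all()


def test_mismap_produces_intersubgenome_contacts(small_sim):
    sg_of = dict(zip(small_sim.truth["contig"], small_sim.truth["subgenome"]))
    s1 = small_sim.pairs["contig1"].map(sg_of)
    s2 = small_sim.pairs["contig2"].map(sg_of)
    cross = float((s1 != s2).mean())
    # two endpoints at m=0.05 each: P(cross) ~= 2*m*(1-m) ~ 0.095
    m = small_sim.params.mismap_fraction
    expect = 2 * m * (1 - m)
    assert 0.5 * expect < cross < 1.5 * expect


def test_separation_power_law_slope():
    """At alpha=1 the log separation is uniform: equal mass per decade."""
    rng = np.random.default_rng(7)
    s = simdata._draw_separation(200_000, 1.0, 1e3, 1e6, rng)
    logs = np.log10(s)
    hist, _ = np.histogram(logs, bins=3, range=(3, 6))
    assert hist.max() / hist.min() < 1.1


def test_simulate_is_deterministic(small_params, small_sim):
    again = simdata.simulate(small_params)
    assert again.contigs == small_sim.contigs
    assert again.diploid == small_sim.diploid
    pd.testing.assert_frame_equal(again.truth, small_sim.truth)
    pd.testing.assert_frame_equal(again.pairs, small_sim.pairs)


def test_different_seeds_differ(small_params):
    other = SimParams(**{**small_params.to_dict(), "seed": 12})
    sim2 = simdata.simulate(other)
    assert sim2.pairs.to_dict() != simdata.simulate(small_params).pairs.to_dict()


def test_invalid_params_rejected():
    with pytest.raises(ParameterError):
        SimParams(n_subgenomes=2)  # divergence tuple length mismatch
    with pytest.raises(ParameterError):
        SimParams(subgenome_divergences=(0.01, 0.01, 0.06))  # not distinct
    with pytest.raises(ParameterError):
        SimParams(gc_fraction=1.5)
    with pytest.raises(ParameterError):
        SimParams(mean_contig_length=100, min_contig_length=5000)


def test_write_outputs_round_trip(tmp_path, small_sim):
    from polyscaf import io as pio

    simdata.write_outputs(small_sim, tmp_path)
    contigs = pio.read_sequences(tmp_path / "contigs.fasta")
    assert contigs == small_sim.contigs
    truth = pio.read_truth(tmp_path / "truth.tsv")
    pd.testing.assert_frame_equal(truth, small_sim.truth)
    pairs = pio.read_pairs(tmp_path / "pairs.tsv", contigs)
    pd.testing.assert_frame_equal(
        pairs, small_sim.pairs, check_dtype=False)
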