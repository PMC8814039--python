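"""Synthetic allopolyploid genome, Hi-C contact and feature simulator.

The generative model: a single random ancestor genome gives rise to a diploid
relative (per-site substitution probability ``diploid_divergence``) and to K
subgenomes (per-site probabilities ``subgenome_divergences``, pairwise
distinct).  Chromosomes are decorated with telomeric ``AAACCCT`` arrays and a
centromeric tandem array of a random 155-bp unit, fragmented into contigs
with exponentially spaced breakpoints, and Hi-C contact pairs are drawn with
power-law distance decay within chromosomes, a small inter-chromosomal
background within subgenomes, and homoeologous endpoint mis-mapping — the
mechanism by which subgenome similarity corrupts Hi-C scaffolding signal.

Substitution-only mutation (no indels) keeps every truth coordinate trivially
mappable between subgenomes.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from ._kmers import reverse_complement
from .errors import ParameterError
from .params import SimParams

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    return _CODE_OF[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``,
    uniformly over the three alternatives."""
    if rate == 0.0:
        return seq
    codes = _encode(seq)
    hits = np.flatnonzero(rng.random(codes.size) < rate)
    codes[hits] = (codes[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return _decode(codes)


# ------------------------------------------------------------------ ancestor

def simulate_ancestor(params: SimParams) -> dict[str, str]:
    """I.i.d. ancestor chromosomes with P(G)+P(C) = gc_fraction."""
    params.validate()
    rng = np.random.default_rng([params.seed, 1])
    gc = params.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for c in range(1, params.n_chromosomes_per_subgenome + 1):
        codes = rng.choice(4, size=params.chromosome_length, p=p)
        out[f"anc_chr{c}"] = _decode(codes.astype(np.int8))
    return out


# --------------------------------------------------------------- divergence

def derive_subgenomes(
    ancestor: dict[str, str], params: SimParams
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Mutate the ancestor into the diploid relative and the K subgenomes.

    Returns (diploid, polyploid chromosomes, chromosome truth skeleton with
    columns chromosome/subgenome/chrom_index).
    """
    rng = np.random.default_rng([params.seed, 2])
    diploid = {}
    for c, (name, seq) in enumerate(ancestor.items(), start=1):
        diploid[f"dip_chr{c}"] = _mutate(seq, params.diploid_divergence, rng)
    polyploid: dict[str, str] = {}
    rows = []
    for s in range(1, params.n_subgenomes + 1):
        d = params.subgenome_divergences[s - 1]
        for c, (name, seq) in enumerate(ancestor.items(), start=1):
            cid = f"sg{s}_chr{c}"
            polyploid[cid] = _mutate(seq, d, rng)
            rows.append({"chromosome": cid, "subgenome": s, "chrom_index": c})
    return diploid, polyploid, pd.DataFrame(rows)


# ---------------------------------------------------------------- decoration

def decorate_features(
    chromosomes: dict[str, str], params: SimParams
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant telomeric and centromeric arrays; return decorated sequences
    plus a feature-truth table (chromosome, feature, start, end, copies).

    The 3' end receives ``telomere_copies`` tandem AAACCCT monomers and the
    5' end the reverse-complement array (same monomer, opposite strand); a
    tandem array of ``centromere_copies`` copies of a random
    ``centromere_unit``-bp unit (5% per-base mutation per copy) is inserted
    at the chromosome midpoint.
    """
    rng = np.random.default_rng([params.seed, 3])
    monomer = "AAACCCT"
    tel_len = len(monomer) * params.telomere_copies
    out: dict[str, str] = {}
    rows = []
    for name, seq in chromosomes.items():
        L0 = len(seq)
        mid = L0 // 2
        if params.centromere_copies > 0:
            unit = _decode(rng.integers(0, 4, size=params.centromere_unit).astype(np.int8))
            array = "".join(
                _mutate(unit, 0.05, rng) for _ in range(params.centromere_copies)
            )
        else:
            array = ""
        tel3 = monomer * params.telomere_copies
        tel5 = reverse_complement(tel3)
        decorated = tel5 + seq[:mid] + array + seq[mid:] + tel3
        out[name] = decorated
        Lf = len(decorated)
        if tel_len:
            rows.append({"chromosome": name, "feature": "telomere5",
                         "start": 0, "end": tel_len, "copies": params.telomere_copies})
            rows.append({"chromosome": name, "feature": "telomere3",
                         "start": Lf - tel_len, "end": Lf, "copies": params.telomere_copies})
        if array:
            rows.append({"chromosome": name, "feature": "centromere",
                         "start": tel_len + mid, "end": tel_len + mid + len(array),
                         "copies": params.centromere_copies})
    cols = ["chromosome", "feature", "start", "end", "copies"]
    return out, pd.DataFrame(rows, columns=cols)


# ------------------------------------------------------------- fragmentation

def fragment_contigs(
    polyploid: dict[str, str],
    chrom_truth: pd.DataFrame,
    params: SimParams,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Cut chromosomes into contigs at exponentially spaced breakpoints.

    Fragments shorter than ``min_contig_length`` are discarded (returned in
    the third table, and logged).  Each kept fragment is reverse-complemented
    with probability 1/2 ('-' orientation).  Returns (contigs, truth,
    discarded) where truth holds one TruthRecord per kept contig.
    """
    rng = np.random.default_rng([params.seed, 4])
    sg_of = dict(zip(chrom_truth["chromosome"], chrom_truth["subgenome"]))
    contigs: dict[str, str] = {}
    truth_rows = []
    discarded_rows = []
    counter = 0
    for name, seq in polyploid.items():
        L = len(seq)
        if L < params.min_contig_length:
            log.warning("chromosome %s shorter than min_contig_length; skipped", name)
            discarded_rows.append({"chromosome": name, "start": 0, "end": L})
            continue
        cuts = [0]
        pos = 0.0
        while True:
            pos += rng.exponential(params.mean_contig_length)
            if pos >= L:
                break
            cuts.append(int(pos))
        cuts.append(L)
        cuts = sorted(set(cuts))
        order = 0
        for start, end in zip(cuts[:-1], cuts[1:]):
            if end - start < params.min_contig_length:
                discarded_rows.append({"chromosome": name, "start": start, "end": end})
                continue
            counter += 1
            cid = f"ctg{counter:05d}"
            frag = seq[start:end]
            orient = "+" if rng.random() < 0.5 else "-"
            if orient == "-":
                frag = reverse_complement(frag)
            contigs[cid] = frag
            truth_rows.append({
                "contig": cid, "subgenome": sg_of[name], "chromosome": name,
                "start": start, "end": end, "orientation": orient,
                "order_index": order,
            })
            order += 1
    if discarded_rows:
        total = sum(r["end"] - r["start"] for r in discarded_rows)
        log.info("discarded %d short fragments (%d bp)", len(discarded_rows), total)
    truth = pd.DataFrame(truth_rows, columns=pio.TRUTH_COLUMNS)
    discarded = pd.DataFrame(discarded_rows, columns=["chromosome", "start", "end"])
    return contigs, truth, discarded


# ------------------------------------------------------------------ contacts

class _GenomeIndex:
    """Maps (chromosome, position) to (contig, offset) through truth intervals."""

    def __init__(self, truth: pd.DataFrame, chrom_lengths: dict[str, int],
                 chrom_truth: pd.DataFrame):
        self.chrom_names = list(chrom_lengths)
        self.chrom_idx = {n: i for i, n in enumerate(self.chrom_names)}
        self.lengths = np.array([chrom_lengths[n] for n in self.chrom_names])
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)))
        ct = chrom_truth.set_index("chromosome")
        self.subgenome = np.array([ct.loc[n, "subgenome"] for n in self.chrom_names])
        self.chrom_index = np.array([ct.loc[n, "chrom_index"] for n in self.chrom_names])
        # chromosome lookup by (subgenome, chrom_index)
        self.by_sg_ci = {
            (int(s), int(c)): i
            for i, (s, c) in enumerate(zip(self.subgenome, self.chrom_index))
        }
        t = truth.copy()
        t["ci"] = t["chromosome"].map(self.chrom_idx)
        t["gstart"] = t["start"] + self.offsets[t["ci"]]
        t["gend"] = t["end"] + self.offsets[t["ci"]]
        t = t.sort_values("gstart").reset_index(drop=True)
        self.gstarts = t["gstart"].to_numpy()
        self.gends = t["gend"].to_numpy()
        self.names = t["contig"].to_numpy()
        self.orient_plus = (t["orientation"] == "+").to_numpy()

    def locate(self, ci: np.ndarray, pos: np.ndarray):
        """Vectorised (chrom idx, pos) -> (contig idx, offset, valid)."""
        g = self.offsets[ci] + pos
        i = np.searchsorted(self.gstarts, g, side="right") - 1
        valid = (i >= 0) & (g < self.gends[np.clip(i, 0, None)])
        i = np.clip(i, 0, None)
        off_plus = g - self.gstarts[i]
        off_minus = self.gends[i] - 1 - g
        off = np.where(self.orient_plus[i], off_plus, off_minus)
        return i, off, valid


def _draw_separation(n: int, alpha: float, s_min: float, s_max: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sample from density proportional to s^-alpha on [s_min, s_max]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return s_min * (s_max / s_min) ** u
    a = 1.0 - alpha
    return (s_min**a + u * (s_max**a - s_min**a)) ** (1.0 / a)


def simulate_contacts(
    truth: pd.DataFrame,
    chrom_lengths: dict[str, int],
    chrom_truth: pd.DataFrame,
    params: SimParams,
) -> pd.DataFrame:
    """Draw exactly ``n_contact_pairs`` Hi-C locus pairs mapped to contigs.

    With probability ``inter_chromosome_background`` a pair joins two
    distinct chromosomes of one subgenome (uniform loci); otherwise both loci
    sit on one chromosome with separation drawn from a truncated power law
    s^-alpha on [1 kb, chromosome length].  Each endpoint is then relocated,
    with probability ``mismap_fraction``, to the homologous coordinate on a
    uniformly chosen homoeologous chromosome — if that coordinate falls in a
    discarded fragment the endpoint keeps its original location.
    """
    if params.n_contact_pairs <= 0:
        raise ParameterError("n_contact_pairs must be positive")
    rng = np.random.default_rng([params.seed, 5])
    gi = _GenomeIndex(truth, chrom_lengths, chrom_truth)
    n_chrom = len(gi.chrom_names)
    K = params.n_subgenomes
    s_min = min(1000.0, float(gi.lengths.min()) / 2)
    want = params.n_contact_pairs
    out_c1, out_p1, out_c2, out_p2 = [], [], [], []
    got = 0
    while got < want:
        batch = max(int((want - got) * 1.4) + 16, 1024)
        inter = rng.random(batch) < params.inter_chromosome_background
        ci1 = rng.integers(0, n_chrom, size=batch)
        ci2 = ci1.copy()
        pos1 = np.zeros(batch, dtype=np.int64)
        pos2 = np.zeros(batch, dtype=np.int64)
        # intra-chromosomal with distance decay
        intra = ~inter
        ni = int(intra.sum())
        if ni:
            L = gi.lengths[ci1[intra]].astype(float)
            sep = np.minimum(_draw_separation(ni, params.decay_exponent, s_min, L.max(), rng), L - 1)
            sep = np.maximum(sep, 1.0)
            x = (rng.random(ni) * (L - sep)).astype(np.int64)
            pos1[intra] = x
            pos2[intra] = x + sep.astype(np.int64)
        # inter-chromosomal background within one subgenome
        nb = int(inter.sum())
        if nb:
            same_sg = gi.subgenome[ci1[inter]]
            # chromosomes of the same subgenome, excluding ci1 when possible
            n_per = params.n_chromosomes_per_subgenome
            if n_per > 1:
                alt = rng.integers(0, n_per - 1, size=nb)
                cur = gi.chrom_index[ci1[inter]] - 1
                alt = np.where(alt >= cur, alt + 1, alt)
                ci2[inter] = [gi.by_sg_ci[(int(s), int(c) + 1)]
                              for s, c in zip(same_sg, alt)]
            pos1[inter] = rng.integers(0, gi.lengths[ci1[inter]])
            pos2[inter] = rng.integers(0, gi.lengths[ci2[inter]])
        # homoeologous mis-mapping at the genomic level, pre-location
        for ci, pos in ((ci1, pos1), (ci2, pos2)):
            if params.mismap_fraction > 0 and K > 1:
                hit = np.flatnonzero(rng.random(batch) < params.mismap_fraction)
                if hit.size:
                    cur_sg = gi.subgenome[ci[hit]]
                    alt = rng.integers(0, K - 1, size=hit.size)
                    alt = np.where(alt >= cur_sg - 1, alt + 1, alt) + 1
                    tgt = np.array([gi.by_sg_ci[(int(s), int(c))]
                                    for s, c in zip(alt, gi.chrom_index[ci[hit]])])
                    tpos = np.minimum(pos[hit], gi.lengths[tgt] - 1)
                    _, _, ok = gi.locate(tgt, tpos)
                    ci[hit[ok]] = tgt[ok]
                    pos[hit[ok]] = tpos[ok]
        i1, o1, v1 = gi.locate(ci1, pos1)
        i2, o2, v2 = gi.locate(ci2, pos2)
        keep = v1 & v2
        out_c1.append(i1[keep]); out_p1.append(o1[keep])
        out_c2.append(i2[keep]); out_p2.append(o2[keep])
        got += int(keep.sum())
    c1 = gi.names[np.concatenate(out_c1)[:want]]
    p1 = np.concatenate(out_p1)[:want]
    c2 = gi.names[np.concatenate(out_c2)[:want]]
    p2 = np.concatenate(out_p2)[:want]
    df = pd.DataFrame({"contig1": c1, "pos1": p1, "contig2": c2, "pos2": p2})
    swap = df["contig1"] > df["contig2"]
    if swap.any():
        df.loc[swap, ["contig1", "pos1", "contig2", "pos2"]] = df.loc[
            swap, ["contig2", "pos2", "contig1", "pos1"]
        ].to_numpy()
    return df


# -------------------------------------------------------------- orchestrator

@dataclass
class SimResult:
    params: SimParams
    ancestor: dict[str, str]
    diploid: dict[str, str]
    polyploid: dict[str, str]          # decorated chromosomes
    chrom_truth: pd.DataFrame          # chromosome, subgenome, chrom_index
    features: pd.DataFrame             # planted feature truth
    contigs: dict[str, str]
    truth: pd.DataFrame                # per-contig TruthRecords
    discarded: pd.DataFrame
    pairs: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.polyploid.items()}


def simulate(params: SimParams) -> SimResult:
    """Run the full generator: ancestor -> divergence -> decoration ->
    fragmentation -> Hi-C contacts.  Deterministic given ``params.seed``."""
    ancestor = simulate_ancestor(params)
    diploid, polyploid, chrom_truth = derive_subgenomes(ancestor, params)
    polyploid, features = decorate_features(polyploid, params)
    contigs, truth, discarded = fragment_contigs(polyploid, chrom_truth, params)
    chrom_lengths = {n: len(s) for n, s in polyploid.items()}
    pairs = simulate_contacts(truth, chrom_lengths, chrom_truth, params)
    return SimResult(params, ancestor, diploid, polyploid, chrom_truth,
                     features, contigs, truth, discarded, pairs)


def write_outputs(sim: SimResult, outdir: str | Path) -> None:
    """Write contigs/diploid/chromosome FASTAs, pairs, truth and feature TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_fasta(sim.contigs, outdir / "contigs.fasta")
    pio.write_fasta(sim.diploid, outdir / "diploid.fasta")
    pio.write_fasta(sim.polyploid, outdir / "chromosomes.fasta")
    pio.write_pairs(sim.pairs, outdir / "pairs.tsv")
    pio.write_truth(sim.truth, outdir / "truth.tsv")
    pio.write_features(sim.features, outdir / "features.tsv")
    pio.dump_config(sim.params.to_dict(), outdir / "sim_params.yaml")
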