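"""Assembly validation and divergence dating.

* subgenome-specific 13-mers: a k-mer is informative for a subgenome when
  its frequency there exceeds ``enrichment_ratio`` (default 10) times the
  maximum frequency in every other subgenome; hierarchical clustering of
  chromosomes on informative-k-mer occurrence vectors should recover the
  subgenome partition exactly on a correctly phased assembly.
* centromere scan: a periodicity scan for tandem arrays of a fixed unit
  length (default 155 bp), reporting the largest array per chromosome.
* telomere scan: counts of the telomeric monomer (default AAACCCT) and its
  reverse complement within each chromosome-end window.
* Ks dating: kernel-density peaks of a Ks sample converted to divergence
  times by T = Ks / (2 r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde

from ._kmers import reverse_complement, valid_canonical
from .errors import ParameterError

log = logging.getLogger(__name__)


# ------------------------------------------------- subgenome-specific k-mers

@dataclass
class KmerPartitionReport:
    k: int
    enrichment_ratio: float
    informative_counts: pd.DataFrame   # chromosomes x subgenome labels (occurrence sums)
    n_informative: dict[int, int]      # subgenome -> number of informative k-mer species
    linkage_matrix: np.ndarray
    grouping: dict[str, int]           # chromosome -> cluster id from the K-cut
    matches_subgenomes: bool           # K-cut groups chromosomes exactly by subgenome


def informative_for(freqs: np.ndarray, ratio: float) -> int:
    """Index (0-based) of the subgenome a k-mer is informative for, or -1.

    Rule: freq_s > ratio * max(freqs of the other subgenomes). Exclusive by
    construction: at most one subgenome can satisfy it when ratio > 1.
    """
    s = int(np.argmax(freqs))
    others = np.delete(freqs, s)
    if freqs[s] > ratio * others.max():
        return s
    return -1


def subgenome_specific_kmers(
    chromosomes_by_subgenome: dict[int, dict[str, str]],
    k_val: int = 13,
    enrichment_ratio: float = 10.0,
) -> KmerPartitionReport:
    """Partition-validation by subgenome-specific k-mers.

    ``chromosomes_by_subgenome`` maps subgenome label -> {chromosome: seq}.
    """
    if enrichment_ratio <= 1:
        raise ParameterError("enrichment_ratio must be > 1")
    sgs = sorted(chromosomes_by_subgenome)
    if len(sgs) < 2:
        log.warning("need >= 2 subgenomes for informative k-mers; none reported")
        empty = pd.DataFrame()
        return KmerPartitionReport(k_val, enrichment_ratio, empty, {}, np.zeros((0, 4)),
                                   {}, False)
    # per-chromosome canonical k-mer counts
    chrom_names: list[str] = []
    chrom_sg: list[int] = []
    chrom_counts: list[tuple[np.ndarray, np.ndarray]] = []
    for s in sgs:
        for name, seq in chromosomes_by_subgenome[s].items():
            codes = valid_canonical(seq, k_val, exact=True)
            u, c = np.unique(codes, return_counts=True)
            chrom_names.append(name)
            chrom_sg.append(s)
            chrom_counts.append((u, c))
    # per-subgenome frequency table over the union of codes
    union = np.unique(np.concatenate([u for u, _ in chrom_counts]))
    freq = np.zeros((union.size, len(sgs)), dtype=np.int64)
    for (u, c), s in zip(chrom_counts, chrom_sg):
        col = sgs.index(s)
        pos = np.searchsorted(union, u)
        np.add.at(freq, (pos, col), c)
    # vectorised informativeness: freq_s > ratio * max(others)
    top = freq.max(axis=1)
    arg = freq.argmax(axis=1)
    tmp = freq.copy()
    tmp[np.arange(union.size), arg] = -1
    second = tmp.max(axis=1)
    informative = top > enrichment_ratio * second
    inf_sg = np.where(informative, arg, -1)
    n_informative = {sgs[s]: int((inf_sg == s).sum()) for s in range(len(sgs))}
    # per-chromosome occurrence sums of each subgenome's informative k-mers
    mat = np.zeros((len(chrom_names), len(sgs)), dtype=np.int64)
    for row, (u, c) in enumerate(chrom_counts):
        pos = np.searchsorted(union, u)
        sg_of_kmer = inf_sg[pos]
        for col in range(len(sgs)):
            mat[row, col] = c[sg_of_kmer == col].sum()
    counts_df = pd.DataFrame(mat, index=chrom_names,
                             columns=[f"sg{s}" for s in sgs])
    # average-linkage Euclidean dendrogram, cut at K clusters
    if len(chrom_names) >= 2:
        Z = linkage(mat.astype(float), method="average", metric="euclidean")
        cut = fcluster(Z, t=len(sgs), criterion="maxclust")
    else:
        Z = np.zeros((0, 4))
        cut = np.ones(len(chrom_names), dtype=int)
    grouping = dict(zip(chrom_names, (int(x) for x in cut)))
    # does the K-cut match the subgenome partition exactly?
    by_cluster: dict[int, set[int]] = {}
    for name, s, cl in zip(chrom_names, chrom_sg, cut):
        by_cluster.setdefault(int(cl), set()).add(s)
    matches = (len(by_cluster) == len(sgs)
               and all(len(v) == 1 for v in by_cluster.values()))
    return KmerPartitionReport(k_val, enrichment_ratio, counts_df, n_informative,
                               Z, grouping, matches)


# ------------------------------------------------------------- feature scans

@dataclass
class TandemArray:
    start: int
    end: int
    unit_length: int
    copies: float
    identity: float


def find_tandem_centromere(
    sequence: str,
    unit_length: int = 155,
    min_copies: int = 10,
    min_identity: float = 0.8,
) -> list[TandemArray]:
    """Detect tandem arrays of period ``unit_length`` by self-match scanning.

    Positions where ``seq[i] == seq[i + unit_length]`` are smoothed over one
    unit; maximal runs whose per-window identity stays >= ``min_identity``
    and that span >= ``min_copies`` units are reported, largest first.
    """
    if unit_length < 2:
        raise ParameterError("unit_length must be >= 2")
    L = len(sequence)
    if L < unit_length * (min_copies + 1):
        return []
    a = np.frombuffer(sequence.encode(), dtype=np.uint8)
    match = (a[:-unit_length] == a[unit_length:]).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(match)))
    # identity over one-unit windows of the match profile
    win = unit_length
    ident = (cs[win:] - cs[:-win]) / win
    good = ident >= min_identity
    arrays: list[TandemArray] = []
    i = 0
    n = good.size
    min_span = unit_length * (min_copies - 1)  # match profile span for min_copies units
    while i < n:
        if not good[i]:
            i += 1
            continue
        j = i
        while j < n and good[j]:
            j += 1
        span = (j - i) + win  # matched-period region in the profile
        if span >= min_span:
            start, end = i, min(j + 2 * win, L)
            seg = match[i : j + win]
            arrays.append(TandemArray(
                start=start, end=end, unit_length=unit_length,
                copies=round((end - start) / unit_length, 2),
                identity=float(seg.mean()) if seg.size else 0.0,
            ))
        i = j
    arrays.sort(key=lambda t: (-(t.end - t.start), t.start))
    return arrays


@dataclass
class TelomereCall:
    end: str            # '5p' or '3p'
    present: bool
    copies: int


def find_telomeres(
    sequence: str,
    monomer: str = "AAACCCT",
    end_window: int = 5000,
    min_copies: int = 10,
) -> dict[str, TelomereCall]:
    """Count the telomeric monomer (both strands) in each chromosome-end window."""
    if not monomer:
        raise ParameterError("monomer must be non-empty")
    rc = reverse_complement(monomer)
    five = sequence[:end_window]
    three = sequence[-end_window:]
    out = {}
    for label, window in (("5p", five), ("3p", three)):
        n = window.count(monomer) + window.count(rc)
        out[label] = TelomereCall(label, n >= min_copies, n)
    return out


# ------------------------------------------------------------------ Ks peaks

def estimate_ks_peak(
    values,
    bandwidth: str | float = "silverman",
    min_values: int = 30,
    prominence_floor: float = 0.1,
    grid_points: int = 2048,
) -> list[float]:
    """Gaussian-KDE peak positions of a Ks sample, densest first.

    Local maxima below ``prominence_floor`` of the global density maximum are
    suppressed.  An all-identical sample returns that value directly.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_values:
        raise ParameterError(f"need >= {min_values} Ks values, got {v.size}")
    if np.any(v < 0):
        raise ParameterError("Ks values must be >= 0")
    if np.ptp(v) == 0:
        return [float(v[0])]
    kde = gaussian_kde(v, bw_method=bandwidth)
    grid = np.linspace(0.0, v.max(), grid_points)
    dens = kde(grid)
    peaks = argrelmax(dens)[0]
    if dens[0] > dens[1]:
        peaks = np.concatenate(([0], peaks))
    if dens[-1] > dens[-2]:
        peaks = np.concatenate((peaks, [grid_points - 1]))
    floor = prominence_floor * dens.max()
    peaks = [int(p) for p in peaks if dens[int(p)] >= floor]
    peaks.sort(key=lambda p: -dens[p])
    return [float(grid[p]) for p in peaks]


def ks_divergence_time(ks_peak: float, rate: float) -> float:
    """Divergence time in years: T = Ks / (2 r)."""
    if rate <= 0:
        raise ParameterError("substitution rate must be > 0")
    if ks_peak < 0:
        raise ParameterError("Ks must be >= 0")
    return ks_peak / (2.0 * rate)


def ks_divergence_time_mya(ks_peak: float, rate: float) -> float:
    """Divergence time in Mya, one-decimal reporting precision."""
    return round(ks_divergence_time(ks_peak, rate) / 1e6, 1)
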