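"""End-resolved Hi-C contact map between contigs.

An endpoint is 'head' when its offset falls in the first half of the contig,
'tail' otherwise; each unordered contig pair carries a 2x2 count table over
end combinations, the directional signal used for contig orientation.
Pair link densities are normalised by the length product (contacts per Mb^2),
making them comparable across contig sizes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import FormatError

log = logging.getLogger(__name__)

HEAD, TAIL = 0, 1


class ContactMap:
    """Symmetric end-resolved contact counts over a fixed contig universe."""

    def __init__(self, contig_ids: list[str], lengths: np.ndarray,
                 cells: dict[tuple[int, int], np.ndarray], n_records: int,
                 n_rejected: int = 0):
        self.contig_ids = list(contig_ids)
        self.index = {c: i for i, c in enumerate(self.contig_ids)}
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self._cells = cells  # (i, j) with i <= j -> 4-vector [e_i*2+e_j]
        self.n_records = n_records
        self.n_rejected = n_rejected
        n = len(self.contig_ids)
        dens = np.zeros((n, n))
        tot = np.zeros((n, n))
        for (i, j), v in cells.items():
            t = float(v.sum())
            tot[i, j] = tot[j, i] = t
            d = t / (self.lengths[i] * self.lengths[j] / 1e12)
            dens[i, j] = dens[j, i] = d
        self.totals = tot
        self.density = dens

    # -- accessors -----------------------------------------------------------
    def cell(self, i: int, ei: int, j: int, ej: int) -> int:
        """Count for (contig i, end ei) x (contig j, end ej); symmetric."""
        if i > j or (i == j and ei > ej):
            i, ei, j, ej = j, ej, i, ei
        v = self._cells.get((i, j))
        return 0 if v is None else int(v[ei * 2 + ej])

    def pair_total(self, i: int, j: int) -> int:
        return int(self.totals[i, j])

    def contig_total(self, i: int) -> int:
        return int(self.totals[i].sum())

    @property
    def n_contigs(self) -> int:
        return len(self.contig_ids)


def contig_contact_matrix(
    pairs: pd.DataFrame,
    contigs: dict[str, str],
    max_reject_fraction: float = 0.01,
) -> ContactMap:
    """Count contact-pair records into an end-resolved :class:`ContactMap`.

    Records naming unknown contigs or out-of-range offsets are rejected and
    counted; more than ``max_reject_fraction`` rejections is a hard error.
    """
    ids = list(contigs)
    index = {c: i for i, c in enumerate(ids)}
    lengths = np.array([len(contigs[c]) for c in ids], dtype=np.int64)
    n_in = len(pairs)
    if n_in == 0:
        return ContactMap(ids, lengths, {}, 0, 0)

    i1 = pairs["contig1"].map(index)
    i2 = pairs["contig2"].map(index)
    p1 = pairs["pos1"].to_numpy()
    p2 = pairs["pos2"].to_numpy()
    known = i1.notna() & i2.notna()
    a = i1.fillna(0).to_numpy(dtype=np.int64)
    b = i2.fillna(0).to_numpy(dtype=np.int64)
    ok = known.to_numpy() & (p1 >= 0) & (p2 >= 0) & (p1 < lengths[a]) & (p2 < lengths[b])
    n_rej = int((~ok).sum())
    if n_rej:
        log.warning("rejected %d/%d contact records", n_rej, n_in)
        if n_rej / n_in > max_reject_fraction:
            raise FormatError(
                f"{n_rej}/{n_in} contact records rejected (unknown contig or bad offset)"
            )
    a, b, p1, p2 = a[ok], b[ok], p1[ok], p2[ok]
    e1 = (p1 >= lengths[a] / 2).astype(np.int64)
    e2 = (p2 >= lengths[b] / 2).astype(np.int64)
    # canonical (i <= j; for self-pairs order the ends)
    swap = (a > b) | ((a == b) & (e1 > e2))
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    f1 = np.where(swap, e2, e1)
    f2 = np.where(swap, e1, e2)
    key = ((a2 * len(ids) + b2) * 2 + f1) * 2 + f2
    uk, counts = np.unique(key, return_counts=True)
    cells: dict[tuple[int, int], np.ndarray] = {}
    for k, c in zip(uk, counts):
        cell = int(k % 4)
        ij = int(k // 4)
        i, j = divmod(ij, len(ids))
        v = cells.setdefault((i, j), np.zeros(4, dtype=np.int64))
        v[cell] += c
    return ContactMap(ids, lengths, cells, int(ok.sum()), n_rej)
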