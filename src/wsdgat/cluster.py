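"""Greedy identity clustering of homolog proteins into OPUs.

OPUs (operational protein units) are the protein-space analogue of OTUs:
sequences are sorted longest-first and each joins the first existing cluster
whose representative it matches at or above the identity cutoff (0.8 by
default), else founds a new cluster — the classic greedy incremental scheme.
Identity is computed from a global affine-gap alignment (match +1, mismatch
0, gap open -10, extend -1 in score space) as identical aligned residues
divided by the shorter sequence's length; the denominator convention is
configurable. Corrected per-sample abundances of each OPU sum member copy
weights (1.0 for unassembled members, scaffold read depth for assembled
ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_NEG = -1e30


def _gotoh_matrices(a: str, b: str, gap_open: float, gap_extend: float):
    """Fill the three Gotoh state matrices for global alignment.

    States: M (a[i-1] aligned to b[j-1]), X (gap in b, consuming a),
    Y (gap in a, consuming b). A gap of length k costs
    ``gap_open + (k-1) * gap_extend``. Direct X<->Y transitions are omitted;
    with non-negative match scores and these penalties they are never
    optimal.
    """
    n, m = len(a), len(b)
    sa = np.frombuffer(a.encode(), dtype=np.uint8)
    sb = np.frombuffer(b.encode(), dtype=np.uint8)
    match = (sa[:, None] == sb[None, :]).astype(float)  # +1 match, 0 mismatch

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = gap_open + gap_extend * np.arange(n)
    if m:
        Y[0, 1:] = gap_open + gap_extend * np.arange(m)

    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = match[i - 1] + best_prev[:-1]
        X[i, 1:] = np.maximum(M[i - 1, 1:] + gap_open, X[i - 1, 1:] + gap_extend)
        # Y has a within-row dependence; solve it with a running max:
        # Y[i,j] = max(M[i,j-1]+open, Y[i,j-1]+ext)
        #        = ext*j + max over k<j of (M[i,k]+open-ext*(k+1)), seeded
        #          by the j=0 boundary.
        cand = M[i, :-1] + gap_open - gap_extend * js
        seed = Y[i, 0]  # -inf boundary
        W = np.maximum.accumulate(np.maximum(cand, np.concatenate(([seed], cand[:-1]))))
        Y[i, 1:] = W + gap_extend * js
    return M, X, Y, match


def align_global(
    a: str, b: str, gap_open: float = -10.0, gap_extend: float = -1.0
) -> tuple[float, int, int]:
    """Global affine-gap alignment of two protein sequences.

    Returns ``(score, n_identical, alignment_length)``. The traceback is
    deterministic: ties prefer the diagonal state, then a gap in ``b``, then
    a gap in ``a``.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    M, X, Y, match = _gotoh_matrices(a, b, gap_open, gap_extend)
    n, m = len(a), len(b)
    tol = 1e-9
    finals = {"M": M[n, m], "X": X[n, m], "Y": Y[n, m]}
    score = max(finals.values())
    state = next(s for s in ("M", "X", "Y") if finals[s] >= score - tol)

    i, j = n, m
    ident = 0
    length = 0
    while i > 0 or j > 0:
        length += 1
        if state == "M":
            if match[i - 1, j - 1] > 0.5:
                ident += 1
            target = M[i, j] - match[i - 1, j - 1]
            i, j = i - 1, j - 1
            for s, v in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(v - target) <= tol:
                    state = s
                    break
        elif state == "X":
            if abs(M[i - 1, j] + gap_open - X[i, j]) <= tol:
                state = "M"
            i -= 1
        else:  # Y
            if abs(M[i, j - 1] + gap_open - Y[i, j]) <= tol:
                state = "M"
            j -= 1
    return float(score), ident, length


def pairwise_identity(
    a: str,
    b: str,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    denominator: str = "shorter",
) -> float:
    """Fraction of identical aligned residues between two proteins.

    ``denominator`` selects the identity convention: ``"shorter"`` (identical
    residues / length of the shorter sequence, the incremental-clustering
    tool convention) or ``"alignment"`` (identical residues / alignment
    length including gap columns).
    """
    if a == b:
        return 1.0
    _, ident, length = align_global(a, b, gap_open, gap_extend)
    if denominator == "shorter":
        return ident / min(len(a), len(b))
    if denominator == "alignment":
        return ident / length
    raise ValueError("denominator must be 'shorter' or 'alignment'")


# ---------------------------------------------------------------------------
# Greedy incremental clustering
# ---------------------------------------------------------------------------

@dataclass
class OPU:
    opu_id: str
    representative_id: str
    member_ids: list[str]

    @property
    def n_sequences(self) -> int:
        return len(self.member_ids)


def greedy_cluster(
    seqs: Mapping[str, str],
    cutoff: float = 0.8,
    denominator: str = "shorter",
) -> list[OPU]:
    """Cluster sequences into OPUs by greedy incremental identity clustering.

    Sequences are processed by descending length (ties: ascending id), which
    makes the result canonical — invariant to input order. Each sequence
    joins the first (oldest) cluster whose representative identity is at or
    above ``cutoff``; representatives are founding members, hence the longest
    in their cluster.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    for sid, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence {sid!r}")
    order = sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))
    reps: list[tuple[str, str]] = []  # (rep_id, rep_seq) in founding order
    members: list[list[str]] = []
    cache: dict[tuple[str, str], float] = {}
    for sid in order:
        seq = seqs[sid]
        placed = False
        for ci, (rid, rseq) in enumerate(reps):
            key = (rseq, seq)
            ident = cache.get(key)
            if ident is None:
                ident = pairwise_identity(rseq, seq, denominator=denominator)
                cache[key] = ident
            if ident >= cutoff:
                members[ci].append(sid)
                placed = True
                break
        if not placed:
            reps.append((sid, seq))
            members.append([sid])
    return [
        OPU(f"OPU{ci + 1}", rid, mids)
        for ci, ((rid, _), mids) in enumerate(zip(reps, members))
    ]


# ---------------------------------------------------------------------------
# OPU x sample abundance table
# ---------------------------------------------------------------------------

@dataclass
class OPUTable:
    """OPUs x samples matrix of corrected abundances with row metadata
    (representative id and raw member count)."""

    abundance: pd.DataFrame  # index: opu_id, columns: sample_id
    meta: pd.DataFrame  # index: opu_id; representative_id, n_sequences

    def to_sample_matrix(self) -> pd.DataFrame:
        """Samples x OPUs orientation used by the community statistics."""
        return self.abundance.T

    def write(self, path: str | Path) -> None:
        out = self.meta.join(self.abundance)
        out.index.name = "opu_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "OPUTable":
        df = pd.read_csv(path, sep="\t", index_col="opu_id")
        meta = df[["representative_id", "n_sequences"]]
        return cls(df.drop(columns=["representative_id", "n_sequences"]), meta)


def opu_abundance(
    opus: Sequence[OPU], weights: pd.DataFrame
) -> OPUTable:
    """Corrected OPU x sample abundance: each cell sums the copy weights of
    that OPU's members observed in that sample.

    ``weights`` needs columns ``protein_id``, ``sample_id``, ``weight``
    (1.0 for unassembled members, scaffold read depth for assembled ones).
    A member without a weight row is an error.
    """
    w = weights.set_index("protein_id")
    samples = sorted(w["sample_id"].unique())
    data = np.zeros((len(opus), len(samples)))
    scol = {s: k for k, s in enumerate(samples)}
    for oi, opu in enumerate(opus):
        for mid in opu.member_ids:
            if mid not in w.index:
                raise ValueError(f"OPU member {mid!r} has no weight entry")
            row = w.loc[mid]
            data[oi, scol[row["sample_id"]]] += float(row["weight"])
    abundance = pd.DataFrame(
        data, index=[o.opu_id for o in opus], columns=samples
    )
    meta = pd.DataFrame(
        {
            "representative_id": [o.representative_id for o in opus],
            "n_sequences": [o.n_sequences for o in opus],
        },
        index=abundance.index,
    )
    return OPUTable(abundance, meta)


def filter_opus(table: OPUTable, min_sequences: int = 10) -> OPUTable:
    """Retain OPUs with at least ``min_sequences`` raw member sequences
    (boundary inclusive), preserving row order. Idempotent."""
    keep = table.meta.index[table.meta["n_sequences"] >= min_sequences]
    return OPUTable(table.abundance.loc[keep].copy(), table.meta.loc[keep].copy())
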