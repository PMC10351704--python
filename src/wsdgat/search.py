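"""Profile-based detection of marker-domain homologs in protein sets.

The detector is an ungapped position-specific scoring matrix (PSSM) built
from a seed alignment, with E-values calibrated on random decoy sequences
via a maximum-likelihood Gumbel fit to decoy maximum-window scores. Hits at
or below the E-value cutoff (1e-5 by default, the conventional domain-search
threshold) are reported, one best hit per protein per domain. A standard
whitespace-delimited domain-hit table can be ingested instead of running the
built-in scan, so externally produced profile-HMM annotations are a
first-class input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .simulate import AMINO_ACIDS, BACKGROUND, seq_to_ints

logger = logging.getLogger(__name__)


class ProfileFormatError(ValueError):
    """Raised for malformed alignments or hit tables."""


class CalibrationError(RuntimeError):
    """Raised when decoy scores carry no usable signal for a Gumbel fit."""


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_id: str
    bit_score: float
    e_value: float
    start: int  # 1-based inclusive envelope on the protein
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("hit envelope start > end")
        if not math.isfinite(self.e_value) or self.e_value < 0:
            raise ValueError("e_value must be finite and >= 0")


@dataclass(frozen=True)
class ProfileModel:
    """Ungapped log-odds profile over the 20-letter amino-acid alphabet.

    ``scores`` is an (L, 20) matrix in bits; ``gumbel_loc``/``gumbel_scale``
    are the calibrated null-distribution parameters of the maximum window
    score of a background-sampled decoy (None before calibration).
    """

    domain_id: str
    scores: np.ndarray
    background: np.ndarray
    gumbel_loc: float | None = None
    gumbel_scale: float | None = None
    n_decoys: int = 0

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.gumbel_loc is not None

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.scores, axis=1))


def build_profile(
    alignment: Sequence[str],
    domain_id: str = "PF03007",
    pseudocount: float = 0.5,
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a PSSM from an aligned set of protein sequences.

    Columns with more than ``max_gap_fraction`` gaps are dropped. Column
    scores are log2 of (pseudocounted column frequency / background
    frequency); the per-residue pseudocount is ``pseudocount * 20 * bg(aa)``,
    i.e. a background-proportional Dirichlet prior with total weight
    ``pseudocount * 20``.
    """
    rows = [s.upper() for s in alignment]
    if len(rows) < 2:
        raise ProfileFormatError("alignment needs at least 2 sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ProfileFormatError("ragged alignment: unequal sequence lengths")
    gap_chars = {"-", "."}
    kept_cols = []
    for j in range(width):
        col = [r[j] for r in rows]
        if sum(c in gap_chars for c in col) / len(col) <= max_gap_fraction:
            kept_cols.append(col)
    if len(kept_cols) < 10:
        raise ProfileFormatError(
            f"profile too short after gap filtering ({len(kept_cols)} columns)"
        )
    pc_total = pseudocount * 20.0
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    scores = np.zeros((len(kept_cols), 20))
    for j, col in enumerate(kept_cols):
        counts = np.zeros(20)
        for c in col:
            if c in aa_index:
                counts[aa_index[c]] += 1.0
        n = counts.sum()
        freqs = (counts + pc_total * BACKGROUND) / (n + pc_total)
        scores[j] = np.log2(freqs / BACKGROUND)
    return ProfileModel(domain_id, scores, BACKGROUND.copy())


def _window_scores(profile: ProfileModel, seq_ints: np.ndarray) -> np.ndarray:
    """Ungapped window scores at every offset (empty if sequence < L)."""
    L = profile.length
    if len(seq_ints) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(seq_ints, L)
    return profile.scores[np.arange(L), windows].sum(axis=1)


def best_window_score(profile: ProfileModel, seq: str) -> tuple[float, int] | None:
    """Best (max) window score and its 0-based offset; ties go to the
    earliest offset. None if the protein is shorter than the profile."""
    scores = _window_scores(profile, seq_to_ints(seq))
    if scores.size == 0:
        return None
    off = int(np.argmax(scores))
    return float(scores[off]), off


def calibrate_evalue(
    profile: ProfileModel,
    decoy_lengths: Sequence[int] | int = 200,
    n_decoys: int = 1000,
    seed: int = 0,
) -> ProfileModel:
    """Calibrate E-value semantics by ML Gumbel fit to decoy maxima.

    Decoys are i.i.d. background-frequency proteins; the fitted Gumbel
    describes the null distribution of the best window score, and
    ``E(s) = N_db * (1 - GumbelCDF(s))`` for a database of N_db proteins.
    """
    if n_decoys < 500:
        raise ValueError("n_decoys must be >= 500 for a stable tail fit")
    if isinstance(decoy_lengths, int):
        decoy_lengths = [decoy_lengths] * n_decoys
    else:
        decoy_lengths = list(decoy_lengths)
        if len(decoy_lengths) != n_decoys:
            raise ValueError("decoy_lengths must match n_decoys")
    if min(decoy_lengths) < profile.length:
        raise ValueError("decoy length shorter than profile length")
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_decoys)
    for i, ln in enumerate(decoy_lengths):
        decoy = rng.choice(20, size=ln, p=profile.background)
        maxima[i] = _window_scores(profile, decoy).max()
    if np.std(maxima) < 1e-9:
        raise CalibrationError("degenerate decoy score variance")
    loc, scale = stats.gumbel_r.fit(maxima)
    return replace(profile, gumbel_loc=float(loc), gumbel_scale=float(scale),
                   n_decoys=n_decoys)


def score_to_evalue(profile: ProfileModel, score: float, n_db: int) -> float:
    if not profile.calibrated:
        raise CalibrationError("profile is not calibrated")
    return float(
        n_db * stats.gumbel_r.sf(score, profile.gumbel_loc, profile.gumbel_scale)
    )


def scan_proteins(
    proteins: Mapping[str, str] | Iterable[tuple[str, str]],
    profile: ProfileModel,
    e_cutoff: float = 1e-5,
    n_db: int | None = None,
) -> list[DomainHit]:
    """Scan proteins with a calibrated profile; emit the best hit per
    protein when its E-value is at or below ``e_cutoff``.

    Proteins shorter than the profile are skipped with a log entry. The
    effective database size for E-values defaults to the number of scanned
    proteins.
    """
    if not profile.calibrated:
        raise CalibrationError("profile must be calibrated before scanning")
    items = list(proteins.items()) if isinstance(proteins, Mapping) else list(proteins)
    if n_db is None:
        n_db = len(items)
    hits = []
    n_skipped = 0
    for pid, seq in items:
        best = best_window_score(profile, seq)
        if best is None:
            n_skipped += 1
            logger.info("skipping %s: shorter than profile (%d aa)",
                        pid, profile.length)
            continue
        score, off = best
        e = score_to_evalue(profile, score, n_db)
        if e <= e_cutoff:
            hits.append(
                DomainHit(pid, profile.domain_id, round(score, 4), e,
                          off + 1, off + profile.length)
            )
    if n_skipped:
        logger.info("skipped %d proteins shorter than the profile", n_skipped)
    return hits


# ---------------------------------------------------------------------------
# Hit-table serialization (whitespace-delimited, '#' comments)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("protein_id", "domain_id", "bit_score", "e_value", "start", "end")


def write_hit_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + " ".join(_TABLE_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.protein_id} {h.domain_id} {h.bit_score:.4f} "
                f"{h.e_value:.6g} {h.start} {h.end}\n"
            )


def ingest_domain_table(path: str | Path, e_cutoff: float = 1e-5) -> list[DomainHit]:
    """Parse a whitespace-delimited per-domain hit table, filter at the
    E-value cutoff, and keep the best-scoring hit per protein per domain.

    Malformed lines are counted and logged, not fatal; a file with no
    parsable rows raises :class:`ProfileFormatError`.
    """
    best: dict[tuple[str, str], DomainHit] = {}
    n_malformed = 0
    n_parsed = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                n_malformed += 1
                continue
            try:
                hit = DomainHit(parts[0], parts[1], float(parts[2]),
                                float(parts[3]), int(parts[4]), int(parts[5]))
            except (ValueError, IndexError):
                n_malformed += 1
                continue
            n_parsed += 1
            if hit.e_value > e_cutoff:
                continue
            key = (hit.protein_id, hit.domain_id)
            if key not in best or hit.bit_score > best[key].bit_score:
                best[key] = hit
    if n_parsed == 0:
        raise ProfileFormatError(f"{path}: no parsable hit rows")
    if n_malformed:
        logger.warning("%s: %d malformed lines skipped", path, n_malformed)
    return sorted(best.values(), key=lambda h: (h.protein_id, h.domain_id))
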