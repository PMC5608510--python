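"""PWM scanning and motif-enrichment selectivity across gene signatures.

ARBS sequences (extended ±1 kb) belonging to each coregulator-dependent gene
signature are scanned on both strands with log-odds position weight matrices;
per (motif, signature) the fraction of sequences with at least one hit is
compared to a background rate with an upper-tail binomial test, BH-adjusted
across motifs within each signature. A motif is "selective" when it is
enriched in at least one and at most ``max_signatures`` signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Pseudocount applied to PWM probabilities before log-odds.
PSEUDOCOUNT = 1e-3

#: Default hit threshold as a fraction of the maximum achievable log-odds score.
DEFAULT_SCORE_FRACTION = 0.8


@dataclass(frozen=True)
class PWM:
    """A position weight matrix: L x 4 base probabilities (A, C, G, T order)."""

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM probs must be L x 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.probs.shape[0]

    def log_odds(self, pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
        """log2(p/bg) with pseudocount-regularized, renormalized probabilities."""
        p = self.probs + pseudocount
        p /= p.sum(axis=1, keepdims=True)
        bg = self.background + pseudocount
        bg /= bg.sum()
        return np.log2(p / bg)

    def max_score(self, pseudocount: float = PSEUDOCOUNT) -> float:
        return float(self.log_odds(pseudocount).max(axis=1).sum())

    def default_threshold(
        self,
        fraction: float = DEFAULT_SCORE_FRACTION,
        pseudocount: float = PSEUDOCOUNT,
    ) -> float:
        return fraction * self.max_score(pseudocount)

    @classmethod
    def from_counts(cls, motif_id: str, counts, background=None) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = counts / counts.sum(axis=1, keepdims=True)
        if background is None:
            return cls(motif_id, probs)
        return cls(motif_id, probs, np.asarray(background, dtype=float))

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str, p_match: float = 0.85) -> "PWM":
        """A synthetic PWM placing ``p_match`` on the consensus base ('N' = uniform)."""
        rows = []
        off = (1.0 - p_match) / 3.0
        for b in consensus.upper():
            if b == "N":
                rows.append([0.25] * 4)
            else:
                row = [off] * 4
                row[_BASE_INDEX[b]] = p_match
                rows.append(row)
        return cls(motif_id, np.array(rows))


def read_jaspar(path) -> list[PWM]:
    """Read PWMs from a JASPAR-format count/probability file (via biopython)."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.column_stack([m.counts[b] for b in BASES]).astype(float)
            out.append(PWM.from_counts(m.matrix_id or m.name, counts))
    return out


def read_matrix_table(path) -> list[PWM]:
    """Read PWMs from a minimal MEME-like text format.

    Blocks of the form::

        MOTIF <id>
        <pA> <pC> <pG> <pT>
        ...

    separated by blank lines; optional ``BACKGROUND <pA> <pC> <pG> <pT>``
    header applies to all motifs that follow.
    """
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    motif_id, rows = None, []

    def flush():
        nonlocal motif_id, rows
        if motif_id is not None:
            pwms.append(PWM(motif_id, np.array(rows, dtype=float), background))
        motif_id, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0].upper() == "BACKGROUND":
                background = np.array(parts[1:5], dtype=float)
            elif parts[0].upper() == "MOTIF":
                flush()
                motif_id = parts[1]
            else:
                rows.append([float(x) for x in parts[:4]])
    flush()
    return pwms


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> -1 (skipped windows)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanResult:
    has_hit: bool
    hits: list[tuple[int, str]]  # (0-based forward-strand window start, strand)


def scan_sequence(
    seq: str,
    pwm: PWM,
    score_min: float | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> ScanResult:
    """Scan both strands of ``seq`` with the PWM's log-odds matrix.

    A hit is any window whose summed log2(p/bg) score reaches ``score_min``
    (default: 80% of the PWM's maximum achievable score). Windows containing
    non-ACGT characters are skipped (logged). Positions are 0-based window
    starts on the forward strand for both orientations.
    """
    L = len(pwm)
    if len(seq) < L:
        raise ValueError(f"sequence shorter than motif ({len(seq)} < {L})")
    if score_min is None:
        score_min = pwm.default_threshold(pseudocount=pseudocount)
    lo = pwm.log_odds(pseudocount)
    lo_rc = lo[::-1, ::-1]  # scanning the reverse strand on forward coordinates
    enc = _encode(seq)
    n_win = len(seq) - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = (windows >= 0).all(axis=1)
    if not valid.all():
        logger.info(
            "scan_sequence: %d/%d windows skipped (non-ACGT characters)",
            int((~valid).sum()), n_win,
        )
    hits: list[tuple[int, str]] = []
    idx = np.arange(L)
    safe = np.where(windows < 0, 0, windows)
    fwd_scores = lo[idx, safe].sum(axis=1)
    rev_scores = lo_rc[idx, safe].sum(axis=1)
    for pos in np.nonzero(valid & (fwd_scores >= score_min))[0]:
        hits.append((int(pos), "+"))
    for pos in np.nonzero(valid & (rev_scores >= score_min))[0]:
        hits.append((int(pos), "-"))
    hits.sort()
    return ScanResult(bool(hits), hits)


def _hit_count(seqs: Sequence[str], pwm: PWM, score_min: float | None, pseudocount: float) -> int:
    return sum(
        1
        for s in seqs
        if len(s) >= len(pwm) and scan_sequence(s, pwm, score_min, pseudocount).has_hit
    )


def motif_enrichment(
    fg_seqs: Mapping[str, Sequence[str]],
    bg_seqs: Sequence[str],
    pwms: Sequence[PWM],
    score_min: float | None = None,
    alpha: float = 0.05,
    method: str = "binomial",
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-(motif, signature) overrepresentation of motif hits vs background.

    ``fg_seqs`` maps signature label -> foreground sequences. For each motif
    and signature, k_fg of n_fg foreground sequences contain >=1 hit; the
    background hit rate comes from ``bg_seqs``. ``method="binomial"`` tests
    P(X >= k_fg | n_fg, k_bg/n_bg) upper-tail (backgrounds are large and
    resampled); ``method="hypergeometric"`` pools fg+bg for an exact test.
    p-values are BH-adjusted across motifs within each signature; the
    ``enriched`` flag is set at adjusted p < alpha.
    """
    if len(bg_seqs) == 0:
        raise ValueError("background sequence set is empty")
    if method not in ("binomial", "hypergeometric"):
        raise ValueError("method must be 'binomial' or 'hypergeometric'")
    n_bg = len(bg_seqs)
    bg_hits = {
        pwm.motif_id: _hit_count(bg_seqs, pwm, score_min, pseudocount) for pwm in pwms
    }
    records = []
    for signature, seqs in fg_seqs.items():
        n_fg = len(seqs)
        sig_rows = []
        for pwm in pwms:
            k_fg = _hit_count(seqs, pwm, score_min, pseudocount)
            k_bg = bg_hits[pwm.motif_id]
            if method == "binomial":
                # a zero background count is floored at 1/(n_bg+1) so that a
                # single chance foreground hit cannot yield p = 0
                rate = k_bg / n_bg if k_bg > 0 else 1.0 / (n_bg + 1)
                p = float(stats.binom.sf(k_fg - 1, n_fg, rate))
            else:
                p = float(stats.hypergeom.sf(k_fg - 1, n_fg + n_bg, k_fg + k_bg, n_fg))
            sig_rows.append(
                {
                    "motif": pwm.motif_id,
                    "signature": signature,
                    "n_fg": n_fg,
                    "k_fg": k_fg,
                    "n_bg": n_bg,
                    "k_bg": k_bg,
                    "p_value": min(max(p, 0.0), 1.0),
                }
            )
        sub = pd.DataFrame(sig_rows)
        sub["p_adj"] = bh_adjust(sub["p_value"].to_numpy())
        sub["enriched"] = sub["p_adj"] < alpha
        records.append(sub)
    return pd.concat(records, ignore_index=True)


def selective_motifs(
    records: pd.DataFrame, max_signatures: int = 2
) -> dict[str, list[str]]:
    """Motifs enriched in at least 1 and at most ``max_signatures`` signatures.

    Returns motif -> sorted list of the signatures in which it is enriched.
    """
    out: dict[str, list[str]] = {}
    enriched = records[records["enriched"]]
    for motif, sub in enriched.groupby("motif"):
        sigs = sorted(sub["signature"].unique())
        if 1 <= len(sigs) <= max_signatures:
            out[str(motif)] = sigs
    return out


def markov_background(
    seqs: Sequence[str], rng: np.random.Generator, n: int | None = None
) -> list[str]:
    """Seeded first-order Markov resample of the pooled foreground.

    Preserves the foreground's dinucleotide composition in expectation;
    generated sequences match the (cycled) lengths of the input.
    """
    if not seqs:
        raise ValueError("no sequences to model")
    counts = np.ones((4, 4))  # +1 smoothing
    start = np.ones(4)
    for s in seqs:
        enc = _encode(s)
        enc = enc[enc >= 0]
        if enc.size == 0:
            continue
        start[enc[0]] += 1
        np.add.at(counts, (enc[:-1], enc[1:]), 1)
    start /= start.sum()
    trans = counts / counts.sum(axis=1, keepdims=True)
    n = n if n is not None else len(seqs)
    out = []
    for i in range(n):
        length = len(seqs[i % len(seqs)])
        states = np.empty(length, dtype=np.int8)
        states[0] = rng.choice(4, p=start)
        for j in range(1, length):
            states[j] = rng.choice(4, p=trans[states[j - 1]])
        out.append("".join(BASES[s] for s in states))
    return out


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def peak_sequences(peaks, genome: Mapping[str, str]) -> dict[str, str]:
    """Extract peak interval sequences from a genome (id -> chromosome string)."""
    out = {}
    names = peaks.names
    for i, (chrom, s, e) in enumerate(
        zip(peaks.df["chrom"].astype(str), peaks.df["start"], peaks.df["end"])
    ):
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        out[str(names.iloc[i])] = genome[chrom][int(s) : int(e)]
    return out
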