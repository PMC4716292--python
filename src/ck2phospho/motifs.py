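"""Site windows, CK2 consensus matching, and binomial log-odds logo scores.

Each phosphosite is summarised by a 15-residue window (site +/- 7,
out-of-protein positions padded with X). The acidophilic CK2 consensus is
matched on S/T centres with acidic residues at +1..+3. Position-specific
enrichment over a proteome background is scored probability-logo style:
the height of residue r at offset j is the log-odds of the exact binomial
tail probability of its foreground count given the background frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
HALF_WIDTH = 7
#: scored offsets, the fixed centre (0) excluded
OFFSETS = tuple(j for j in range(-HALF_WIDTH, HALF_WIDTH + 1) if j != 0)
ACIDIC = frozenset("DE")
CENTER_RESIDUES = frozenset("STY")


class WindowError(ValueError):
    """Window extraction failed (unknown accession or invalid centre)."""


def extract_window(
    proteome: Mapping[str, str], accession: str, site: int, half_width: int = HALF_WIDTH
) -> str:
    """Extract the ``2*half_width+1`` window centred on a 1-based site.

    Positions beyond the protein termini are padded with ``X``.
    """
    if accession not in proteome:
        raise WindowError(f"unknown accession {accession!r}")
    seq = proteome[accession]
    if not (1 <= site <= len(seq)):
        raise WindowError(f"site {site} outside protein {accession!r} (length {len(seq)})")
    if seq[site - 1] not in CENTER_RESIDUES:
        raise WindowError(
            f"residue {seq[site - 1]!r} at {accession}:{site} is not a phosphorylatable S/T/Y"
        )
    chars = []
    for j in range(site - 1 - half_width, site + half_width):
        chars.append(seq[j] if 0 <= j < len(seq) else "X")
    return "".join(chars)


# The six published combined CK2 motifs. Their union is exactly
# "centre S/T with >=1 acidic residue at +1..+3"; individual patterns are
# kept so matches can be reported per pattern.
CK2_PATTERNS: tuple[tuple[str, dict[int, frozenset[str]]], ...] = (
    ("S/T-D/E", {1: ACIDIC}),
    ("S/T-X-D/E", {2: ACIDIC}),
    ("S/T-X-D/E-D/E", {2: ACIDIC, 3: ACIDIC}),
    ("S/T-D/E-X/D/E", {1: ACIDIC}),
    ("S/T-X-X-D/E", {3: ACIDIC}),
    ("S/T-D/E-D/E-D/E", {1: ACIDIC, 2: ACIDIC, 3: ACIDIC}),
)


def ck2_match(
    window: str,
    patterns: Sequence[tuple[str, dict[int, frozenset[str]]]] = CK2_PATTERNS,
) -> tuple[bool, list[str]]:
    """Match a site window against the CK2 consensus pattern set.

    The centre must be S or T; X padding at +1..+3 counts as non-acidic.
    Returns (matched, names of satisfied patterns).
    """
    if len(window) != 2 * HALF_WIDTH + 1:
        raise WindowError(f"window must have length {2 * HALF_WIDTH + 1}, got {len(window)}")
    center = window[HALF_WIDTH]
    if center not in "ST":
        return False, []
    matched = [
        name
        for name, constraints in patterns
        if all(window[HALF_WIDTH + off] in allowed for off, allowed in constraints.items())
    ]
    return bool(matched), matched


def ck2_percentage(windows_per_motif: Sequence[Sequence[str]]) -> float:
    """Percent of motifs with at least one CK2-matching site window.

    ``windows_per_motif`` holds one list of 15-mer windows per motif
    (multi-site motifs contribute one window per site). Reported to one
    decimal, as in sequence-logo figure annotations.
    """
    if len(windows_per_motif) == 0:
        raise ValueError("ck2_percentage undefined for an empty group")
    n_match = sum(1 for ws in windows_per_motif if any(ck2_match(w)[0] for w in ws))
    return round(100.0 * n_match / len(windows_per_motif), 1)


def background_frequencies(
    proteome: Mapping[str, str], *, centers: frozenset[str] = CENTER_RESIDUES
) -> np.ndarray:
    """Per-position background residue probabilities from a proteome.

    Background windows are the 15-mers centred on every S, T and Y in the
    proteome (X-padded at termini). Returns a (20 residues x 14 offsets)
    array of probabilities; X never counts, so each used column sums to 1.
    """
    counts = np.zeros((len(AMINO_ACIDS), len(OFFSETS)), dtype=np.int64)
    n_centers = 0
    for acc, seq in proteome.items():
        for i, res in enumerate(seq):
            if res not in centers:
                continue
            n_centers += 1
            for jidx, off in enumerate(OFFSETS):
                k = i + off
                if 0 <= k < len(seq):
                    ridx = AA_INDEX.get(seq[k])
                    if ridx is not None:
                        counts[ridx, jidx] += 1
    if n_centers == 0:
        raise ValueError("proteome contains no S/T/Y centres")
    totals = counts.sum(axis=0, dtype=float)
    p = np.zeros_like(counts, dtype=float)
    nonzero = totals > 0
    p[:, nonzero] = counts[:, nonzero] / totals[nonzero]
    return p


@dataclass
class LogoMatrix:
    """Binomial log-odds logo statistics over residues x offsets.

    ``score[r, j]`` is ``-log10`` of the exact binomial tail probability of
    the foreground count ``k[r, j]`` out of ``n[j]`` given background
    probability ``p[r, j]``; positive above the axis for overrepresentation,
    negative below for underrepresentation. ``sig_threshold`` is the default
    Bonferroni line over the 20 x 14 residue-position tests.
    """

    score: np.ndarray
    k: np.ndarray
    n: np.ndarray
    p: np.ndarray
    sig_threshold: float
    significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.significant = np.abs(self.score) > self.sig_threshold

    @property
    def offsets(self) -> tuple[int, ...]:
        return OFFSETS

    @property
    def residues(self) -> str:
        return AMINO_ACIDS

    def to_dict(self) -> dict:
        def clean(a):
            return [[None if not math.isfinite(v) else v for v in row] for row in a.tolist()]

        return {
            "residues": list(AMINO_ACIDS),
            "offsets": list(OFFSETS),
            "score": clean(self.score),
            "k": self.k.tolist(),
            "n": self.n.tolist(),
            "p": self.p.tolist(),
            "sig_threshold": self.sig_threshold,
            "significant": self.significant.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogoMatrix":
        score = np.array(
            [[math.inf if v is None else v for v in row] for row in d["score"]], dtype=float
        )
        return cls(
            score=score,
            k=np.array(d["k"], dtype=np.int64),
            n=np.array(d["n"], dtype=np.int64),
            p=np.array(d["p"], dtype=float),
            sig_threshold=float(d["sig_threshold"]),
        )


def binomial_tail_log10(k: int, n: int, p: float) -> float:
    """Signed log-odds of the exact binomial tail of k successes in n.

    Overrepresentation (k/n > p): -log10 P(X >= k), positive.
    Underrepresentation (k/n < p): log10 P(X <= k), negative.
    k/n == p exactly: 0.
    """
    if n == 0:
        return 0.0
    if p <= 0.0:
        return math.inf if k > 0 else 0.0
    if p >= 1.0:
        return -math.inf if k < n else 0.0
    f = k / n
    if f > p:
        tail = sps.binom.sf(k - 1, n, p)
        if tail <= 0.0:  # beyond double underflow; use the log survival function
            return -sps.binom.logsf(k - 1, n, p) / math.log(10)
        return -math.log10(tail)
    if f < p:
        tail = sps.binom.cdf(k, n, p)
        if tail <= 0.0:
            return sps.binom.logcdf(k, n, p) / math.log(10)
        return math.log10(tail)
    return 0.0


def plogo_scores(
    foreground: Iterable[str],
    background: np.ndarray,
    *,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> LogoMatrix:
    """Score foreground windows against background frequencies.

    X positions are excluded from the foreground counts, so the effective
    sample size n[j] varies by offset; the fixed centre is not scored.
    A residue observed in the foreground but impossible under the
    background (p = 0) gets a +inf sentinel score.
    """
    windows = list(foreground)
    if not windows:
        raise ValueError("plogo_scores requires at least one foreground window")
    k = np.zeros((len(AMINO_ACIDS), len(OFFSETS)), dtype=np.int64)
    n = np.zeros(len(OFFSETS), dtype=np.int64)
    for w in windows:
        if len(w) != 2 * HALF_WIDTH + 1:
            raise WindowError(f"window must have length {2 * HALF_WIDTH + 1}: {w!r}")
        for jidx, off in enumerate(OFFSETS):
            ridx = AA_INDEX.get(w[HALF_WIDTH + off])
            if ridx is not None:
                k[ridx, jidx] += 1
                n[jidx] += 1
    m_tests = k.size if bonferroni else 1
    threshold = -math.log10(alpha / m_tests)
    score = np.zeros_like(k, dtype=float)
    for jidx in range(len(OFFSETS)):
        for ridx in range(len(AMINO_ACIDS)):
            score[ridx, jidx] = binomial_tail_log10(
                int(k[ridx, jidx]), int(n[jidx]), float(background[ridx, jidx])
            )
    return LogoMatrix(score=score, k=k, n=n, p=background.copy(), sig_threshold=threshold)
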