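"""Position-weight-matrix scoring, genome scanning, and EM training.

The weight matrix is the additive 4xL model standard in the field: the
score of an L-mer is the sum over positions of the matrix entry for the
observed base, and scores are log-linear in binding affinity.  ``N`` bases
score as the column mean so that assembly gaps neither create nor destroy
high-scoring sites.

``train_matrix_em`` fits a base-frequency matrix to a set of bound
sequences under a one-occurrence-per-sequence (OOPS) model with a 0-order
background, considering both strands, starting from a consensus string.
This mirrors the common practice of refining a motif model from SELEX reads
or ChIP-seq peak sequences by expectation-maximization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN (case-insensitive) as int codes 0..3, N/other -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class WeightMatrix:
    """Additive 4xL scoring matrix in whatever score units the source uses.

    Rows are in A, C, G, T order.  Thresholds are meaningful only on the
    native scale of the supplied matrix.
    """

    scores: np.ndarray
    name: str = ""

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[0] != 4:
            raise ValueError("weight matrix must be 4xL")
        if scores.shape[1] < 5:
            raise ValueError("weight matrix length must be >= 5")
        if not np.isfinite(scores).all():
            raise ValueError("weight matrix entries must be finite")

    @property
    def length(self) -> int:
        return self.scores.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.scores.min(axis=0).sum())

    def reverse_complement(self) -> "WeightMatrix":
        return WeightMatrix(self.scores[::-1, ::-1].copy(), name=self.name)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.scores.argmax(axis=0))

    def extended(self) -> np.ndarray:
        """5xL score table whose 5th row (code 4 = N) is the column mean."""
        return np.vstack([self.scores, self.scores.mean(axis=0)])

    @classmethod
    def from_frequencies(cls, freqs: np.ndarray, background=0.25,
                         name: str = "") -> "WeightMatrix":
        """log2(f/bg) matrix from a column-normalized frequency matrix."""
        freqs = np.asarray(freqs, dtype=float)
        bg = np.broadcast_to(np.asarray(background, dtype=float).reshape(-1, 1)
                             if np.ndim(background) else np.full((4, 1), background),
                             freqs.shape)
        with np.errstate(divide="ignore"):
            scores = np.log2(freqs / bg)
        scores = np.where(np.isneginf(scores), -30.0, scores)
        return cls(scores, name=name)


def score_window(matrix: WeightMatrix, seq: str) -> float:
    """Score one L-mer; N contributes the column mean."""
    if len(seq) != matrix.length:
        raise ValueError(f"sequence length {len(seq)} != matrix length {matrix.length}")
    ext = matrix.extended()
    codes = encode(seq)
    return float(ext[codes, np.arange(matrix.length)].sum())


def _window_scores(ext: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores of all windows of a coded sequence under a 5xL extended table."""
    L = ext.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    acc = np.zeros(n)
    for j in range(L):
        acc += ext[codes[j:j + n], j]
    return acc


def scan_sequence(matrix: WeightMatrix, seq: str, threshold: float,
                  chrom: str = "seq") -> "pd.DataFrame":
    """Scan one sequence on both strands; see :func:`scan_genome`."""
    return scan_genome(matrix, {chrom: seq}, threshold)


def scan_genome(matrix: WeightMatrix, seqs: dict, threshold: float):
    """Predict sites with score >= threshold on both strands.

    ``pos`` is the 0-based window start; ``center`` the dyad position
    ``pos + L//2``.  When the forward and reverse match of one window both
    clear the threshold (dyad symmetry), only the higher-scoring strand is
    kept (ties go to +), so each locus is reported once.  Chromosomes
    shorter than the matrix are skipped with a warning.
    """
    import pandas as pd

    L = matrix.length
    ext_fwd = matrix.extended()
    ext_rev = matrix.reverse_complement().extended()
    frames = []
    for chrom, seq in seqs.items():
        if len(seq) < L:
            warnings.warn(f"chromosome {chrom} shorter than matrix; skipped")
            continue
        codes = encode(seq)
        fwd = _window_scores(ext_fwd, codes)
        rev = _window_scores(ext_rev, codes)
        take_fwd = fwd >= rev  # ties go to +
        best = np.where(take_fwd, fwd, rev)
        keep = best >= threshold
        pos = np.nonzero(keep)[0]
        if pos.size == 0:
            continue
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "center": pos + L // 2,
            "strand": np.where(take_fwd[pos], "+", "-"),
            "score": best[pos],
        }))
    if not frames:
        out = pd.DataFrame(columns=["chrom", "pos", "center", "strand", "score"])
    else:
        out = pd.concat(frames, ignore_index=True)
    out.attrs["motif_length"] = L
    return out


# ---------------------------------------------------------------------------
# EM training
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    matrix: WeightMatrix          # log2(f/bg) scores
    frequencies: np.ndarray       # 4xL column-normalized
    background: np.ndarray        # length-4 0-order background
    log_likelihood: list = field(default_factory=list)  # penalized, per iteration
    n_iter: int = 0
    converged: bool = False


def consensus_frequencies(consensus: str, strength: float = 0.7) -> np.ndarray:
    """Initial frequency matrix from a consensus string (N -> uniform)."""
    L = len(consensus)
    freqs = np.full((4, L), (1.0 - strength) / 3.0)
    for j, b in enumerate(consensus.upper()):
        if b == "N":
            freqs[:, j] = 0.25
        elif b in _BASE_INDEX:
            freqs[_BASE_INDEX[b], j] = strength
        else:
            raise ValueError(f"bad consensus base {b!r}")
    return freqs


def train_matrix_em(seqs, init_consensus: str, max_iter: int = 200,
                    tol: float = 1e-4, pseudocount: float = 0.5,
                    background=None) -> EMResult:
    """Train a frequency matrix from bound sequences by OOPS expectation-
    maximization over both strands.

    E-step: posterior over (motif start, strand) per sequence under the
    current matrix against a 0-order background (uniform prior over
    placements).  M-step: expected base counts, smoothed with
    ``pseudocount``, renormalized per column.  Convergence: maximum
    absolute frequency change < ``tol``.

    Returns an :class:`EMResult`; its ``matrix`` holds log2(f/bg) scores.
    The recorded log-likelihood (observed-data likelihood plus the Dirichlet
    smoothing term that the pseudocounts implement) is non-decreasing.
    """
    seqs = [s.upper() for s in seqs]
    if not seqs:
        raise ValueError("train_matrix_em: empty sequence set")
    if len(set(seqs)) == 1:
        warnings.warn("all input sequences identical: trained matrix will "
                      "have (near) zero entropy")
    L = len(init_consensus)
    if any(len(s) < L for s in seqs):
        raise ValueError(f"all sequences must be >= motif length {L}")

    if background is None:
        counts = np.zeros(4)
        for s in seqs:
            codes = encode(s)
            counts += np.bincount(codes[codes < 4], minlength=4)
        background = (counts + 1.0) / (counts.sum() + 4.0)
    background = np.asarray(background, dtype=float)
    logbg = np.log(background)

    # group sequences by length so windows vectorize
    groups = {}
    for s in seqs:
        groups.setdefault(len(s), []).append(s)
    cols = np.arange(L)
    windows = {}   # seqlen -> (n, S, L) int codes of every window
    for slen, ss in groups.items():
        codes = np.vstack([encode(s) for s in ss])
        win = np.lib.stride_tricks.sliding_window_view(codes, L, axis=1)
        windows[slen] = np.ascontiguousarray(win)

    freqs = consensus_frequencies(init_consensus)
    result = EMResult(matrix=WeightMatrix.from_frequencies(freqs, background),
                      frequencies=freqs, background=background)
    for it in range(max_iter):
        with np.errstate(divide="ignore"):
            ratio = np.log(freqs) - logbg[:, None]
        ratio = np.where(np.isneginf(ratio), -700.0, ratio)
        ratio_ext = np.vstack([ratio, np.zeros((1, L))])      # N scores as background
        ratio_rc = ratio_ext[[3, 2, 1, 0, 4], ::-1]

        exp_counts = np.zeros((4, L))
        loglik = 0.0
        for slen, win in windows.items():
            n, S, _ = win.shape
            s_fwd = ratio_ext[win, cols].sum(axis=2)          # (n, S)
            s_rev = ratio_rc[win, cols].sum(axis=2)
            allsc = np.concatenate([s_fwd, s_rev], axis=1)    # (n, 2S)
            m = allsc.max(axis=1, keepdims=True)
            w = np.exp(allsc - m)
            z = w.sum(axis=1, keepdims=True)
            post = w / z
            loglik += float((m[:, 0] + np.log(z[:, 0]) - np.log(2 * S)).sum())
            p_fwd, p_rev = post[:, :S], post[:, S:]
            # expected base counts: forward placements read the window as-is,
            # reverse placements read its reverse complement
            flat = win.reshape(-1, L)
            wf = p_fwd.reshape(-1)
            wr = p_rev.reshape(-1)
            for j in range(L):
                b = flat[:, j]
                ok = b < 4
                np.add.at(exp_counts[:, j], b[ok], wf[ok])
                brc = 3 - flat[:, L - 1 - j]
                ok = brc >= 0
                np.add.at(exp_counts[:, j], brc[ok], wr[ok])
        new = exp_counts + pseudocount
        new /= new.sum(axis=0, keepdims=True)
        penalty = float(pseudocount * np.log(np.clip(new, 1e-300, None)).sum())
        result.log_likelihood.append(loglik + penalty)
        delta = np.abs(new - freqs).max()
        freqs = new
        result.n_iter = it + 1
        if delta < tol:
            result.converged = True
            break

    ent = -(freqs * np.log2(np.clip(freqs, 1e-12, None))).sum(axis=0)
    if (ent < 1e-6).all():
        warnings.warn("trained matrix has zero entropy (identical input sequences?)")
    result.frequencies = freqs
    result.matrix = WeightMatrix.from_frequencies(freqs, background,
                                                  name="em-trained")
    return result


def frequencies_from_sequences(seqs, pseudocount: float = 0.0) -> np.ndarray:
    """Column base frequencies of pre-aligned, equal-length sequences."""
    lens = {len(s) for s in seqs}
    if len(lens) != 1:
        raise ValueError("sequences must be aligned to equal length")
    L = lens.pop()
    counts = np.full((4, L), pseudocount, dtype=float)
    for s in seqs:
        codes = encode(s)
        for j in range(L):
            if codes[j] < 4:
                counts[codes[j], j] += 1
    return counts / counts.sum(axis=0, keepdims=True)


def information_content(freqs: np.ndarray) -> np.ndarray:
    """Per-column information in bits: 2 - H(column)."""
    freqs = np.asarray(freqs, dtype=float)
    if not np.allclose(freqs.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("columns must sum to 1")
    logs = np.where(freqs > 0, np.log2(np.clip(freqs, 1e-300, None)), 0.0)
    return 2.0 + (freqs * logs).sum(axis=0)
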