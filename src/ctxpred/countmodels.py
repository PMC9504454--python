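"""Count-based conditional probability models of the focus base.

Two estimators are provided, both fitted "simply by counting" how often
each of the four bases occurs in the focus position for each context:

* :class:`CentralModel` — conditions on both flanks of size k (a context
  of 2k bases), giving ``3 * 4**(2k)`` free parameters;
* :class:`MarkovModel` — an order-k Markov model conditioning on the k
  bases of the left flank only, giving ``3 * 4**k`` free parameters.

Both follow the statsmodels pattern: the model object holds the data and
configuration, ``fit()`` returns a results object with the estimated
conditional distributions, a ``summary()`` table, a common prediction
contract, and serialization.  Count tables are stored sparsely (observed
contexts only), so a k=14 Markov model can be fitted to a small genome
even though its dense table has ~0.8 billion parameters.

Estimation uses the forward strand only.  Prediction can optionally use
the bidirectional average: the model applied to the forward-strand context
and to the reverse-complemented context (with complemented outcome), and
the two distributions averaged.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .alphabet import BASES, COMPLEMENT, N
from .sequences import ContextWindow, GenomeSequence, build_position_mask

__all__ = [
    "CentralModel",
    "MarkovModel",
    "CountModelResults",
    "argmax_base",
    "bidirectional_average",
    "parameter_count",
    "load_results",
]

#: dense-table size guard; larger context spaces are refused at fit time
DEFAULT_MAX_TABLE_ENTRIES = 4 ** 16


def parameter_count(kind: str, k: int) -> int:
    """Number of free parameters of a dense count model.

    central -> 3 * 4**(2k)   (both flanks of size k)
    markov  -> 3 * 4**k      (left flank of size k)
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if kind == "central":
        return 3 * 4 ** (2 * k)
    if kind == "markov":
        return 3 * 4 ** k
    raise ValueError(f"unknown model kind {kind!r}")


def argmax_base(p) -> str:
    """Most probable base; ties broken by fixed order A < C < G < T."""
    return BASES[int(np.argmax(np.asarray(p)))]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code of every length-k window (MSB = first base).

    Windows containing N produce meaningless codes; callers must mask them.
    """
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return sliding_window_view(codes, k).astype(np.int64) @ powers


def _n_free_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean: window of length k starting at j contains no N."""
    is_n = (codes == N).astype(np.int64)
    cums = np.concatenate([[0], np.cumsum(is_n)])
    return (cums[k:] - cums[:-k]) == 0


class _CountModelBase:
    """Shared fitting machinery for the central and Markov models."""

    kind: str

    def __init__(self, genomes, k: int, pseudocount: float = 0.0,
                 max_table_entries: int = DEFAULT_MAX_TABLE_ENTRIES):
        if isinstance(genomes, GenomeSequence):
            genomes = [genomes]
        if k < 1:
            raise ValueError("k must be >= 1")
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        dense = 4 ** self._context_width(k)
        if dense > max_table_entries:
            raise MemoryError(
                f"{self.kind} model with k={k} has a dense context table of "
                f"{dense} entries, above the configured budget of "
                f"{max_table_entries}; raise max_table_entries to override")
        self.genomes = list(genomes)
        self.k = int(k)
        self.pseudocount = float(pseudocount)

    @staticmethod
    def _context_width(k: int) -> int:
        raise NotImplementedError

    def _context_and_focus(self, genome: GenomeSequence, positions):
        """(context codes, focus codes) at qualified positions."""
        raise NotImplementedError

    def fit(self, positions=None) -> "CountModelResults":
        """Accumulate focus-base counts per context over all genomes.

        Parameters
        ----------
        positions : optional
            Either None (all qualified positions) or a list parallel to
            the genomes giving, per genome, an array of positions to use
            (disqualified entries among them are dropped).
        """
        combined_parts = []
        n_positions = 0
        for gi, genome in enumerate(self.genomes):
            sub = None if positions is None else positions[gi]
            ctx, focus = self._context_and_focus(genome, sub)
            n_positions += ctx.size
            combined_parts.append(ctx * 4 + focus)
        if n_positions == 0:
            raise ValueError("no qualified positions to fit on")
        combined = np.concatenate(combined_parts)
        u, cnt = np.unique(combined, return_counts=True)
        ctx_codes, inverse = np.unique(u >> 2, return_inverse=True)
        counts = np.zeros((ctx_codes.size, 4), dtype=np.int64)
        counts[inverse, u & 3] = cnt
        return CountModelResults(self.kind, self.k, ctx_codes, counts,
                                 pseudocount=self.pseudocount,
                                 n_training_positions=n_positions)


class CentralModel(_CountModelBase):
    """Central model: distribution of the focus base given both flanks of size k."""

    kind = "central"

    @staticmethod
    def _context_width(k: int) -> int:
        return 2 * k

    def _context_and_focus(self, genome, positions):
        k = self.k
        codes = genome.codes
        mask = build_position_mask(genome, k)
        if positions is None:
            pos = mask.qualified_positions
        else:
            pos = np.asarray(positions, dtype=np.int64)
            pos = pos[~mask.disqualified[pos]]
        if pos.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        wc = _kmer_codes(codes, k)
        left = wc[pos - k]
        right = wc[pos + 1]
        ctx = left * (4 ** k) + right
        return ctx, codes[pos].astype(np.int64)


class MarkovModel(_CountModelBase):
    """Order-k Markov model: distribution of a base given its k left neighbours."""

    kind = "markov"

    @staticmethod
    def _context_width(k: int) -> int:
        return k

    def _context_and_focus(self, genome, positions):
        k = self.k
        codes = genome.codes
        disq = left_context_disqualified(genome, k)
        if positions is None:
            pos = np.flatnonzero(~disq)
        else:
            pos = np.asarray(positions, dtype=np.int64)
            pos = pos[~disq[pos]]
        if pos.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        wc = _kmer_codes(codes, k)
        return wc[pos - k], codes[pos].astype(np.int64)


def left_context_disqualified(genome: GenomeSequence, k: int) -> np.ndarray:
    """Positions lacking k non-N left bases or with an N focus base."""
    L = len(genome)
    disq = np.ones(L, dtype=bool)
    if L > k:
        ok_left = _n_free_windows(genome.codes, k)[: L - k]
        disq[k:] = ~ok_left | (genome.codes[k:] == N)
    return disq


class CountModelResults:
    """Fitted conditional distributions of a count model.

    Probabilities for a seen context equal its counts divided by their sum
    (optionally with an additive pseudocount).  Contexts never seen in
    training fall back to the uniform distribution over the four bases.
    """

    def __init__(self, kind, k, context_codes, counts, pseudocount=0.0,
                 n_training_positions=0):
        self.kind = kind
        self.k = int(k)
        self.context_codes = np.asarray(context_codes, dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.pseudocount = float(pseudocount)
        self.n_training_positions = int(n_training_positions)

    # -- basic properties -------------------------------------------------
    @property
    def context_width(self) -> int:
        return 2 * self.k if self.kind == "central" else self.k

    @property
    def n_parameters(self) -> int:
        """Dense free-parameter count, by formula (not the sparse table size)."""
        return parameter_count(self.kind, self.k)

    @property
    def n_contexts_observed(self) -> int:
        return int(self.context_codes.size)

    @property
    def probabilities(self) -> np.ndarray:
        """(n_contexts, 4) conditional probabilities for observed contexts."""
        a = self.pseudocount
        tot = self.counts.sum(axis=1, keepdims=True)
        return (self.counts + a) / (tot + 4 * a)

    # -- prediction -------------------------------------------------------
    def predict_context_codes(self, ctx_codes: np.ndarray) -> np.ndarray:
        """(n, 4) conditional distributions for integer context codes.

        Unseen contexts get the uniform (0.25 each) fallback.
        """
        ctx_codes = np.asarray(ctx_codes, dtype=np.int64)
        out = np.full((ctx_codes.size, 4), 0.25)
        if self.context_codes.size == 0:
            return out
        idx = np.searchsorted(self.context_codes, ctx_codes)
        idx_c = np.minimum(idx, self.context_codes.size - 1)
        found = self.context_codes[idx_c] == ctx_codes
        if np.any(found):
            out[found] = self.probabilities[idx_c[found]]
        return out

    def predict(self, context: ContextWindow) -> np.ndarray:
        """Conditional distribution over (A,C,G,T) for one context window."""
        if context.flank_size < self.k:
            raise ValueError(f"context flank {context.flank_size} < model k {self.k}")
        left = np.asarray(context.left[-self.k:], dtype=np.int64)
        right = np.asarray(context.right[: self.k], dtype=np.int64)
        if (left == N).any() or (self.kind == "central" and (right == N).any()):
            raise ValueError("context contains N; position is disqualified")
        powers = 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        code = int(left @ powers)
        if self.kind == "central":
            code = code * (4 ** self.k) + int(right @ powers)
        return self.predict_context_codes(np.array([code]))[0]

    def predict_positions(self, genome: GenomeSequence, positions: np.ndarray,
                          bidirectional: bool = False) -> np.ndarray:
        """(n, 4) distributions at genomic positions (assumed qualified)."""
        positions = np.asarray(positions, dtype=np.int64)
        probs = self._forward_probs(genome.codes, positions)
        if bidirectional:
            rc = COMPLEMENT[genome.codes][::-1].copy()
            rev_probs = self._forward_probs(rc, len(genome) - 1 - positions)
            probs = 0.5 * (probs + rev_probs[:, ::-1])
        return probs

    def _forward_probs(self, codes: np.ndarray, positions: np.ndarray) -> np.ndarray:
        k = self.k
        wc = _kmer_codes(codes, k)
        ctx = wc[positions - k]
        if self.kind == "central":
            ctx = ctx * (4 ** k) + wc[positions + 1]
        return self.predict_context_codes(ctx)

    def disqualified(self, genome: GenomeSequence) -> np.ndarray:
        """Positions this model cannot score (N in the required context/ends)."""
        if self.kind == "central":
            return build_position_mask(genome, self.k).disqualified
        return left_context_disqualified(genome, self.k)

    # -- reporting and serialization --------------------------------------
    def summary(self) -> str:
        lines = [
            f"{self.kind.capitalize()} count model (k = {self.k})",
            "=" * 44,
            f"context width          {self.context_width} bases",
            f"free parameters        {self.n_parameters:,} (dense, 3 x 4^{self.context_width})",
            f"contexts observed      {self.n_contexts_observed:,}",
            f"training positions     {self.n_training_positions:,}",
            f"pseudocount            {self.pseudocount}",
            "unseen-context fallback uniform (0.25 per base)",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize to an .npz container with a JSON header."""
        header = json.dumps({
            "kind": self.kind, "k": self.k, "pseudocount": self.pseudocount,
            "n_training_positions": self.n_training_positions,
        })
        np.savez_compressed(path, header=np.frombuffer(header.encode(), dtype=np.uint8),
                            context_codes=self.context_codes, counts=self.counts)

    def to_frame(self):
        """Per-context probabilities as a DataFrame (small k only)."""
        import pandas as pd

        width = self.context_width
        contexts = []
        for code in self.context_codes:
            s = ""
            c = int(code)
            for _ in range(width):
                s = BASES[c & 3] + s
                c >>= 2
            if self.kind == "central":
                s = s[: self.k] + "." + s[self.k:]
            contexts.append(s)
        df = pd.DataFrame(self.probabilities, columns=list("ACGT"))
        df.insert(0, "context", contexts)
        return df


def load_results(path) -> CountModelResults:
    """Load a :meth:`CountModelResults.save` container."""
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        return CountModelResults(header["kind"], header["k"], z["context_codes"],
                                 z["counts"], pseudocount=header["pseudocount"],
                                 n_training_positions=header["n_training_positions"])


def bidirectional_average(results, genome: GenomeSequence, pos: int) -> np.ndarray:
    """Strand-averaged prediction at one position.

    q(x) = 0.5 * [ p_fwd(x | context) + p_rev(complement(x) | rc context) ]
    """
    disq = results.disqualified(genome)
    mask_rev = results.disqualified(
        GenomeSequence(genome.name, COMPLEMENT[genome.codes][::-1].copy()))
    if disq[pos] or mask_rev[len(genome) - 1 - pos]:
        raise ValueError(f"position {pos} is disqualified on one of the strands")
    return results.predict_positions(genome, np.array([pos]), bidirectional=True)[0]
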