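"""Synthetic genomes with known conditional structure, plus exact oracles.

Genomes are sampled from an order-m Markov chain (m = 0..3) and may carry

* a planted periodic GC modulation: the probability that position i holds
  G or C is forced to ``baseline + amplitude * cos(2*pi*i/period)``, with
  the within-class split (G vs C, A vs T) following the chain's own
  conditional distribution;
* soft-masked repeat copies: a fixed motif overwritten at random
  non-overlapping positions, flagged lowercase;
* N blocks, overwritten last so masks are unambiguous.

Because the generating chain is known, exact oracle quantities are
available: the stationary distribution, the conditional entropy (the
cross-entropy floor any model can reach) and the Bayes accuracy (the
accuracy ceiling of the optimal context predictor), either given the left
context only (the Markov-model setting) or given both flanks (the setting
of the central and neural models).

With GC modulation switched on the process is no longer stationary; the
oracles then describe the unmodulated chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .alphabet import A, C, G, T, decode
from .sequences import GenomeSequence

__all__ = [
    "MarkovChain",
    "SyntheticGenomeSpec",
    "generate_genome",
    "bayes_accuracy",
    "conditional_entropy",
    "default_order2_chain",
    "small_genome_spec",
]


class MarkovChain:
    """An order-m Markov chain over {A,C,G,T} with exact oracle computations.

    Parameters
    ----------
    order : int
        Context length m (0 gives an iid model).
    table : (4**m, 4) array
        Conditional distribution of the next base given the left m-mer,
        contexts coded base-4 with the most significant digit first.
    """

    def __init__(self, order: int, table):
        table = np.asarray(table, dtype=float)
        if not 0 <= order <= 12:
            raise ValueError("order must be in 0..12")
        if table.shape != (4 ** order, 4):
            raise ValueError(f"table must have shape ({4 ** order}, 4)")
        if (table < 0).any() or not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each conditional distribution must sum to 1")
        self.order = int(order)
        self.table = table

    # ------------------------------------------------------------------
    @classmethod
    def uniform(cls) -> "MarkovChain":
        return cls(0, np.full((1, 4), 0.25))

    @classmethod
    def random(cls, order: int, seed: int, concentration: float = 0.6) -> "MarkovChain":
        """A chain with Dirichlet-distributed conditional rows."""
        rng = np.random.default_rng(seed)
        return cls(order, rng.dirichlet([concentration] * 4, size=4 ** order))

    def stationary(self) -> np.ndarray:
        """Stationary distribution over the 4**m context states."""
        S = 4 ** self.order
        if S == 1:
            return np.ones(1)
        mask = S - 1
        pi = np.full(S, 1.0 / S)
        states = np.arange(S)
        targets = ((states[:, None] * 4 + np.arange(4)[None, :]) & mask).ravel()
        for _ in range(20000):
            nxt = np.zeros(S)
            np.add.at(nxt, targets, (pi[:, None] * self.table).ravel())
            if np.abs(nxt - pi).sum() < 1e-13:
                return nxt
            pi = nxt
        return pi

    def marginal(self) -> np.ndarray:
        """Stationary single-base marginal distribution."""
        if self.order == 0:
            return self.table[0]
        pi = self.stationary()
        out = np.zeros(4)
        np.add.at(out, np.arange(4 ** self.order) & 3, pi)
        return out

    # ------------------------------------------------------------------
    def sample(self, length: int, rng: np.random.Generator,
               gc_period=None, gc_amplitude=0.0, gc_baseline=0.5) -> np.ndarray:
        """Sample a code array of the given length (uint8).

        The first m bases are drawn from the stationary distribution of
        the chain.  When ``gc_period`` is set the G/C class probability at
        position i is ``gc_baseline + gc_amplitude*cos(2*pi*i/gc_period)``
        and the within-class split follows the chain.
        """
        m = self.order
        S = 4 ** m
        mask = S - 1
        out = np.empty(length, dtype=np.uint8)
        if length == 0:
            return out
        # initial state from the stationary distribution
        if m > 0:
            state = int(rng.choice(S, p=self.stationary()))
            seed_len = min(m, length)
            # decode state digits MSB-first into out[0:m]
            digits = [(state >> (2 * (m - 1 - j))) & 3 for j in range(m)]
            out[:seed_len] = digits[:seed_len]
            start = seed_len
        else:
            state = 0
            start = 0

        if gc_period is None:
            cum = np.cumsum(self.table, axis=1)
            cum_list = cum.tolist()
            u = rng.random(length)
            s = state
            o = out
            for i in range(start, length):
                row = cum_list[s]
                ui = u[i]
                b = 0
                while ui > row[b]:
                    b += 1
                o[i] = b
                s = ((s << 2) | b) & mask
            return out

        # planted periodic GC modulation
        w = gc_baseline + gc_amplitude * np.cos(
            2.0 * np.pi * np.arange(length) / gc_period)
        p = self.table
        p_gc = p[:, C] + p[:, G]
        p_at = p[:, A] + p[:, T]
        with np.errstate(invalid="ignore", divide="ignore"):
            c_given_gc = np.where(p_gc > 0, p[:, C] / np.where(p_gc > 0, p_gc, 1), 0.5)
            a_given_at = np.where(p_at > 0, p[:, A] / np.where(p_at > 0, p_at, 1), 0.5)
        c_given_gc = c_given_gc.tolist()
        a_given_at = a_given_at.tolist()
        u1 = rng.random(length)
        u2 = rng.random(length)
        wl = w.tolist()
        s = state
        for i in range(start, length):
            if u1[i] < wl[i]:
                b = C if u2[i] < c_given_gc[s] else G
            else:
                b = A if u2[i] < a_given_at[s] else T
            out[i] = b
            s = ((s << 2) | b) & mask
        return out

    # ------------------------------------------------------------------
    def _both_sided_joint(self):
        """Joint p(left m-mer, x, right m bases) under stationarity.

        Returns (joint, n_left_states, n_right_tuples) with joint shaped
        (4**m, 4, 4**m); right tuples are coded base-4 MSB-first.
        """
        m = self.order
        S = 4 ** m
        mask = S - 1
        pi = self.stationary()
        joint = np.zeros((S, 4, S))
        for s0 in range(S):
            for x in range(4):
                base_p = pi[s0] * self.table[s0, x]
                if base_p == 0.0:
                    continue
                s1 = ((s0 << 2) | x) & mask
                for rvec in product(range(4), repeat=m):
                    p = base_p
                    s = s1
                    for r in rvec:
                        p *= self.table[s, r]
                        s = ((s << 2) | r) & mask
                    code = 0
                    for r in rvec:
                        code = (code << 2) | r
                    joint[s0, x, code] = p
        return joint

    def bayes_accuracy(self, k: int, sided: str = "left") -> float:
        """Accuracy of the optimal k-context predictor, by exact enumeration.

        ``sided="left"`` conditions on the k left bases (the Markov-model
        setting); ``sided="both"`` conditions on both flanks (the central
        and neural setting).  For an order-m chain the value is the same
        for every k >= m; k < m is refused because the result would not be
        the Bayes ceiling.
        """
        if k < self.order:
            raise ValueError(f"context order k={k} is below the generating order "
                             f"{self.order}; the value would not be the Bayes bound")
        if sided == "left" or self.order == 0:
            pi = self.stationary()
            return float(np.sum(pi * self.table.max(axis=1)))
        if sided == "both":
            joint = self._both_sided_joint()
            return float(joint.max(axis=1).sum())
        raise ValueError("sided must be 'left' or 'both'")

    def conditional_entropy(self, sided: str = "left") -> float:
        """Entropy (nats/base) of the focus base given the context.

        The cross-entropy floor of any predictor with access to that
        context: left flank only, or both flanks.
        """
        if sided == "left" or self.order == 0:
            pi = self.stationary()
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(self.table > 0, self.table * np.log(self.table), 0.0)
            return float(-np.sum(pi * plogp.sum(axis=1)))
        if sided == "both":
            joint = self._both_sided_joint()
            marg = joint.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                cond = np.where(joint > 0, joint / marg, 1.0)
                h = -np.where(joint > 0, joint * np.log(cond), 0.0)
            return float(h.sum())
        raise ValueError("sided must be 'left' or 'both'")

    def log_prob_positions(self, codes: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """log p(base_i | left m bases) of the true chain at given positions."""
        m = self.order
        positions = np.asarray(positions, dtype=np.int64)
        if m == 0:
            return np.log(self.table[0][codes[positions].astype(np.int64)])
        if (positions < m).any():
            raise ValueError("positions must have a full left context")
        powers = 4 ** np.arange(m - 1, -1, -1, dtype=np.int64)
        offs = np.arange(-m, 0)
        ctx = codes[positions[:, None] + offs[None, :]].astype(np.int64) @ powers
        return np.log(self.table[ctx, codes[positions].astype(np.int64)])

    def conditional_probs_positions(self, codes: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """(n, 4) true conditional distributions at given positions."""
        m = self.order
        positions = np.asarray(positions, dtype=np.int64)
        if m == 0:
            return np.tile(self.table[0], (positions.size, 1))
        powers = 4 ** np.arange(m - 1, -1, -1, dtype=np.int64)
        offs = np.arange(-m, 0)
        ctx = codes[positions[:, None] + offs[None, :]].astype(np.int64) @ powers
        return self.table[ctx]


def bayes_accuracy(chain: MarkovChain, k: int, sided: str = "left") -> float:
    """Module-level convenience wrapper; see :meth:`MarkovChain.bayes_accuracy`."""
    return chain.bayes_accuracy(k, sided=sided)


def conditional_entropy(chain: MarkovChain, sided: str = "left") -> float:
    """Module-level convenience wrapper; see :meth:`MarkovChain.conditional_entropy`."""
    return chain.conditional_entropy(sided=sided)


@dataclass
class SyntheticGenomeSpec:
    """Full description of a synthetic genome; deterministic given the seed."""

    length: int
    order: int = 0
    transition_table: np.ndarray = None  # type: ignore[assignment]
    gc_period: int | None = None
    gc_amplitude: float = 0.0
    gc_baseline: float = 0.5
    repeat_motif: str | None = None
    repeat_copies: int = 0
    n_blocks: list = field(default_factory=list)  # list of (start, end)
    seed: int = 0
    name: str = "synthetic"

    def validate(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if self.transition_table is None:
            self.transition_table = np.full((4 ** self.order, 4), 0.25)
        self.chain  # shape/normalization checks
        if self.gc_period is not None:
            lo = self.gc_baseline - self.gc_amplitude
            hi = self.gc_baseline + self.gc_amplitude
            if not (0.0 < lo and hi < 1.0):
                raise ValueError("gc_baseline +/- gc_amplitude must stay inside (0,1)")
            if not 0.0 <= self.gc_amplitude < 0.5:
                raise ValueError("gc_amplitude must be in [0, 0.5)")
        for start, end in self.n_blocks:
            if not (0 <= start < end <= self.length):
                raise ValueError(f"invalid N block ({start},{end})")
        if self.repeat_copies and not self.repeat_motif:
            raise ValueError("repeat_copies > 0 requires a repeat_motif")

    @property
    def chain(self) -> MarkovChain:
        return MarkovChain(self.order, self.transition_table)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        d["transition_table"] = np.asarray(self.transition_table).tolist()
        d["n_blocks"] = [list(b) for b in self.n_blocks]
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticGenomeSpec":
        d = json.loads(text)
        d["transition_table"] = np.asarray(d["transition_table"], dtype=float)
        d["n_blocks"] = [tuple(b) for b in d["n_blocks"]]
        return cls(**d)


def generate_genome(spec: SyntheticGenomeSpec):
    """Sample a genome from its spec.

    Returns ``(GenomeSequence, MarkovChain)`` — the sequence and a handle
    on the generating chain for oracle computations.  Deterministic given
    ``spec.seed``; identical specs give byte-identical sequences.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chain = spec.chain
    codes = chain.sample(spec.length, rng,
                         gc_period=spec.gc_period,
                         gc_amplitude=spec.gc_amplitude,
                         gc_baseline=spec.gc_baseline)
    repeat_flags = np.zeros(spec.length, dtype=bool)

    if spec.repeat_copies:
        from .alphabet import encode

        motif = encode(spec.repeat_motif)
        mlen = motif.size
        placed = 0
        attempts = 0
        while placed < spec.repeat_copies and attempts < 50 * spec.repeat_copies:
            attempts += 1
            start = int(rng.integers(0, max(1, spec.length - mlen)))
            if repeat_flags[start : start + mlen].any():
                continue
            codes[start : start + mlen] = motif
            repeat_flags[start : start + mlen] = True
            placed += 1
        if placed < spec.repeat_copies:
            raise ValueError("could not place all repeat copies without overlap")

    from .alphabet import N as N_CODE

    for start, end in spec.n_blocks:
        codes[start:end] = N_CODE
        repeat_flags[start:end] = False

    return GenomeSequence(spec.name, codes, repeat_flags), chain


def default_order2_chain() -> MarkovChain:
    """The package's reference order-2 chain for tests and examples.

    Rows are Dirichlet draws from a fixed internal seed, giving moderately
    skewed conditionals: a predictor that learns the chain beats the
    marginal guesser by a wide margin, but no context is deterministic.
    """
    return MarkovChain.random(2, seed=7_102_201, concentration=0.6)


def small_genome_spec(seed: int = 0, length: int = 2_000_000) -> SyntheticGenomeSpec:
    """The "small" study genome: 2 Mb, order-2 chain, planted 200 bp GC
    modulation, 50 soft-masked copies of a 300-base motif."""
    chain = default_order2_chain()
    motif_rng = np.random.default_rng(422)
    motif = decode(motif_rng.integers(0, 4, size=300).astype(np.uint8))
    copies = round(50 * length / 2_000_000)  # same repeat density at any length
    return SyntheticGenomeSpec(
        length=length, order=2, transition_table=chain.table,
        gc_period=200, gc_amplitude=0.1, gc_baseline=0.4,
        repeat_motif=motif, repeat_copies=copies, seed=seed, name=f"synthetic_{seed}",
    )
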