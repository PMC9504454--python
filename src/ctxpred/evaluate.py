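"""Model scoring: accuracy, reference-base probabilities, density grids
and the Vuong likelihood-ratio test for non-nested models.

All scorers accept any object satisfying the common prediction contract:
``predict_positions(genome, positions, bidirectional=...) -> (n, 4)`` and
``disqualified(genome) -> bool array`` (the count-model results and the
fitted neural model both provide it).

The Vuong test compares two models' per-position log-likelihoods of the
reference base.  Under the null of equally performing models the statistic
z = sqrt(n) * mean(d) / sd(d), with d_i the per-position log-likelihood
difference (numerator minus denominator), is asymptotically standard
normal; positive z favours the numerator model.  The basic non-nested
z-statistic is implemented (no variance correction for overlapping
models).  Genome-level results are obtained by pooling the per-chromosome
sufficient statistics (sums, sums of squares, counts), equivalent to
running the test on the union sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sequences import GenomeSequence, annotation_to_mask

__all__ = [
    "RefProbArray",
    "AccuracyReport",
    "DensityGrid",
    "VuongResult",
    "reference_base_probabilities",
    "accuracy",
    "density_grid",
    "vuong_test",
    "aggregate_vuong",
    "sample_test_positions",
    "log_likelihoods",
]

#: floor applied to probabilities before taking logs, keeping tests finite
LOGP_FLOOR = 1e-12


@dataclass
class RefProbArray:
    """Per-position probability a model assigns to the reference base.

    Disqualified positions hold the imputed constant (default 0.25) and
    are flagged, so downstream spectral arrays are gap-free.
    """

    values: np.ndarray
    disqualified: np.ndarray
    imputed_value: float = 0.25
    genome_name: str = ""

    def __post_init__(self) -> None:
        if self.values.size != self.disqualified.size:
            raise ValueError("values and disqualified must have equal length")

    def __len__(self) -> int:
        return int(self.values.size)

    def save_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.values, self.disqualified.astype(int)]),
                   fmt=["%.10g", "%d"], delimiter="\t", header="value\tdisqualified",
                   comments="")


def reference_base_probabilities(results, genome: GenomeSequence,
                                 bidirectional: bool = False,
                                 imputed_value: float = 0.25) -> RefProbArray:
    """Probability the model assigns to the true base, at every position."""
    disq = results.disqualified(genome)
    values = np.full(len(genome), imputed_value)
    pos = np.flatnonzero(~disq)
    if pos.size:
        probs = results.predict_positions(genome, pos, bidirectional=bidirectional)
        values[pos] = probs[np.arange(pos.size), genome.codes[pos].astype(np.int64)]
    return RefProbArray(values, disq, imputed_value, genome.name)


@dataclass
class AccuracyReport:
    """Fraction of positions where the argmax prediction equals the true base."""

    overall: float
    n_overall: int
    per_chromosome: dict = field(default_factory=dict)   # name -> (acc, n)
    per_annotation: dict = field(default_factory=dict)   # label -> (acc, n)

    def to_frame(self) -> pd.DataFrame:
        rows = [("all", "all", self.overall, self.n_overall)]
        rows += [("chromosome", k, a, n) for k, (a, n) in self.per_chromosome.items()]
        rows += [("annotation", k, a, n) for k, (a, n) in self.per_annotation.items()]
        return pd.DataFrame(rows, columns=["stratum", "name", "accuracy", "n"])

    def summary(self) -> str:
        df = self.to_frame()
        return df.to_string(index=False, float_format=lambda x: f"{x:.4f}")


def _genome_hits(results, genome, bidirectional):
    """(correct bool array, positions) over qualified positions."""
    disq = results.disqualified(genome)
    pos = np.flatnonzero(~disq)
    if pos.size == 0:
        return np.zeros(0, dtype=bool), pos
    probs = results.predict_positions(genome, pos, bidirectional=bidirectional)
    return np.argmax(probs, axis=1) == genome.codes[pos].astype(np.int64), pos


def accuracy(results, genomes, annotations=None, bidirectional: bool = False,
             extra_masks: dict | None = None) -> AccuracyReport:
    """Accuracy overall, per chromosome, and per annotation label.

    Parameters
    ----------
    results : prediction-contract object
    genomes : GenomeSequence or list thereof
    annotations : AnnotationSet, optional
        Labels are stratified via half-open interval masks.  The built-in
        ``repeat`` stratum from soft-masking is always reported when any
        repeat flags are set.
    bidirectional : bool
        Use the strand-averaged predictor.
    extra_masks : dict, optional
        label -> {chrom name -> bool array} for caller-supplied strata.
    """
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    total_hits = 0
    total_n = 0
    per_chrom = {}
    ann_hits: dict = {}
    ann_n: dict = {}
    labels = list(annotations.labels) if annotations is not None else []
    for genome in genomes:
        hits, pos = _genome_hits(results, genome, bidirectional)
        n = pos.size
        if n:
            per_chrom[genome.name] = (float(hits.mean()), int(n))
        total_hits += int(hits.sum())
        total_n += int(n)
        strata = {}
        for label in labels:
            strata[label] = annotation_to_mask(annotations, genome.name, len(genome), label)
        if genome.repeat_flags.any():
            strata.setdefault("repeat", genome.repeat_flags)
        if extra_masks:
            for label, per_genome in extra_masks.items():
                if genome.name in per_genome:
                    strata[label] = per_genome[genome.name]
        for label, mask in strata.items():
            sel = mask[pos]
            if sel.any():
                ann_hits[label] = ann_hits.get(label, 0) + int(hits[sel].sum())
                ann_n[label] = ann_n.get(label, 0) + int(sel.sum())
    if total_n == 0:
        raise ValueError("no qualified positions to score")
    per_annotation = {lab: (ann_hits[lab] / ann_n[lab], ann_n[lab]) for lab in ann_n}
    return AccuracyReport(total_hits / total_n, total_n, per_chrom, per_annotation)


@dataclass
class DensityGrid:
    """2-D histogram of paired reference-base probabilities, 50x50 bins on [0,1]."""

    counts: np.ndarray
    bins: int = 50

    def to_frame(self) -> pd.DataFrame:
        edges = [f"{i / self.bins:.2f}" for i in range(self.bins)]
        return pd.DataFrame(self.counts, index=edges, columns=edges)


def density_grid(a: RefProbArray, b: RefProbArray, positions=None,
                 bins: int = 50) -> DensityGrid:
    """Joint density grid of two models' reference-base probabilities.

    Bin edges are i/bins for i = 0..bins; the last bin is right-closed so
    a probability of exactly 1 lands in the top bin.
    """
    if len(a) != len(b):
        raise ValueError("arrays must cover the same genome")
    if positions is None:
        keep = ~(a.disqualified | b.disqualified)
        va, vb = a.values[keep], b.values[keep]
    else:
        positions = np.asarray(positions, dtype=np.int64)
        va, vb = a.values[positions], b.values[positions]
    ia = np.minimum((va * bins).astype(np.int64), bins - 1)
    ib = np.minimum((vb * bins).astype(np.int64), bins - 1)
    counts = np.zeros((bins, bins), dtype=np.int64)
    np.add.at(counts, (ia, ib), 1)
    return DensityGrid(counts, bins)


@dataclass
class VuongResult:
    """Non-nested likelihood-ratio z-test on per-position log-likelihoods."""

    n: int
    mean_lr: float
    sd_lr: float
    z: float
    p: float
    label: str = ""

    def summary(self) -> str:
        return ("Vuong non-nested likelihood-ratio test"
                + (f" [{self.label}]" if self.label else "") + "\n"
                + "-" * 42 + "\n"
                + f"n positions   {self.n:,}\n"
                + f"mean log-LR   {self.mean_lr:.6g}\n"
                + f"sd log-LR     {self.sd_lr:.6g}\n"
                + f"z             {self.z:.4f}\n"
                + f"p (two-sided) {self.p:.3g}\n"
                + "positive z favours the numerator model")


def _vuong_from_stats(n: int, sum_d: float, sum_d2: float, label="") -> VuongResult:
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = sum_d / n
    var = (sum_d2 - n * mean * mean) / (n - 1)
    sd = float(np.sqrt(max(var, 0.0)))
    if sd == 0.0:
        raise ValueError("degenerate test: the models are identical on this sample")
    z = float(np.sqrt(n) * mean / sd)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return VuongResult(int(n), float(mean), sd, z, p, label)


def vuong_test(logp_num, logp_den, label: str = "") -> VuongResult:
    """Vuong z-test for two non-nested models scored on the same positions.

    ``logp_num`` and ``logp_den`` are per-position log-likelihoods of the
    reference base under the numerator and denominator model.
    """
    logp_num = np.asarray(logp_num, dtype=float)
    logp_den = np.asarray(logp_den, dtype=float)
    if logp_num.shape != logp_den.shape:
        raise ValueError("log-likelihood arrays must align position-wise")
    if not (np.isfinite(logp_num).all() and np.isfinite(logp_den).all()):
        raise ValueError("log-likelihoods must be finite")
    d = logp_num - logp_den
    return _vuong_from_stats(d.size, float(d.sum()), float((d * d).sum()), label)


def aggregate_vuong(per_chromosome, label: str = "genome") -> VuongResult:
    """Pool per-chromosome sufficient statistics ``(sum d, sum d^2, n)``.

    Equivalent to running the test on the union of the chromosome samples.
    """
    per_chromosome = list(per_chromosome)
    if not per_chromosome:
        raise ValueError("nothing to aggregate")
    sum_d = sum(t[0] for t in per_chromosome)
    sum_d2 = sum(t[1] for t in per_chromosome)
    n = sum(t[2] for t in per_chromosome)
    return _vuong_from_stats(n, sum_d, sum_d2, label)


def sample_test_positions(genome: GenomeSequence, mask, fraction: float = 0.10,
                          seed: int = 0) -> np.ndarray:
    """Seeded uniform sample (without replacement) of qualified positions.

    ``mask`` may be a PositionMask or a boolean disqualification array.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    disq = getattr(mask, "disqualified", mask)
    qualified = np.flatnonzero(~np.asarray(disq, dtype=bool))
    if qualified.size == 0:
        raise ValueError("no qualified positions to sample from")
    n = int(round(fraction * qualified.size))
    if fraction == 1.0:
        return qualified
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(qualified, size=n, replace=False))


def log_likelihoods(results, genome: GenomeSequence, positions,
                    bidirectional: bool = False) -> np.ndarray:
    """Natural-log likelihood of the reference base at given positions.

    Zero probabilities are floored at ``LOGP_FLOOR`` so the Vuong test
    stays finite.
    """
    positions = np.asarray(positions, dtype=np.int64)
    probs = results.predict_positions(genome, positions, bidirectional=bidirectional)
    p_ref = probs[np.arange(positions.size), genome.codes[positions].astype(np.int64)]
    return np.log(np.maximum(p_ref, LOGP_FLOOR))
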