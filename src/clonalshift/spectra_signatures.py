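"""Mutation spectra and mutational-signature analysis.

Tabulates single-nucleotide variants into the standard 96 trinucleotide
channels (six pyrimidine-strand substitution classes x 16 flanking-base
contexts), tests pre- vs post-treatment spectrum shifts with exact or
chi-square tests, and extracts nonnegative-matrix-factorisation signatures
with an automated rank-selection criterion ("maximum differentiation":
the admissible rank whose fitted signatures are most mutually distinct).

Channel ordering is alphabetical by substitution class (C>A, C>G, C>T,
T>A, T>C, T>G), then by 5' base, then by 3' base:
``channel = 16*class + 4*five_prime + three_prime``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import NMF

from ._stats import fisher_exact_2xk, sample_tables_2xk

__all__ = [
    "CLASSES6",
    "SpectrumVector",
    "SignatureModel",
    "context_channel",
    "channel_label",
    "spectrum",
    "compare_spectra",
    "fit_signatures",
    "select_rank",
    "predominant_signature",
    "signature_change",
]

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
CLASSES6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_CLASS_IDX = {c: i for i, c in enumerate(CLASSES6)}


def context_channel(ref: str, alt: str, five_prime: str, three_prime: str) -> int:
    """Map a strand-specific SNV in its trinucleotide context to a channel 0-95.

    Purine-reference mutations are reverse-complemented onto the pyrimidine
    strand, so each biological event maps to exactly one of 96 channels.
    """
    ref, alt = ref.upper(), alt.upper()
    five_prime, three_prime = five_prime.upper(), three_prime.upper()
    for b in (ref, alt, five_prime, three_prime):
        if b not in _BASE_IDX:
            raise ValueError(f"invalid base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":  # purine reference: flip strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five_prime, three_prime = _COMPLEMENT[three_prime], _COMPLEMENT[five_prime]
    cls = _CLASS_IDX[f"{ref}>{alt}"]
    return 16 * cls + 4 * _BASE_IDX[five_prime] + _BASE_IDX[three_prime]


def channel_label(channel: int) -> str:
    """Human-readable label, e.g. channel for A[C>T]G -> 'A[C>T]G'."""
    if not 0 <= channel < 96:
        raise ValueError("channel must be in 0..95")
    cls, rest = divmod(channel, 16)
    fp, tp = divmod(rest, 4)
    ref, alt = CLASSES6[cls].split(">")
    return f"{BASES[fp]}[{ref}>{alt}]{BASES[tp]}"


@dataclass
class SpectrumVector:
    """96-channel mutation counts with their 6-class marginal."""

    counts96: np.ndarray

    def __post_init__(self):
        self.counts96 = np.asarray(self.counts96, dtype=np.int64)
        if self.counts96.shape != (96,):
            raise ValueError("counts96 must have 96 entries")
        if (self.counts96 < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def counts6(self) -> np.ndarray:
        return self.counts96.reshape(6, 16).sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts96.sum())


def spectrum(variants: pd.DataFrame) -> SpectrumVector:
    """Tabulate SNVs (rows with a ``context96`` channel) into a SpectrumVector.

    Rows without a channel (indels, missing context) are skipped.
    """
    counts = np.zeros(96, dtype=np.int64)
    if len(variants):
        ch = pd.to_numeric(variants["context96"], errors="coerce")
        ch = ch[ch.notna()].astype(int)
        ch = ch[(ch >= 0) & (ch < 96)]
        np.add.at(counts, ch.to_numpy(), 1)
    return SpectrumVector(counts)


def compare_spectra(
    group_a,
    group_b,
    method: str = "fisher",
    exact_cap: int = 200,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided p-value for a difference between two 6-class spectra.

    ``method='chisq'`` runs the chi-square test of independence on the 2x6
    table; ``method='fisher'`` runs the exact conditional test (probability
    ordering) by full enumeration when the table total is at most
    ``exact_cap``, otherwise by Monte-Carlo with ``n_mc`` seeded draws.
    """
    a = group_a.counts6 if isinstance(group_a, SpectrumVector) else np.asarray(group_a, dtype=np.int64)
    b = group_b.counts6 if isinstance(group_b, SpectrumVector) else np.asarray(group_b, dtype=np.int64)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("cannot compare spectra: a group has zero total")
    table = np.vstack([a, b])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if method == "chisq":
        return float(stats.chi2_contingency(table).pvalue)
    if method != "fisher":
        raise ValueError(f"unknown method {method!r}")
    if table.sum() <= exact_cap:
        return fisher_exact_2xk(table)
    # Monte-Carlo estimate of the same probability-ordering p-value
    rng = np.random.default_rng(seed)
    c = table.sum(axis=0)
    r0 = int(table[0].sum())
    from scipy.special import gammaln

    def logp(rows0):
        rows0 = np.atleast_2d(rows0)
        return (
            gammaln(c + 1.0)
            - gammaln(rows0 + 1.0)
            - gammaln(c - rows0 + 1.0)
        ).sum(axis=1)

    lp_obs = float(logp(table[0])[0])
    draws = sample_tables_2xk(r0, c, n_mc, rng)
    lp = logp(draws)
    hits = int(np.sum(lp <= lp_obs + 1e-12 * abs(lp_obs) + 1e-12))
    return (1 + hits) / (1 + n_mc)


@dataclass
class SignatureModel:
    """NMF decomposition of a samples x 96 count matrix.

    ``signatures`` is 96 x r with column sums 1; ``exposures`` is
    r x n_samples, scaled so that signatures @ exposures approximates the
    transposed count matrix.
    """

    r: int
    signatures: np.ndarray
    exposures: np.ndarray
    reconstruction_error: float
    sample_ids: list = field(default_factory=list)

    def exposure_shares(self) -> np.ndarray:
        tot = self.exposures.sum(axis=0, keepdims=True)
        tot[tot == 0] = 1.0
        return self.exposures / tot


def fit_signatures(
    count_matrix,
    r: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 2000,
    sample_ids=None,
) -> SignatureModel:
    """Fit an r-signature NMF model (multiplicative updates, Frobenius loss).

    The best of ``restarts`` seeded random initialisations is kept; signature
    columns are normalised to sum to 1 with the exposures rescaled to match.
    """
    X = np.asarray(count_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != 96:
        raise ValueError("count_matrix must be samples x 96")
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    if r < 1:
        raise ValueError("r must be >= 1")
    n_samples = X.shape[0]
    if r > n_samples:
        raise ValueError("r may not exceed the number of samples")
    if int((X.sum(axis=1) > 0).sum()) < r:
        raise ValueError("need at least r samples with nonzero totals")

    best = None
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    for i in range(max(1, restarts)):
        nmf = NMF(
            n_components=r,
            solver="mu",
            beta_loss="frobenius",
            init="random",
            max_iter=max_iter,
            tol=1e-6,
            random_state=seed + i,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = nmf.fit_transform(X)  # samples x r (exposures)
        H = nmf.components_  # r x 96 (signatures)
        err = float(np.linalg.norm(X - W @ H, "fro"))
        if best is None or err < best[0]:
            best = (err, W, H)
    err, W, H = best
    scale = H.sum(axis=1)  # per-signature mass
    scale[scale == 0] = 1.0
    signatures = (H / scale[:, None]).T  # 96 x r, columns sum to 1
    exposures = (W * scale[None, :]).T  # r x samples
    return SignatureModel(
        r=r,
        signatures=signatures,
        exposures=exposures,
        reconstruction_error=err,
        sample_ids=list(sample_ids) if sample_ids is not None else list(range(n_samples)),
    )


def _min_pairwise_cosine_distance(signatures: np.ndarray) -> float:
    S = signatures / np.maximum(np.linalg.norm(signatures, axis=0, keepdims=True), 1e-300)
    G = S.T @ S
    r = G.shape[0]
    if r < 2:
        return 0.0
    iu = np.triu_indices(r, k=1)
    return float(np.min(1.0 - G[iu]))


def _admissible_ranks(models: dict, noise_factor: float) -> dict:
    """Ranks past the reconstruction-error elbow.

    Adding components past the true rank only absorbs sampling noise, so the
    error drops in the tail of the rank scan estimate the noise-level
    improvement.  A rank is admissible once every later per-rank drop is at
    most ``noise_factor`` times the median tail drop - i.e. all remaining
    structure is noise-sized.  A profile with no elbow (single-signature
    data) admits every rank.
    """
    ranks = sorted(models)
    errs = np.array([models[r].reconstruction_error for r in ranks])
    if len(ranks) < 3:
        return {r: True for r in ranks}
    drops = errs[:-1] - errs[1:]  # drop achieved by moving to ranks[i+1]
    tail = drops[-max(3, len(drops) // 3):]
    cutoff = noise_factor * max(np.median(tail), 1e-12)
    ok = {}
    for i, r in enumerate(ranks):
        ok[r] = bool(np.all(drops[i:] <= cutoff))
    ok[ranks[-1]] = True
    return ok


def select_rank(models: dict, noise_factor: float = 2.0, tie_tol: float = 0.15) -> int:
    """Choose the signature count by maximum differentiation.

    Among admissible ranks (see :func:`_admissible_ranks`), return the rank
    whose fitted signatures have the largest minimum pairwise cosine
    distance; components past the true rank duplicate existing signatures
    and collapse this score.  Scores within ``tie_tol`` of each other are
    considered indistinguishable (duplicate-level separation) and resolve to
    the smallest rank.
    """
    if len(models) < 2:
        raise ValueError("need models for at least two candidate ranks")
    ok = _admissible_ranks(models, noise_factor)
    best_r, best_score = None, -np.inf
    for r in sorted(models):
        if not ok[r]:
            continue
        score = _min_pairwise_cosine_distance(models[r].signatures)
        if score > best_score + tie_tol:
            best_r, best_score = r, score
    return best_r


def rank_criterion_table(models: dict, noise_factor: float = 2.0) -> pd.DataFrame:
    """Per-rank reconstruction error, separation score and admissibility."""
    ok = _admissible_ranks(models, noise_factor)
    rows = []
    for r in sorted(models):
        m = models[r]
        rows.append(
            {
                "r": r,
                "reconstruction_error": m.reconstruction_error,
                "min_pairwise_cosine_distance": _min_pairwise_cosine_distance(m.signatures),
                "admissible": ok[r],
            }
        )
    return pd.DataFrame(rows)


def predominant_signature(
    model: SignatureModel, totals=None, min_mutations: int = 50
) -> list:
    """Per-sample label of the signature with the largest exposure share.

    Samples whose mutation total is below ``min_mutations`` are labelled
    ``None`` (not assessable).  Argmax ties break to the lowest index.
    """
    shares = model.exposure_shares()
    labels = []
    for j in range(shares.shape[1]):
        if totals is not None and totals[j] < min_mutations:
            labels.append(None)
            continue
        labels.append(f"S{int(np.argmax(shares[:, j])) + 1}")
    return labels


def signature_change(pre_label, post_label) -> bool:
    """True iff both samples are assessable and their predominant labels differ."""
    return pre_label is not None and post_label is not None and pre_label != post_label
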