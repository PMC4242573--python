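"""Mutation-selection (FMutSel family) codon substitution models.

These models describe codon substitution as point mutation filtered by
selection on codon fitness. For codons i, j differing at exactly one
position with base change a -> b, the substitution rate is

    q_ij = kappa^[transition] * pistar_b * h(S_ij),
    S_ij = F_j - F_i,   h(S) = S / (1 - exp(-S)),   h(0) = 1,

where ``kappa`` is the transition/transversion ratio, ``pistar`` the
mutational base frequencies, and ``F`` a fitness assigned to each of the
61 sense codons (S is the scaled selection coefficient 2*Ne*s of the
change). The chain is reversible with stationary distribution

    pi_j  proportional to  pistar_j1 * pistar_j2 * pistar_j3 * exp(F_j).

FMutSel0 constrains F to be equal within each amino acid (19 free
parameters: codon usage evolves by mutation bias alone), while FMutSel
gives every codon its own fitness (60 free). Their likelihood-ratio test
has 41 degrees of freedom and detects selection on synonymous codon
usage. ``|Ne*s|`` per synonymous codon pair is |S|/2 under the S = 2*Ne*s
convention (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .seqio import BASES, GeneticCode, STANDARD_CODE

logger = logging.getLogger(__name__)

CODONS = STANDARD_CODE.codons
N_CODONS = len(CODONS)
_AA = sorted(set(STANDARD_CODE.codon_to_aa.values()))
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
AA_OF_CODON = np.array([_AA_INDEX[STANDARD_CODE.codon_to_aa[c]] for c in CODONS])

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _neighbor_arrays():
    """Index arrays over ordered codon pairs differing at one position."""
    src, dst, tgt_base, is_ts = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            src.append(i)
            dst.append(j)
            tgt_base.append(BASES.index(cj[p]))
            is_ts.append((ci[p], cj[p]) in _TRANSITIONS)
    return (
        np.array(src), np.array(dst), np.array(tgt_base),
        np.array(is_ts, dtype=bool),
    )


_SRC, _DST, _TGT, _IS_TS = _neighbor_arrays()

#: Synonymous single-nucleotide codon pairs (ordered), used by nes_summary.
_SYN_PAIR = AA_OF_CODON[_SRC] == AA_OF_CODON[_DST]

# Base composition matrix: codon x base -> number of occurrences, for the
# stationary distribution pi_j ∝ prod_p pistar_{j_p} * exp(F_j).
_BASE_COUNT = np.zeros((N_CODONS, 4))
for _i, _c in enumerate(CODONS):
    for _b in _c:
        _BASE_COUNT[_i, BASES.index(_b)] += 1


def fixation_factor(S: np.ndarray) -> np.ndarray:
    """Relative fixation probability h(S) = S / (1 - exp(-S)), h(0) = 1."""
    S = np.asarray(S, dtype=float)
    out = np.ones_like(S)
    nz = np.abs(S) > 1e-8
    out[nz] = S[nz] / -np.expm1(-S[nz])
    small = ~nz
    out[small] = 1.0 + S[small] / 2.0
    return out


def stationary_distribution(pi_star: np.ndarray, F: np.ndarray) -> np.ndarray:
    """pi_j ∝ pistar_j1 * pistar_j2 * pistar_j3 * exp(F_j) over 61 codons."""
    log_pi = _BASE_COUNT @ np.log(np.asarray(pi_star, dtype=float)) + F
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    return pi / pi.sum()


def build_rate_matrix(
    kappa: float,
    pi_star: np.ndarray,
    F: np.ndarray,
    normalize: bool = True,
) -> np.ndarray:
    """61x61 reversible generator of the mutation-selection model.

    Rates are zero for multi-nucleotide changes; the diagonal makes rows
    sum to zero. When ``normalize`` is set the matrix is scaled so the
    stationary flow is one expected substitution per unit branch length.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    pi_star = np.asarray(pi_star, dtype=float)
    F = np.asarray(F, dtype=float)
    mu = np.where(_IS_TS, kappa, 1.0) * pi_star[_TGT]
    S = F[_DST] - F[_SRC]
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[_SRC, _DST] = mu * fixation_factor(S)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        pi = stationary_distribution(pi_star, F)
        rate = -float(pi @ np.diag(Q))
        if rate > 0:
            Q /= rate
    return Q


def transition_probabilities(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) via the symmetric eigendecomposition of a
    reversible generator (D^1/2 Q D^-1/2 is symmetric for D = diag(pi))."""
    d = np.sqrt(pi)
    A = (Q * d[:, None]) / d[None, :]
    A = 0.5 * (A + A.T)  # enforce exact symmetry against round-off
    w, V = np.linalg.eigh(A)
    P = (V * np.exp(w * t)) @ V.T
    P = P / d[:, None] * d[None, :]
    return np.clip(P, 0.0, None)


@dataclass
class CodonModelFit:
    """Maximum-likelihood fit of an FMutSel-family model to a codon pair."""

    model: str  # "FMutSel0" | "FMutSel"
    kappa: float
    pi_star: np.ndarray
    fitness: np.ndarray  # length 61, identified by one fixed zero
    t: float
    log_likelihood: float
    converged: bool = True
    n_codons: int = 0
    n_starts: int = 1
    message: str = ""

    @property
    def n_parameters(self) -> int:
        return 5 + (19 if self.model == "FMutSel0" else 60)


@dataclass
class LRTResult:
    """Likelihood-ratio test of FMutSel against FMutSel0."""

    statistic: float
    df: int
    p: float
    significant: bool
    alpha: float = 0.05


def _pair_counts(alignment) -> np.ndarray:
    """Aggregate a two-sequence in-frame codon alignment to a 61x61 count
    matrix; codons outside the sense set raise ValueError."""
    if isinstance(alignment, np.ndarray):
        return alignment
    (seq_a, seq_b) = alignment
    if len(seq_a) != len(seq_b) or len(seq_a) % 3:
        raise ValueError("pair alignment must be equal-length and in frame")
    counts = np.zeros((N_CODONS, N_CODONS))
    idx = STANDARD_CODE.codon_index
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k: k + 3].upper(), seq_b[k: k + 3].upper()
        if ca not in idx or cb not in idx:
            raise ValueError(f"non-sense codon in alignment: {ca}/{cb}")
        counts[idx[ca], idx[cb]] += 1
    return counts


def pair_log_likelihood(
    alignment,
    kappa: float,
    pi_star: np.ndarray,
    F: np.ndarray,
    t: float,
) -> float:
    """log L = sum_sites log( pi_i * P_ij(t) ) for observed codon pairs.

    The model is reversible, so swapping the two sequences leaves the
    likelihood unchanged.
    """
    counts = _pair_counts(alignment)
    pi = stationary_distribution(pi_star, F)
    Q = build_rate_matrix(kappa, pi_star, F)
    P = transition_probabilities(Q, pi, max(t, 0.0))
    joint = pi[:, None] * P
    nz = counts > 0
    return float(np.sum(counts[nz] * np.log(np.clip(joint[nz], 1e-300, None))))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _unpack(x: np.ndarray, model: str):
    kappa = np.exp(x[0])
    logits = np.concatenate([x[1:4], [0.0]])
    pi_star = np.exp(logits - logits.max())
    pi_star /= pi_star.sum()
    t = np.exp(x[4])
    if model == "FMutSel0":
        F_aa = np.concatenate([[0.0], x[5:]])  # first amino acid fixed at 0
        F = F_aa[AA_OF_CODON]
    else:
        F = np.concatenate([[0.0], x[5:]])  # first codon fixed at 0
    return kappa, pi_star, F, t


def _initial_point(counts: np.ndarray, model: str) -> np.ndarray:
    """Moment-style starting values from the empirical pair counts."""
    freq = counts.sum(axis=0) + counts.sum(axis=1)
    total = freq.sum()
    f = (freq + 0.5) / (total + 0.5 * N_CODONS)
    base = (_BASE_COUNT.T @ f) / 3.0
    base = np.clip(base, 1e-4, None)
    base /= base.sum()
    p_diff = 1.0 - np.trace(counts) / max(counts.sum(), 1.0)
    t0 = max(p_diff, 1e-3) * 1.5
    # residual log-frequency after removing the mutational expectation
    log_mut = _BASE_COUNT @ np.log(base)
    F0 = np.log(f) - log_mut
    if model == "FMutSel0":
        F_aa = np.array(
            [np.mean(F0[AA_OF_CODON == a]) for a in range(len(_AA))]
        )
        F_aa -= F_aa[0]
        tail = F_aa[1:]
    else:
        F0 -= F0[0]
        tail = F0[1:]
    logits = np.log(base) - np.log(base[3])
    return np.concatenate([[np.log(2.0)], logits[:3], [np.log(t0)], tail])


def fit_model(
    alignment,
    model: str = "FMutSel0",
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> CodonModelFit:
    """Fit FMutSel0 or FMutSel to a pairwise codon alignment by ML.

    Maximizes the pair likelihood over kappa, mutational base frequencies,
    branch length, and fitness parameters (19 amino-acid fitnesses for
    FMutSel0, 60 codon fitnesses for FMutSel; one reference fixed at 0)
    with quasi-Newton restarts jittered from a moment-based start.
    """
    if model not in ("FMutSel0", "FMutSel"):
        raise ValueError(f"unknown model {model!r}")
    counts = _pair_counts(alignment)
    n_codons = int(counts.sum())

    def nll(x: np.ndarray) -> float:
        kappa, pi_star, F, t = _unpack(x, model)
        try:
            return -pair_log_likelihood(counts, kappa, pi_star, F, t)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    x0 = _initial_point(counts, model)
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, 0.25, size=x0.shape)
        res = optimize.minimize(
            nll, xs, method="L-BFGS-B",
            options={"ftol": tol, "maxiter": max_iter, "maxcor": 20},
        )
        if best is None or res.fun < best.fun:
            best = res
    kappa, pi_star, F, t = _unpack(best.x, model)
    converged = bool(best.success) and np.isfinite(best.fun)
    if not converged:
        logger.warning("fit_model(%s): optimizer flag %s", model, best.message)
    return CodonModelFit(
        model=model,
        kappa=float(kappa),
        pi_star=pi_star,
        fitness=F,
        t=float(t),
        log_likelihood=-float(best.fun),
        converged=converged,
        n_codons=n_codons,
        n_starts=n_starts,
        message=str(best.message),
    )


def lrt_critical_value(df: int = 41, alpha: float = 0.05) -> float:
    """Upper-alpha chi-square critical value (56.94 for df=41, alpha=.05)."""
    return float(stats.chi2.ppf(1.0 - alpha, df))


def lrt(
    fit0: CodonModelFit,
    fit1: CodonModelFit,
    df: int = 41,
    alpha: float = 0.05,
) -> LRTResult:
    """Likelihood-ratio test of the nested FMutSel0 within FMutSel."""
    if df <= 0:
        raise ValueError("df must be positive")
    statistic = max(0.0, 2.0 * (fit1.log_likelihood - fit0.log_likelihood))
    p = float(stats.chi2.sf(statistic, df))
    return LRTResult(statistic=statistic, df=df, p=p, significant=p < alpha, alpha=alpha)


def nes_summary(
    fit: CodonModelFit,
    usage: np.ndarray | None = None,
    s_convention: float = 2.0,
) -> dict[str, float]:
    """Per-gene |Ne*s| over synonymous single-nucleotide codon pairs.

    For each such ordered pair (i, j), |Ne*s| = |F_j - F_i| / s_convention
    (the default treats S as 2*Ne*s). Returns the unweighted median over
    pairs and a median weighted by gene codon usage of the two codons.
    """
    F = fit.fitness
    vals = np.abs(F[_DST[_SYN_PAIR]] - F[_SRC[_SYN_PAIR]]) / s_convention
    if vals.size == 0:
        return {"median_abs_nes": 0.0, "median_abs_nes_weighted": 0.0}
    out = {"median_abs_nes": float(np.median(vals))}
    if usage is None:
        out["median_abs_nes_weighted"] = out["median_abs_nes"]
    else:
        w = usage[_SRC[_SYN_PAIR]] + usage[_DST[_SYN_PAIR]]
        if w.sum() <= 0:
            out["median_abs_nes_weighted"] = out["median_abs_nes"]
        else:
            order = np.argsort(vals)
            cw = np.cumsum(w[order])
            out["median_abs_nes_weighted"] = float(
                vals[order][np.searchsorted(cw, 0.5 * cw[-1])]
            )
    return out
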