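"""Stage (iii): sigmoid regression, R scoring, permutation p-values, gene ranking.

Each methylation-expression association is fitted with the three-parameter
monotone-decreasing logistic E_fit(M) = a / (1 + exp(b (M - c))).  Fit
quality is scored by

    R = SSR / (SSR + SSE),
    SSR = sum((E_fit - mean(E))^2),   SSE = sum((E_fit - E)^2),

which lies in [0, 1] and equals 1 exactly when the fit is perfect
(SSE = 0 with nonconstant fitted values).  Significance is a permutation
p-value: the methylation vector is shuffled against the fixed expression
vector M_perm times, the curve is refitted from scratch on each shuffle,
and p is the fraction of permuted fits whose R meets or exceeds the
observed R.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from . import _sigfit
from .datatypes import Association, FitResult, RankedGene

logger = logging.getLogger(__name__)

DEFAULT_M_PERM = 10_000
DEFAULT_ALPHA = 0.05
MIN_PAIRS = 4  # three free parameters plus one


class FitSkipped(Exception):
    """Raised when an association cannot be fitted (too few paired values)."""


def _paired(M: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    M = np.asarray(M, dtype=float)
    E = np.asarray(E, dtype=float)
    ok = np.isfinite(M) & np.isfinite(E)
    return M[ok], E[ok]


def compute_R(ssr: float, sse: float) -> float:
    """R = SSR / (SSR + SSE); 0 by convention when both sums vanish."""
    if ssr < 0 or sse < 0:
        raise ValueError("SSR and SSE must be nonnegative")
    total = ssr + sse
    if total == 0:
        return 0.0
    return ssr / total


def _result_from(M: np.ndarray, E: np.ndarray, a: float, b: float, c: float) -> FitResult:
    E_fit = _sigfit.sigmoid(M, a, b, c)
    ssr = float(((E_fit - E.mean()) ** 2).sum())
    sse = float(((E_fit - E) ** 2).sum())
    return FitResult(a=float(a), b=float(b), c=float(c), E_fit=E_fit,
                     SSR=ssr, SSE=sse, R=compute_R(ssr, sse), n_pairs=M.size)


def fit_curve(
    M_profile: np.ndarray,
    E_profile: np.ndarray,
    restarts: int = 11,
    seed: int = 0,
) -> FitResult:
    """Multi-start constrained least-squares fit of the decreasing sigmoid.

    Pairs with a missing value on either side are dropped; fewer than four
    remaining pairs raises :class:`FitSkipped`.  The fit is deterministic:
    it always runs the nine canonical starts plus two grid-seeded ones
    (``restarts`` and ``seed`` are accepted for interface stability; the
    start set is deterministic and seed-free).
    """
    M, E = _paired(M_profile, E_profile)
    if M.size < MIN_PAIRS:
        raise FitSkipped(
            f"only {M.size} non-missing pairs, need >= {MIN_PAIRS}"
        )
    if np.ptp(E) == 0.0:
        # constant expression: the exact degenerate fit, R = 0 by convention
        return FitResult(a=float(2 * E[0]), b=0.0, c=float(np.median(M)),
                         E_fit=E.copy(), SSR=0.0, SSE=0.0, R=0.0,
                         n_pairs=M.size)
    out = _sigfit.fit_pairs(M[None, :], E[None, :])
    a, b, c, _ = out[0]
    return _result_from(M, E, a, b, c)


def permutation_pvalue(
    M_profile: np.ndarray,
    E_profile: np.ndarray,
    R_obs: float,
    M_perm: int = DEFAULT_M_PERM,
    seed: int = 0,
    add_one: bool = False,
) -> float:
    """Permutation p-value for an observed R.

    Each permutation shuffles the methylation values uniformly at random
    against the fixed expression vector and refits the curve from scratch;
    p = #{m : R_m >= R_obs} / M_perm.  ``add_one=True`` switches to the
    (# + 1) / (M_perm + 1) convention.

    Exact ties between R_obs and an R_m (within 1e-9) are resolved by the
    classical randomized-test rule: a seeded uniform share of the tied
    permutations counts as exceedances.  Ties arise only for associations
    with no decreasing trend at all, where the constrained fit degenerates
    to the constant curve for the original and the permuted data alike;
    counting every such tie as an exceedance would make the null p-value
    distribution pile up at 1 instead of being uniform.  Associations with
    any signal are unaffected.
    """
    if M_perm < 1:
        raise ValueError("M_perm must be >= 1")
    M, E = _paired(M_profile, E_profile)
    rng = np.random.default_rng(seed)
    perms = np.empty((M_perm, M.size))
    for m in range(M_perm):
        perms[m] = rng.permutation(M)
    Es = np.broadcast_to(E, (M_perm, E.size))
    out = _sigfit.fit_pairs(perms, np.ascontiguousarray(Es))
    # R_m from each refit's SSR/SSE on the permuted data, vectorized
    a, b, c, sse = out[:, 0:1], out[:, 1:2], out[:, 2:3], out[:, 3]
    z = np.clip(b * (perms - c), -500.0, 500.0)
    E_fit = a / (1.0 + np.exp(z))
    ssr = ((E_fit - E.mean()) ** 2).sum(axis=1)
    total = ssr + sse
    R_m = np.divide(ssr, total, out=np.zeros_like(ssr), where=total > 0)
    tol = 1e-9
    n_gt = int((R_m > R_obs + tol).sum())
    n_tie = int((np.abs(R_m - R_obs) <= tol).sum())
    count = n_gt + int(np.round(rng.random() * n_tie))
    if add_one:
        return (count + 1) / (M_perm + 1)
    return count / M_perm


def score_associations(
    associations: list[Association],
    M_perm: int = DEFAULT_M_PERM,
    seed: int = 0,
    add_one: bool = False,
) -> tuple[list[tuple[Association, FitResult, float]], list[tuple[Association, str]]]:
    """Fit and permutation-test every association.

    Per-association permutation seeds derive deterministically from the run
    seed and the association id, so results do not depend on iteration
    order.  Returns (scored, skipped-with-reason).
    """
    import zlib

    scored: list[tuple[Association, FitResult, float]] = []
    skipped: list[tuple[Association, str]] = []
    for assoc in associations:
        try:
            fit = fit_curve(assoc.M_profile, assoc.E_profile)
        except FitSkipped as e:
            skipped.append((assoc, str(e)))
            continue
        sub = (zlib.crc32(assoc.assoc_id.encode()) ^ (seed * 2654435761)) % (2**31)
        p = permutation_pvalue(
            assoc.M_profile, assoc.E_profile, fit.R,
            M_perm=M_perm, seed=sub, add_one=add_one,
        )
        scored.append((assoc, fit, p))
    if skipped:
        logger.info("score_associations: skipped %d association(s)", len(skipped))
    return scored, skipped


def rank_genes(
    scored: list[tuple[Association, FitResult, float]],
    alpha: float = DEFAULT_ALPHA,
) -> list[RankedGene]:
    """Per gene, keep the association with maximal R (ties: smaller p, then
    lexicographic assoc_id); retain genes with p < alpha; sort by descending R."""
    best: dict[str, tuple[Association, FitResult, float]] = {}
    for assoc, fit, p in scored:
        cur = best.get(assoc.gene)
        if cur is None:
            best[assoc.gene] = (assoc, fit, p)
            continue
        key_new = (-fit.R, p, assoc.assoc_id)
        key_cur = (-cur[1].R, cur[2], cur[0].assoc_id)
        if key_new < key_cur:
            best[assoc.gene] = (assoc, fit, p)
    ranked = [
        RankedGene(
            gene=gene, assoc_id=a.assoc_id, region_id=a.region_id,
            cluster=a.cluster, probeset_id=a.probeset_id,
            R=f.R, p_value=p, fit=f,
        )
        for gene, (a, f, p) in best.items()
        if p < alpha
    ]
    ranked.sort(key=lambda rg: (-rg.R, rg.p_value, rg.gene))
    if not ranked:
        logger.warning("rank_genes: no gene passed the p < %.3g filter", alpha)
    return ranked
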