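"""Model-based clustering: admixture-model Gibbs sampler and Evanno delta-K.

Each individual's genome is a mixture over K ancestral populations with
proportions ``Q``; each allele copy at marker ``l`` comes from cluster
``k`` with probability ``q_ik`` and is then the counted allele with
probability ``p_kl``.  Priors: independent Uniform(0,1) on every
``p_kl`` and symmetric Dirichlet(alpha) on each ``Q`` row.  One Gibbs
sweep resamples (i) per-copy cluster labels, (ii) ``P`` rows from Beta
posteriors, (iii) ``Q`` rows from Dirichlet posteriors.

The model log-probability reported per fit is the standard harness
statistic ``lnP_D = mean(loglik trace) - var(loglik trace)/2`` over the
sampling sweeps, which is what the delta-K model-choice criterion
consumes:

    delta_K(K) = | mean_L(K+1) - 2 mean_L(K) + mean_L(K-1) | / sd_runs(L(K))

with per-K means/sds taken over independent runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

_LOG2 = float(np.log(2.0))


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray            # (n_samples, K) posterior-mean memberships
    P: np.ndarray            # (K, n_markers) posterior-mean frequencies
    lnP_D: float
    loglik_trace: np.ndarray  # sampling sweeps only
    n_burnin: int
    n_sweeps: int
    seed: int
    sample_ids: list[str]


def _data_loglik(x, obs, Q, P) -> float:
    """log P(X | Q, P): per-genotype binomial with mixture copy prob."""
    f = Q @ P  # (n, L) per-copy probability of the counted allele
    f = np.clip(f, 1e-300, 1.0 - 1e-16)
    ll = x * np.log(f) + (2.0 - x) * np.log1p(-f)
    ll = ll + (x == 1) * _LOG2  # binomial coefficient C(2,1)
    return float(ll[obs].sum())


def gibbs_admixture(
    gm: GenotypeMatrix,
    K: int,
    n_burnin: int = 5_000,
    n_sweeps: int = 10_000,
    seed: int = 0,
    alpha_prior: float = 1.0,
) -> AdmixtureFit:
    """Fit the K-cluster admixture model by Gibbs sampling.

    Deterministic given ``(seed, data, K)``.  Missing dosages are
    excluded from assignment counts and from the likelihood.  Posterior
    means of ``Q`` and ``P`` are accumulated over the sampling sweeps.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_samples:
        raise ValueError(f"K={K} exceeds sample count {gm.n_samples}")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = np.random.default_rng(seed)

    X = gm.dosage
    obs = X != MISSING
    x = np.where(obs, X, 0).astype(np.float64)
    n, L = x.shape

    # copy c carries the counted allele iff dosage > c (c in {0,1})
    carries = np.stack([x > 0, x > 1])  # (2, n, L) bool
    obs2 = np.broadcast_to(obs, (2, n, L))

    Q = rng.dirichlet([alpha_prior] * K, size=n)          # (n, K)
    P = rng.uniform(size=(K, L))                          # (K, L)

    Q_acc = np.zeros_like(Q)
    P_acc = np.zeros_like(P)
    ll_trace = np.empty(n_sweeps)

    ks = np.arange(K)
    for sweep in range(n_burnin + n_sweeps):
        # (i) per-copy cluster labels
        w_b = Q[:, None, :] * P.T[None, :, :]             # (n, L, K)
        w_a = Q[:, None, :] * (1.0 - P).T[None, :, :]
        z = np.empty((2, n, L), dtype=np.int64)
        for c in range(2):
            w = np.where(carries[c][:, :, None], w_b, w_a)
            cum = np.cumsum(w, axis=2)
            u = rng.random((n, L)) * cum[:, :, -1]
            z[c] = (cum < u[:, :, None]).sum(axis=2)

        # (ii) allele frequencies
        cnt_tot = np.empty((K, L))
        cnt_b = np.empty((K, L))
        m_ik = np.empty((n, K))
        for k in ks:
            hit0 = (z[0] == k) & obs
            hit1 = (z[1] == k) & obs
            cnt_tot[k] = hit0.sum(axis=0) + hit1.sum(axis=0)
            cnt_b[k] = (hit0 & carries[0]).sum(axis=0) + (hit1 & carries[1]).sum(axis=0)
            m_ik[:, k] = hit0.sum(axis=1) + hit1.sum(axis=1)
        P = rng.beta(1.0 + cnt_b, 1.0 + cnt_tot - cnt_b)

        # (iii) membership proportions (normalised gammas = Dirichlet)
        g = rng.gamma(alpha_prior + m_ik)
        Q = g / g.sum(axis=1, keepdims=True)

        if sweep >= n_burnin:
            t = sweep - n_burnin
            Q_acc += Q
            P_acc += P
            ll_trace[t] = _data_loglik(x, obs, Q, P)

    mu = float(ll_trace.mean())
    var = float(ll_trace.var(ddof=1)) if n_sweeps > 1 else 0.0
    return AdmixtureFit(
        K=K,
        Q=Q_acc / n_sweeps,
        P=P_acc / n_sweeps,
        lnP_D=mu - var / 2.0,
        loglik_trace=ll_trace,
        n_burnin=n_burnin,
        n_sweeps=n_sweeps,
        seed=seed,
        sample_ids=list(gm.sample_ids),
    )


def multi_run(
    gm: GenotypeMatrix,
    k_range,
    n_runs: int = 5,
    n_burnin: int = 5_000,
    n_sweeps: int = 10_000,
    base_seed: int = 0,
    alpha_prior: float = 1.0,
    keep_fits: bool = True,
) -> tuple[pd.DataFrame, dict[tuple[int, int], AdmixtureFit]]:
    """Independent seeded fits over a K grid; feeds the delta-K table.

    Run ``r`` of ``K`` uses seed ``base_seed + 1000*K + r`` so every
    fit is independent yet reproducible.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 (run sd undefined otherwise)")
    rows = []
    fits: dict[tuple[int, int], AdmixtureFit] = {}
    for K in k_range:
        for r in range(n_runs):
            seed = base_seed + 1000 * int(K) + r
            fit = gibbs_admixture(
                gm, int(K), n_burnin=n_burnin, n_sweeps=n_sweeps,
                seed=seed, alpha_prior=alpha_prior,
            )
            rows.append({"K": int(K), "run": r, "seed": seed, "lnP_D": fit.lnP_D})
            if keep_fits:
                fits[(int(K), r)] = fit
    return pd.DataFrame(rows, columns=["K", "run", "seed", "lnP_D"]), fits


def evanno_delta_k(run_table: pd.DataFrame) -> pd.DataFrame:
    """Delta-K table from a ``(K, run, lnP_D)`` grid.

    Requires >= 3 consecutive K values with >= 2 runs each.  The second
    difference is taken over per-K run means; the denominator is the
    across-run standard deviation (ddof=1) of L(K).  Rows with zero sd
    get NaN and are flagged.
    """
    grp = run_table.groupby("K")["lnP_D"]
    m = grp.mean()
    s = grp.std(ddof=1)
    n = grp.count()
    ks = np.asarray(sorted(m.index))
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValueError(">=3 consecutive K values required")
    if (n < 2).any():
        raise ValueError(">=2 runs per K required")

    rows = []
    for K in ks:
        rec = {
            "K": int(K),
            "n_runs": int(n[K]),
            "mean_lnP_D": float(m[K]),
            "sd_lnP_D": float(s[K]),
            "delta_K": np.nan,
            "sd_zero": False,
        }
        if K - 1 in m.index and K + 1 in m.index:
            num = abs(m[K + 1] - 2.0 * m[K] + m[K - 1])
            if s[K] > 0:
                rec["delta_K"] = float(num / s[K])
            else:
                rec["sd_zero"] = True
        rows.append(rec)
    return pd.DataFrame(rows)


def best_k(delta_table: pd.DataFrame) -> int:
    """argmax of delta-K over interior K values."""
    valid = delta_table.dropna(subset=["delta_K"])
    if valid.empty:
        raise ValueError("no K with defined delta_K")
    return int(valid.loc[valid["delta_K"].idxmax(), "K"])


# ---------------------------------------------------------------------------
# label-switching resolution
# ---------------------------------------------------------------------------

def _column_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two membership columns; constant-safe."""
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return -float(np.mean((a - b) ** 2))  # fall back to closeness
    return float(np.corrcoef(a, b)[0, 1])


def align_to_reference(fit: AdmixtureFit, reference_q: np.ndarray) -> AdmixtureFit:
    """Permute cluster labels to best match a reference Q (greedy)."""
    K = fit.K
    sim = np.array(
        [
            [_column_similarity(reference_q[:, i], fit.Q[:, j]) for j in range(K)]
            for i in range(K)
        ]
    )
    perm = np.full(K, -1)
    used_ref, used_col = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(sim, axis=None)[::-1], sim.shape))[0]
    for i, j in order:
        if i in used_ref or j in used_col:
            continue
        perm[i] = j
        used_ref.add(int(i))
        used_col.add(int(j))
        if len(used_ref) == K:
            break
    fit.Q = fit.Q[:, perm]
    fit.P = fit.P[perm, :]
    return fit


def align_q_across_runs(fits: list[AdmixtureFit]) -> list[AdmixtureFit]:
    """Align cluster labels of every fit to the first run."""
    if not fits:
        return fits
    K = fits[0].K
    n = fits[0].Q.shape[0]
    for f in fits[1:]:
        if f.K != K or f.Q.shape[0] != n:
            raise ValueError("fits must share K and sample count")
    ref = fits[0].Q
    return [fits[0]] + [align_to_reference(f, ref) for f in fits[1:]]


def best_permutation_error(q: np.ndarray, q_true: np.ndarray) -> float:
    """min over label permutations of mean |Q - Q_true| (exhaustive)."""
    K = q.shape[1]
    if K > 8:
        raise ValueError("exhaustive alignment limited to K <= 8")
    best = np.inf
    for perm in itertools.permutations(range(K)):
        err = float(np.mean(np.abs(q[:, perm] - q_true)))
        best = min(best, err)
    return best
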